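"""Synthetic stop-signal (SST) and cued stop-signal (CSST) session generator.

Go finish times are ex-Gaussian; the stop process is an independent racer
with a fixed latency (true SSRT), so a response occurs on a stop trial iff
the go process finishes before SSD + SSRT.  The stop-signal delay follows a
1-up/1-down staircase (start 200 ms, step 50 ms) that tracks ~50% stop
accuracy.  Proactive control enters the go finish time additively: a context
cost on uncertain-cue CSST trials, a post-error cost on trials immediately
following an unsuccessful stop, and an anticipation cost proportional to
the deviation of the subject's internal trial-wise stop expectation from
the task's baseline stop rate, the expectation being produced by the
dynamic belief model with the subject's own forgetting parameter.

Group presets reproduce the direction (and approximate magnitude) of
reported TD vs ADHD differences: longer SSRT, smaller post-error slowing and
weaker anticipatory slowing in the ADHD group.  Symptom scores are noisy
linear functions of the latent control parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from dualcontrol.dbm import DBMConfig, dbm_forward
from dualcontrol.trial_data import (
    TrialRecord,
    trials_to_frame,
    write_subjects,
    write_trials,
)

SSD_START = 200.0
SSD_STEP = 50.0
SSD_MAX = 900.0

SST_N_GO = 64
SST_N_STOP = 32
CSST_N_CERTAIN = 32
CSST_N_UNCERTAIN = 32
CSST_N_STOP = 16


def staircase_update(ssd: float, stop_succeeded: bool, ssd_max: float = SSD_MAX) -> float:
    """1-up/1-down SSD tracking: +50 ms after a successful stop, -50 after a
    failed one, clamped to [0, ssd_max]."""
    if ssd < 0:
        raise ValueError("ssd must be >= 0")
    step = SSD_STEP if stop_succeeded else -SSD_STEP
    return float(min(max(ssd + step, 0.0), ssd_max))


@dataclass(frozen=True)
class SubjectProfile:
    """Latent generative parameters of one simulated subject.

    mu, sigma, tau : ex-Gaussian go-finish-time parameters (ms).
    ssrt_true : latency of the stop process (ms).
    beta_context : ms added to the go finish on uncertain-cue CSST trials.
    beta_pes : ms added on trials following an unsuccessful stop.
    beta_antic : ms per unit of internal p_stop (anticipatory slowing).
    alpha_gen : forgetting parameter of the subject's internal belief model.
    stop_noise_sd : SD of the stop-process latency; 0 (default) makes the
        true SSRT exactly recoverable by the integration method.
    """

    subject_id: str
    group: str
    mu: float
    sigma: float
    tau: float
    ssrt_true: float
    p_choice_error: float = 0.05
    p_omission: float = 0.03
    beta_context: float = 0.0
    beta_pes: float = 0.0
    beta_antic: float = 0.0
    alpha_gen: float = 0.3
    stop_noise_sd: float = 0.0

    def __post_init__(self) -> None:
        if min(self.mu, self.sigma, self.tau, self.ssrt_true) <= 0:
            raise ValueError("mu, sigma, tau, ssrt_true must be > 0")
        for p in (self.p_choice_error, self.p_omission):
            if not (0.0 <= p <= 1.0):
                raise ValueError("probabilities must be in [0, 1]")


def simulate_trial(
    profile: SubjectProfile,
    trial_type: str,
    ssd: float | None,
    p_stop_current: float | None,
    post_error_state: bool,
    rng: np.random.Generator,
    uncertain_cue: bool = False,
    pm_baseline: float = 1.0 / 3.0,
) -> dict:
    """Simulate one trial; returns responded / choice_correct / rt fields.

    The go finish time is ex-Gaussian plus the additive proactive terms
    (context cost when ``uncertain_cue`` on the CSST, post-error cost,
    anticipation cost).  Anticipatory slowing is relative to the baseline
    stop expectation: beta_antic * (p_stop - pm), so that a subject whose
    belief sits at the task's true stop rate shows no net slowing and the
    preset go-RT mean is the observed mean.  ``p_stop_current=None`` (e.g.
    certain-cue trials) disables the term.  On stop trials a response
    occurs iff the go process wins the race against SSD + SSRT (and the
    trial is not an omission).
    """
    g = profile.mu + rng.normal(0.0, profile.sigma) + rng.exponential(profile.tau)
    if uncertain_cue:
        g += profile.beta_context
    if p_stop_current is not None:
        g += profile.beta_antic * (p_stop_current - pm_baseline)
    if post_error_state:
        g += profile.beta_pes
    g = max(g, 1.0)

    omitted = rng.random() < profile.p_omission
    if trial_type == "stop":
        if ssd is None:
            raise ValueError("stop trial requires an ssd")
        stop_finish = ssd + profile.ssrt_true
        if profile.stop_noise_sd > 0:
            stop_finish += rng.normal(0.0, profile.stop_noise_sd)
        responded = (g < stop_finish) and not omitted
    else:
        responded = not omitted
    if responded:
        correct = rng.random() >= profile.p_choice_error
        return {"responded": True, "choice_correct": bool(correct), "rt": float(g)}
    return {"responded": False, "choice_correct": None, "rt": None}


def _trial_plan(task: str, rng: np.random.Generator) -> list[str]:
    if task == "SST":
        plan = ["go"] * SST_N_GO + ["stop"] * SST_N_STOP
    elif task == "CSST":
        plan = (
            ["certain_go"] * CSST_N_CERTAIN
            + ["uncertain_go"] * CSST_N_UNCERTAIN
            + ["stop"] * CSST_N_STOP
        )
    else:
        raise ValueError(f"unknown task {task!r}")
    return list(rng.permutation(plan))


def simulate_session(
    profile: SubjectProfile,
    task: str,
    run: int,
    rng: np.random.Generator | int,
    dbm_cfg: DBMConfig | None = None,
) -> list[TrialRecord]:
    """Simulate one run of the SST (96 trials) or CSST (80 trials).

    The subject's internal stop-signal expectation is the DBM forward pass
    (with ``alpha_gen``) over the planned trial-type sequence — for the CSST
    over uncertain-cue trials only, since certain-go cues rule stops out.
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    plan = _trial_plan(task, rng)

    base = dbm_cfg or DBMConfig(grid_size=500)
    cfg = replace(base, alpha=profile.alpha_gen)
    p_stop = np.zeros(len(plan))
    cued = [t != "certain_go" for t in plan]
    idx = np.flatnonzero(cued)
    if len(idx):
        seq = np.array([plan[i] == "stop" for i in idx], dtype=int)
        p_stop[idx], _ = dbm_forward(seq, cfg)

    records: list[TrialRecord] = []
    ssd = SSD_START
    prev_unsucc_stop = False
    for k, ttype in enumerate(plan):
        trial_ssd = ssd if ttype == "stop" else None
        outcome = simulate_trial(
            profile,
            ttype,
            trial_ssd,
            p_stop[k] if cued[k] else None,
            prev_unsucc_stop,
            rng,
            uncertain_cue=(task == "CSST" and cued[k]),
        )
        records.append(
            TrialRecord(
                subject_id=profile.subject_id,
                group=profile.group,
                task=task,
                run=run,
                trial_index=k + 1,
                trial_type=ttype,
                ssd=trial_ssd,
                **outcome,
            )
        )
        if ttype == "stop":
            prev_unsucc_stop = outcome["responded"]
            ssd = staircase_update(ssd, stop_succeeded=not outcome["responded"])
        else:
            prev_unsucc_stop = False
    return records


@dataclass(frozen=True)
class GroupPreset:
    """Group-level means/SDs from which SubjectProfiles are drawn."""

    go_rt_mean: float
    go_rt_mean_sd: float
    go_rt_sd: float
    go_rt_sd_sd: float
    ssrt_mean: float
    ssrt_sd: float
    p_choice_error: float
    p_omission: float
    beta_context_mean: float
    beta_context_sd: float
    beta_pes_mean: float
    beta_pes_sd: float
    beta_antic_mean: float
    beta_antic_sd: float
    alpha_gen: float
    age_mean: float = 11.0
    age_sd: float = 1.0
    p_female: float = 0.4
    iq_mean: float = 107.0
    iq_sd: float = 13.0


DEFAULT_PRESETS: dict[str, GroupPreset] = {
    "TD": GroupPreset(
        go_rt_mean=497.0,
        go_rt_mean_sd=61.0,
        go_rt_sd=107.0,
        go_rt_sd_sd=20.0,
        ssrt_mean=282.0,
        ssrt_sd=42.0,
        p_choice_error=0.04,
        p_omission=0.02,
        beta_context_mean=31.0,
        beta_context_sd=20.0,
        beta_pes_mean=42.0,
        beta_pes_sd=25.0,
        beta_antic_mean=500.0,
        beta_antic_sd=150.0,
        alpha_gen=0.3,
        p_female=14.0 / 30.0,
        iq_mean=109.0,
    ),
    "ADHD": GroupPreset(
        go_rt_mean=547.0,
        go_rt_mean_sd=79.0,
        go_rt_sd=138.0,
        go_rt_sd_sd=25.0,
        ssrt_mean=314.0,
        ssrt_sd=57.0,
        p_choice_error=0.06,
        p_omission=0.04,
        beta_context_mean=26.0,
        beta_context_sd=25.0,
        beta_pes_mean=13.0,
        beta_pes_sd=25.0,
        beta_antic_mean=250.0,
        beta_antic_sd=120.0,
        alpha_gen=0.3,
        p_female=16.0 / 50.0,
        iq_mean=105.0,
    ),
}

# SWAN scores = intercept + loadings . (ssrt_true - 300, beta_pes, beta_antic) + noise.
# Better control (short SSRT, large post-error and anticipatory adjustment)
# maps to higher (more normal) SWAN scores.
SWAN_MODEL = {
    "swan_inattention": {
        "intercept": -21.0,
        "load_ssrt": -0.30,
        "load_pes": 0.30,
        "load_antic": 0.024,
        "noise_sd": 6.0,
    },
    "swan_hyperimpulsivity": {
        "intercept": -14.0,
        "load_ssrt": -0.25,
        "load_pes": 0.25,
        "load_antic": 0.020,
        "noise_sd": 7.0,
    },
}


@dataclass(frozen=True)
class CohortConfig:
    """Cohort composition and reproducibility settings."""

    n_td: int = 30
    n_adhd: int = 50
    runs_per_task: int = 2
    seed: int = 0
    tasks: tuple[str, ...] = ("SST", "CSST")
    presets: dict = field(default_factory=lambda: dict(DEFAULT_PRESETS))
    dbm_grid_size: int = 500

    def __post_init__(self) -> None:
        if self.n_td < 0 or self.n_adhd < 0 or self.n_td + self.n_adhd <= 0:
            raise ValueError("cohort must contain at least one subject")
        if self.runs_per_task < 1:
            raise ValueError("runs_per_task must be >= 1")


def draw_profile(
    subject_id: str, group: str, preset: GroupPreset, rng: np.random.Generator
) -> SubjectProfile:
    """Draw one subject's latent parameters from the group preset.

    The ex-Gaussian is parameterised from the drawn go-RT mean m and SD s by
    tau = 0.7 s, sigma = sqrt(s^2 - tau^2), mu = m - tau, giving realistic
    right skew.  Because anticipatory slowing is centred on the baseline
    stop expectation, the preset go-RT mean is the observed mean RT.
    """
    beta_antic = float(max(rng.normal(preset.beta_antic_mean, preset.beta_antic_sd), 0.0))
    m = rng.normal(preset.go_rt_mean, preset.go_rt_mean_sd)
    s = max(rng.normal(preset.go_rt_sd, preset.go_rt_sd_sd), 40.0)
    tau = 0.7 * s
    sigma = float(np.sqrt(s**2 - tau**2))
    mu = max(m - tau, 150.0)
    return SubjectProfile(
        subject_id=subject_id,
        group=group,
        mu=float(mu),
        sigma=sigma,
        tau=float(tau),
        ssrt_true=float(max(rng.normal(preset.ssrt_mean, preset.ssrt_sd), 120.0)),
        p_choice_error=preset.p_choice_error,
        p_omission=preset.p_omission,
        beta_context=float(rng.normal(preset.beta_context_mean, preset.beta_context_sd)),
        beta_pes=float(rng.normal(preset.beta_pes_mean, preset.beta_pes_sd)),
        beta_antic=beta_antic,
        alpha_gen=preset.alpha_gen,
    )


def _swan_scores(profile: SubjectProfile, rng: np.random.Generator) -> dict[str, float]:
    out = {}
    for name, m in SWAN_MODEL.items():
        out[name] = float(
            m["intercept"]
            + m["load_ssrt"] * (profile.ssrt_true - 300.0)
            + m["load_pes"] * profile.beta_pes
            + m["load_antic"] * profile.beta_antic
            + rng.normal(0.0, m["noise_sd"])
        )
    return out


def simulate_cohort(
    config: CohortConfig,
    out_dir: str | Path | None = None,
    return_profiles: bool = False,
):
    """Simulate a full cohort; returns (trials, subjects[, profiles]).

    With ``out_dir`` set, writes ``trials.csv`` and ``subjects.csv`` there.
    Identical config + seed yields identical output.
    """
    ss = np.random.SeedSequence(config.seed)
    n_total = config.n_td + config.n_adhd
    child_seeds = ss.spawn(n_total)
    groups = ["TD"] * config.n_td + ["ADHD"] * config.n_adhd

    all_records: list[TrialRecord] = []
    subject_rows = []
    profiles = []
    dbm_cfg = DBMConfig(grid_size=config.dbm_grid_size)
    for i, (group, child) in enumerate(zip(groups, child_seeds)):
        rng = np.random.default_rng(child)
        preset = config.presets[group]
        sid = f"{group.lower()}{i + 1:03d}"
        profile = draw_profile(sid, group, preset, rng)
        profiles.append(profile)
        for task in config.tasks:
            for run in range(1, config.runs_per_task + 1):
                all_records.extend(simulate_session(profile, task, run, rng, dbm_cfg))
        scores = _swan_scores(profile, rng)
        subject_rows.append(
            {
                "subject_id": sid,
                "group": group,
                "age": float(np.round(rng.normal(preset.age_mean, preset.age_sd), 1)),
                "gender": "F" if rng.random() < preset.p_female else "M",
                "verbal_iq": float(np.round(rng.normal(preset.iq_mean, preset.iq_sd))),
                **scores,
            }
        )

    trials = trials_to_frame(all_records)
    subjects = pd.DataFrame(subject_rows)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        write_trials(trials, out_dir / "trials.csv")
        write_subjects(subjects, out_dir / "subjects.csv")
    if return_profiles:
        return trials, subjects, profiles
    return trials, subjects
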