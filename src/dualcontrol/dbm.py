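"""Dynamic belief model (DBM) of trial-wise stop-signal anticipation.

A Bayesian observer tracks the probability ``r_k`` that the upcoming trial
carries a stop signal.  Between trials the rate is assumed to persist with
probability ``alpha`` and to be re-sampled from a Beta prior ``pi(r)`` with
probability ``1 - alpha``:

    p(r_k | s_{k-1}) = alpha * p(r_{k-1} | s_{k-1}) + (1 - alpha) * pi(r_k)

After observing the trial type ``s_k`` (1 = stop, 0 = go) the belief is
updated by Bayes' rule, with likelihood ``r`` for a stop and ``1 - r`` for a
go.  The predictive probability of a stop on trial k is the mean of the
predictive distribution, ``p_stop[k] = E[r_k | s_{1:k-1}]``.

The filter is implemented on a fixed grid of cells over (0, 1) (masses from
exact Beta CDF differences, each cell represented by its prior-conditional
mean of r), which is exact to grid tolerance and directly checkable against
the conjugate beta-binomial closed form in the non-forgetting limit
``alpha = 1``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

ALPHA_GRID_DEFAULT = np.round(np.arange(0.2, 0.7001, 0.05), 2)


@dataclass(frozen=True)
class DBMConfig:
    """Parameters of the dynamic belief model.

    alpha : persistence probability of the stop rate between trials.
    pm : prior mean of the Beta prior over the stop rate; defaults to the
        tasks' true stop-signal rate of 1/3.
    scale : concentration of the Beta prior, shape (pm*scale, (1-pm)*scale).
    grid_size : number of grid cells discretising r in (0, 1).
    """

    alpha: float = 0.3
    pm: float = 1.0 / 3.0
    scale: float = 2.0
    grid_size: int = 1000

    def __post_init__(self) -> None:
        if not (0.0 <= self.alpha <= 1.0):
            raise ValueError("alpha must be in [0, 1]")
        if not (0.0 < self.pm < 1.0):
            raise ValueError("pm must be in (0, 1)")
        if self.scale <= 0:
            raise ValueError("scale must be > 0")
        if self.grid_size < 100:
            raise ValueError("grid_size must be >= 100")

    @property
    def beta_a(self) -> float:
        return self.pm * self.scale

    @property
    def beta_b(self) -> float:
        return (1.0 - self.pm) * self.scale


@dataclass
class BeliefState:
    """Discretised probability mass over the stop rate r."""

    r_grid: np.ndarray
    mass: np.ndarray

    def __post_init__(self) -> None:
        total = float(self.mass.sum())
        if not np.isfinite(total) or abs(total - 1.0) > 1e-10:
            raise ValueError("belief mass must sum to 1")
        if (self.mass < 0).any():
            raise ValueError("belief mass must be nonnegative")

    @property
    def mean(self) -> float:
        return float(np.dot(self.r_grid, self.mass))


def _prior_mass(cfg: DBMConfig) -> tuple[np.ndarray, np.ndarray]:
    """Beta prior discretised on a fixed cell grid.

    Cell masses are exact CDF differences, and each cell is represented by
    the prior-conditional mean of r within it (via the Beta first-moment
    identity E[r; cell] = a/(a+b) * dI_{a+1,b}).  Both choices are robust to
    the edge singularities of Beta shapes with a or b < 1, where midpoint
    rules lose several digits.
    """
    a, b = cfg.beta_a, cfg.beta_b
    edges = np.linspace(0.0, 1.0, cfg.grid_size + 1)
    mass = np.diff(sps.beta.cdf(edges, a, b))
    m1 = (a / (a + b)) * np.diff(sps.beta.cdf(edges, a + 1.0, b))
    mid = 0.5 * (edges[:-1] + edges[1:])
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(mass > 0, m1 / np.maximum(mass, 1e-300), mid)
    r = np.clip(r, edges[:-1], edges[1:])
    mass = mass / mass.sum()
    return r, mass


def dbm_forward(
    trial_types: np.ndarray, cfg: DBMConfig | None = None
) -> tuple[np.ndarray, BeliefState]:
    """Run the DBM filter over a stop/go sequence.

    Parameters
    ----------
    trial_types : array of 0/1 (or booleans), 1 marking a stop trial.
    cfg : model configuration; defaults to ``DBMConfig()``.

    Returns
    -------
    p_stop : predictive stop probability for each trial, computed before that
        trial's type is observed; ``p_stop[0]`` equals the prior mean ``pm``
        up to grid tolerance.
    final_state : posterior belief after the last observation.
    """
    cfg = cfg or DBMConfig()
    s = np.asarray(trial_types).astype(float)
    if s.ndim != 1 or len(s) == 0:
        raise ValueError("trial_types must be a nonempty 1-d sequence")
    if not np.isin(s, (0.0, 1.0)).all():
        raise ValueError("trial_types must contain only 0 (go) and 1 (stop)")

    r, prior = _prior_mass(cfg)
    post = prior.copy()
    p_stop = np.empty(len(s))
    for k, sk in enumerate(s):
        predictive = cfg.alpha * post + (1.0 - cfg.alpha) * prior
        p_stop[k] = float(np.dot(r, predictive))
        lik = r if sk == 1.0 else 1.0 - r
        post = lik * predictive
        post /= post.sum()
    return p_stop, BeliefState(r_grid=r, mass=post)


def dbm_forward_batch(seq_matrix: np.ndarray, cfg: DBMConfig | None = None) -> np.ndarray:
    """Vectorised forward pass over many equal-length sequences.

    ``seq_matrix`` is (n_sequences, n_trials) of 0/1; returns the matching
    matrix of predictive stop probabilities.  Identical to running
    :func:`dbm_forward` on each row.
    """
    cfg = cfg or DBMConfig()
    s = np.asarray(seq_matrix, float)
    if s.ndim != 2 or s.size == 0:
        raise ValueError("seq_matrix must be 2-d and nonempty")
    if not np.isin(s, (0.0, 1.0)).all():
        raise ValueError("sequences must contain only 0 and 1")
    r, prior = _prior_mass(cfg)
    n_seq, n_tr = s.shape
    post = np.tile(prior[:, None], (1, n_seq))
    p_stop = np.empty((n_seq, n_tr))
    lik_stop = r[:, None]
    lik_go = (1.0 - r)[:, None]
    for k in range(n_tr):
        predictive = cfg.alpha * post + (1.0 - cfg.alpha) * prior[:, None]
        p_stop[:, k] = r @ predictive
        lik = np.where(s[:, k][None, :] == 1.0, lik_stop, lik_go)
        post = lik * predictive
        post /= post.sum(axis=0, keepdims=True)
    return p_stop


def pstop_per_run(trials: pd.DataFrame, cfg: DBMConfig | None = None) -> pd.Series:
    """Trial-wise p_stop for one subject's trial table, run by run.

    The belief restarts at the prior for each (task, run): runs are separated
    in time.  For the SST every trial enters the sequence; for the CSST only
    uncertain-cue trials (uncertain_go and stop) do — certain-go trials carry
    a no-stop cue, get NaN, and do not advance the belief.
    """
    cfg = cfg or DBMConfig()
    out = pd.Series(np.nan, index=trials.index, name="p_stop")
    for (_, _), run_df in trials.groupby(["task", "run"], sort=True):
        run_df = run_df.sort_values("trial_index")
        mask = run_df["trial_type"] != "certain_go"
        sub = run_df[mask]
        if len(sub) == 0:
            continue
        seq = (sub["trial_type"] == "stop").to_numpy().astype(int)
        p, _ = dbm_forward(seq, cfg)
        out.loc[sub.index] = p
    return out


def anticipation_correlation(
    trials: pd.DataFrame,
    p_stop: pd.Series,
    min_trials: int = 10,
) -> tuple[float, float, bool]:
    """Correlation between trial-wise go RT and anticipated stop probability.

    Restricted to responded go-class trials; run-wise forward passes are
    concatenated by the caller (``p_stop`` aligned with ``trials``).  Returns
    (r, p, flagged); flagged is True when fewer than ``min_trials`` usable
    trials exist, in which case r and p are NaN.
    """
    go = trials["trial_type"].isin(["go", "uncertain_go"]) & trials["responded"]
    usable = go & p_stop.notna() & trials["rt"].notna()
    rts = trials.loc[usable, "rt"].to_numpy(float)
    ps = p_stop.loc[usable].to_numpy(float)
    if len(rts) < min_trials or np.std(ps) == 0 or np.std(rts) == 0:
        return float("nan"), float("nan"), True
    r, p = sps.pearsonr(ps, rts)
    return float(r), float(p), False


def _binned_correlation(p_stop: np.ndarray, rts: np.ndarray, n_bins: int) -> float:
    """Pearson r between equal-count bin means of p_stop and go RT."""
    order = np.argsort(p_stop, kind="stable")
    ps, rs = p_stop[order], rts[order]
    idx = np.array_split(np.arange(len(ps)), n_bins)
    bp = np.array([ps[i].mean() for i in idx if len(i)])
    br = np.array([rs[i].mean() for i in idx if len(i)])
    if len(bp) < 3 or np.std(bp) == 0 or np.std(br) == 0:
        return float("nan")
    return float(sps.pearsonr(bp, br)[0])


def calibrate_alpha(
    trials: pd.DataFrame,
    alpha_grid: np.ndarray | None = None,
    n_bins: int = 20,
    cfg: DBMConfig | None = None,
    sst_only: bool = True,
    center_rts: bool = True,
) -> tuple[pd.DataFrame, float]:
    """Select the forgetting parameter alpha by binned aggregate correlation.

    For each candidate alpha the filter is run per subject and run, the
    (p_stop, go RT) pairs of responded go trials are pooled across subjects,
    binned into ``n_bins`` equal-count bins by p_stop, and bin means are
    correlated.  The selected alpha maximises the binned correlation (ties
    broken toward the smaller alpha).

    Go trials immediately following an unsuccessful stop are excluded from
    the pooled pairs: post-error slowing elevates RT exactly where recent
    history predicts a stop, and with those trials included the sweep
    systematically favours the smallest alpha regardless of the true
    forgetting rate.  Excluding them isolates the anticipation effect the
    calibration is meant to capture.  With ``center_rts`` (default) RTs are
    mean-centred within subject before pooling, removing between-subject
    baseline differences that only add noise to the bin means.

    Returns (curve, alpha_selected) where curve has columns alpha and
    binned_r.
    """
    if n_bins < 3:
        raise ValueError("n_bins must be >= 3")
    alpha_grid = ALPHA_GRID_DEFAULT if alpha_grid is None else np.asarray(alpha_grid, float)
    base = cfg or DBMConfig()
    if sst_only:
        trials = trials[trials["task"] == "SST"]

    # collect one stop/go sequence per (subject, task, run); uncertain-cue
    # trials only on the CSST
    seqs: list[np.ndarray] = []
    go_rts: list[np.ndarray] = []
    go_pos: list[np.ndarray] = []
    run_subjects: list[str] = []
    for (sid, _, _), run_df in trials.groupby(["subject_id", "task", "run"], sort=True):
        run_df = run_df.sort_values("trial_index")
        run_df = run_df[run_df["trial_type"] != "certain_go"]
        if len(run_df) == 0:
            continue
        s = (run_df["trial_type"] == "stop").to_numpy().astype(int)
        seqs.append(s)
        post_error = np.zeros(len(run_df), bool)
        post_error[1:] = (s[:-1] == 1) & run_df["responded"].to_numpy(bool)[:-1]
        usable = (run_df["trial_type"] != "stop").to_numpy(bool) & run_df[
            "responded"
        ].to_numpy(bool) & ~post_error
        go_pos.append(usable)
        go_rts.append(run_df.loc[usable, "rt"].to_numpy(float))
        run_subjects.append(str(sid))
    if center_rts and go_rts:
        subj_mean: dict[str, float] = {}
        for sid in set(run_subjects):
            vals = np.concatenate([r for s, r in zip(run_subjects, go_rts) if s == sid])
            subj_mean[sid] = float(vals.mean()) if len(vals) else 0.0
        go_rts = [r - subj_mean[s] for s, r in zip(run_subjects, go_rts)]
    rts_pooled = np.concatenate(go_rts) if go_rts else np.empty(0)

    rows = []
    lengths = {len(s) for s in seqs}
    for alpha in alpha_grid:
        acfg = DBMConfig(alpha=float(alpha), pm=base.pm, scale=base.scale, grid_size=base.grid_size)
        pooled_p: list[np.ndarray] = []
        for L in sorted(lengths):
            idx = [i for i, s in enumerate(seqs) if len(s) == L]
            P = dbm_forward_batch(np.stack([seqs[i] for i in idx]), acfg)
            pooled_p.extend(P[j][go_pos[i]] for j, i in enumerate(idx))
        # restore pooling order to match rts_pooled
        order = np.argsort([i for L in sorted(lengths) for i, s in enumerate(seqs) if len(s) == L], kind="stable")
        ps = np.concatenate([pooled_p[j] for j in order]) if pooled_p else np.empty(0)
        r = _binned_correlation(ps, rts_pooled, n_bins) if len(ps) >= n_bins else float("nan")
        rows.append({"alpha": float(alpha), "binned_r": r})
    curve = pd.DataFrame(rows)
    valid = curve.dropna(subset=["binned_r"])
    if len(valid) == 0:
        raise ValueError("no candidate alpha produced a defined binned correlation")
    best = valid.loc[valid["binned_r"].idxmax()]
    # idxmax returns the first maximum; grid is ascending, so ties resolve low
    return curve, float(best["alpha"])
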