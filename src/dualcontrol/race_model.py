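"""Reactive control: race-model checks and SSRT by the integration method.

Under the independent-race account, a response occurs on a stop trial iff
the go process finishes before the stop process.  The stop-signal reaction
time is then estimated as SSRT = T - mean SSD, where T is the point at which
the integral of the observed go-RT distribution equals the probability of
responding on stop trials.  T is taken as the ceil(p*N)-th order statistic
of the go RTs (empirical-CDF inverse, no interpolation), with omitted go
trials replaced by the maximum observed go RT beforehand — the consensus
treatment for omissions in the integration method.

For the CSST, the go-RT distribution is restricted to uncertain-cue go
trials, since only those share the stopping context of stop trials.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import ceil

import numpy as np
import pandas as pd
from scipy import stats as sps

GO_CLASSES = {"SST": ["go"], "CSST": ["uncertain_go"]}


@dataclass
class ReactiveSummary:
    """Per-subject, per-task reactive-control summary (times in ms)."""

    subject_id: str
    task: str
    n_go: int
    n_stop: int
    go_accuracy: float
    go_rt_mean: float
    go_rt_sd: float
    unsucc_stop_rt_mean: float
    unsucc_stop_rt_sd: float
    stop_accuracy: float
    ssd_mean: float
    quantile_rt_T: float
    ssrt: float
    flagged: bool = False
    flag_reason: str = ""


def check_race_assumption(trials: pd.DataFrame) -> tuple[bool, float, float]:
    """Race-model sanity check for one subject and task.

    Returns (ok, mean RT on responded stop trials, mean go RT); ok is True
    iff the unsuccessful-stop mean is strictly below the go mean.
    """
    task = trials["task"].iloc[0]
    go_rts = trials.loc[
        trials["trial_type"].isin(GO_CLASSES[task]) & trials["responded"], "rt"
    ].to_numpy(float)
    stop_rts = trials.loc[
        (trials["trial_type"] == "stop") & trials["responded"], "rt"
    ].to_numpy(float)
    if len(go_rts) == 0 or len(stop_rts) == 0:
        raise ValueError("need at least one responded trial in each class")
    return bool(stop_rts.mean() < go_rts.mean()), float(stop_rts.mean()), float(go_rts.mean())


def ssrt_integration(
    go_rts: np.ndarray,
    n_omissions: int,
    p_respond_given_stop: float,
    ssd_mean: float,
    min_go: int = 10,
) -> tuple[float, float, bool]:
    """Integration-method SSRT.

    Parameters
    ----------
    go_rts : observed (responded) go RTs in ms.
    n_omissions : go trials without a response; each is assigned the maximum
        observed go RT before integrating.
    p_respond_given_stop : probability of (unsuccessfully) responding on
        stop trials; must lie strictly in (0, 1).
    ssd_mean : mean stop-signal delay over all stop trials, ms.

    Returns
    -------
    (T, ssrt, flagged) with T the ceil(p*N)-th order statistic of the padded
    go-RT distribution and ssrt = T - ssd_mean.  The estimate is flagged
    when fewer than ``min_go`` go trials are available.
    """
    if not (0.0 < p_respond_given_stop < 1.0):
        raise ValueError("p_respond_given_stop must be strictly inside (0, 1)")
    go_rts = np.sort(np.asarray(go_rts, float))
    if len(go_rts) == 0:
        raise ValueError("no responded go trials")
    if n_omissions > 0:
        go_rts = np.sort(np.concatenate([go_rts, np.full(n_omissions, go_rts.max())]))
    n = len(go_rts)
    # 1e-9 relief keeps ceil at the definitional rank when p*n sits a few
    # ulps above an integer
    rank = ceil(p_respond_given_stop * n - 1e-9)
    t_point = float(go_rts[max(rank, 1) - 1])
    return t_point, t_point - float(ssd_mean), n < min_go


def summarize_reactive(trials: pd.DataFrame, min_go: int = 10) -> ReactiveSummary:
    """Reactive-control summary for one subject's trials on one task.

    Go accuracy counts correct responses over all go-class trials (omissions
    count as incorrect); stop accuracy is the withhold rate on stop trials.
    SSRT is undefined (NaN, flagged) when stop responding is at 0 or 1.
    """
    sid = str(trials["subject_id"].iloc[0])
    task = str(trials["task"].iloc[0])
    go_classes = GO_CLASSES[task]
    go = trials[trials["trial_type"].isin(go_classes)]
    stop = trials[trials["trial_type"] == "stop"]
    if len(go) == 0 or len(stop) == 0:
        raise ValueError(f"subject {sid}: no go or stop trials for task {task}")

    responded_go = go[go["responded"]]
    go_rts = responded_go["rt"].to_numpy(float)
    n_omissions = int((~go["responded"]).sum())
    go_acc = float((responded_go["choice_correct"].fillna(False)).sum() / len(go))
    stop_resp = stop[stop["responded"]]
    stop_acc = float((~stop["responded"]).sum() / len(stop))
    p_respond = 1.0 - stop_acc
    ssd_mean = float(stop["ssd"].mean())

    flagged, reason = False, ""
    if len(go_rts) == 0:
        raise ValueError(f"subject {sid}: no responded go trials")
    if p_respond <= 0.0 or p_respond >= 1.0:
        t_point, ssrt = float("nan"), float("nan")
        flagged, reason = True, "stop responding at 0 or 1; SSRT undefined"
    else:
        t_point, ssrt, few = ssrt_integration(go_rts, n_omissions, p_respond, ssd_mean, min_go)
        if few:
            flagged, reason = True, f"fewer than {min_go} go trials"

    n_stop_resp = len(stop_resp)
    return ReactiveSummary(
        subject_id=sid,
        task=task,
        n_go=len(go),
        n_stop=len(stop),
        go_accuracy=go_acc,
        go_rt_mean=float(go_rts.mean()),
        go_rt_sd=float(go_rts.std(ddof=1)) if len(go_rts) > 1 else float("nan"),
        unsucc_stop_rt_mean=float(stop_resp["rt"].mean()) if n_stop_resp else float("nan"),
        unsucc_stop_rt_sd=float(stop_resp["rt"].std(ddof=1)) if n_stop_resp > 1 else float("nan"),
        stop_accuracy=stop_acc,
        ssd_mean=ssd_mean,
        quantile_rt_T=t_point,
        ssrt=ssrt,
        flagged=flagged,
        flag_reason=reason,
    )


def summarize_cohort_reactive(trials: pd.DataFrame, min_go: int = 10) -> pd.DataFrame:
    """Reactive summaries for every (subject, task) in a trial table."""
    rows = []
    for (_, _), df in trials.groupby(["subject_id", "task"], sort=True):
        rows.append(vars(summarize_reactive(df, min_go)))
    return pd.DataFrame(rows)


def ssrt_reliability(ssrt_a: np.ndarray, ssrt_b: np.ndarray) -> tuple[float, float]:
    """Pearson correlation between paired SSRT estimates from two tasks."""
    a = np.asarray(ssrt_a, float)
    b = np.asarray(ssrt_b, float)
    keep = ~(np.isnan(a) | np.isnan(b))
    a, b = a[keep], b[keep]
    if len(a) < 4:
        raise ValueError("need at least 4 paired non-missing SSRT values")
    r, p = sps.pearsonr(a, b)
    return float(r), float(p)
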