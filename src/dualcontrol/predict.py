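"""Cross-validated prediction of symptom scores from control measures.

A multiple linear regression over the dual-control feature set (SSRT plus
context-, performance-monitoring- and anticipation-driven proactive
measures) is evaluated by leave-one-out cross-validation: each subject is
predicted by a model trained on all others, and performance is the Pearson
correlation between out-of-fold predictions and observed scores.  A reduced
SSRT-only model provides the baseline; the two (dependent, overlapping)
prediction-observation correlations are compared with the Pearson-Filon
test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from dualcontrol.stats import StatResult

FULL_FEATURES = ("ssrt_sst", "context_effect", "pes", "antic_corr")
REDUCED_FEATURES = ("ssrt_sst",)


@dataclass
class PredictionResult:
    model_spec: tuple[str, ...]
    subject_ids: list[str]
    predicted: np.ndarray
    observed: np.ndarray
    r_pred_obs: float
    p: float
    n_folds_flagged: int = 0


def loocv_predict(
    features: pd.DataFrame,
    feature_set: tuple[str, ...] = FULL_FEATURES,
    outcome: str = "swan_inattention",
    standardize: bool = True,
) -> PredictionResult:
    """Leave-one-out linear prediction of ``outcome`` from ``feature_set``.

    Features are standardised with training-fold statistics only (no
    leakage).  Rank-deficient folds are flagged and excluded.  Complete
    cases only; requires >= 10 of them.
    """
    if len(feature_set) == 0:
        raise ValueError("feature_set must be nonempty")
    cols = ["subject_id", *feature_set, outcome]
    data = features[cols].dropna().reset_index(drop=True)
    n = len(data)
    if n < 10:
        raise ValueError("need at least 10 complete cases")
    X = data[list(feature_set)].to_numpy(float)
    y = data[outcome].to_numpy(float)

    preds = np.full(n, np.nan)
    flagged = 0
    for i in range(n):
        mask = np.ones(n, bool)
        mask[i] = False
        Xtr, ytr = X[mask], y[mask]
        xte = X[i]
        if standardize:
            mu, sd = Xtr.mean(axis=0), Xtr.std(axis=0, ddof=0)
            sd[sd == 0] = 1.0
            Xtr = (Xtr - mu) / sd
            xte = (xte - mu) / sd
        A = np.column_stack([np.ones(len(Xtr)), Xtr])
        if np.linalg.matrix_rank(A) < A.shape[1]:
            flagged += 1
            continue
        beta, *_ = np.linalg.lstsq(A, ytr, rcond=None)
        preds[i] = beta[0] + xte @ beta[1:]

    ok = ~np.isnan(preds)
    if ok.sum() < 4:
        raise ValueError("too few successful folds to correlate")
    r, p = sps.pearsonr(preds[ok], y[ok])
    return PredictionResult(
        model_spec=tuple(feature_set),
        subject_ids=data.loc[ok, "subject_id"].astype(str).tolist(),
        predicted=preds[ok],
        observed=y[ok],
        r_pred_obs=float(r),
        p=float(p),
        n_folds_flagged=flagged,
    )


def pearson_filon(
    r_jk: float, r_jh: float, r_kh: float, n: int
) -> tuple[float, float, float]:
    """Pearson-Filon statistic for two dependent overlapping correlations.

    Compares r(j,k) with r(j,h) sharing variable j, given r(k,h).  Returns
    (z, one-sided p for r_jk > r_jh, two-sided p).
    """
    k = (
        r_kh * (1.0 - r_jk**2 - r_jh**2)
        - 0.5 * r_jk * r_jh * (1.0 - r_jk**2 - r_jh**2 - r_kh**2)
    )
    denom = (1.0 - r_jk**2) ** 2 + (1.0 - r_jh**2) ** 2 - 2.0 * k
    if denom <= 0:
        return float("nan"), float("nan"), float("nan")
    z = (r_jk - r_jh) * np.sqrt(n) / np.sqrt(denom)
    p_one = float(sps.norm.sf(z))
    return float(z), p_one, 2.0 * float(sps.norm.sf(abs(z)))


def hotelling_williams(r_jk: float, r_jh: float, r_kh: float, n: int) -> tuple[float, float]:
    """Hotelling-Williams t for the same comparison (alternative method).

    Returns (t, one-sided p for r_jk > r_jh) with df = n - 3.
    """
    det = (
        1.0
        - r_jk**2
        - r_jh**2
        - r_kh**2
        + 2.0 * r_jk * r_jh * r_kh
    )
    rbar = 0.5 * (r_jk + r_jh)
    denom = 2.0 * det * (n - 1) / (n - 3) + rbar**2 * (1.0 - r_kh) ** 3
    if denom <= 0:
        return float("nan"), float("nan")
    t = (r_jk - r_jh) * np.sqrt((n - 1) * (1.0 + r_kh) / denom)
    return float(t), float(sps.t.sf(t, n - 3))


def compare_models(
    full: PredictionResult,
    reduced: PredictionResult,
    method: str = "pearson-filon",
) -> StatResult:
    """Compare full vs reduced LOOCV models on the same observed vector.

    Tests r(observed, predicted_full) > r(observed, predicted_reduced) for
    dependent overlapping correlations, using r(predicted_full,
    predicted_reduced).  One-sided p is the headline number; two-sided is
    also reported.
    """
    if full.subject_ids != reduced.subject_ids:
        raise ValueError("models must be evaluated on the same subjects")
    if not np.allclose(full.observed, reduced.observed):
        raise ValueError("observed vectors differ between models")
    n = len(full.observed)
    r_of = full.r_pred_obs
    r_or = reduced.r_pred_obs
    r_fr = float(sps.pearsonr(full.predicted, reduced.predicted)[0])
    if method == "pearson-filon":
        if abs(r_of - r_or) < 1e-15:
            return StatResult(0.0, float("nan"), 1.0, p_one_sided=0.5)
        z, p_one, p_two = pearson_filon(r_of, r_or, r_fr, n)
        return StatResult(z, float("nan"), p_two, p_one_sided=p_one)
    if method == "hotelling-williams":
        t, p_one = hotelling_williams(r_of, r_or, r_fr, n)
        return StatResult(t, float(n - 3), 2.0 * min(p_one, 1.0 - p_one), p_one_sided=p_one)
    raise ValueError(f"unknown method {method!r}")
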