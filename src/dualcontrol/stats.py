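"""Group-level statistical apparatus for per-subject feature tables.

Welch two-sample t with Satterthwaite degrees of freedom and pooled-SD
Cohen's d, one-sample t, t-based 95% confidence intervals from summary
statistics, Fisher-Z comparison of two independent correlations, OLS
regression with demographic confounds, normality/variance checks, and the
task-performance cohort filter (go accuracy > 50%, stop accuracy within
25-75%).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps


@dataclass
class StatResult:
    statistic: float
    df: float
    p_two_sided: float
    effect_size: float = float("nan")
    ci_low: float = float("nan")
    ci_high: float = float("nan")
    p_one_sided: float = float("nan")


def cohens_d(a: np.ndarray, b: np.ndarray) -> float:
    """Cohen's d with pooled SD."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    na, nb = len(a), len(b)
    sp = np.sqrt(((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2))
    return float((a.mean() - b.mean()) / sp)


def welch_t(a: np.ndarray, b: np.ndarray) -> StatResult:
    """Welch two-sample t-test (Satterthwaite df), with pooled-SD Cohen's d."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    a, b = a[~np.isnan(a)], b[~np.isnan(b)]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least 2 observations per group")
    res = sps.ttest_ind(a, b, equal_var=False)
    va, vb = a.var(ddof=1) / len(a), b.var(ddof=1) / len(b)
    df = (va + vb) ** 2 / (va**2 / (len(a) - 1) + vb**2 / (len(b) - 1))
    return StatResult(
        statistic=float(res.statistic),
        df=float(df),
        p_two_sided=float(res.pvalue),
        effect_size=cohens_d(a, b),
    )


def one_sample_t(values: np.ndarray, mu0: float = 0.0) -> StatResult:
    values = np.asarray(values, float)
    values = values[~np.isnan(values)]
    n = len(values)
    if n < 2:
        raise ValueError("need at least 2 observations")
    sd = values.std(ddof=1)
    lo, hi = summary_ci95(values.mean(), sd, n)
    if sd == 0:
        delta = values.mean() - mu0
        t = 0.0 if delta == 0 else float(np.sign(delta) * np.inf)
        return StatResult(t, float(n - 1), 1.0 if delta == 0 else 0.0, float("nan"), lo, hi)
    res = sps.ttest_1samp(values, mu0)
    return StatResult(
        statistic=float(res.statistic),
        df=float(n - 1),
        p_two_sided=float(res.pvalue),
        effect_size=float((values.mean() - mu0) / sd),
        ci_low=lo,
        ci_high=hi,
    )


def one_sample_t_from_summary(mean: float, sd: float, n: int, mu0: float = 0.0) -> StatResult:
    """One-sample t from summary statistics (mean, SD, n)."""
    if n < 2:
        raise ValueError("need n >= 2")
    t = (mean - mu0) / (sd / np.sqrt(n)) if sd > 0 else float("inf")
    p = 2.0 * sps.t.sf(abs(t), n - 1)
    lo, hi = summary_ci95(mean, sd, n)
    return StatResult(statistic=float(t), df=float(n - 1), p_two_sided=float(p), ci_low=lo, ci_high=hi)


def summary_ci95(mean: float, sd: float, n: int) -> tuple[float, float]:
    """t-based 95% confidence interval mean +- t_{0.975, n-1} * sd / sqrt(n)."""
    if n < 2:
        raise ValueError("need n >= 2")
    if sd < 0:
        raise ValueError("sd must be >= 0")
    half = sps.t.ppf(0.975, n - 1) * sd / np.sqrt(n)
    return float(mean - half), float(mean + half)


def fisher_z_compare(r1: float, n1: int, r2: float, n2: int) -> StatResult:
    """Fisher-Z comparison of two independent correlations.

    z = (atanh(r1) - atanh(r2)) / sqrt(1/(n1-3) + 1/(n2-3)).  Reported as
    the signed statistic with both one-sided (on |z|, the default reporting
    convention here) and two-sided p-values.
    """
    for r in (r1, r2):
        if not abs(r) < 1:
            raise ValueError("correlations must satisfy |r| < 1")
    if min(n1, n2) < 4:
        raise ValueError("need n >= 4 per correlation")
    z = (np.arctanh(r1) - np.arctanh(r2)) / np.sqrt(1.0 / (n1 - 3) + 1.0 / (n2 - 3))
    p_one = float(sps.norm.sf(abs(z)))
    return StatResult(
        statistic=float(z),
        df=float("nan"),
        p_two_sided=2.0 * p_one,
        p_one_sided=p_one,
    )


def regression_with_confounds(
    df: pd.DataFrame,
    outcome: str,
    predictor: str,
    confounds: tuple[str, ...] = ("age", "gender", "verbal_iq"),
) -> pd.DataFrame:
    """OLS of outcome on predictor plus confounds; gender coded 0/1 (M=0).

    Returns the statsmodels coefficient table as a DataFrame (coef, se, t,
    p, CI bounds) indexed by term.
    """
    cols = [outcome, predictor, *confounds]
    data = df[cols].copy()
    if "gender" in data.columns and data["gender"].dtype == object:
        data["gender"] = (data["gender"] == "F").astype(float)
    data = data.dropna()
    if len(data) < 10:
        raise ValueError("need at least 10 complete cases")
    X = sm.add_constant(data[[predictor, *confounds]].astype(float))
    model = sm.OLS(data[outcome].astype(float), X).fit()
    table = pd.DataFrame(
        {
            "coef": model.params,
            "se": model.bse,
            "t": model.tvalues,
            "p": model.pvalues,
        }
    )
    ci = model.conf_int()
    table["ci_low"], table["ci_high"] = ci[0], ci[1]
    return table


def normality_and_variance_checks(a: np.ndarray, b: np.ndarray) -> dict:
    """Shapiro-Wilk per group and Levene across groups (reported, not gating)."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    a, b = a[~np.isnan(a)], b[~np.isnan(b)]
    sw_a = sps.shapiro(a)
    sw_b = sps.shapiro(b)
    lev = sps.levene(a, b)
    return {
        "shapiro_a": (float(sw_a.statistic), float(sw_a.pvalue)),
        "shapiro_b": (float(sw_b.statistic), float(sw_b.pvalue)),
        "levene": (float(lev.statistic), float(lev.pvalue)),
    }


def cohort_filter(
    summaries: pd.DataFrame,
    go_acc_min: float = 0.5,
    stop_acc_low: float = 0.25,
    stop_acc_high: float = 0.75,
) -> tuple[list[str], pd.DataFrame]:
    """Task-performance inclusion filter applied per subject across tasks.

    A subject is retained iff, on every task, go accuracy is strictly above
    ``go_acc_min`` and stop accuracy lies inclusively within
    [``stop_acc_low``, ``stop_acc_high``].  Returns (retained subject ids,
    exclusion log with reasons).
    """
    rows = []
    retained = []
    for sid, df in summaries.groupby("subject_id", sort=True):
        reasons = []
        for _, row in df.iterrows():
            if not row["go_accuracy"] > go_acc_min:
                reasons.append(f"{row['task']}: go accuracy {row['go_accuracy']:.2f} <= {go_acc_min}")
            if not (stop_acc_low <= row["stop_accuracy"] <= stop_acc_high):
                reasons.append(
                    f"{row['task']}: stop accuracy {row['stop_accuracy']:.2f} outside "
                    f"[{stop_acc_low}, {stop_acc_high}]"
                )
        if reasons:
            rows.append({"subject_id": sid, "reason": "; ".join(reasons)})
        else:
            retained.append(str(sid))
    return retained, pd.DataFrame(rows, columns=["subject_id", "reason"])
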