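"""Drift-diffusion decomposition of post-error slowing.

A two-boundary Wiener diffusion with boundary separation ``a`` (evidence
units), drift rate ``v`` (units/s), non-decision time ``t0`` (s), unit
diffusion coefficient and an unbiased start point z = a/2.  Responses are
accuracy-coded: correct choices absorb at the upper boundary, errors at the
lower.  Parameters are estimated per condition (GoPUS vs GoPSG) by maximum
likelihood with multi-start local optimisation, and post-error changes are
the GoPUS - GoPSG parameter differences.

The first-passage-time density uses the classical pair of series expansions
(a short-time expansion in image terms and a long-time spectral expansion),
switching to whichever needs fewer terms for the requested accuracy.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize

_EPS = 1e-10  # target absolute accuracy of the normalized density f1

DEFAULT_BOUNDS = {"a": (0.2, 4.0), "v": (-8.0, 8.0), "t0_low": 0.05}


def _f1(tau: np.ndarray, w: float) -> np.ndarray:
    """Normalized lower-boundary FPT density (a=1, v=0, start w) at scaled
    times tau, accurate to ~_EPS absolutely."""
    tau = np.asarray(tau, float)
    out = np.zeros_like(tau)
    pos = tau > 0
    t = tau[pos]
    if t.size == 0:
        return out

    # terms needed by each expansion (Navarro & Fuss style bounds)
    with np.errstate(divide="ignore", invalid="ignore"):
        arg_s = 2.0 * _EPS * np.sqrt(2.0 * np.pi * t)
        ks = np.where(
            arg_s < 1.0,
            2.0 + np.sqrt(np.maximum(-2.0 * t * np.log(arg_s), 0.0)),
            2.0,
        )
        ks = np.maximum(ks, np.sqrt(t) + 1.0)
        arg_l = np.pi * t * _EPS
        kl = np.where(
            arg_l < 1.0,
            np.sqrt(np.maximum(-2.0 * np.log(arg_l), 0.0) / (np.pi**2 * t)),
            1.0 / (np.pi * np.sqrt(t)),
        )
        kl = np.maximum(kl, 1.0)

    use_small = ks < kl
    f = np.zeros_like(t)

    if use_small.any():
        ts = t[use_small]
        K = int(np.ceil(ks[use_small].max()))
        s = np.zeros_like(ts)
        for k in range(-K, K + 1):
            wk = w + 2.0 * k
            s += wk * np.exp(-(wk**2) / (2.0 * ts))
        f[use_small] = s / np.sqrt(2.0 * np.pi * ts**3)

    if (~use_small).any():
        tl = t[~use_small]
        K = int(np.ceil(kl[~use_small].max()))
        s = np.zeros_like(tl)
        for k in range(1, K + 1):
            s += k * np.exp(-(k**2) * np.pi**2 * tl / 2.0) * np.sin(k * np.pi * w)
        f[~use_small] = np.pi * s

    out[pos] = np.maximum(f, 0.0)
    return out


def wiener_fpt_density(
    t: np.ndarray | float,
    a: float,
    v: float,
    t0: float,
    boundary: str = "upper",
) -> np.ndarray | float:
    """First-passage density of the Wiener process at one boundary.

    ``t`` is the observed response time in seconds; the decision time is
    t - t0.  Start point is fixed at a/2.  Densities are 0 for t <= t0.
    """
    if a <= 0:
        raise ValueError("boundary separation a must be > 0")
    if boundary not in ("upper", "lower"):
        raise ValueError("boundary must be 'upper' or 'lower'")
    scalar = np.isscalar(t)
    t = np.atleast_1d(np.asarray(t, float))
    dt = t - t0
    w = 0.5
    # upper-boundary passage of (v, w) == lower-boundary passage of (-v, 1-w)
    vv, ww = (-v, 1.0 - w) if boundary == "upper" else (v, w)
    tau = np.where(dt > 0, dt / a**2, 0.0)
    dens = np.zeros_like(t)
    pos = dt > 0
    if pos.any():
        f = _f1(tau[pos], ww)
        dens[pos] = (1.0 / a**2) * np.exp(-vv * a * ww - (vv**2) * dt[pos] / 2.0) * f
    return float(dens[0]) if scalar else dens


def prob_upper(a: float, v: float) -> float:
    """Probability of absorbing at the upper boundary (start z = a/2)."""
    # (1 - e^{-2vz}) / (1 - e^{-2va}) reduces to a logistic at z = a/2
    return float(1.0 / (1.0 + np.exp(-v * a)))


@dataclass
class DDMParams:
    """Fitted diffusion parameters for one condition."""

    a: float
    v: float
    t0: float
    condition: str = ""
    loglik: float = float("nan")
    n_trials: int = 0
    flagged: bool = False
    flag_reason: str = ""


@dataclass
class DDMDelta:
    """GoPUS - GoPSG differences in fitted parameters."""

    d_a: float
    d_v: float
    d_t0: float
    flagged: bool = False
    flag_reason: str = ""


def _nll(params: np.ndarray, rts: np.ndarray, correct: np.ndarray) -> float:
    a, v, t0 = params
    dens = np.empty_like(rts)
    dens[correct] = wiener_fpt_density(rts[correct], a, v, t0, "upper")
    dens[~correct] = wiener_fpt_density(rts[~correct], a, v, t0, "lower")
    if (dens <= 0).any():
        return 1e10
    return float(-np.log(dens).sum())


def fit_ddm(
    rts: np.ndarray,
    correct: np.ndarray,
    seed: int = 0,
    n_starts: int = 5,
    condition: str = "",
    min_trials: int = 10,
) -> DDMParams:
    """Maximum-likelihood diffusion fit for one condition.

    ``rts`` in seconds, ``correct`` boolean (accuracy coding).  Runs
    ``n_starts`` seeded L-BFGS-B starts within box constraints
    a in (0.2, 4), v in (-8, 8), t0 in (0.05, min RT) and returns the best.
    """
    rts = np.asarray(rts, float)
    correct = np.asarray(correct, bool)
    if len(rts) != len(correct):
        raise ValueError("rts and correct must have equal length")
    flagged, reason = False, ""
    if len(rts) < min_trials:
        flagged, reason = True, f"fewer than {min_trials} trials"
    if len(rts) == 0:
        return DDMParams(np.nan, np.nan, np.nan, condition, np.nan, 0, True, "no trials")
    if correct.all():
        flagged, reason = True, (reason + "; " if reason else "") + "all responses correct: v weakly identified"

    t0_hi = float(rts.min()) - 1e-4
    lo = np.array([DEFAULT_BOUNDS["a"][0], DEFAULT_BOUNDS["v"][0], DEFAULT_BOUNDS["t0_low"]])
    hi = np.array([DEFAULT_BOUNDS["a"][1], DEFAULT_BOUNDS["v"][1], max(t0_hi, DEFAULT_BOUNDS["t0_low"] + 1e-4)])
    rng = np.random.default_rng(seed)

    best = None
    for _ in range(n_starts):
        x0 = lo + rng.random(3) * (hi - lo)
        try:
            res = optimize.minimize(
                _nll,
                x0,
                args=(rts, correct),
                method="L-BFGS-B",
                bounds=list(zip(lo, hi)),
            )
        except Exception:  # pragma: no cover - optimizer pathologies
            continue
        if res.success or np.isfinite(res.fun):
            if best is None or res.fun < best.fun:
                best = res
    if best is None:
        return DDMParams(np.nan, np.nan, np.nan, condition, np.nan, len(rts), True, "no start converged")
    a, v, t0 = best.x
    return DDMParams(
        a=float(a),
        v=float(v),
        t0=float(t0),
        condition=condition,
        loglik=float(-best.fun),
        n_trials=len(rts),
        flagged=flagged,
        flag_reason=reason,
    )


def post_error_ddm(
    trials: pd.DataFrame,
    labels: pd.Series,
    seed: int = 0,
    min_trials: int = 10,
) -> tuple[DDMDelta, DDMParams, DDMParams]:
    """Fit GoPUS and GoPSG independently and return parameter differences.

    RTs are converted from ms to seconds; go omissions are excluded.
    """
    fits = {}
    for cond in ("GoPUS", "GoPSG"):
        sel = trials[(labels == cond) & trials["responded"]]
        rts = sel["rt"].to_numpy(float) / 1000.0
        correct = sel["choice_correct"].fillna(False).to_numpy(bool)
        fits[cond] = fit_ddm(rts, correct, seed=seed, condition=cond, min_trials=min_trials)
    pus, psg = fits["GoPUS"], fits["GoPSG"]
    flagged = pus.flagged or psg.flagged
    reason = "; ".join(r for r in (pus.flag_reason, psg.flag_reason) if r)
    delta = DDMDelta(
        d_a=pus.a - psg.a,
        d_v=pus.v - psg.v,
        d_t0=pus.t0 - psg.t0,
        flagged=flagged,
        flag_reason=reason,
    )
    return delta, pus, psg


class WienerMLE:
    """Estimator-style wrapper around :func:`fit_ddm`.

    ``fit(rts, correct)`` stores ``a_``, ``v_``, ``t0_`` and ``loglik_``.
    """

    def __init__(self, seed: int = 0, n_starts: int = 5):
        self.seed = seed
        self.n_starts = n_starts

    def fit(self, rts: np.ndarray, correct: np.ndarray) -> "WienerMLE":
        res = fit_ddm(rts, correct, seed=self.seed, n_starts=self.n_starts)
        self.a_, self.v_, self.t0_ = res.a, res.v, res.t0
        self.loglik_ = res.loglik
        self.result_ = res
        return self


def sample_wiener(
    n: int,
    a: float,
    v: float,
    t0: float,
    rng: np.random.Generator | int = 0,
    t_max: float = 30.0,
    grid: int = 20000,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw (rt, correct) samples by inverting the FPT distribution.

    The conditional CDF at each boundary is built by trapezoidal integration
    of the series density on a fine decision-time grid, then inverted by
    interpolation.  Exact up to quadrature error; used for parameter
    recovery and as a generator of condition-level go RT data.
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    p_up = prob_upper(a, v)
    ts = t0 + np.linspace(1e-6, t_max, grid)
    out_rt = np.empty(n)
    out_correct = rng.random(n) < p_up
    for is_up, prob in ((True, p_up), (False, 1.0 - p_up)):
        m = out_correct == is_up
        k = int(m.sum())
        if k == 0:
            continue
        dens = wiener_fpt_density(ts, a, v, t0, "upper" if is_up else "lower")
        cdf = np.concatenate([[0.0], np.cumsum((dens[1:] + dens[:-1]) / 2.0 * np.diff(ts))])
        total = cdf[-1]
        if total <= 0:
            raise RuntimeError("degenerate FPT distribution on sampling grid")
        cdf /= total
        u = rng.random(k)
        out_rt[m] = np.interp(u, cdf, ts)
    return out_rt, out_correct


def sample_wiener_em(
    n: int,
    a: float,
    v: float,
    t0: float,
    rng: np.random.Generator | int = 0,
    dt: float = 1e-3,
    t_max: float = 20.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Euler-Maruyama path-simulation sampler (independent oracle).

    Slower and discretisation-biased (O(sqrt(dt)) in hitting times), but a
    fully independent check of choice probabilities and density shape.
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    n_steps = int(t_max / dt)
    x = np.full(n, a / 2.0)
    alive = np.ones(n, bool)
    rt = np.full(n, np.nan)
    correct = np.zeros(n, bool)
    sq = np.sqrt(dt)
    for step in range(1, n_steps + 1):
        k = int(alive.sum())
        if k == 0:
            break
        x[alive] += v * dt + sq * rng.standard_normal(k)
        hit_up = alive & (x >= a)
        hit_lo = alive & (x <= 0.0)
        t_now = t0 + step * dt
        rt[hit_up | hit_lo] = t_now
        correct[hit_up] = True
        alive &= ~(hit_up | hit_lo)
    done = ~np.isnan(rt)
    return rt[done], correct[done]
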