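"""Group-level statistics: multivariate outliers, bootstrap CIs,
circular means and phase-delay tests, and the ADI-BSI correlation.

Outlier rule: a subject's measurements form a point in d dimensions; its
squared Mahalanobis distance from the sample mean is referred to the
chi-squared distribution with d degrees of freedom, and points with
upper-tail probability below 1 % are flagged (multivariate-normal
"likelihood less than 1 %") and excluded from downstream tests.

Circular machinery follows the standard directional-statistics formulas
(Fisher 1993; Zar 1999; Berens's CircStat conventions): mean direction via
the resultant vector, the one-sample mean test by checking whether the
hypothesized direction falls outside the confidence interval of the
circular mean, and the Watson-Williams two-sample test for equal mean
directions with the concentration correction factor.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as ss

from .ssvep import phase_to_delay, wrap_phase


# ---------------------------------------------------------------------------
# Mahalanobis outliers


def mahalanobis_outliers(
    points: np.ndarray,
    alpha: float = 0.01,
    mean: np.ndarray | None = None,
    cov: np.ndarray | None = None,
) -> pd.DataFrame:
    """Flag multivariate outliers by the chi-squared tail of D^2.

    Parameters
    ----------
    points : (n, d)
        One row per subject.
    alpha :
        Tail-probability threshold (default 0.01: likelihood below 1 %).
    mean, cov :
        Population parameters; estimated from the sample when omitted
        (requires n > d + 1).

    Returns
    -------
    DataFrame with ``mahalanobis_sq``, ``tail_prob`` and ``flagged``.
    """
    points = np.atleast_2d(np.asarray(points, float))
    n, d = points.shape
    if not 0 < alpha < 0.5:
        raise ValueError("alpha must lie in (0, 0.5)")
    if mean is None or cov is None:
        if n <= d + 1:
            raise ValueError(f"need more than d+1 = {d + 1} points to estimate moments")
        mean = points.mean(axis=0)
        cov = np.cov(points, rowvar=False)
    mean = np.asarray(mean, float)
    cov = np.atleast_2d(np.asarray(cov, float))
    cond = np.linalg.cond(cov)
    if not np.isfinite(cond) or cond > 1e12:
        raise np.linalg.LinAlgError(
            f"covariance is singular or near-singular (condition number {cond:.3g})"
        )
    delta = points - mean
    d2 = np.einsum("ij,ij->i", delta, np.linalg.solve(cov, delta.T).T)
    tail = ss.chi2.sf(d2, df=d)
    return pd.DataFrame(
        {
            "point_id": np.arange(n),
            "mahalanobis_sq": d2,
            "tail_prob": tail,
            "flagged": tail < alpha,
        }
    )


# ---------------------------------------------------------------------------
# Bootstrap


def bootstrap_ci(
    values: np.ndarray, n_boot: int = 10000, level: float = 0.95, seed: int = 0
) -> tuple[float, float]:
    """Percentile bootstrap confidence interval of the mean."""
    values = np.asarray(values, float).ravel()
    if values.size < 2:
        raise ValueError("need at least two values")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, values.size, size=(n_boot, values.size))
    means = values[idx].mean(axis=1)
    lo, hi = np.percentile(means, [(1 - level) / 2 * 100, (1 + level) / 2 * 100])
    return float(lo), float(hi)


# ---------------------------------------------------------------------------
# Circular statistics


def circular_mean(angles: np.ndarray) -> tuple[float, float]:
    """Mean direction and mean resultant length of a circular sample.

    Returns ``(mean, r)``; the mean is NaN (undefined) when the resultant
    length is numerically zero.
    """
    angles = np.asarray(angles, float).ravel()
    if angles.size == 0:
        raise ValueError("empty circular sample")
    z = np.exp(1j * angles).mean()
    r = float(np.abs(z))
    mean = float(np.angle(z)) if r > 1e-12 else np.nan
    return mean, r


def circular_mean_ci(angles: np.ndarray, level: float = 0.95) -> tuple[float, float, float]:
    """Confidence interval half-width of the circular mean.

    Upper-tail chi-squared construction for the mean-direction CI
    (Zar 1999, eq. 26.24-25; identical to CircStat's ``circ_confmean``).
    Returns ``(mean, half_width, r)``; half-width is NaN when the sample
    is too dispersed for the construction to apply.
    """
    angles = np.asarray(angles, float).ravel()
    n = angles.size
    mean, rbar = circular_mean(angles)
    bigr = n * rbar
    c2 = ss.chi2.ppf(level, df=1)
    if rbar < 0.9 and rbar > np.sqrt(c2 / (2 * n)):
        t = np.sqrt((2 * n * (2 * bigr**2 - n * c2)) / (4 * n - c2))
    elif rbar >= 0.9:
        t = np.sqrt(n**2 - (n**2 - bigr**2) * np.exp(c2 / n))
    else:
        return mean, np.nan, rbar
    half = float(np.arccos(np.clip(t / bigr, -1.0, 1.0)))
    return mean, half, rbar


def paired_phase_test(
    deltas: np.ndarray,
    f_context: float,
    alpha: float = 0.05,
    null_direction: float = 0.0,
) -> dict:
    """One-sample circular mean test of within-subject phase differences.

    Tests whether the circular mean of per-subject phase deltas differs
    from ``null_direction`` (default 0) by checking whether it falls
    outside the ``1 - alpha`` confidence interval of the mean direction
    (the mean-test contract of CircStat's ``circ_mtest``).  ``p_proxy``
    is the confidence level at which the null direction sits exactly on
    the CI boundary (found by bisection), i.e. an approximate p-value.
    The mean delta is also reported in milliseconds at ``f_context``.
    """
    deltas = np.asarray(deltas, float).ravel()
    mean, half, rbar = circular_mean_ci(deltas, level=1 - alpha)
    if np.isnan(mean):
        raise ValueError("circular mean undefined (zero resultant)")
    dev = abs(wrap_phase(mean - null_direction))
    # the epsilon guards the degenerate zero-dispersion case (CI width 0)
    reject = bool(not np.isnan(half) and dev > half + 1e-9)

    # bisection on the CI level for an approximate p-value
    lo_a, hi_a = 1e-6, 1.0 - 1e-6
    def outside(a: float) -> bool:
        _, h, _ = circular_mean_ci(deltas, level=1 - a)
        return (not np.isnan(h)) and dev > h
    p = np.nan
    if outside(hi_a) is False and outside(lo_a) is False:
        p = 1.0
    elif outside(lo_a):
        p = 0.0
    else:
        for _ in range(60):
            mid = 0.5 * (lo_a + hi_a)
            if outside(mid):
                hi_a = mid
            else:
                lo_a = mid
        p = 0.5 * (lo_a + hi_a)

    return {
        "mean_direction": mean,
        "mean_delay_ms": phase_to_delay(mean, 0.0, f_context),
        "ci_half_width": half,
        "r": rbar,
        "reject": reject,
        "p_proxy": float(p),
    }


def _kappa_from_r(r: float) -> float:
    """Fisher's approximation of the von Mises concentration."""
    if r < 0.53:
        return 2 * r + r**3 + 5 * r**5 / 6
    if r < 0.85:
        return -0.4 + 1.39 * r + 0.43 / (1 - r)
    return 1.0 / (r**3 - 4 * r**2 + 3 * r)


def watson_williams(sample_a: np.ndarray, sample_b: np.ndarray) -> dict:
    """Watson-Williams two-sample test for equal mean directions.

    Standard one-way formula with the ``1 + 3/(8 kappa)`` correction;
    the assumption check (pooled mean resultant length >= 0.45, i.e.
    adequate concentration) is reported as ``assumption_ok`` and a
    warning flag rather than blocking the result.
    """
    a = np.asarray(sample_a, float).ravel()
    b = np.asarray(sample_b, float).ravel()
    if a.size < 5 or b.size < 5:
        raise ValueError("each sample needs at least 5 angles")
    n1, n2 = a.size, b.size
    n = n1 + n2
    r1 = n1 * circular_mean(a)[1]
    r2 = n2 * circular_mean(b)[1]
    rt = n * circular_mean(np.concatenate([a, b]))[1]
    rw = (r1 + r2) / n
    kappa = _kappa_from_r(rw)
    correction = 1 + 3 / (8 * kappa) if kappa > 0 else 1.0
    num = (n - 2) * (r1 + r2 - rt)
    den = n - r1 - r2
    f_stat = correction * num / den if den > 0 else np.inf
    f_stat = max(f_stat, 0.0)
    p = float(ss.f.sf(f_stat, 1, n - 2))
    return {
        "F": float(f_stat),
        "p": p,
        "assumption_ok": bool(rw >= 0.45),
        "pooled_r": float(rw),
    }


# ---------------------------------------------------------------------------
# Correlation


def adi_bsi_correlation(adi_diff: np.ndarray, bsi_diff: np.ndarray) -> dict:
    """Pearson correlation between per-subject ADI and BSI differences.

    ``adi_diff`` is binocular minus monocular ADI, ``bsi_diff`` AE minus
    FE suppression; a positive correlation says the extra binocular
    deficit tracks the suppression asymmetry.  Outliers should already be
    excluded.
    """
    x = np.asarray(adi_diff, float).ravel()
    y = np.asarray(bsi_diff, float).ravel()
    if x.size != y.size or x.size < 3:
        raise ValueError("need paired samples with n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance: correlation undefined")
    r, p = ss.pearsonr(x, y)
    return {"r": float(r), "p": float(p), "n": int(x.size)}
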