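"""Reporting statistics for simulation outputs.

Ordinary least-squares regression of bone mass against time (slope, R^2,
F test on 1 and n-2 degrees of freedom), quadratic least-squares
comparison of force-displacement curves by the extra-sum-of-squares F
test, and mean +/- sample-SD summaries across contact scenarios.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps


@dataclass
class RegressionReport:
    slope: float
    intercept: float
    r_squared: float
    F: float
    df: tuple[int, int]
    p: float
    n: int


def linreg(x, y) -> RegressionReport:
    """OLS line fit with the regression F statistic on (1, n-2) df."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 points")
    if np.ptp(x) == 0:
        raise ValueError("constant x: degenerate design")
    slope, intercept = np.polyfit(x, y, 1)
    yhat = slope * x + intercept
    ss_res = float(np.sum((y - yhat) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    ss_reg = ss_tot - ss_res
    r2 = 0.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    df1, df2 = 1, n - 2
    ms_res = ss_res / df2
    F = np.inf if ms_res == 0 else (ss_reg / df1) / ms_res
    p = float(sps.f.sf(F, df1, df2)) if np.isfinite(F) else 0.0
    return RegressionReport(float(slope), float(intercept), float(r2),
                            float(F), (df1, df2), p, n)


def _quad_rss(x, y):
    X = np.column_stack([np.ones_like(x), x, x * x])
    coef, res, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < 3:
        raise ValueError("collinear abscissae: quadratic fit degenerate")
    rss = float(np.sum((y - X @ coef) ** 2))
    return coef, rss


@dataclass
class QuadCompareReport:
    coefficients: list          # per-curve (a, b, c)
    pooled_coefficients: np.ndarray
    F: float
    df: tuple[int, int]
    p: float
    rss_separate: float
    rss_pooled: float


def quadfit_compare(curves) -> QuadCompareReport:
    """Equality-of-curves test for quadratic fits y = a + b x + c x^2.

    Fits each (x, y) curve separately and all pooled; the extra-sum-of-
    squares F statistic has (3 (k-1), N - 3 k) degrees of freedom for k
    curves with N total points.
    """
    curves = [(np.asarray(x, float), np.asarray(y, float)) for x, y in curves]
    if len(curves) < 2:
        raise ValueError("need at least two curves to compare")
    for x, y in curves:
        if len(x) < 4:
            raise ValueError("each curve needs >= 4 points")
    coefs, rss_sep = [], 0.0
    for x, y in curves:
        c, r = _quad_rss(x, y)
        coefs.append(c)
        rss_sep += r
    x_all = np.concatenate([x for x, _ in curves])
    y_all = np.concatenate([y for _, y in curves])
    pooled_coef, rss_pool = _quad_rss(x_all, y_all)
    k = len(curves)
    N = len(x_all)
    df1 = 3 * (k - 1)
    df2 = N - 3 * k
    if df2 <= 0:
        raise ValueError("not enough points for the equality test")
    ms_sep = rss_sep / df2
    F = 0.0 if rss_pool <= rss_sep and ms_sep == 0 else \
        ((rss_pool - rss_sep) / df1) / ms_sep if ms_sep > 0 else np.inf
    p = float(sps.f.sf(F, df1, df2)) if np.isfinite(F) else 0.0
    return QuadCompareReport(coefs, pooled_coef, float(F), (df1, df2), p,
                             rss_sep, rss_pool)


def scenario_summary(masses: dict) -> dict:
    """Per-checkpoint mean and sample SD across scenarios.

    ``masses`` maps scenario name -> {checkpoint week -> mass}. A single
    scenario yields SD 0 with a warning (undefined sample SD).
    """
    if not masses:
        raise ValueError("no scenarios given")
    scenarios = sorted(masses)
    weeks = sorted({w for sc in scenarios for w in masses[sc]})
    if len(scenarios) == 1:
        warnings.warn("single scenario: sample SD undefined, reported as 0")
    out = {}
    for w in weeks:
        vals = np.array([masses[sc][w] for sc in scenarios if w in masses[sc]])
        sd = float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0
        out[w] = {"mean": float(vals.mean()), "sd": sd, "n": len(vals)}
    return out
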