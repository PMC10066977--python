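"""Evaluation statistics for actual-versus-estimated shunt.

Reproduces the study-style evaluation of a parameter-recovery experiment:
ordinary least squares of the actual value on its blinded estimate (slope,
intercept, R^2, confidence interval, p-value), a summary of the per-record
deviations (mean/SD, median/IQR, range, skewness, normality), and Gaussian
kernel-density overlays of the two distributions for visual comparison.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm
from scipy import stats

__all__ = ["RegressionReport", "ErrorSummary", "regress_actual_on_estimate",
           "error_summary", "kde_overlay"]


@dataclass(frozen=True)
class RegressionReport:
    """OLS of actual on estimate; perfect agreement is (1.00, 0.00, 1.00)."""

    slope: float
    intercept: float
    r_squared: float
    slope_ci: tuple[float, float]   # 95% CI from the t distribution
    p_value: float
    n: int

    def as_dict(self) -> dict:
        return {"slope": self.slope, "intercept": self.intercept,
                "r_squared": self.r_squared,
                "slope_ci": list(self.slope_ci),
                "p_value": self.p_value, "n": self.n}


@dataclass(frozen=True)
class ErrorSummary:
    """Distribution of per-record deviations (default: actual - estimate)."""

    mean: float
    sd: float
    median: float
    iqr: tuple[float, float]
    range: tuple[float, float]
    skewness: float
    shapiro_p: float
    n: int

    def as_dict(self) -> dict:
        return {"mean": self.mean, "sd": self.sd, "median": self.median,
                "iqr": list(self.iqr), "range": list(self.range),
                "skewness": self.skewness, "shapiro_p": self.shapiro_p,
                "n": self.n}


def _check_pair(actual, estimate, min_n: int = 3) -> tuple[np.ndarray, np.ndarray]:
    a = np.asarray(actual, dtype=float)
    e = np.asarray(estimate, dtype=float)
    if a.shape != e.shape or a.ndim != 1:
        raise ValueError("actual and estimate must be equal-length 1-D sequences")
    if len(a) < min_n:
        raise ValueError(f"need at least {min_n} pairs, got {len(a)}")
    if not (np.isfinite(a).all() and np.isfinite(e).all()):
        raise ValueError("non-finite values in inputs")
    return a, e


def regress_actual_on_estimate(actual, estimate) -> RegressionReport:
    """OLS with the actual value as the dependent variable."""
    a, e = _check_pair(actual, estimate)
    if np.ptp(e) == 0:
        raise ValueError("estimate vector has zero variance; regression undefined")
    x = sm.add_constant(e)
    fit = sm.OLS(a, x).fit()
    ci = fit.conf_int(alpha=0.05)
    return RegressionReport(
        slope=float(fit.params[1]), intercept=float(fit.params[0]),
        r_squared=float(fit.rsquared),
        slope_ci=(float(ci[1][0]), float(ci[1][1])),
        p_value=float(fit.pvalues[1]), n=len(a))


def error_summary(actual, estimate, sign: str = "actual_minus_estimate") -> ErrorSummary:
    """Summary statistics of the deviation vector.

    ``sign`` selects the convention: "actual_minus_estimate" (default) or
    "estimate_minus_actual".
    """
    a, e = _check_pair(actual, estimate)
    if sign == "actual_minus_estimate":
        d = a - e
    elif sign == "estimate_minus_actual":
        d = e - a
    else:
        raise ValueError(f"unknown sign convention {sign!r}")
    q1, med, q3 = np.percentile(d, [25, 50, 75])
    if np.ptp(d) == 0:
        skew, sw_p = 0.0, 1.0
    else:
        skew = float(stats.skew(d, bias=False))
        sw_p = float(stats.shapiro(d).pvalue)
    return ErrorSummary(mean=float(d.mean()), sd=float(d.std(ddof=1)),
                        median=float(med), iqr=(float(q1), float(q3)),
                        range=(float(d.min()), float(d.max())),
                        skewness=skew, shapiro_p=sw_p, n=len(d))


def kde_overlay(actual, estimate, bandwidth: str | float = "silverman",
                n_grid: int = 512) -> dict[str, np.ndarray]:
    """Gaussian-kernel density curves of actual and estimate on a shared grid.

    Returns ``{"grid", "actual", "estimate"}``; each curve integrates to ~1
    on the grid.  ``bandwidth`` is a scipy ``gaussian_kde`` bandwidth rule
    or a numeric factor.
    """
    a = np.asarray(actual, dtype=float)
    e = np.asarray(estimate, dtype=float)
    if len(a) < 2 or len(e) < 2:
        raise ValueError("need at least two observations per curve")
    lo = min(a.min(), e.min())
    hi = max(a.max(), e.max())
    pad = 0.15 * (hi - lo + 1e-12)
    grid = np.linspace(lo - pad, hi + pad, n_grid)
    out = {"grid": grid}
    for name, v in (("actual", a), ("estimate", e)):
        if np.ptp(v) == 0:   # degenerate: point mass, represent as spike
            dens = np.zeros_like(grid)
            j = int(np.argmin(np.abs(grid - v[0])))
            dens[j] = 1.0 / (grid[1] - grid[0])
            out[name] = dens
        else:
            out[name] = stats.gaussian_kde(v, bw_method=bandwidth)(grid)
    return out
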