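"""Turnover rate constants from dwell-time and duration distributions.

A single rate-limiting step makes the intervals between (or durations of)
turnover events exponentially distributed; the maximum-likelihood rate is
the reciprocal mean interval and its exact confidence interval follows
from the chi-squared pivot 2nk/k̂ ~ χ²(2n).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import statsmodels.api as sm
from scipy import stats


@dataclass
class RateEstimate:
    """Exponential rate constant with its exact 95% confidence interval.

    ``kind`` distinguishes dwell-based (k^Δt, between events) from
    duration-based (k^τ, event widths) estimates.
    """

    k: float  # s⁻¹
    ci95: tuple[float, float]  # s⁻¹
    n: int
    kind: str = "dwell"

    @property
    def se(self) -> float:
        """Large-sample standard error k/√n of the exponential MLE."""
        return self.k / np.sqrt(self.n)


def fit_dwell_rate(
    intervals: Sequence[float], kind: str = "dwell", conf: float = 0.95
) -> RateEstimate:
    """Maximum-likelihood exponential rate from observed intervals.

    k̂ = 1/mean(intervals); the exact CI uses 2·k·Σx ~ χ²(2n), giving
    [χ²_{2n}(α/2), χ²_{2n}(1−α/2)] / (2Σx).
    """
    x = np.asarray(intervals, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 intervals to estimate a rate")
    if np.any(x <= 0):
        raise ValueError("intervals must be strictly positive")
    n = x.size
    total = float(x.sum())
    k = n / total
    alpha = 1.0 - conf
    lo = stats.chi2.ppf(alpha / 2.0, 2 * n) / (2.0 * total)
    hi = stats.chi2.ppf(1.0 - alpha / 2.0, 2 * n) / (2.0 * total)
    return RateEstimate(k=k, ci95=(float(lo), float(hi)), n=n, kind=kind)


@dataclass
class RateTrend:
    """Weighted linear trend of a rate constant with hotspot intensity."""

    slope: float
    intercept: float
    slope_se: float
    ci95: tuple[float, float]
    sign: int  # -1, 0, +1: CI below, spanning, or above zero

    def contains(self, slope: float) -> bool:
        lo, hi = self.ci95
        return lo <= slope <= hi


def rate_vs_intensity(estimates: Sequence[tuple[float, RateEstimate]]) -> RateTrend:
    """Weighted least-squares trend of rate constants versus intensity.

    Weights are the inverse squared large-sample standard errors; the
    reported ``sign`` states whether the 95% CI excludes zero.
    """
    if len(estimates) < 2:
        raise ValueError("need at least 2 intensities for a trend")
    I = np.array([e[0] for e in estimates], dtype=float)
    if np.unique(I).size < 2:
        raise ValueError("need at least 2 distinct intensities")
    k = np.array([e[1].k for e in estimates])
    se = np.array([e[1].se for e in estimates])
    weights = 1.0 / se**2 if np.all(se > 0) else np.ones_like(se)
    X = sm.add_constant(I)
    fit = sm.WLS(k, X, weights=weights).fit()
    ci = fit.conf_int(alpha=0.05)
    lo, hi = float(ci[1][0]), float(ci[1][1])
    sign = 0 if lo <= 0 <= hi else (1 if lo > 0 else -1)
    return RateTrend(
        slope=float(fit.params[1]),
        intercept=float(fit.params[0]),
        slope_se=float(fit.bse[1]),
        ci95=(lo, hi),
        sign=sign,
    )
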