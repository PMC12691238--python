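"""Bland-Altman agreement between paired LDL-C series, and a difference-vs-age trend.

Differences are always first-argument-minus-second.  The analysis pipeline
passes (direct, calculated), so a method that underestimates LDL-C relative
to the direct assay shows a positive bias.  Limits of agreement use
z = 1.96 and the n-1 sample SD; the bias CI is the normal-theory interval
bias +/- 1.96 * SD/sqrt(n).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "BlandAltmanResult",
    "TrendResult",
    "bland_altman",
    "bias_pct_of_range",
    "difference_trend",
]

_Z95 = 1.96


@dataclass(frozen=True)
class BlandAltmanResult:
    """Bias, its 95% CI, and 1.96-SD limits of agreement, all in mg/dL."""

    n: int
    bias: float
    bias_se: float
    bias_ci95: tuple[float, float]
    sd_diff: float
    loa_low: float
    loa_high: float
    loa_range: float
    bias_pct_of_range: float

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["bias_ci95"] = list(self.bias_ci95)
        return d


@dataclass(frozen=True)
class TrendResult:
    """OLS slope of paired differences on centered age."""

    slope: float
    intercept: float
    slope_ci95: tuple[float, float]
    centering_age: float

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["slope_ci95"] = list(self.slope_ci95)
        return d


def bland_altman(series_a, series_b) -> BlandAltmanResult:
    """Bland-Altman agreement statistics for paired measurements a - b.

    Requires two equal-length, pairwise-complete series with n >= 2.
    When the two series are identical the limits degenerate to [0, 0] and
    the bias-as-percent-of-range is reported as 0.
    """
    a = np.asarray(series_a, dtype=float)
    b = np.asarray(series_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError(f"series must be 1-D and equal length, got {a.shape} vs {b.shape}")
    if a.size < 2:
        raise ValueError(f"need at least 2 pairs, got {a.size}")
    if not (np.isfinite(a).all() and np.isfinite(b).all()):
        raise ValueError("series must be pairwise complete (no NaN/inf)")

    d = a - b
    n = d.size
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    se = sd / np.sqrt(n)
    loa_low = bias - _Z95 * sd
    loa_high = bias + _Z95 * sd
    loa_range = loa_high - loa_low
    pct = 100.0 * bias / loa_range if loa_range > 0 else 0.0
    return BlandAltmanResult(
        n=n,
        bias=bias,
        bias_se=float(se),
        bias_ci95=(bias - _Z95 * se, bias + _Z95 * se),
        sd_diff=sd,
        loa_low=float(loa_low),
        loa_high=float(loa_high),
        loa_range=float(loa_range),
        bias_pct_of_range=float(pct),
    )


def bias_pct_of_range(bias: float, loa_low: float, loa_high: float) -> float:
    """Bias expressed as a percentage of the limits-of-agreement range."""
    if not loa_high > loa_low:
        raise ValueError(f"degenerate LoA range: [{loa_low}, {loa_high}]")
    return 100.0 * bias / (loa_high - loa_low)


def difference_trend(differences, ages, centering_age: float = 13.0) -> TrendResult:
    """OLS regression of paired differences on (age - centering_age).

    A positive slope means the between-method difference grows with age.
    The slope CI is the normal-theory interval slope +/- 1.96 * SE.
    """
    d = np.asarray(differences, dtype=float)
    x = np.asarray(ages, dtype=float) - centering_age
    if d.shape != x.shape or d.ndim != 1:
        raise ValueError("differences and ages must be 1-D and equal length")
    if d.size < 3:
        raise ValueError(f"need at least 3 pairs, got {d.size}")
    if np.ptp(x) == 0:
        raise ValueError("ages are constant; trend is undefined")

    fit = stats.linregress(x, d)
    half = _Z95 * fit.stderr
    return TrendResult(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        slope_ci95=(float(fit.slope - half), float(fit.slope + half)),
        centering_age=float(centering_age),
    )
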