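"""Per-pixel linear trend of the annual composite index, F-test significance,
and classification into five weighted change grades.

The slope is the closed-form univariate OLS slope of the index on calendar
year; its significance is the regression F test with (1, l-2) degrees of
freedom. Pixels are graded by slope sign and p-value:

    grade 1 (+2): slope > 0, p < 0.01   extremely significant improvement
    grade 2 (+1): slope > 0, 0.01 <= p < 0.05
    grade 3 ( 0): p >= 0.05             no significant change
    grade 4 (-1): slope < 0, 0.01 <= p < 0.05
    grade 5 (-2): slope < 0, p < 0.01   extremely significant degradation

Boundary p values fall into the less-significant class so the rule is total.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from .types import (
    AnnualRasterStack,
    AlignmentError,
    InsufficientYearsError,
    TrendGradeRaster,
)

__all__ = ["pixel_slope", "slope_significance", "trend_grades", "classify_grades"]

# Residual/total sum-of-squares below this (relative) is treated as zero.
_SS_RTOL = 1e-12


def _period_stack(vqqi: AnnualRasterStack, period: tuple[int, int]) -> AnnualRasterStack:
    start, end = period
    sub = vqqi.select_years(start, end)
    if sub.n_years < 3:
        raise InsufficientYearsError(
            f"period {start}-{end} covers {sub.n_years} years; need >= 3"
        )
    return sub


def _ols_components(sub: AnnualRasterStack):
    """Vectorized per-pixel OLS of value on year: slope, SSR, SSE, SST."""
    t = sub.years.astype(float)
    tc = t - t.mean()
    stt = float((tc**2).sum())
    y = sub.data  # (l, r, c)
    ybar = y.mean(axis=0)
    slope = np.tensordot(tc, y, axes=(0, 0)) / stt
    sst = ((y - ybar) ** 2).sum(axis=0)
    ssr = stt * slope**2
    sse = np.maximum(sst - ssr, 0.0)
    return slope, ssr, sse, sst


def pixel_slope(vqqi: AnnualRasterStack, period: tuple[int, int]) -> np.ndarray:
    """OLS slope of the index on year, per pixel, over an inclusive period."""
    sub = _period_stack(vqqi, period)
    slope, *_ = _ols_components(sub)
    slope[~sub.mask] = np.nan
    return slope


def slope_significance(vqqi: AnnualRasterStack, period: tuple[int, int]) -> np.ndarray:
    """Regression F-test p-value per pixel.

    F = SSR / (SSE / (l-2)) with df (1, l-2). A perfect nonconstant fit
    (zero residual variance) gives p = 0; a constant series gives p = 1.
    """
    sub = _period_stack(vqqi, period)
    _, ssr, sse, sst = _ols_components(sub)
    l = sub.n_years
    p = np.ones(sub.shape)
    scale = np.maximum(sst, 1.0)
    zero_sse = sse <= _SS_RTOL * scale
    zero_sst = sst <= _SS_RTOL * np.maximum(np.abs(sub.data).max(axis=0) ** 2, 1.0)
    regular = ~zero_sse
    with np.errstate(divide="ignore", invalid="ignore"):
        f = ssr / (sse / (l - 2))
    p[regular] = stats.f.sf(f[regular], 1, l - 2)
    p[zero_sse & ~zero_sst] = 0.0  # exact line, nonzero slope
    p[zero_sst] = 1.0  # constant series
    p[~sub.mask] = np.nan
    return p


def classify_grades(
    slope: np.ndarray,
    p_value: np.ndarray,
    mask: np.ndarray,
    period: tuple[int, int],
    thresholds: tuple[float, float] = (0.01, 0.05),
) -> TrendGradeRaster:
    """Assign each valid pixel exactly one of the five grades."""
    if slope.shape != p_value.shape or slope.shape != mask.shape:
        raise AlignmentError("slope/p/mask grids are not aligned")
    t1, t2 = thresholds
    if not (0 < t1 < t2 < 1):
        raise AlignmentError(f"thresholds must satisfy 0 < {t1} < {t2} < 1")
    grade = np.zeros(slope.shape, dtype=int)
    ns = p_value >= t2  # not significant (includes slope == 0 defensively)
    grade[mask & (ns | (slope == 0))] = 3
    pos, neg = slope > 0, slope < 0
    grade[mask & pos & (p_value < t1)] = 1
    grade[mask & pos & (p_value >= t1) & (p_value < t2)] = 2
    grade[mask & neg & (p_value >= t1) & (p_value < t2)] = 4
    grade[mask & neg & (p_value < t1)] = 5
    return TrendGradeRaster(period, slope, p_value, grade, mask)


def trend_grades(
    vqqi: AnnualRasterStack,
    period: tuple[int, int],
    thresholds: tuple[float, float] = (0.01, 0.05),
) -> TrendGradeRaster:
    """Slope, significance and grades for one period in a single call."""
    slope = pixel_slope(vqqi, period)
    p = slope_significance(vqqi, period)
    return classify_grades(
        np.nan_to_num(slope), np.nan_to_num(p, nan=1.0), vqqi.mask, period, thresholds
    )
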