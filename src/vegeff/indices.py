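"""Vegetation indices: FVC from NDVI, normalization, the composite VQQI,
regional annual series, and abrupt-change detection.

The composite index (VQQI, 0-100%) is the equal-weight mean of min-max
normalized fractional vegetation cover (structure) and net primary
productivity (function):

    VQQI = (N_FVC + N_NPP) / 2 x 100%

FVC comes from NDVI through the dimidiate pixel model, which linearly unmixes
each pixel between a bare-soil endmember and a full-vegetation endmember taken
as low/high percentiles of the yearly scene.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from .types import (
    AnnualRasterStack,
    AnnualSeries,
    DegenerateNormalizationError,
    DegenerateSceneError,
    EmptySelectionError,
    VegeffError,
)

__all__ = [
    "maximum_value_composite",
    "fvc_from_ndvi",
    "normalize_stack",
    "vqqi",
    "regional_series",
    "pettitt",
    "change_year",
]


def maximum_value_composite(layers: np.ndarray) -> np.ndarray:
    """Annual maximum-value composite of sub-year layers (e.g. 8-day NDVI).

    ``layers`` is (n_layers, rows, cols); NaNs are ignored unless a pixel is
    NaN in every layer.
    """
    layers = np.asarray(layers, dtype=float)
    if layers.ndim != 3 or layers.shape[0] < 1:
        raise VegeffError("composite requires a (n_layers, rows, cols) array")
    with np.errstate(all="ignore"):
        return np.nanmax(layers, axis=0)


def fvc_from_ndvi(
    ndvi: AnnualRasterStack, soil_pct: float = 5.0, veg_pct: float = 95.0
) -> AnnualRasterStack:
    """Fractional vegetation cover via the dimidiate pixel model.

    For each yearly scene, the bare-soil endmember ``NDVI_soil`` and the full
    vegetation endmember ``NDVI_veg`` are the ``soil_pct`` and ``veg_pct``
    percentiles of the valid pixels of that year, and

        FVC = (NDVI - NDVI_soil) / (NDVI_veg - NDVI_soil)

    clipped to [0, 1].
    """
    if not (0 <= soil_pct < veg_pct <= 100):
        raise VegeffError("need 0 <= soil_pct < veg_pct <= 100")
    out = np.full_like(ndvi.data, np.nan)
    for i, year in enumerate(ndvi.years):
        scene = ndvi.data[i][ndvi.mask]
        lo, hi = np.percentile(scene, [soil_pct, veg_pct])
        if hi <= lo:
            raise DegenerateSceneError(
                f"NDVI scene for {year} is degenerate: "
                f"percentiles {soil_pct} and {veg_pct} coincide at {lo:g}"
            )
        out[i] = np.clip((ndvi.data[i] - lo) / (hi - lo), 0.0, 1.0)
    return AnnualRasterStack("FVC", ndvi.years, out, ndvi.mask, ndvi.cell_area)


def normalize_stack(stack: AnnualRasterStack, per_year: bool = False) -> AnnualRasterStack:
    """Min-max scale a stack to [0, 1].

    By default one affine map is fitted over all years and pixels jointly so
    that interannual ordering (and hence trends) is preserved; ``per_year``
    rescales each yearly scene independently instead.
    """
    out = np.full_like(stack.data, np.nan)
    if per_year:
        for i in range(stack.n_years):
            vals = stack.data[i][stack.mask]
            lo, hi = vals.min(), vals.max()
            if hi <= lo:
                raise DegenerateNormalizationError(
                    f"{stack.variable_name} is constant in {stack.years[i]}"
                )
            out[i] = (stack.data[i] - lo) / (hi - lo)
    else:
        vals = stack.valid_values()
        if vals.size == 0:
            raise EmptySelectionError(f"{stack.variable_name} has no valid pixels")
        lo, hi = vals.min(), vals.max()
        if hi <= lo:
            raise DegenerateNormalizationError(f"{stack.variable_name} stack is constant")
        out[:] = (stack.data - lo) / (hi - lo)
    out = np.clip(out, 0.0, 1.0)
    return AnnualRasterStack(
        f"N_{stack.variable_name}", stack.years, out, stack.mask, stack.cell_area
    )


def vqqi(nfvc: AnnualRasterStack, nnpp: AnnualRasterStack) -> AnnualRasterStack:
    """Composite quality-quantity index, (N_FVC + N_NPP)/2 x 100, in percent."""
    nfvc.require_aligned(nnpp)
    for s in (nfvc, nnpp):
        vals = s.valid_values()
        if vals.size and (vals.min() < -1e-9 or vals.max() > 1 + 1e-9):
            raise VegeffError(f"{s.variable_name} is not normalized to [0, 1]")
    data = (nfvc.data + nnpp.data) / 2.0 * 100.0
    return AnnualRasterStack("VQQI", nfvc.years, data, nfvc.mask, nfvc.cell_area)


def regional_series(
    stack: AnnualRasterStack, mask: np.ndarray | None = None
) -> AnnualSeries:
    """Annual mean over valid (optionally sub-masked) pixels, with OLS trend.

    The attached slope is the ordinary least-squares regression of the yearly
    means on calendar year; its p-value is the two-sided t test on the slope.
    """
    sel = stack.mask if mask is None else (stack.mask & np.asarray(mask, dtype=bool))
    if not sel.any():
        raise EmptySelectionError("no valid pixels in selection")
    values = stack.data[:, sel].mean(axis=1)
    if np.ptp(values) == 0:
        slope, p = 0.0, 1.0
    else:
        res = stats.linregress(stack.years, values)
        slope, p = float(res.slope), float(res.pvalue)
    return AnnualSeries(stack.years, values, trend_slope=slope, trend_p=p)


def pettitt(values: np.ndarray) -> tuple[int, int, float]:
    """Pettitt rank test for a single change point.

    Returns ``(t_index, K, p)`` where ``t_index`` is the last index of the
    first segment (the change occurs between ``t_index`` and ``t_index + 1``),
    ``K = max_t |U_t|`` with ``U_t = sum_{i<=t} sum_{j>t} sign(x_j - x_i)``,
    and ``p = 2 exp(-6 K^2 / (n^3 + n^2))`` (capped at 1).
    """
    x = np.asarray(values, dtype=float)
    n = len(x)
    if n < 4:
        raise VegeffError("change-point detection needs at least 4 points")
    sign = np.sign(x[None, :] - x[:, None])  # sign(x_j - x_i)
    # U_t via cumulative row sums: U_t = sum_{i<=t, j>t} sign(x_j - x_i)
    u = np.array([sign[: t + 1, t + 1 :].sum() for t in range(n - 1)])
    t_index = int(np.argmax(np.abs(u)))
    k = int(np.abs(u).max())
    p = float(min(1.0, 2.0 * np.exp(-6.0 * k * k / (n**3 + n**2))))
    return t_index, k, p


def change_year(series: AnnualSeries) -> AnnualSeries:
    """Attach the Pettitt change year (first year of the new regime) and its p.

    An all-equal series carries no signal: the change year is left unset and
    p = 1.
    """
    if np.ptp(series.values) == 0:
        series.change_year = None
        series.change_p = 1.0
        return series
    t_index, _, p = pettitt(series.values)
    series.change_year = int(series.years[t_index + 1])
    series.change_p = p
    return series
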