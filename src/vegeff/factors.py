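"""Driver-variable preparation: land-use change intensities, afforestation
normalization, zonal aggregation, and natural-breaks discretization.

Engineering intensities are pure area ratios per evaluation unit, in percent.
The denominator is the whole unit area by default (bounded and comparable
across units); ``denominator="prior"`` divides by the source-class area
instead.

Natural breaks (Jenks) is implemented as the exact Fisher dynamic program
minimizing the total within-class sum of squared deviations over contiguous
classes of the sorted values, so the optimum is well defined and testable.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .types import (
    AlignmentError,
    EmptySelectionError,
    FactorPartition,
    InfeasibleSpecError,
    JoinError,
    UnitMap,
    VegeffError,
)

__all__ = [
    "transition_intensity",
    "maintenance_intensity",
    "afforestation_intensity",
    "zonal_aggregate",
    "jenks_split",
    "jenks_breaks",
]


def _check_epochs(lu_t0: np.ndarray, lu_t1: np.ndarray, units: UnitMap) -> None:
    if lu_t0.shape != lu_t1.shape or lu_t0.shape != units.labels.shape:
        raise AlignmentError("land-use epochs and unit map are not aligned")


def transition_intensity(
    lu_t0: np.ndarray,
    lu_t1: np.ndarray,
    from_class: int,
    to_class: int,
    units: UnitMap,
    denominator: str = "unit",
) -> pd.Series:
    """Percent of unit cells converted from one class to another between epochs.

    ``denominator="unit"`` divides by all cells of the unit; ``"prior"``
    divides by the epoch-0 cells of ``from_class`` (0 when the unit had none).
    """
    _check_epochs(lu_t0, lu_t1, units)
    if denominator not in ("unit", "prior"):
        raise VegeffError("denominator must be 'unit' or 'prior'")
    changed = (lu_t0 == from_class) & (lu_t1 == to_class)
    out = {}
    for uid in units.unit_ids:
        sel = units.labels == uid
        denom = (
            int(sel.sum()) if denominator == "unit" else int((sel & (lu_t0 == from_class)).sum())
        )
        out[uid] = 100.0 * int((changed & sel).sum()) / denom if denom else 0.0
    s = pd.Series(out, name=f"transition_{from_class}_to_{to_class}_pct")
    s.index.name = "unit_id"
    return s


def maintenance_intensity(
    lu_t0: np.ndarray,
    lu_t1: np.ndarray,
    klass: int,
    units: UnitMap,
    denominator: str = "unit",
) -> pd.Series:
    """Percent of unit cells that stayed in ``klass`` in both epochs."""
    s = transition_intensity(lu_t0, lu_t1, klass, klass, units, denominator)
    return s.rename(f"maintained_{klass}_pct")


def afforestation_intensity(table: pd.DataFrame, units: UnitMap) -> pd.Series:
    """Accumulated afforested area as a percent of unit area.

    ``table`` has columns unit_id, year, afforested_area_km2; duplicate
    (unit, year) rows are summed with a warning, units without records get 0.
    """
    required = {"unit_id", "year", "afforested_area_km2"}
    if not required.issubset(table.columns):
        raise VegeffError(f"afforestation table needs columns {sorted(required)}")
    if (table["afforested_area_km2"] < 0).any():
        raise VegeffError("afforested areas must be nonnegative")
    areas = units.areas
    unknown = sorted(set(table["unit_id"]) - set(areas.index))
    if unknown:
        raise JoinError(f"afforestation rows reference unknown unit ids: {unknown}")
    if table.duplicated(subset=["unit_id", "year"]).any():
        warnings.warn("duplicate (unit_id, year) afforestation rows summed", stacklevel=2)
    totals = table.groupby("unit_id")["afforested_area_km2"].sum()
    s = 100.0 * totals.reindex(areas.index, fill_value=0.0) / areas
    s.index.name = "unit_id"
    return s.rename("afforestation_pct")


def zonal_aggregate(
    raster: np.ndarray,
    units: UnitMap,
    statistic: str = "mean",
    mask: np.ndarray | None = None,
) -> pd.Series:
    """Per-unit mean or sum of a continuous raster over valid cells.

    Units with no valid cell are excluded with a warning.
    """
    raster = np.asarray(raster, dtype=float)
    if raster.shape != units.labels.shape:
        raise AlignmentError("raster and unit map are not aligned")
    if statistic not in ("mean", "sum"):
        raise VegeffError("statistic must be 'mean' or 'sum'")
    valid = ~np.isnan(raster)
    if mask is not None:
        valid &= np.asarray(mask, dtype=bool)
    out = {}
    for uid in units.unit_ids:
        sel = valid & (units.labels == uid)
        if not sel.any():
            warnings.warn(f"unit {uid} has no valid cells; excluded", stacklevel=2)
            continue
        vals = raster[sel]
        out[uid] = float(vals.mean() if statistic == "mean" else vals.sum())
    if not out:
        raise EmptySelectionError("no unit has valid cells")
    s = pd.Series(out, name=statistic)
    s.index.name = "unit_id"
    return s


def jenks_split(values: np.ndarray, n_classes: int) -> tuple[list[float], np.ndarray]:
    """Exact natural-breaks partition of 1-D values into contiguous classes.

    Dynamic program over blocks of tied values (an optimal partition never
    needs to split equal values). Returns ``(breaks, labels)`` where breaks
    are the n_classes-1 strictly increasing upper boundaries between classes
    (midpoints of adjacent distinct values) and labels are 1..L per input
    value in increasing value order.
    """
    x = np.asarray(values, dtype=float)
    if np.isnan(x).any():
        raise VegeffError("values must not contain NaN")
    order = np.argsort(x, kind="stable")
    xs = x[order]
    uniq, counts = np.unique(xs, return_counts=True)
    m = len(uniq)
    if n_classes < 1:
        raise VegeffError("need at least one class")
    if m < n_classes:
        raise InfeasibleSpecError(
            f"{m} distinct values cannot form {n_classes} groups"
        )
    # Prefix sums over blocks of tied values.
    cw = np.concatenate([[0], np.cumsum(counts)])
    cs = np.concatenate([[0.0], np.cumsum(uniq * counts)])
    cs2 = np.concatenate([[0.0], np.cumsum(uniq**2 * counts)])

    inf = float("inf")
    cost = np.full((n_classes + 1, m + 1), inf)
    back = np.zeros((n_classes + 1, m + 1), dtype=int)
    cost[0, 0] = 0.0
    for k in range(1, n_classes + 1):
        for j in range(k, m + 1):
            i = np.arange(k - 1, j)
            n_i = cw[j] - cw[i]
            s_i = cs[j] - cs[i]
            ssd_i = np.maximum((cs2[j] - cs2[i]) - s_i * s_i / n_i, 0.0)
            cand = cost[k - 1, i] + ssd_i
            arg = int(np.argmin(cand))
            cost[k, j] = cand[arg]
            back[k, j] = k - 1 + arg
    # Recover block boundaries.
    bounds = [m]
    j = m
    for k in range(n_classes, 0, -1):
        j = back[k, j]
        bounds.append(j)
    bounds = bounds[::-1]  # 0 = b0 < b1 < ... < bL = m
    labels_sorted = np.empty(len(xs), dtype=int)
    breaks = []
    for k in range(n_classes):
        lo, hi = cw[bounds[k]], cw[bounds[k + 1]]
        labels_sorted[lo:hi] = k + 1
        if k < n_classes - 1:
            breaks.append(float((uniq[bounds[k + 1] - 1] + uniq[bounds[k + 1]]) / 2.0))
    labels = np.empty(len(x), dtype=int)
    labels[order] = labels_sorted
    return breaks, labels


def jenks_breaks(
    values: pd.Series,
    n_classes: int,
    factor_name: str = "factor",
    category: str = "other",
) -> FactorPartition:
    """Discretize per-unit values into L natural-breaks strata."""
    values = pd.Series(values, dtype=float)
    breaks, labels = jenks_split(values.to_numpy(), n_classes)
    strata = pd.Series(labels, index=values.index, name="stratum")
    return FactorPartition(factor_name, category, values, strata, breaks)
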