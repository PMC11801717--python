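"""County-level restoration effectiveness.

Grades are aggregated per evaluation unit into area fractions A_{k,t}; the net
change is their weight-weighted sum

    N_t = sum_k omega_k A_{k,t}          (bounded in [-2, 2])

and the effectiveness score divides by a shared baseline, the cross-unit mean
net change of the first programme phase (2000-2010 by default):

    E_t = N_t / N0

E_t <= 0 marks net degradation, 0 < E_t <= 1 recovery below baseline, and
E_t > 1 significant recovery.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .types import (
    AlignmentError,
    BaselineError,
    GRADE_WEIGHTS,
    TrendGradeRaster,
    UnitMap,
    VegeffError,
)

__all__ = [
    "CLASS_LABELS",
    "grade_fractions",
    "net_change",
    "baseline",
    "effectiveness_score",
    "effectiveness_table",
    "area_summary",
]

CLASS_LABELS = ("degraded", "not-significant", "significant")

_WEIGHTS = np.array([GRADE_WEIGHTS[k] for k in range(1, 6)], dtype=float)


def grade_fractions(grades: TrendGradeRaster, units: UnitMap) -> pd.DataFrame:
    """Area fraction of each grade per unit (columns A1..A5, index unit_id).

    Units without any valid pixel are excluded with a warning.
    """
    if grades.grade.shape != units.labels.shape:
        raise AlignmentError("grade raster and unit map are not aligned")
    valid = grades.mask & (units.labels > 0)
    rows = {}
    for uid in units.unit_ids:
        sel = valid & (units.labels == uid)
        n = int(sel.sum())
        if n == 0:
            warnings.warn(f"unit {uid} has no valid pixels; excluded", stacklevel=2)
            continue
        counts = np.array([(grades.grade[sel] == k).sum() for k in range(1, 6)])
        rows[uid] = counts / n
    out = pd.DataFrame.from_dict(rows, orient="index", columns=[f"A{k}" for k in range(1, 6)])
    out.index.name = "unit_id"
    return out


def net_change(fractions: pd.DataFrame, weights: np.ndarray | None = None) -> pd.Series:
    """N_t = sum_k omega_k A_{k,t} per unit."""
    a = fractions[[f"A{k}" for k in range(1, 6)]].to_numpy(dtype=float)
    sums = a.sum(axis=1)
    if np.any(np.abs(sums - 1.0) > 1e-9) or np.any(a < -1e-12):
        raise VegeffError("grade fractions must be nonnegative and sum to 1 per unit")
    w = _WEIGHTS if weights is None else np.asarray(weights, dtype=float)
    if w.shape != (5,):
        raise VegeffError("need exactly 5 grade weights")
    return pd.Series(a @ w, index=fractions.index, name="N_t")


def baseline(n_t0: pd.Series) -> float:
    """Cross-unit mean of the baseline-period net change (a single scalar N0)."""
    if len(n_t0) == 0:
        raise BaselineError("no units to average")
    n0 = float(np.mean(n_t0))
    if abs(n0) < 1e-6:
        raise BaselineError(f"baseline N0 = {n0:g} is too close to zero to normalize by")
    if n0 < 0:
        raise BaselineError(
            f"baseline N0 = {n0:g} is negative; E_t class semantics require N0 > 0"
        )
    return n0


def effectiveness_score(n_t: pd.Series, n0: float) -> pd.DataFrame:
    """E_t = N_t / N0 with its class per unit.

    The boundary E_t = 1 belongs to the not-significant class.
    """
    if n0 <= 0:
        raise BaselineError("N0 must be positive")
    e = n_t / n0
    cls = np.where(e <= 0, CLASS_LABELS[0], np.where(e <= 1, CLASS_LABELS[1], CLASS_LABELS[2]))
    return pd.DataFrame({"E_t": e, "class": cls}, index=n_t.index)


def effectiveness_table(
    grades_by_period: dict[tuple[int, int], TrendGradeRaster],
    units: UnitMap,
    baseline_period: tuple[int, int],
) -> pd.DataFrame:
    """Full per-(unit, period) table: A1..A5, N_t, E_t, class and shared N0.

    The baseline period must be one of the graded periods; its cross-unit mean
    net change becomes N0 for every period.
    """
    if baseline_period not in grades_by_period:
        raise VegeffError(f"baseline period {baseline_period} was not graded")
    frames = {}
    for period, gr in grades_by_period.items():
        a = grade_fractions(gr, units)
        a["N_t"] = net_change(a)
        frames[period] = a
    n0 = baseline(frames[baseline_period]["N_t"])
    out = []
    for period, a in frames.items():
        score = effectiveness_score(a["N_t"], n0)
        block = a.join(score)
        block.insert(0, "period", f"{period[0]}-{period[1]}")
        block["N0"] = n0
        out.append(block.reset_index())
    return pd.concat(out, ignore_index=True)


def area_summary(table: pd.DataFrame, units: UnitMap) -> pd.DataFrame:
    """Area proportion of each effectiveness class, overall and per sub-region.

    ``table`` needs columns unit_id, period, class. Proportions sum to 1
    within each (period, scope) row group.
    """
    areas = units.areas
    sub = dict(units.subregion) if units.subregion is not None else {}
    df = table[["unit_id", "period", "class"]].copy()
    df["area"] = df["unit_id"].map(areas)
    df["subregion"] = df["unit_id"].map(sub).fillna("") if sub else ""
    rows = []
    scopes = [("all", df)]
    if sub:
        scopes += [(name, g) for name, g in df.groupby("subregion") if name]
    for scope_name, g in scopes:
        for period, gp in g.groupby("period"):
            total = gp["area"].sum()
            for cls in CLASS_LABELS:
                rows.append(
                    {
                        "scope": scope_name,
                        "period": period,
                        "class": cls,
                        "area_km2": gp.loc[gp["class"] == cls, "area"].sum(),
                        "proportion": gp.loc[gp["class"] == cls, "area"].sum() / total,
                        "n_units": int((gp["class"] == cls).sum()),
                    }
                )
    return pd.DataFrame(rows)
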