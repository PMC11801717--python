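"""Core containers and error types shared across the pipeline.

Rasters are held as plain numpy arrays on a common grid: an annual stack is a
``(n_years, rows, cols)`` float array plus a single validity mask, and an
evaluation-unit map ("counties") is an integer label grid. All statistics in
the pipeline operate on these containers; file formats live in :mod:`vegeff.io`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "VegeffError",
    "ConfigError",
    "AlignmentError",
    "DegenerateSceneError",
    "DegenerateNormalizationError",
    "InsufficientYearsError",
    "EmptySelectionError",
    "BaselineError",
    "InfeasibleSpecError",
    "JoinError",
    "ConstantResponseError",
    "GRADE_WEIGHTS",
    "GRADE_NAMES",
    "AnnualRasterStack",
    "AnnualSeries",
    "UnitMap",
    "TrendGradeRaster",
    "FactorPartition",
]


class VegeffError(Exception):
    """Base class for all pipeline errors."""


class ConfigError(VegeffError):
    """Invalid scenario or pipeline configuration."""


class AlignmentError(VegeffError):
    """Rasters or stacks do not share grid shape, mask, or years."""


class DegenerateSceneError(VegeffError):
    """A yearly scene is constant, so endmember percentiles coincide."""


class DegenerateNormalizationError(VegeffError):
    """A stack is constant, so min-max normalization is undefined."""


class InsufficientYearsError(VegeffError):
    """A trend period covers fewer than three years."""


class EmptySelectionError(VegeffError):
    """A mask or unit selection contains no valid pixels."""


class BaselineError(VegeffError):
    """The cross-unit baseline is unusable (near zero or negative)."""


class InfeasibleSpecError(VegeffError):
    """A synthetic-data request cannot be satisfied (e.g. more strata than units)."""


class JoinError(VegeffError):
    """Tabular records reference unknown unit ids."""


class ConstantResponseError(VegeffError):
    """The response variable has zero variance; q is undefined."""


#: Grade k -> weight omega_k. Grade 1 is extremely significant improvement,
#: grade 5 extremely significant degradation.
GRADE_WEIGHTS: dict[int, int] = {1: 2, 2: 1, 3: 0, 4: -1, 5: -2}

GRADE_NAMES: dict[int, str] = {
    1: "extremely significant improvement",
    2: "significant improvement",
    3: "no significant change",
    4: "significant degradation",
    5: "extremely significant degradation",
}


@dataclass
class AnnualRasterStack:
    """A per-year gridded variable (NDVI, FVC, NPP, VQQI) on a common grid.

    Parameters
    ----------
    variable_name : str
        Name of the variable stored in the stack.
    years : array of int
        Strictly increasing calendar years, one per band.
    data : float array, shape (n_years, rows, cols)
        Values; entries outside ``mask`` are ignored everywhere.
    mask : bool array, shape (rows, cols)
        True where the pixel carries valid data in every year.
    cell_area : float
        Area of one grid cell in km^2.
    """

    variable_name: str
    years: np.ndarray
    data: np.ndarray
    mask: np.ndarray
    cell_area: float = 1.0

    def __post_init__(self) -> None:
        self.years = np.asarray(self.years, dtype=int)
        self.data = np.asarray(self.data, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.data.ndim != 3:
            raise ConfigError("stack data must be (n_years, rows, cols)")
        if len(self.years) != self.data.shape[0]:
            raise AlignmentError(
                f"{self.variable_name}: {len(self.years)} years but "
                f"{self.data.shape[0]} bands"
            )
        if np.any(np.diff(self.years) <= 0):
            raise ConfigError("years must be strictly increasing")
        if self.mask.shape != self.data.shape[1:]:
            raise AlignmentError("mask shape does not match grid shape")
        if self.cell_area <= 0:
            raise ConfigError("cell_area must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape[1:]

    @property
    def n_years(self) -> int:
        return len(self.years)

    def year_index(self, year: int) -> int:
        idx = np.nonzero(self.years == year)[0]
        if len(idx) == 0:
            raise ConfigError(f"year {year} not in stack ({self.years[0]}..{self.years[-1]})")
        return int(idx[0])

    def select_years(self, start: int, end: int) -> "AnnualRasterStack":
        """Inclusive year-range subset sharing the same grid and mask."""
        sel = (self.years >= start) & (self.years <= end)
        if not sel.any():
            raise ConfigError(f"period {start}-{end} outside stack years")
        return AnnualRasterStack(
            self.variable_name, self.years[sel], self.data[sel], self.mask, self.cell_area
        )

    def valid_values(self) -> np.ndarray:
        """All values at valid pixels, flattened over years."""
        return self.data[:, self.mask].ravel()

    def require_aligned(self, other: "AnnualRasterStack") -> None:
        if self.shape != other.shape or not np.array_equal(self.years, other.years):
            raise AlignmentError(
                f"{self.variable_name} and {other.variable_name} are not aligned"
            )
        if not np.array_equal(self.mask, other.mask):
            raise AlignmentError(
                f"{self.variable_name} and {other.variable_name} have different masks"
            )


@dataclass
class AnnualSeries:
    """A regional annual mean series with its linear trend and change point."""

    years: np.ndarray
    values: np.ndarray
    trend_slope: float = float("nan")
    trend_p: float = float("nan")
    change_year: int | None = None
    change_p: float = float("nan")

    def __post_init__(self) -> None:
        self.years = np.asarray(self.years, dtype=int)
        self.values = np.asarray(self.values, dtype=float)
        if len(self.years) != len(self.values):
            raise AlignmentError("series years and values differ in length")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"year": self.years, "value": self.values})


@dataclass
class UnitMap:
    """Tessellation of the grid into evaluation units ("counties").

    ``labels`` assigns every valid cell a positive integer unit id; 0 marks
    cells outside all units. Unit areas are cell counts times ``cell_area``.
    """

    labels: np.ndarray
    cell_area: float = 1.0
    subregion: Mapping[int, str] | None = None

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if self.labels.ndim != 2:
            raise ConfigError("unit labels must be a 2-D grid")
        if self.cell_area <= 0:
            raise ConfigError("cell_area must be positive")

    @property
    def unit_ids(self) -> np.ndarray:
        ids = np.unique(self.labels)
        return ids[ids > 0]

    @property
    def areas(self) -> pd.Series:
        ids, counts = np.unique(self.labels[self.labels > 0], return_counts=True)
        return pd.Series(counts * self.cell_area, index=ids, name="area_km2")

    def unit_mask(self, unit_id: int) -> np.ndarray:
        return self.labels == unit_id

    def to_frame(self) -> pd.DataFrame:
        df = self.areas.rename_axis("unit_id").reset_index()
        if self.subregion is not None:
            df["subregion"] = df["unit_id"].map(dict(self.subregion))
        return df


@dataclass
class TrendGradeRaster:
    """Per-pixel slope, significance and grade for one evaluation period."""

    period: tuple[int, int]
    slope: np.ndarray
    p_value: np.ndarray
    grade: np.ndarray
    mask: np.ndarray

    def __post_init__(self) -> None:
        for name in ("slope", "p_value", "grade", "mask"):
            arr = np.asarray(getattr(self, name))
            setattr(self, name, arr)
            if arr.shape != self.slope.shape:
                raise AlignmentError("trend rasters are not aligned")

    @property
    def weight(self) -> np.ndarray:
        """omega_k per pixel (0 outside the mask)."""
        w = np.zeros(self.grade.shape, dtype=int)
        for k, om in GRADE_WEIGHTS.items():
            w[(self.grade == k) & self.mask] = om
        return w


@dataclass
class FactorPartition:
    """A factor's per-unit values with their discretized stratum labels.

    ``values`` and ``strata`` are pandas Series indexed by unit id; strata are
    consecutive integers 1..L ordered by increasing value when produced by
    natural-breaks discretization.
    """

    factor_name: str
    category: str
    values: pd.Series
    strata: pd.Series
    breaks: Sequence[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = pd.Series(self.values, dtype=float)
        self.strata = pd.Series(self.strata, dtype=int)
        if not self.values.index.equals(self.strata.index):
            raise AlignmentError(f"{self.factor_name}: values/strata index mismatch")
        if len(self.strata) and self.strata.min() < 1:
            raise ConfigError("stratum labels must start at 1")

    @property
    def n_strata(self) -> int:
        return int(self.strata.nunique())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"unit_id": self.values.index, "value": self.values.values,
             "stratum": self.strata.values}
        )
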