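"""File I/O: ESRI ASCII grid rasters, annual stacks as one grid per year,
unit maps (labeled grid + attribute CSV + GeoJSON rectangles), CSV tables,
YAML configs and JSON reports.

ASCII grid is the plain-text raster interchange format (``ncols``/``nrows``
header followed by whitespace-separated values); every GIS reads it, and it
keeps the whole pipeline's on-disk footprint human-inspectable.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .types import AnnualRasterStack, UnitMap, VegeffError

__all__ = [
    "write_ascii_grid",
    "read_ascii_grid",
    "write_stack",
    "read_stack",
    "write_units",
    "read_units",
    "units_to_geojson",
    "write_report",
]

NODATA = -9999.0


def write_ascii_grid(
    path: str | Path, grid: np.ndarray, cellsize: float = 1.0, nodata: float = NODATA
) -> Path:
    path = Path(path)
    grid = np.asarray(grid, dtype=float)
    if grid.ndim != 2:
        raise VegeffError("ASCII grid requires a 2-D array")
    out = np.where(np.isnan(grid), nodata, grid)
    header = (
        f"ncols {grid.shape[1]}\nnrows {grid.shape[0]}\n"
        f"xllcorner 0.0\nyllcorner 0.0\ncellsize {cellsize}\nNODATA_value {nodata}\n"
    )
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, out, fmt="%.6g")
    return path


def read_ascii_grid(path: str | Path) -> tuple[np.ndarray, float]:
    """Returns (grid with NaN at nodata, cellsize)."""
    path = Path(path)
    header: dict[str, float] = {}
    with open(path) as fh:
        for _ in range(6):
            key, val = fh.readline().split()
            header[key.lower()] = float(val)
        grid = np.loadtxt(fh)
    grid = grid.reshape(int(header["nrows"]), int(header["ncols"]))
    grid[grid == header["nodata_value"]] = np.nan
    return grid, header["cellsize"]


def write_stack(directory: str | Path, stack: AnnualRasterStack) -> Path:
    """One ASCII grid per year, ``<var>_<year>.asc``, NaN outside the mask."""
    directory = Path(directory)
    for i, year in enumerate(stack.years):
        band = np.where(stack.mask, stack.data[i], np.nan)
        write_ascii_grid(directory / f"{stack.variable_name}_{year}.asc", band)
    return directory


def read_stack(directory: str | Path, variable_name: str, cell_area: float = 1.0) -> AnnualRasterStack:
    directory = Path(directory)
    files = sorted(directory.glob(f"{variable_name}_*.asc"))
    if not files:
        raise VegeffError(f"no {variable_name}_*.asc files in {directory}")
    years, bands = [], []
    for f in files:
        years.append(int(f.stem.rsplit("_", 1)[1]))
        grid, _ = read_ascii_grid(f)
        bands.append(grid)
    data = np.stack(bands)
    mask = ~np.isnan(data).any(axis=0)
    return AnnualRasterStack(variable_name, np.array(years), data, mask, cell_area)


def write_units(directory: str | Path, units: UnitMap, name: str = "units") -> Path:
    """Labeled grid + attribute table + GeoJSON rectangles (grid coordinates)."""
    directory = Path(directory)
    write_ascii_grid(directory / f"{name}.asc", units.labels.astype(float), units.cell_area)
    units.to_frame().to_csv(directory / f"{name}.csv", index=False)
    gj = units_to_geojson(units)
    if gj is not None:
        (directory / f"{name}.geojson").write_text(json.dumps(gj))
    return directory


def read_units(directory: str | Path, name: str = "units") -> UnitMap:
    directory = Path(directory)
    grid, cellsize = read_ascii_grid(directory / f"{name}.asc")
    labels = np.nan_to_num(grid, nan=0.0).astype(int)
    sub = None
    csv = directory / f"{name}.csv"
    if csv.exists():
        df = pd.read_csv(csv)
        if "subregion" in df.columns:
            sub = dict(zip(df["unit_id"].astype(int), df["subregion"]))
    return UnitMap(labels, cellsize, sub)


def units_to_geojson(units: UnitMap) -> dict | None:
    """GeoJSON FeatureCollection of unit rectangles, or None if any unit is
    not a filled axis-aligned block (only block tessellations are exported).

    Coordinates are grid cell indices (col = x, row = y, row 0 at top).
    """
    features = []
    areas = units.areas
    for uid in units.unit_ids:
        rows, cols = np.nonzero(units.labels == uid)
        r0, r1, c0, c1 = rows.min(), rows.max(), cols.min(), cols.max()
        if len(rows) != (r1 - r0 + 1) * (c1 - c0 + 1):
            return None
        ring = [
            [float(c0), float(r0)],
            [float(c1 + 1), float(r0)],
            [float(c1 + 1), float(r1 + 1)],
            [float(c0), float(r1 + 1)],
            [float(c0), float(r0)],
        ]
        props = {"unit_id": int(uid), "area_km2": float(areas[uid])}
        if units.subregion is not None:
            props["subregion"] = units.subregion.get(int(uid))
        features.append(
            {
                "type": "Feature",
                "geometry": {"type": "Polygon", "coordinates": [ring]},
                "properties": props,
            }
        )
    return {"type": "FeatureCollection", "features": features}


def write_report(path: str | Path, payload: dict) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)

    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON serializable: {type(o)}")

    path.write_text(json.dumps(payload, indent=2, default=default))
    return path


def load_yaml(path: str | Path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def dump_yaml(path: str | Path, payload: dict) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(yaml.safe_dump(payload, sort_keys=False))
    return path
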