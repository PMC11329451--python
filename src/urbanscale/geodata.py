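"""Containers and I/O for city tables, region tables and gridded measures.

Coordinates are abstract planar: a :class:`GridMeasure` lives on a rectilinear
grid anchored at ``origin`` (lower-left corner) with square cells of side
``cell_size``.  Cell ``(i, j)`` (row ``i``, column ``j``) spans the half-open
square ``[origin_x + j*s, origin_x + (j+1)*s) x [origin_y + i*s, origin_y +
(i+1)*s)`` with the row index increasing northward.  No CRS handling is done
in the core; callers that start from projected shapefiles should hand in plain
shapely polygons in the grid's frame.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from shapely.geometry import box as shapely_box
from shapely.geometry.base import BaseGeometry

__all__ = [
    "GridMeasure",
    "CityTable",
    "RegionTable",
    "read_city_table",
    "write_city_table",
    "read_region_table",
    "write_region_table",
    "read_grid",
    "write_grid",
    "aggregate_grid_to_polygons",
]

CITY_COLUMNS = ["city_id", "population", "e_co2", "e_pm25", "c_pm25"]
REGION_COLUMNS = [
    "region_id",
    "e_co2",
    "forest_area",
    "capture",
    "c_pm25",
    "population",
    "land_area",
]


@dataclass
class GridMeasure:
    """A nonnegative measure on a regular square-cell grid.

    Parameters
    ----------
    values
        2-D array of measure mass per cell; ``values[i, j]`` is row ``i``
        (south to north), column ``j`` (west to east).
    origin
        ``(x, y)`` of the grid's lower-left corner.
    cell_size
        Edge length of one cell, in the same length unit as ``origin``.
    units
        Free-text unit of the cell masses (e.g. ``"tons/yr"``).
    """

    values: np.ndarray
    origin: tuple[float, float] = (0.0, 0.0)
    cell_size: float = 1.0
    units: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("grid values must be a 2-D array")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("grid values must be finite")
        if np.any(self.values < 0):
            raise ValueError("grid values must be nonnegative")
        if not self.cell_size > 0:
            raise ValueError("cell_size must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def total_mass(self) -> float:
        return float(self.values.sum())

    def cell_polygon(self, i: int, j: int) -> BaseGeometry:
        """Shapely rectangle of cell (i, j)."""
        x0 = self.origin[0] + j * self.cell_size
        y0 = self.origin[1] + i * self.cell_size
        return shapely_box(x0, y0, x0 + self.cell_size, y0 + self.cell_size)


def _validate_city_frame(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in ("city_id", "population") if c not in df.columns]
    if missing:
        raise ValueError(f"city table missing required columns: {missing}")
    df["population"] = pd.to_numeric(df["population"])
    for col in CITY_COLUMNS:
        if col not in df.columns:
            df[col] = np.nan
        elif col not in ("city_id", "population"):
            # blank fields mean "measure absent"
            df[col] = pd.to_numeric(df[col], errors="coerce")
    df = df[CITY_COLUMNS + [c for c in df.columns if c not in CITY_COLUMNS]]
    if df["city_id"].duplicated().any():
        dup = df.loc[df["city_id"].duplicated(), "city_id"].iloc[0]
        raise ValueError(f"duplicate city_id: {dup!r}")
    bad = df.index[~(df["population"] >= 1)]
    if len(bad):
        row = int(bad[0])
        raise ValueError(
            f"row {row} (city_id={df.loc[row, 'city_id']!r}): population must be >= 1, "
            f"got {df.loc[row, 'population']!r}"
        )
    for col in ("e_co2", "e_pm25", "c_pm25"):
        vals = df[col]
        bad = df.index[vals.notna() & (vals < 0)]
        if len(bad):
            row = int(bad[0])
            raise ValueError(f"row {row}: {col} must be nonnegative")
    return df


@dataclass
class CityTable:
    """One record per city: population and named measures.

    Wraps a :class:`pandas.DataFrame` with columns ``city_id, population,
    e_co2, e_pm25, c_pm25`` (measures may be NaN where absent) plus any extra
    columns such as a ``country`` group label.
    """

    df: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        self.df = _validate_city_frame(pd.DataFrame(self.df).reset_index(drop=True))

    def __len__(self) -> int:
        return len(self.df)

    @property
    def population(self) -> np.ndarray:
        return self.df["population"].to_numpy(dtype=float)

    def measure(self, name: str) -> np.ndarray:
        if name not in self.df.columns:
            raise KeyError(f"no such measure column: {name!r}")
        return self.df[name].to_numpy(dtype=float)


@dataclass
class RegionTable:
    """Per-region quantities for the impact calculus.

    Columns: ``region_id`` plus any of ``e_co2`` (tons CO2/yr), ``forest_area``
    (km^2), ``capture`` (tons CO2/yr), ``c_pm25`` (ug/m^3), ``population``,
    ``land_area`` (km^2).  Missing quantities are NaN.
    """

    df: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        df = pd.DataFrame(self.df).reset_index(drop=True)
        if "region_id" not in df.columns:
            raise ValueError("region table requires a region_id column")
        for col in REGION_COLUMNS:
            if col not in df.columns:
                df[col] = np.nan
        for col in REGION_COLUMNS[1:]:
            vals = df[col]
            bad = df.index[vals.notna() & (vals < 0)]
            if len(bad):
                raise ValueError(f"row {int(bad[0])}: {col} must be nonnegative")
        self.df = df

    def __len__(self) -> int:
        return len(self.df)


# ---------------------------------------------------------------------------
# CSV I/O


def read_city_table(path: str | Path) -> CityTable:
    """Read a city table CSV (header ``city_id,population,e_co2,e_pm25,c_pm25``)."""
    df = pd.read_csv(path)
    return CityTable(df)


def write_city_table(table: CityTable, path: str | Path) -> None:
    table.df.to_csv(path, index=False)


def read_region_table(path: str | Path) -> RegionTable:
    return RegionTable(pd.read_csv(path))


def write_region_table(table: RegionTable, path: str | Path) -> None:
    table.df.to_csv(path, index=False)


def write_grid(grid: GridMeasure, path: str | Path) -> None:
    """Write grid values as dense CSV plus a JSON sidecar ``<path>.hdr``.

    The CSV holds rows in array order (row 0 first); the sidecar records
    ``origin_x, origin_y, cell_size, units`` so the geometry round-trips.
    """
    path = Path(path)
    np.savetxt(path, grid.values, delimiter=",")
    header = {
        "origin_x": grid.origin[0],
        "origin_y": grid.origin[1],
        "cell_size": grid.cell_size,
        "units": grid.units,
    }
    Path(str(path) + ".hdr").write_text(json.dumps(header))


def read_grid(path: str | Path) -> GridMeasure:
    path = Path(path)
    values = np.loadtxt(path, delimiter=",", ndmin=2)
    hdr_path = Path(str(path) + ".hdr")
    if hdr_path.exists():
        hdr = json.loads(hdr_path.read_text())
    else:
        hdr = {"origin_x": 0.0, "origin_y": 0.0, "cell_size": 1.0, "units": ""}
    return GridMeasure(
        values,
        origin=(hdr["origin_x"], hdr["origin_y"]),
        cell_size=hdr["cell_size"],
        units=hdr.get("units", ""),
    )


# ---------------------------------------------------------------------------
# Areal aggregation


def aggregate_grid_to_polygons(
    grid: GridMeasure,
    polygons: Sequence[BaseGeometry] | Iterable[BaseGeometry],
    extensive: bool = True,
) -> np.ndarray:
    """Aggregate a gridded measure onto polygons by exact area overlap.

    With ``extensive=True`` (emissions, mass-like): each cell's mass is split
    among polygons proportionally to the overlapped fraction of the cell, and
    a polygon's value is the sum of its shares — if the polygons tile the grid
    the total mass is conserved.  With ``extensive=False`` (concentrations,
    field-like): a polygon's value is the area-weighted mean of the cell
    values it overlaps.

    Polygons entirely outside the grid get 0 (extensive) or NaN (intensive).
    Overlap areas come from exact polygon–rectangle clipping, no resampling.
    """
    polygons = list(polygons)
    nrow, ncol = grid.shape
    s = grid.cell_size
    x0, y0 = grid.origin
    out = np.zeros(len(polygons))
    for k, poly in enumerate(polygons):
        minx, miny, maxx, maxy = poly.bounds
        j0 = max(int(np.floor((minx - x0) / s)), 0)
        j1 = min(int(np.ceil((maxx - x0) / s)), ncol)
        i0 = max(int(np.floor((miny - y0) / s)), 0)
        i1 = min(int(np.ceil((maxy - y0) / s)), nrow)
        wsum = 0.0
        acc = 0.0
        for i in range(i0, i1):
            for j in range(j0, j1):
                inter = poly.intersection(grid.cell_polygon(i, j)).area
                if inter <= 0.0:
                    continue
                if extensive:
                    acc += grid.values[i, j] * inter / (s * s)
                else:
                    acc += grid.values[i, j] * inter
                    wsum += inter
        if extensive:
            out[k] = acc
        else:
            out[k] = acc / wsum if wsum > 0 else np.nan
    return out
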