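"""Assignment of daily gridded exposure surfaces to localities.

Urban localities (polygons) get a population-weighted average over the
grid cells they intersect, with weights = population x exact
intersection-area fraction.  Rural localities (points) get the value of
the single 1x1-km cell containing the point.  Cells are half-open
intervals ``[x, x+1) x [y, y+1)`` so every in-domain point has exactly
one containing cell.

A locality-day is flagged incomplete when any contributing cell value is
missing that day; weights are never renormalised over the non-missing
cells.  Incomplete days are excluded downstream by the complete-lag-
history rule rather than imputed.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from shapely.geometry import Point, box, shape, mapping
from shapely.geometry.base import BaseGeometry

__all__ = [
    "Grid",
    "Locality",
    "ExposureFields",
    "LocalitySeries",
    "MissingValue",
    "population_weighted_extract",
    "point_extract",
    "build_locality_series",
    "read_localities_geojson",
    "write_localities_geojson",
]


class ExposureError(ValueError):
    pass


@dataclass(frozen=True)
class Grid:
    """Regular unit-cell grid in a single planar CRS (km units).

    Cell ids are row-major integers; cell (row, col) covers
    ``[x0+col, x0+col+1) x [y0+row, y0+row+1)``.
    """

    nrows: int
    ncols: int
    x0: float = 0.0
    y0: float = 0.0

    @property
    def n_cells(self) -> int:
        return self.nrows * self.ncols

    def cell_id(self, row: int, col: int) -> int:
        if not (0 <= row < self.nrows and 0 <= col < self.ncols):
            raise ExposureError(f"cell ({row}, {col}) outside grid")
        return row * self.ncols + col

    def cell_of_point(self, x: float, y: float) -> int:
        """Containing cell under the half-open convention."""
        col = math.floor(x - self.x0)
        row = math.floor(y - self.y0)
        if not (0 <= row < self.nrows and 0 <= col < self.ncols):
            raise ExposureError(f"point ({x}, {y}) outside grid domain")
        return row * self.ncols + col

    def cell_box(self, cell_id: int):
        row, col = divmod(int(cell_id), self.ncols)
        return box(self.x0 + col, self.y0 + row, self.x0 + col + 1, self.y0 + row + 1)

    def intersecting_cells(self, geom: BaseGeometry) -> dict[int, float]:
        """Cell -> fraction of the cell covered by ``geom`` (exact areas)."""
        minx, miny, maxx, maxy = geom.bounds
        c0 = max(0, math.floor(minx - self.x0))
        c1 = min(self.ncols - 1, math.ceil(maxx - self.x0) - 1)
        r0 = max(0, math.floor(miny - self.y0))
        r1 = min(self.nrows - 1, math.ceil(maxy - self.y0) - 1)
        out: dict[int, float] = {}
        for row in range(r0, r1 + 1):
            for col in range(c0, c1 + 1):
                cell = box(
                    self.x0 + col, self.y0 + row, self.x0 + col + 1, self.y0 + row + 1
                )
                a = geom.intersection(cell).area
                if a > 0:
                    out[row * self.ncols + col] = a / cell.area
        return out


@dataclass
class Locality:
    locality_id: str
    urban: bool
    geometry: BaseGeometry  # polygon when urban, point when rural


@dataclass(frozen=True)
class MissingValue:
    """A missing extraction result with the reason it is missing."""

    reason: str

    def __bool__(self) -> bool:
        return False


def population_weighted_extract(
    values: Mapping[int, float],
    weights: Mapping[int, float],
    coverage: Mapping[int, float],
) -> float | MissingValue:
    """Population-weighted mean of cell values over a polygon.

    ``w_c = population_c * coverage_c``; returns
    ``sum(v_c w_c) / sum(w_c)`` over cells with positive weight.
    Missing cell values (absent key or NaN) make the result missing —
    weights are not renormalised.
    """
    cells = [c for c in coverage if weights.get(c, 0.0) * coverage[c] > 0]
    if not cells:
        raise ExposureError("zero total population-coverage weight over polygon")
    vals = [values.get(c, float("nan")) for c in cells]
    if any(v is None or (isinstance(v, float) and math.isnan(v)) for v in vals):
        missing = [c for c, v in zip(cells, vals) if v is None or math.isnan(v)]
        return MissingValue(f"missing cell values: {missing}")
    w = np.array([weights[c] * coverage[c] for c in cells], dtype=float)
    v = np.array(vals, dtype=float)
    return float(v @ w / w.sum())


def point_extract(
    values: Mapping[int, float], point: Point | tuple[float, float], grid: Grid
) -> float | MissingValue:
    """Value of the unique grid cell containing the point."""
    x, y = (point.x, point.y) if isinstance(point, Point) else point
    cell = grid.cell_of_point(x, y)
    v = values.get(cell, float("nan"))
    if v is None or (isinstance(v, float) and math.isnan(v)):
        return MissingValue(f"cell {cell} missing")
    return float(v)


@dataclass
class ExposureFields:
    """Daily cell-level PM2.5 and temperature surfaces.

    ``pm`` and ``temp`` are ``(n_days, n_cells)`` arrays; NaN encodes a
    missing cell-day.
    """

    grid: Grid
    dates: pd.DatetimeIndex
    pm: np.ndarray
    temp: np.ndarray

    def __post_init__(self) -> None:
        self.dates = pd.DatetimeIndex(self.dates)
        for name in ("pm", "temp"):
            a = np.asarray(getattr(self, name), dtype=float)
            if a.shape != (len(self.dates), self.grid.n_cells):
                raise ExposureError(
                    f"{name} shape {a.shape} != (n_days, n_cells) "
                    f"({len(self.dates)}, {self.grid.n_cells})"
                )
            setattr(self, name, a)
        if np.nanmin(self.pm, initial=0.0) < 0:
            raise ExposureError("pm25 must be >= 0 where present")

    def day_values(self, date, var: str = "pm") -> dict[int, float]:
        t = self.dates.get_loc(pd.Timestamp(date))
        arr = getattr(self, var)[t]
        return {c: arr[c] for c in range(self.grid.n_cells)}

    def to_frame(self) -> pd.DataFrame:
        """Long format: one row per (date, cell_id)."""
        t, c = np.meshgrid(np.arange(len(self.dates)), np.arange(self.grid.n_cells),
                           indexing="ij")
        return pd.DataFrame(
            {
                "date": self.dates[t.ravel()],
                "cell_id": c.ravel(),
                "pm25": self.pm.ravel(),
                "temp": self.temp.ravel(),
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame, grid: Grid) -> "ExposureFields":
        dates = pd.DatetimeIndex(sorted(pd.to_datetime(df["date"]).unique()))
        dpos = {d: i for i, d in enumerate(dates)}
        pm = np.full((len(dates), grid.n_cells), np.nan)
        temp = np.full_like(pm, np.nan)
        t = pd.to_datetime(df["date"]).map(dpos).to_numpy()
        c = df["cell_id"].to_numpy(dtype=int)
        pm[t, c] = df["pm25"].to_numpy(dtype=float)
        temp[t, c] = df["temp"].to_numpy(dtype=float)
        return cls(grid=grid, dates=dates, pm=pm, temp=temp)


@dataclass
class LocalitySeries:
    """Per-locality daily assigned PM2.5 and temperature.

    Arrays are ``(n_days, n_localities)``; ``complete`` is False where
    any contributing cell was missing that day (the assigned value is
    NaN there).
    """

    dates: pd.DatetimeIndex
    locality_ids: list[str]
    pm: np.ndarray
    temp: np.ndarray
    complete: np.ndarray

    _index: dict[str, int] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        self.dates = pd.DatetimeIndex(self.dates)
        self._index = {lid: j for j, lid in enumerate(self.locality_ids)}

    def column(self, locality_id: str) -> int:
        if locality_id not in self._index:
            raise KeyError(f"locality {locality_id!r} absent from series")
        return self._index[locality_id]

    def to_frame(self) -> pd.DataFrame:
        t, j = np.meshgrid(
            np.arange(len(self.dates)), np.arange(len(self.locality_ids)), indexing="ij"
        )
        return pd.DataFrame(
            {
                "locality_id": np.asarray(self.locality_ids, dtype=object)[j.ravel()],
                "date": self.dates[t.ravel()],
                "pm25_assigned": self.pm.ravel(),
                "temp_assigned": self.temp.ravel(),
                "complete": self.complete.ravel(),
            }
        )


def _locality_weights(
    loc: Locality, grid: Grid, population: Mapping[int, float]
) -> dict[int, float]:
    """Cell -> population x coverage weight for one locality."""
    if loc.urban:
        coverage = grid.intersecting_cells(loc.geometry)
        w = {c: population.get(c, 0.0) * f for c, f in coverage.items()}
        w = {c: v for c, v in w.items() if v > 0}
        if not w:
            raise ExposureError(
                f"urban locality {loc.locality_id!r}: zero total population weight"
            )
        return w
    cell = grid.cell_of_point(loc.geometry.x, loc.geometry.y)
    return {cell: 1.0}


def build_locality_series(
    fields: ExposureFields,
    localities: Sequence[Locality],
    population: Mapping[int, float],
) -> LocalitySeries:
    """One assigned (pm25, temp) pair per locality-day.

    Weighted averages are computed with frozen weights; a day with any
    missing contributing cell is flagged incomplete and left NaN.
    """
    n_t = len(fields.dates)
    n_loc = len(localities)
    pm = np.full((n_t, n_loc), np.nan)
    temp = np.full((n_t, n_loc), np.nan)
    complete = np.zeros((n_t, n_loc), dtype=bool)
    for j, loc in enumerate(localities):
        w = _locality_weights(loc, fields.grid, population)
        cells = np.fromiter(w.keys(), dtype=int)
        wt = np.fromiter(w.values(), dtype=float)
        wt = wt / wt.sum()
        vp = fields.pm[:, cells]
        vt = fields.temp[:, cells]
        ok = ~(np.isnan(vp).any(axis=1) | np.isnan(vt).any(axis=1))
        complete[ok, j] = True
        pm[ok, j] = vp[ok] @ wt
        temp[ok, j] = vt[ok] @ wt
    return LocalitySeries(
        dates=fields.dates,
        locality_ids=[l.locality_id for l in localities],
        pm=pm,
        temp=temp,
        complete=complete,
    )


def read_localities_geojson(path) -> list[Locality]:
    with open(path) as fh:
        gj = json.load(fh)
    return [
        Locality(
            locality_id=str(f["properties"]["locality_id"]),
            urban=bool(f["properties"]["urban"]),
            geometry=shape(f["geometry"]),
        )
        for f in gj["features"]
    ]


def write_localities_geojson(localities: Sequence[Locality], path) -> None:
    gj = {
        "type": "FeatureCollection",
        "features": [
            {
                "type": "Feature",
                "properties": {"locality_id": l.locality_id, "urban": l.urban},
                "geometry": mapping(l.geometry),
            }
            for l in localities
        ],
    }
    with open(path, "w") as fh:
        json.dump(gj, fh)
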