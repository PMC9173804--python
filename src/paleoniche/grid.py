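"""Spatial lattice, camp records and presence rasterization.

The study area is a regular longitude/latitude grid (default 0.1 deg cells)
indexed row-major from the north-west corner.  Cells are half-open
``[lon, lon+d) x (lat-d, lat]`` and distances are great-circle on a sphere
of radius 6,371 km.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

EARTH_RADIUS_KM = 6371.0


def haversine_km(lon1, lat1, lon2, lat2):
    """Great-circle distance in km between points given in decimal degrees.

    Accepts scalars or broadcastable arrays.
    """
    lon1, lat1, lon2, lat2 = (np.radians(np.asarray(x, dtype=float))
                              for x in (lon1, lat1, lon2, lat2))
    dlon = lon2 - lon1
    dlat = lat2 - lat1
    a = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))


@dataclass
class GridSpec:
    """Regular lon/lat lattice with a land mask.

    Row 0 is the northernmost row; column 0 the westernmost column.
    ``total_cells`` (TC) counts land cells only.
    """

    lon_min: float
    lon_max: float
    lat_min: float
    lat_max: float
    cell_size: float
    land_mask: np.ndarray  # (n_rows, n_cols) bool

    def __post_init__(self):
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")
        if self.lon_max <= self.lon_min or self.lat_max <= self.lat_min:
            raise ValueError("inverted bounding box")
        self.land_mask = np.asarray(self.land_mask, dtype=bool)
        if self.land_mask.shape != (self.n_rows, self.n_cols):
            raise ValueError(
                f"land mask shape {self.land_mask.shape} does not match "
                f"grid dims {(self.n_rows, self.n_cols)}"
            )
        if self.total_cells < 1:
            raise ValueError("grid must contain at least one land cell")

    @property
    def n_rows(self) -> int:
        return int(round((self.lat_max - self.lat_min) / self.cell_size))

    @property
    def n_cols(self) -> int:
        return int(round((self.lon_max - self.lon_min) / self.cell_size))

    @property
    def total_cells(self) -> int:
        """TC: number of land cells."""
        return int(self.land_mask.sum())

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """(lon, lat) arrays of shape (n_rows, n_cols) with cell-center coordinates."""
        j = np.arange(self.n_cols)
        i = np.arange(self.n_rows)
        lons = self.lon_min + (j + 0.5) * self.cell_size
        lats = self.lat_max - (i + 0.5) * self.cell_size
        return np.meshgrid(lons, lats)

    def cell_of(self, lon: float, lat: float) -> tuple[int, int]:
        """Row/col of the cell containing a point; raises if outside the grid."""
        if not (self.lon_min <= lon <= self.lon_max and self.lat_min <= lat <= self.lat_max):
            raise ValueError(f"point ({lon}, {lat}) outside grid bounds")
        col = min(int((lon - self.lon_min) / self.cell_size), self.n_cols - 1)
        row = min(int((self.lat_max - lat) / self.cell_size), self.n_rows - 1)
        return row, col


@dataclass
class CampRecord:
    """A documented camp location (optionally with observed population size)."""

    id: str
    lon: float
    lat: float
    population_size: float | None = None
    excluded: bool = False  # e.g. resettlement camps, dropped before rasterizing

    def __post_init__(self):
        if self.population_size is not None and self.population_size < 0:
            raise ValueError(f"camp {self.id}: negative population size")


@dataclass
class PresenceGrid:
    """Binary presence raster on a grid; presences only on land cells."""

    grid: GridSpec
    presence: np.ndarray  # (n_rows, n_cols) bool

    def __post_init__(self):
        self.presence = np.asarray(self.presence, dtype=bool)
        if self.presence.shape != self.grid.shape:
            raise ValueError("presence raster does not match grid dims")
        if np.any(self.presence & ~self.grid.land_mask):
            raise ValueError("presence on water cell")

    @property
    def n_presence(self) -> int:
        """PP: count of presence cells."""
        return int(self.presence.sum())


@dataclass
class LayerStack:
    """Named environmental rasters per time slice (ages in years BP, increasing)."""

    grid: GridSpec
    ages: list[int]
    layers: dict[int, dict[str, np.ndarray]] = field(default_factory=dict)
    categorical: set[str] = field(default_factory=set)

    def __post_init__(self):
        ages = list(self.ages)
        if any(a < 0 for a in ages):
            raise ValueError("ages must be non-negative")
        if any(b <= a for a, b in zip(ages, ages[1:])):
            raise ValueError("ages must be strictly increasing")
        for age, lyr in self.layers.items():
            for name, arr in lyr.items():
                if np.asarray(arr).shape != self.grid.shape:
                    raise ValueError(f"layer {name!r} at age {age} does not match grid")

    def slice(self, age: int) -> dict[str, np.ndarray]:
        return self.layers[age]

    def layer_names(self) -> list[str]:
        first = self.layers[self.ages[0]]
        return sorted(first)

    def nearest_age(self, age_bp: float) -> int:
        """Nearest available slice; exact midpoints resolve to the younger slice."""
        ages = np.asarray(self.ages, dtype=float)
        d = np.abs(ages - age_bp)
        best = d.min()
        # candidates within floating tolerance of the minimum; youngest wins
        cands = ages[np.isclose(d, best)]
        return int(cands.min())


def build_grid(bbox: tuple[float, float, float, float], cell_size: float,
               land_mask: np.ndarray) -> GridSpec:
    """Build a GridSpec from (lon_min, lon_max, lat_min, lat_max).

    The mask is (n_rows, n_cols) with row 0 at the north edge.
    """
    lon_min, lon_max, lat_min, lat_max = bbox
    return GridSpec(lon_min=lon_min, lon_max=lon_max, lat_min=lat_min,
                    lat_max=lat_max, cell_size=cell_size, land_mask=land_mask)


def rasterize_presences(camps: list[CampRecord], grid: GridSpec,
                        buffer_km: float = 20.0) -> PresenceGrid:
    """Mark every land cell whose center lies within ``buffer_km`` of any camp.

    Excluded camps are dropped first.  The buffered areas are unioned, so
    overlapping camp buffers never double-count cells.
    """
    active = [c for c in camps if not c.excluded]
    pres = np.zeros(grid.shape, dtype=bool)
    if not active:
        warnings.warn("no camps left after exclusion filter; empty presence grid")
        return PresenceGrid(grid=grid, presence=pres)

    lon_c, lat_c = grid.cell_centers()
    # degree window that certainly contains the buffer (lat: 1 deg >= 111 km)
    pad = buffer_km / 111.0 / max(np.cos(np.radians(
        max(abs(grid.lat_min), abs(grid.lat_max)))), 0.05) + grid.cell_size
    for c in active:
        if not (grid.lon_min <= c.lon <= grid.lon_max
                and grid.lat_min <= c.lat <= grid.lat_max):
            raise ValueError(f"camp {c.id} outside grid bounds")
        box = (np.abs(lon_c - c.lon) <= pad) & (np.abs(lat_c - c.lat) <= pad)
        idx = np.where(box)
        if idx[0].size == 0:
            continue
        d = haversine_km(lon_c[idx], lat_c[idx], c.lon, c.lat)
        hit = d <= buffer_km
        pres[idx[0][hit], idx[1][hit]] = True
    pres &= grid.land_mask
    return PresenceGrid(grid=grid, presence=pres)


def camps_from_frame(df: pd.DataFrame) -> list[CampRecord]:
    """Parse a camps table (columns id, lon, lat[, population_size, excluded])."""
    out = []
    for rec in df.to_dict("records"):
        size = rec.get("population_size")
        if size is not None and (pd.isna(size)):
            size = None
        out.append(CampRecord(
            id=str(rec["id"]), lon=float(rec["lon"]), lat=float(rec["lat"]),
            population_size=None if size is None else float(size),
            excluded=bool(rec.get("excluded", False)),
        ))
    return out
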