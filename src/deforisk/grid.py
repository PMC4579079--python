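"""Regular lat-lon grid and per-cell raster fields.

All spatial data in the package lives on a :class:`GridSpec`: a regular
latitude-longitude grid with cell-centre registration, row 0 at the
northern edge and 0-based (row, col) indexing.  Distances between cells
are planar Euclidean distances in km computed from the grid's nominal
resolution (the domains targeted sit within a few degrees of the
equator, where the distortion of a plate-carree grid is negligible).

A :class:`RasterField` couples a value array with a validity mask;
masked cells are excluded from every statistic and regional sum.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterator, Literal, Sequence

import numpy as np

__all__ = [
    "GridSpec",
    "RasterField",
    "VectorLayer",
    "QALayer",
    "DriverStack",
]

LayerKind = Literal["roads", "rivers", "parks", "concessions"]


@dataclass(frozen=True)
class GridSpec:
    """Regular lat-lon grid, cell-centre registered, row 0 northernmost.

    Parameters
    ----------
    n_rows, n_cols
        Grid shape.
    origin_lat, origin_lon
        Coordinates (degrees) of the centre of cell ``(0, 0)``.
    cell_size
        Cell edge in degrees.
    nominal_resolution
        Cell edge in km, used for all planar distance computations
        (e.g. 5 km for the standard integration grid).
    """

    n_rows: int
    n_cols: int
    origin_lat: float = 0.0
    origin_lon: float = 0.0
    cell_size: float = 0.05
    nominal_resolution: float = 5.0

    def __post_init__(self) -> None:
        if self.n_rows <= 0 or self.n_cols <= 0:
            raise ValueError("grid shape must be positive")
        if self.cell_size <= 0 or self.nominal_resolution <= 0:
            raise ValueError("cell_size and nominal_resolution must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    @property
    def lats(self) -> np.ndarray:
        """Cell-centre latitudes, north to south."""
        return self.origin_lat - np.arange(self.n_rows) * self.cell_size

    @property
    def lons(self) -> np.ndarray:
        """Cell-centre longitudes, west to east."""
        return self.origin_lon + np.arange(self.n_cols) * self.cell_size

    def cell_bounds(self, row: int, col: int) -> tuple[float, float, float, float]:
        """(lon_min, lat_min, lon_max, lat_max) of a cell in degrees."""
        h = self.cell_size / 2.0
        lat = self.origin_lat - row * self.cell_size
        lon = self.origin_lon + col * self.cell_size
        return (lon - h, lat - h, lon + h, lat + h)

    def bounding_box(self) -> tuple[float, float, float, float]:
        """(lon_min, lat_min, lon_max, lat_max) of the full grid."""
        h = self.cell_size / 2.0
        return (
            self.origin_lon - h,
            self.origin_lat - (self.n_rows - 1) * self.cell_size - h,
            self.origin_lon + (self.n_cols - 1) * self.cell_size + h,
            self.origin_lat + h,
        )

    def pairwise_distance_km(self) -> np.ndarray:
        """All-pairs planar distances between cell centres, in km.

        Shape ``(n_cells, n_cells)`` with cells flattened row-major.
        Intended for brute-force kernels on small grids only.
        """
        rr, cc = np.meshgrid(
            np.arange(self.n_rows), np.arange(self.n_cols), indexing="ij"
        )
        pts = np.column_stack([rr.ravel(), cc.ravel()]).astype(float)
        diff = pts[:, None, :] - pts[None, :, :]
        return np.hypot(diff[..., 0], diff[..., 1]) * self.nominal_resolution


@dataclass
class RasterField:
    """A per-cell scalar field on a :class:`GridSpec` with a nodata mask.

    ``mask`` is True on *invalid* cells (numpy masked-array convention).
    ``units`` is a free-form declaration ("fraction", "km",
    "people km-2", "1") used for provenance only.
    """

    grid: GridSpec
    values: np.ndarray
    mask: np.ndarray | None = None
    units: str = "1"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.grid.shape:
            raise ValueError(
                f"values shape {self.values.shape} != grid shape {self.grid.shape}"
            )
        if self.mask is None:
            self.mask = np.zeros(self.grid.shape, dtype=bool)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.grid.shape:
                raise ValueError("mask shape does not match grid shape")

    # -- convenience -------------------------------------------------
    @property
    def valid(self) -> np.ndarray:
        """Boolean array, True on valid cells."""
        return ~self.mask

    def valid_values(self) -> np.ndarray:
        return self.values[self.valid]

    def copy(self) -> "RasterField":
        return RasterField(self.grid, self.values.copy(), self.mask.copy(), self.units)

    def with_values(self, values: np.ndarray, units: str | None = None) -> "RasterField":
        """New field on the same grid/mask with different values."""
        return RasterField(
            self.grid, values, self.mask.copy(), self.units if units is None else units
        )

    def sum(self) -> float:
        return float(self.values[self.valid].sum())

    def mean(self) -> float:
        return float(self.values[self.valid].mean())

    def check_fraction(self, upper: float = 1.0) -> None:
        v = self.valid_values()
        if v.size and (v.min() < -1e-12 or v.max() > upper + 1e-12):
            raise ValueError(f"fraction field out of [0, {upper}]")


@dataclass
class VectorLayer:
    """Polyline or polygon features in geographic coordinates.

    ``geoms`` are shapely geometries (degrees); ``kind`` tags the layer
    role so downstream code can pick the right rasterization semantics.
    """

    geoms: Sequence
    kind: LayerKind

    def __post_init__(self) -> None:
        self.geoms = list(self.geoms)
        for g in self.geoms:
            if g.is_empty:
                raise ValueError("vector layer contains an empty geometry")

    def __len__(self) -> int:
        return len(self.geoms)

    def __iter__(self) -> Iterator:
        return iter(self.geoms)


@dataclass
class QALayer:
    """Per-cell bad-quality fraction in percent [0, 100]."""

    grid: GridSpec
    percent_bad: np.ndarray

    def __post_init__(self) -> None:
        self.percent_bad = np.asarray(self.percent_bad, dtype=float)
        if self.percent_bad.shape != self.grid.shape:
            raise ValueError("QA shape does not match grid shape")
        if self.percent_bad.min() < 0 or self.percent_bad.max() > 100:
            raise ValueError("QA values must lie in [0, 100]")


@dataclass
class DriverStack:
    """Co-registered local-driver fields used by the risk model.

    road_distance, river_distance : km to the nearest feature cell
    population : people km-2
    park_mask, logging_mask : binary membership fields
    """

    road_distance: RasterField
    river_distance: RasterField
    population: RasterField
    park_mask: RasterField
    logging_mask: RasterField

    def __post_init__(self) -> None:
        g = self.road_distance.grid
        for name in ("river_distance", "population", "park_mask", "logging_mask"):
            f = getattr(self, name)
            if f.grid.shape != g.shape:
                raise ValueError(f"driver '{name}' not co-registered")
        for name in ("road_distance", "river_distance", "population"):
            f = getattr(self, name)
            if f.valid_values().size and f.valid_values().min() < 0:
                raise ValueError(f"driver '{name}' must be non-negative")

    @property
    def grid(self) -> GridSpec:
        return self.road_distance.grid

    def combined_invalid(self) -> np.ndarray:
        """Cells masked in any driver (propagated to regional sums)."""
        m = np.zeros(self.grid.shape, dtype=bool)
        for f in (
            self.road_distance,
            self.river_distance,
            self.population,
            self.park_mask,
            self.logging_mask,
        ):
            m |= f.mask
        return m
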