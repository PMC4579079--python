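"""Raster/vector I/O, rasterization, distance fields, QA masking, aggregation.

Rasters are NetCDF (dimensions ``lat``, ``lon``, optional ``year``)
read and written through xarray.  Vector layers (road/river polylines,
park/concession polygons) are GeoJSON FeatureCollections handled with
shapely.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
import shapely
import xarray as xr
from scipy import ndimage
from shapely.geometry import mapping, shape

from .grid import DriverStack, GridSpec, QALayer, RasterField, VectorLayer

__all__ = [
    "rasterize_vector",
    "distance_to_features",
    "apply_qa_filter",
    "block_aggregate",
    "read_raster",
    "write_raster",
    "write_simulation",
    "read_vector",
    "write_vector",
    "build_driver_stack",
]

_NODATA = -9999.0


# ----------------------------------------------------------------- raster ops
def rasterize_vector(layer: VectorLayer, grid: GridSpec) -> RasterField:
    """Burn vector features onto the grid as a binary field.

    A cell is 1 iff any feature geometry intersects the cell rectangle
    (boundary touch counts), 0 otherwise.

    Raises
    ------
    ValueError
        If the layer holds no features.  A layer that does not overlap
        the grid yields an all-zero field with a warning.
    """
    if len(layer) == 0:
        raise ValueError("no features to rasterize")
    h = grid.cell_size / 2.0
    lons = grid.lons
    lats = grid.lats
    llon, llat = np.meshgrid(lons, lats)
    boxes = shapely.box(
        llon.ravel() - h, llat.ravel() - h, llon.ravel() + h, llat.ravel() + h
    )
    out = np.zeros(grid.n_rows * grid.n_cols, dtype=bool)
    tree = shapely.STRtree(boxes)
    for geom in layer:
        out[tree.query(geom, predicate="intersects")] = True
    if not out.any():
        warnings.warn("vector layer does not overlap the grid; all-zero field")
    return RasterField(grid, out.reshape(grid.shape).astype(float), units="1")


def distance_to_features(binary: RasterField) -> RasterField:
    """Planar Euclidean distance (km) from each cell to the nearest 1-cell.

    Distances are measured between cell centres on the projected grid
    using the nominal resolution; on-feature cells hold 0.
    """
    on = binary.values > 0.5
    if not on.any():
        raise ValueError("no features to measure distance to")
    res = binary.grid.nominal_resolution
    dist = ndimage.distance_transform_edt(~on, sampling=res)
    return RasterField(binary.grid, dist, binary.mask.copy(), units="km")


def apply_qa_filter(
    field: RasterField, qa: QALayer, threshold: float = 12.5
) -> RasterField:
    """Mask cells whose bad-quality percentage *strictly exceeds* the threshold.

    The comparison is strict, so a cell flagged at exactly the
    threshold (12.5% by default) is retained.  Idempotent.
    """
    if qa.grid.shape != field.grid.shape:
        raise ValueError("QA layer not co-registered with the field")
    out = field.copy()
    out.mask |= qa.percent_bad > threshold
    return out


def block_aggregate(field: RasterField, factor: int) -> RasterField:
    """Average the field onto a coarser grid of ``factor`` x ``factor`` blocks.

    Each coarse cell is the mean over the *valid* fine cells in its
    block; a coarse cell is masked only when every fine cell is masked.
    Trailing rows/columns that do not fill a block are dropped.
    """
    if factor < 1:
        raise ValueError("factor must be >= 1")
    g = field.grid
    if factor > g.n_rows or factor > g.n_cols:
        raise ValueError("aggregation factor exceeds grid dimension")
    if factor == 1:
        return field.copy()
    nr, nc = g.n_rows // factor, g.n_cols // factor
    v = field.values[: nr * factor, : nc * factor].reshape(nr, factor, nc, factor)
    ok = field.valid[: nr * factor, : nc * factor].reshape(nr, factor, nc, factor)
    counts = ok.sum(axis=(1, 3))
    sums = np.where(ok, v, 0.0).sum(axis=(1, 3))
    with np.errstate(invalid="ignore"):
        means = np.where(counts > 0, sums / np.maximum(counts, 1), 0.0)
    coarse = GridSpec(
        n_rows=nr,
        n_cols=nc,
        origin_lat=g.origin_lat - (factor - 1) * g.cell_size / 2.0,
        origin_lon=g.origin_lon + (factor - 1) * g.cell_size / 2.0,
        cell_size=g.cell_size * factor,
        nominal_resolution=g.nominal_resolution * factor,
    )
    return RasterField(coarse, means, counts == 0, units=field.units)


# ----------------------------------------------------------------- NetCDF I/O
def _grid_attrs(grid: GridSpec) -> dict:
    return {
        "cell_size_deg": grid.cell_size,
        "nominal_resolution_km": grid.nominal_resolution,
    }


def _grid_from_dataset(ds: xr.Dataset) -> GridSpec:
    lats = ds["lat"].values
    lons = ds["lon"].values
    cell = float(abs(lats[1] - lats[0])) if lats.size > 1 else float(
        ds.attrs.get("cell_size_deg", 0.05)
    )
    res = float(ds.attrs.get("nominal_resolution_km", cell * 111.0))
    return GridSpec(
        n_rows=lats.size,
        n_cols=lons.size,
        origin_lat=float(lats[0]),
        origin_lon=float(lons[0]),
        cell_size=cell,
        nominal_resolution=res,
    )


def write_raster(field: RasterField, path: str | Path, variable: str = "field") -> None:
    """Write a single field to NetCDF; mask encoded through a nodata value."""
    vals = np.where(field.mask, _NODATA, field.values)
    ds = xr.Dataset(
        {variable: (("lat", "lon"), vals, {"units": field.units, "_FillValue_raw": _NODATA})},
        coords={"lat": field.grid.lats, "lon": field.grid.lons},
        attrs=_grid_attrs(field.grid),
    )
    ds.to_netcdf(path, engine="scipy")


def read_raster(path: str | Path, variable: str = "field") -> RasterField:
    """Read one 2-D variable from a NetCDF file into a :class:`RasterField`.

    Values equal to the package nodata sentinel become masked cells.
    An unrecognized units attribute is passed through with a warning.
    """
    with xr.open_dataset(path, engine="scipy") as ds:
        if variable not in ds:
            raise KeyError(f"variable {variable!r} not found in {path}")
        da = ds[variable].load()
        grid = _grid_from_dataset(ds)
    units = str(da.attrs.get("units", "1"))
    if units not in ("1", "fraction", "km", "people km-2", "percent"):
        warnings.warn(f"unknown units attribute {units!r}; values passed through")
    vals = np.asarray(da.values, dtype=float)
    mask = np.isclose(vals, _NODATA) | np.isnan(vals)
    vals = np.where(mask, 0.0, vals)
    return RasterField(grid, vals, mask, units=units)


def write_simulation(
    covers: list[RasterField], years: list[int], path: str | Path,
    variable: str = "forest_cover",
) -> None:
    """Write an annual sequence of cover fields as one NetCDF with a year axis."""
    if len(covers) != len(years):
        raise ValueError("one cover field per year label required")
    grid = covers[0].grid
    stack = np.stack([np.where(f.mask, _NODATA, f.values) for f in covers])
    ds = xr.Dataset(
        {variable: (("year", "lat", "lon"), stack, {"units": "fraction"})},
        coords={"year": np.asarray(years, dtype=np.int32),
                "lat": grid.lats, "lon": grid.lons},
        attrs=_grid_attrs(grid),
    )
    ds.to_netcdf(path, engine="scipy")


def read_simulation(
    path: str | Path, variable: str = "forest_cover"
) -> tuple[list[RasterField], list[int]]:
    """Inverse of :func:`write_simulation`."""
    with xr.open_dataset(path, engine="scipy") as ds:
        if variable not in ds:
            raise KeyError(f"variable {variable!r} not found in {path}")
        da = ds[variable].load()
        grid = _grid_from_dataset(ds)
        years = [int(y) for y in ds["year"].values]
    covers = []
    for k in range(len(years)):
        vals = np.asarray(da.values[k], dtype=float)
        mask = np.isclose(vals, _NODATA) | np.isnan(vals)
        covers.append(RasterField(grid, np.where(mask, 0.0, vals), mask, "fraction"))
    return covers, years


# ----------------------------------------------------------------- vector I/O
def write_vector(layer: VectorLayer, path: str | Path) -> None:
    fc = {
        "type": "FeatureCollection",
        "properties": {"kind": layer.kind},
        "features": [
            {"type": "Feature", "properties": {}, "geometry": mapping(g)}
            for g in layer
        ],
    }
    Path(path).write_text(json.dumps(fc))


def read_vector(path: str | Path, kind: str | None = None) -> VectorLayer:
    fc = json.loads(Path(path).read_text())
    k = kind or fc.get("properties", {}).get("kind")
    if k is None:
        raise ValueError(f"{path}: layer kind missing; pass kind= explicitly")
    return VectorLayer([shape(f["geometry"]) for f in fc["features"]], k)


# ----------------------------------------------------------------- assembly
def build_driver_stack(
    grid: GridSpec,
    roads: VectorLayer,
    rivers: VectorLayer,
    parks: VectorLayer | None,
    concessions: VectorLayer | None,
    population: RasterField,
) -> DriverStack:
    """Rasterize vector drivers and derive the distance fields."""

    def mask_of(layer: VectorLayer | None) -> RasterField:
        if layer is None or len(layer) == 0:
            return RasterField(grid, np.zeros(grid.shape), units="1")
        return rasterize_vector(layer, grid)

    return DriverStack(
        road_distance=distance_to_features(rasterize_vector(roads, grid)),
        river_distance=distance_to_features(rasterize_vector(rivers, grid)),
        population=population,
        park_mask=mask_of(parks),
        logging_mask=mask_of(concessions),
    )
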