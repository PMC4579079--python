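"""Synthetic landscape fixtures.

Generates a co-registered set of model inputs emulating a dense
tropical-forest domain: a smooth forest-cover field close to the
potential cover with degraded corridors, road/river polylines crossing
the domain, a few protected-area and logging-concession polygons, a
population field made of exponential "towns", and a QA layer with
scattered bad-quality patches.  Everything is deterministic in the
seed, so fixtures are reproduced bit-identically at test time instead
of being shipped as data files.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from shapely.geometry import LineString, Point

from .grid import DriverStack, GridSpec, QALayer, RasterField, VectorLayer
from .grid_io import build_driver_stack

__all__ = ["ScenarioKnobs", "make_synthetic_landscape", "make_synthetic_vectors"]


@dataclass(frozen=True)
class ScenarioKnobs:
    """Dials of the fixture generator.

    Defaults emulate the Congo-core study conditions: near-saturated
    cover (potential 0.86), sparse population (peak densities of a few
    hundred people km-2 around a handful of towns), a sparse transport
    network and mostly clean QA with a few rejected patches.
    """

    f_t: float = 0.86          # potential forest cover cap
    cover_mean: float = 0.70   # target mean cover before clipping
    cover_sigma: float = 0.18  # spatial amplitude of cover variation
    smooth_cells: float = 4.0  # gaussian smoothing length, cells
    n_roads: int = 3
    n_rivers: int = 2
    n_parks: int = 2
    n_concessions: int = 2
    n_towns: int = 4
    town_peak: float = 300.0   # people km-2 at town centres
    town_scale_km: float = 12.0
    qa_bad_patches: int = 3
    qa_patch_percent: float = 30.0


def _smooth_field(rng: np.random.Generator, shape, smooth_cells: float) -> np.ndarray:
    """Zero-mean, unit-std smooth random field."""
    noise = rng.standard_normal(shape)
    f = ndimage.gaussian_filter(noise, sigma=smooth_cells, mode="reflect")
    f -= f.mean()
    sd = f.std()
    return f / sd if sd > 0 else f


def _random_crossing_line(rng: np.random.Generator, grid: GridSpec) -> LineString:
    """A jittered polyline crossing the full domain."""
    lon0, lat0, lon1, lat1 = grid.bounding_box()
    horizontal = rng.random() < 0.5
    n_way = 6
    ts = np.linspace(0.0, 1.0, n_way)
    if horizontal:
        y = rng.uniform(lat0, lat1)
        xs = lon0 + ts * (lon1 - lon0)
        ys = y + rng.normal(0.0, 0.08 * (lat1 - lat0), n_way)
    else:
        x = rng.uniform(lon0, lon1)
        ys = lat0 + ts * (lat1 - lat0)
        xs = x + rng.normal(0.0, 0.08 * (lon1 - lon0), n_way)
    xs = np.clip(xs, lon0, lon1)
    ys = np.clip(ys, lat0, lat1)
    return LineString(np.column_stack([xs, ys]))


def make_synthetic_vectors(
    seed: int, grid: GridSpec, knobs: ScenarioKnobs = ScenarioKnobs()
) -> dict[str, VectorLayer]:
    """Road/river polylines and park/concession polygons for the grid."""
    rng = np.random.default_rng([seed, 17])
    lon0, lat0, lon1, lat1 = grid.bounding_box()
    span = min(lon1 - lon0, lat1 - lat0)

    def polygons(n: int) -> list:
        out = []
        for _ in range(n):
            cx = rng.uniform(lon0 + 0.15 * (lon1 - lon0), lon1 - 0.15 * (lon1 - lon0))
            cy = rng.uniform(lat0 + 0.15 * (lat1 - lat0), lat1 - 0.15 * (lat1 - lat0))
            radius = rng.uniform(0.08, 0.18) * span
            out.append(Point(cx, cy).buffer(radius, quad_segs=8))
        return out

    layers = {
        "roads": VectorLayer(
            [_random_crossing_line(rng, grid) for _ in range(knobs.n_roads)], "roads"
        ),
        "rivers": VectorLayer(
            [_random_crossing_line(rng, grid) for _ in range(knobs.n_rivers)], "rivers"
        ),
    }
    if knobs.n_parks:
        layers["parks"] = VectorLayer(polygons(knobs.n_parks), "parks")
    if knobs.n_concessions:
        layers["concessions"] = VectorLayer(polygons(knobs.n_concessions), "concessions")
    return layers


def _population_field(
    rng: np.random.Generator, grid: GridSpec, knobs: ScenarioKnobs
) -> RasterField:
    """Sum of exponential town kernels, people km-2."""
    pop = np.zeros(grid.shape)
    if knobs.n_towns > 0:
        rr, cc = np.meshgrid(
            np.arange(grid.n_rows), np.arange(grid.n_cols), indexing="ij"
        )
        for _ in range(knobs.n_towns):
            r0 = rng.uniform(0, grid.n_rows - 1)
            c0 = rng.uniform(0, grid.n_cols - 1)
            peak = knobs.town_peak * rng.uniform(0.3, 1.0)
            d_km = np.hypot(rr - r0, cc - c0) * grid.nominal_resolution
            pop += peak * np.exp(-d_km / knobs.town_scale_km)
    return RasterField(grid, pop, units="people km-2")


def make_synthetic_landscape(
    seed: int, grid: GridSpec, knobs: ScenarioKnobs = ScenarioKnobs()
) -> tuple[RasterField, DriverStack, QALayer]:
    """Generate (cover, drivers, qa) for a seeded synthetic landscape.

    Cover is a smooth random field centred on ``cover_mean``, depressed
    near roads and towns (so risk and cover are spatially correlated,
    as on real landscapes), clipped to [0, f_t].
    """
    rng = np.random.default_rng([seed, 29])
    vectors = make_synthetic_vectors(seed, grid, knobs)
    population = _population_field(rng, grid, knobs)
    drivers = build_driver_stack(
        grid,
        roads=vectors["roads"],
        rivers=vectors["rivers"],
        parks=vectors.get("parks"),
        concessions=vectors.get("concessions"),
        population=population,
    )

    cover = knobs.cover_mean + knobs.cover_sigma * _smooth_field(
        rng, grid.shape, knobs.smooth_cells
    )
    # degrade cover along roads and around towns
    cover -= 0.25 * np.exp(-drivers.road_distance.values / 15.0)
    cover -= 0.30 * (1.0 - np.exp(-population.values / 150.0))
    cover = np.clip(cover, 0.0, knobs.f_t)
    cover_field = RasterField(grid, cover, units="fraction")

    qa = np.zeros(grid.shape)
    for _ in range(knobs.qa_bad_patches):
        r0 = rng.integers(0, grid.n_rows)
        c0 = rng.integers(0, grid.n_cols)
        half = max(1, int(0.04 * min(grid.n_rows, grid.n_cols)))
        qa[max(0, r0 - half): r0 + half, max(0, c0 - half): c0 + half] = (
            knobs.qa_patch_percent
        )
    qa_layer = QALayer(grid, qa)
    return cover_field, drivers, qa_layer
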