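"""Local deforestation risk factors and their multiplicative combination.

Each grid cell carries a total risk

    r_tot = r_road * r_pop * r_river * r_park * r_log * r_frag

built from the simplest functional forms with two constants per driver:
a maximum relative impact ``k`` and a spatial scale ``l``.  Distance
drivers decay exponentially toward a neutral value of 1 far from the
feature; population risk saturates at ``k`` with weighted density; park
and concession membership multiply risk by a constant ratio; and the
fragmentation factor is a beta-shaped function of cover that vanishes
at 0 and 100% cover and peaks at intermediate cover, encoding the edge
effect by which fragmented forest is cleared fastest.

The factors are deliberately *not* normalized — risk enters the
allocation only through its spatial pattern (a region-wide scale factor
absorbs any common multiple), so only relative changes matter.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .grid import DriverStack, GridSpec, RasterField
from .params import RiskParams

__all__ = [
    "RiskFields",
    "kernel_weighted_mean",
    "kernel_weighted_mean_bruteforce",
    "fragmentation_risk",
    "road_risk",
    "river_risk",
    "population_risk",
    "designation_risk",
    "total_risk",
    "compute_risk_fields",
]

#: Kernel truncation radius in units of the e-folding scale l.  Weights
#: beyond the cutoff are < e^-30 ~ 1e-13 of the peak, so the windowed
#: convolution is numerically indistinguishable from the full double sum.
KERNEL_TRUNCATION_FACTOR = 30.0


# ------------------------------------------------------------------ kernels
def kernel_weighted_mean(
    field: RasterField, l: float, truncation: float = KERNEL_TRUNCATION_FACTOR
) -> RasterField:
    """Exponential distance-weighted mean of a field.

    For each cell i the weighted mean over the domain's valid cells j
    (including i itself, with d_ii = 0) is

        x_bar_i = sum_j x_j exp(-d_ij / l) / sum_j exp(-d_ij / l)

    with planar distances in km.  Computed by FFT convolution with the
    kernel truncated at ``truncation * l``; masked cells contribute
    neither to the numerator nor the normalization.
    """
    if l <= 0:
        raise ValueError("kernel scale l must be > 0")
    g = field.grid
    res = g.nominal_resolution
    radius = int(np.ceil(truncation * l / res))
    radius = max(1, min(radius, max(g.n_rows, g.n_cols) - 1))
    offsets = np.arange(-radius, radius + 1)
    dy, dx = np.meshgrid(offsets, offsets, indexing="ij")
    kernel = np.exp(-np.hypot(dy, dx) * res / l)

    valid = field.valid.astype(float)
    num = signal.fftconvolve(field.values * valid, kernel, mode="same")
    den = signal.fftconvolve(valid, kernel, mode="same")
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(den > 0, num / den, 0.0)
    # FFT round-off can nudge values past the data range; clip back.
    v = field.values[field.valid]
    if v.size:
        out = np.clip(out, v.min(), v.max())
    return field.with_values(out)


def kernel_weighted_mean_bruteforce(field: RasterField, l: float) -> RasterField:
    """Untruncated double-sum evaluation of the weighted mean.

    O(n_cells^2); the reference oracle for small grids.
    """
    if l <= 0:
        raise ValueError("kernel scale l must be > 0")
    d = field.grid.pairwise_distance_km()
    w = np.exp(-d / l)
    x = field.values.ravel()
    ok = field.valid.ravel().astype(float)
    num = w @ (x * ok)
    den = w @ ok
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(den > 0, num / den, 0.0)
    return field.with_values(out.reshape(field.grid.shape))


# ------------------------------------------------------------------ factors
def fragmentation_risk(
    f: RasterField, f_bar: RasterField, params: RiskParams
) -> RasterField:
    """Beta-shaped fragmentation/edge-effect risk.

    Default (``as_printed``) form:

        r_frag = (k_frag - 1) * f^p * (1 - f_bar)^q / 0.5^(p+q+1)

    which vanishes at f = 0 and at f_bar = 1 and, for homogeneous cover
    (f_bar = f), peaks at 50% cover.  The local cover f enters the
    rising limb (sparse remnants carry little risk) while the
    neighbourhood-weighted cover f_bar drives the edge term.

    The ``k_at_half`` variant rescales to (k_frag - 1) * f^p *
    (1 - f_bar)^q / 0.5^(p+q) + 1 so that homogeneous 50% cover carries
    risk exactly k_frag, at the cost of a neutral (1, not 0) floor.
    """
    k, p, q = params.k_frag, params.p, params.q
    fv = np.clip(f.values, 0.0, 1.0)
    fb = np.clip(f_bar.values, 0.0, 1.0)
    core = (k - 1.0) * fv**p * (1.0 - fb) ** q
    if params.frag_normalization == "as_printed":
        out = core / 0.5 ** (p + q + 1.0)
    else:  # k_at_half
        out = core / 0.5 ** (p + q) + 1.0
    return f.with_values(out, units="1")


def road_risk(d: RasterField, k: float, l: float) -> RasterField:
    """r = (k - 1) exp(-d / l) + 1: k on the feature, decaying to 1."""
    if l <= 0:
        raise ValueError("road e-folding scale must be > 0")
    return d.with_values((k - 1.0) * np.exp(-d.values / l) + 1.0, units="1")


def river_risk(d: RasterField, k: float, l: float) -> RasterField:
    """Identical form to :func:`road_risk` with the river constants."""
    if l <= 0:
        raise ValueError("river e-folding scale must be > 0")
    return d.with_values((k - 1.0) * np.exp(-d.values / l) + 1.0, units="1")


def population_risk(p_bar: RasterField, k: float, d_p: float) -> RasterField:
    """r = (k - 1)(1 - exp(-p_bar / d_p)) + 1: 1 when empty, saturating at k."""
    if d_p <= 0:
        raise ValueError("population e-folding density d_p must be > 0")
    return p_bar.with_values(
        (k - 1.0) * (1.0 - np.exp(-p_bar.values / d_p)) + 1.0, units="1"
    )


def designation_risk(mask: RasterField, k_inside: float) -> RasterField:
    """Constant factor k inside the designated polygons, 1 outside.

    Used for protected areas (k_park <= 1 when protection is enforced)
    and logging concessions (k_log >= 1).
    """
    return mask.with_values(
        np.where(mask.values > 0.5, k_inside, 1.0), units="1"
    )


@dataclass
class RiskFields:
    """The six per-factor fields plus their product."""

    road: RasterField
    river: RasterField
    pop: RasterField
    park: RasterField
    log: RasterField
    frag: RasterField
    total: RasterField


def total_risk(
    road: RasterField,
    river: RasterField,
    pop: RasterField,
    park: RasterField,
    log: RasterField,
    frag: RasterField,
) -> RasterField:
    """Element-wise product of the six factors (order-independent)."""
    factors = (road, river, pop, park, log, frag)
    shape = road.grid.shape
    for f in factors:
        if f is None:
            raise ValueError("missing risk factor")
        if f.grid.shape != shape:
            raise ValueError("risk factors not co-registered")
    out = np.ones(shape)
    mask = np.zeros(shape, dtype=bool)
    for f in factors:
        out = out * f.values
        mask |= f.mask
    return RasterField(road.grid, out, mask, units="1")


def compute_risk_fields(
    cover: RasterField,
    drivers: DriverStack,
    params: RiskParams,
    p_bar: RasterField | None = None,
) -> RiskFields:
    """Evaluate all six factors for the current cover and static drivers.

    ``p_bar`` (the distance-weighted population density) depends only
    on the static population map and may be precomputed once and passed
    in to avoid re-convolving every year.
    """
    if p_bar is None:
        p_bar = kernel_weighted_mean(drivers.population, params.l_p)
    f_bar = kernel_weighted_mean(cover, params.l_f)
    road = road_risk(drivers.road_distance, params.k_road, params.l_road)
    river = river_risk(drivers.river_distance, params.k_river, params.l_river)
    pop = population_risk(p_bar, params.k_pop, params.d_p)
    park = designation_risk(drivers.park_mask, params.k_park)
    logf = designation_risk(drivers.logging_mask, params.k_log)
    frag = fragmentation_risk(cover, f_bar, params)
    tot = total_risk(road, river, pop, park, logf, frag)
    return RiskFields(road, river, pop, park, logf, frag, tot)
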