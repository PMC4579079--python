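"""Trend-based evaluation of simulated cover against an observed series.

Decadal cover series are too noisy (and too gappy, after QA masking)
for year-by-year comparison, so both model and observations are
reduced to a per-pixel linear trend over the simulated period.  Trends
are then block-averaged to a coarser evaluation grid — allocation is
quasi-stochastic at the native resolution, so skill is measured at a
scale where the spatial pattern, not the individual pixel, matters —
and compared with Pearson correlation, RMSE and bias.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .grid import RasterField
from .grid_io import block_aggregate

__all__ = [
    "TrendField",
    "EvaluationReport",
    "pixel_linear_trend",
    "compare_trends",
    "hyde_forest_fraction",
]

#: Minimum valid annual maps a pixel needs for a trend (decade series).
MIN_VALID_YEARS = 5


@dataclass
class TrendField:
    """Per-cell OLS slope of cover against year."""

    slope: RasterField          # fraction yr-1
    n_years: np.ndarray         # valid years used per cell


@dataclass
class EvaluationReport:
    """Spatial skill scores over jointly valid coarse cells."""

    R: float
    RMSE: float
    bias: float                 # mean(model) - mean(obs)
    n_cells: int
    aggregation_factor: int

    def to_dict(self) -> dict:
        return {
            "R": self.R,
            "RMSE": self.RMSE,
            "BIAS": self.bias,
            "n_cells": self.n_cells,
            "aggregation_factor": self.aggregation_factor,
        }


def pixel_linear_trend(
    series: list[RasterField],
    years: list[int] | None = None,
    min_valid_years: int = MIN_VALID_YEARS,
) -> TrendField:
    """Per-pixel OLS slope of the annual cover series.

    Cells with fewer than ``min_valid_years`` unmasked years are
    masked (the requirement is clamped to the series length, so short
    series remain usable).  Years are centred before the fit for
    conditioning (the slope is unchanged).
    """
    if len(series) < 2:
        raise ValueError("at least two annual fields are required for a trend")
    min_valid_years = max(2, min(min_valid_years, len(series)))
    grid = series[0].grid
    t = np.asarray(
        years if years is not None else range(len(series)), dtype=float
    )
    if t.size != len(series):
        raise ValueError("one year label per field required")
    vals = np.stack([f.values for f in series])          # (T, R, C)
    ok = np.stack([f.valid for f in series])
    n = ok.sum(axis=0)

    tt = t[:, None, None] * np.ones_like(vals)
    t_sum = np.where(ok, tt, 0.0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        t_mean = np.where(n > 0, t_sum / np.maximum(n, 1), 0.0)
    v_sum = np.where(ok, vals, 0.0).sum(axis=0)
    v_mean = np.where(n > 0, v_sum / np.maximum(n, 1), 0.0)
    dt = np.where(ok, tt - t_mean, 0.0)
    dv = np.where(ok, vals - v_mean, 0.0)
    sxx = (dt * dt).sum(axis=0)
    sxy = (dt * dv).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        slope = np.where(sxx > 0, sxy / np.where(sxx > 0, sxx, 1.0), 0.0)
    mask = (n < min_valid_years) | (sxx <= 0)
    return TrendField(
        RasterField(grid, slope, mask, units="fraction yr-1"), n
    )


def compare_trends(
    model: TrendField, obs: TrendField, factor: int = 1
) -> EvaluationReport:
    """Aggregate both trend fields and score the spatial agreement.

    Both fields are block-averaged by ``factor`` (e.g. 10 to go from a
    5 km to a 50 km evaluation grid), then Pearson R, RMSE and bias
    (model minus observations) are computed over the coarse cells valid
    in both.
    """
    if model.slope.grid.shape != obs.slope.grid.shape:
        raise ValueError("model and observed trends are not co-registered")
    m = block_aggregate(model.slope, factor)
    o = block_aggregate(obs.slope, factor)
    joint = m.valid & o.valid
    n = int(joint.sum())
    if n < 3:
        raise ValueError("correlation undefined: fewer than 3 joint cells")
    x = m.values[joint]
    y = o.values[joint]
    if x.std() == 0.0 or y.std() == 0.0:
        raise ValueError("correlation undefined: zero variance in a field")
    r = float(np.corrcoef(x, y)[0, 1])
    rmse = float(np.sqrt(np.mean((x - y) ** 2)))
    bias = float(x.mean() - y.mean())
    return EvaluationReport(R=r, RMSE=rmse, bias=bias, n_cells=n,
                            aggregation_factor=factor)


def hyde_forest_fraction(
    primary: RasterField, secondary: RasterField, potential: RasterField
) -> RasterField:
    """Benchmark-style forest fraction from land-use categories.

    Forest = (primary + secondary land fraction) x potential forest
    cover, the standard derivation for harmonized land-use databases
    that report primary/secondary proportions instead of forest cover
    directly.
    """
    psum = primary.values + secondary.values
    valid = primary.valid & secondary.valid
    if np.any(psum[valid] > 1.0 + 1e-9):
        raise ValueError("primary + secondary fraction exceeds 1")
    pot = potential.values
    if np.any((pot < -1e-12) | (pot > 1.0 + 1e-12)):
        raise ValueError("potential cover must lie in [0, 1]")
    out = psum * pot
    mask = primary.mask | secondary.mask | potential.mask
    return RasterField(primary.grid, out, mask, units="fraction")
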