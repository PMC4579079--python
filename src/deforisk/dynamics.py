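"""Annual forest-cover dynamics: risk-proportional allocation of a
macro-regional deforestation rate.

Each macro-region Omega carries a prescribed *net* annual rate M(t),
expressed as a fraction of the region's current total forest cover per
year.  Sign convention (used consistently throughout the package):
M, alpha and the gross change D are negative for net loss; the
reforestation rate A is >= 0.  One annual step solves, per region, for
the scale factor

    alpha = (M * sum(f) - sum(A)) / sum(r_tot * f)

so that the risk-proportional gross change D_i = alpha * r_tot_i * f_i
plus reforestation meets the regional demand exactly:

    sum(D) + sum(A) = M * sum(f).

Cells driven outside [0, f_t] are clamped and the unmet demand is
redistributed over the remaining cells by re-solving alpha, iterating
until the regional budget closes to a relative tolerance.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .grid import DriverStack, GridSpec, RasterField
from .params import RiskParams
from .risk import RiskFields, compute_risk_fields, kernel_weighted_mean

__all__ = [
    "MacroScenario",
    "SimState",
    "StepDiagnostics",
    "SimulationResult",
    "reforestation_rate",
    "scale_factor",
    "gross_change",
    "pft_update",
    "annual_step",
    "run_simulation",
]

logger = logging.getLogger(__name__)

MAX_REBALANCE_ITERATIONS = 20
REBALANCE_RTOL = 1e-6

#: PFT bookkeeping: index 0 tracks forest, index 1 the replacement
#: category (agriculture/pasture) absorbing cleared area.
PFT_CATEGORIES = ("forest", "replacement")


@dataclass
class MacroScenario:
    """Macro-region labels and per-region, per-year net rates.

    region_mask
        Integer labels on the grid; every valid cell belongs to exactly
        one region.
    rates
        ``{region_label: {year: M}}`` with M a signed fraction yr-1
        (negative = net deforestation).
    param_overrides
        Optional per-region :class:`RiskParams` replacing the global set.
    """

    region_mask: RasterField
    rates: dict[int, dict[int, float]]
    param_overrides: dict[int, RiskParams] = field(default_factory=dict)

    @classmethod
    def uniform(
        cls, grid: GridSpec, rate: float, years: range | list[int], label: int = 1
    ) -> "MacroScenario":
        """Single region covering the grid with one constant rate."""
        mask = RasterField(grid, np.full(grid.shape, float(label)))
        return cls(mask, {label: {int(y): rate for y in years}})

    def labels(self) -> list[int]:
        return sorted(self.rates)

    def rate_for(self, label: int, year: int) -> float:
        try:
            return self.rates[label][year]
        except KeyError:
            raise KeyError(f"no rate for region {label} in year {year}") from None

    def region_cells(self, label: int) -> np.ndarray:
        return (self.region_mask.values.astype(int) == label) & self.region_mask.valid


@dataclass
class SimState:
    """Forest cover and PFT fractions at the start of a calendar year."""

    year: int
    cover: RasterField
    pft: np.ndarray | None = None  # (2, n_rows, n_cols), sums to 1 per cell

    def __post_init__(self) -> None:
        if self.pft is None:
            f = np.clip(self.cover.values, 0.0, 1.0)
            self.pft = np.stack([f, 1.0 - f])
        self.pft = np.asarray(self.pft, dtype=float)
        sums = self.pft.sum(axis=0)
        if not np.allclose(sums, 1.0, atol=1e-9):
            raise ValueError("PFT fractions must sum to 1 per cell")


@dataclass
class StepDiagnostics:
    """Per-region budget terms recorded at every annual step."""

    year: int
    alpha: dict[int, float]
    sum_D: dict[int, float]
    sum_A: dict[int, float]
    sum_f: dict[int, float]
    clamped_cells: int
    rebalance_iterations: int


@dataclass
class SimulationResult:
    """Annual cover states, risk snapshots and the diagnostics table."""

    states: list[SimState]
    diagnostics: list[StepDiagnostics]
    risk_history: list[RiskFields] | None = None

    @property
    def years(self) -> list[int]:
        return [s.year for s in self.states]

    @property
    def covers(self) -> list[RasterField]:
        return [s.cover for s in self.states]

    def diagnostics_table(self) -> pd.DataFrame:
        rows = []
        for d in self.diagnostics:
            for label in d.alpha:
                rows.append(
                    {
                        "year": d.year,
                        "region": label,
                        "alpha": d.alpha[label],
                        "sum_D": d.sum_D[label],
                        "sum_A": d.sum_A[label],
                        "sum_f": d.sum_f[label],
                        "clamped_cells": d.clamped_cells,
                        "rebalance_iterations": d.rebalance_iterations,
                    }
                )
        return pd.DataFrame(rows)


# ----------------------------------------------------------------- pieces
def reforestation_rate(
    cover: RasterField, p_bar: RasterField, params: RiskParams
) -> RasterField:
    """Regrowth rate A_i >= 0 toward a population-modified potential cover.

    A_i = (f_t * exp(-p_bar_i / tau_rp) - f_i) / tau_r, floored at zero
    where the cover already exceeds the modified potential.  The
    exponential discount encodes the higher likelihood of *permanent*
    conversion near dense population.
    """
    modified_potential = params.f_t * np.exp(-p_bar.values / params.tau_rp)
    a = (modified_potential - cover.values) / params.tau_r
    return cover.with_values(np.maximum(a, 0.0), units="fraction yr-1")


def scale_factor(
    M: float,
    cover: RasterField,
    risk: RasterField,
    A: RasterField,
    region_cells: np.ndarray,
) -> float:
    """Regional scale factor alpha = (M*sum(f) - sum(A)) / sum(r*f)."""
    cells = region_cells & cover.valid & risk.valid
    f = cover.values[cells]
    demand = M * f.sum() - A.values[cells].sum()
    weight = (risk.values[cells] * f).sum()
    if weight <= 0.0:
        if abs(demand) > 0.0:
            raise ValueError(
                "cannot allocate demand: region has zero total risk-weighted cover"
            )
        return 0.0
    return float(demand / weight)


def gross_change(alpha: float, risk: RasterField, cover: RasterField) -> RasterField:
    """Per-cell gross deforestation D_i = alpha * r_tot_i * f_i."""
    if not np.isfinite(alpha):
        raise ValueError("alpha must be finite")
    return cover.with_values(
        alpha * risk.values * cover.values, units="fraction yr-1"
    )


def pft_update(pft: np.ndarray, delta_forest: np.ndarray) -> np.ndarray:
    """Transfer cover change between the forest and replacement categories.

    Forest gains delta, replacement loses delta; per-cell sums are
    preserved exactly.  Raises if any fraction would leave [0, 1].
    """
    out = pft.copy()
    out[0] += delta_forest
    out[1] -= delta_forest
    if out.min() < -1e-9 or out.max() > 1.0 + 1e-9:
        raise ValueError("PFT update would drive a fraction outside [0, 1]")
    return np.clip(out, 0.0, 1.0)


# ----------------------------------------------------------------- stepping
def annual_step(
    state: SimState,
    drivers: DriverStack,
    params: RiskParams,
    scenario: MacroScenario,
    p_bar: RasterField | None = None,
    reforestation: bool = True,
    risk_fields: RiskFields | None = None,
) -> tuple[SimState, StepDiagnostics]:
    """Advance the cover one year.

    Risk is evaluated on the current cover (fragmentation feedback),
    reforestation and the regional scale factors are computed, and the
    new cover is clamped to [0, f_t] with iterative redistribution of
    any demand unmet because of clamping.
    """
    cover = state.cover
    if p_bar is None:
        p_bar = kernel_weighted_mean(drivers.population, params.l_p)
    if risk_fields is None:
        risk_fields = compute_risk_fields(cover, drivers, params, p_bar=p_bar)
    risk = risk_fields.total

    if reforestation:
        A = reforestation_rate(cover, p_bar, params)
    else:
        A = cover.with_values(np.zeros(cover.grid.shape), units="fraction yr-1")

    invalid = cover.mask | drivers.combined_invalid() | risk.mask
    f_old = cover.values
    new = f_old.copy()
    alpha_by_region: dict[int, float] = {}
    sum_D: dict[int, float] = {}
    sum_A: dict[int, float] = {}
    sum_f: dict[int, float] = {}
    total_clamped = 0
    max_iters_used = 0

    for label in scenario.labels():
        M = scenario.rate_for(label, state.year)
        region = scenario.region_cells(label) & ~invalid
        if not region.any():
            continue
        f_r = f_old[region]
        r_r = risk.values[region]
        a_r = A.values[region]
        target = M * f_r.sum()  # signed demand: total cover change wanted
        free = np.ones(f_r.size, dtype=bool)
        delta = np.zeros(f_r.size)
        alpha = 0.0
        iters = 0
        for iters in range(1, MAX_REBALANCE_ITERATIONS + 1):
            # demand still to be met by the free cells, after the change
            # already locked in on clamped cells
            locked = delta[~free].sum()
            demand = target - locked - a_r[free].sum()
            weight = (r_r[free] * f_r[free]).sum()
            if weight <= 0.0:
                if abs(demand) > abs(target) * REBALANCE_RTOL + 1e-15:
                    raise ValueError(
                        f"cannot allocate demand in region {label}: no "
                        "risk-weighted cover left after clamping"
                    )
                break
            alpha = demand / weight
            trial = f_r + np.where(free, alpha * r_r * f_r + a_r, delta)
            clipped = np.clip(trial, 0.0, params.f_t)
            delta = clipped - f_r
            newly_clamped = free & ~np.isclose(trial, clipped, rtol=0.0, atol=1e-15)
            achieved = delta.sum()
            residual = target - achieved
            if abs(residual) <= abs(target) * REBALANCE_RTOL + 1e-15:
                break
            if not newly_clamped.any():
                break
            free &= ~newly_clamped
        else:
            iters = MAX_REBALANCE_ITERATIONS
        achieved = delta.sum()
        if abs(target - achieved) > abs(target) * REBALANCE_RTOL + 1e-12:
            warnings.warn(
                f"region {label}, year {state.year}: residual demand "
                f"{target - achieved:+.3e} after {iters} rebalancing iterations"
            )
        new[region] = f_r + delta
        alpha_by_region[label] = alpha
        # On clamped cells D and A are folded into the locked delta, so
        # book reforestation on free cells and charge the rest to D.
        sum_A[label] = float(a_r[free].sum())
        sum_D[label] = float(delta.sum() - a_r[free].sum())
        sum_f[label] = float(f_r.sum())
        total_clamped += int((~free).sum())
        max_iters_used = max(max_iters_used, iters)

    new = np.where(invalid, f_old, new)
    new_cover = RasterField(cover.grid, new, cover.mask.copy(), cover.units)
    delta_forest = np.where(invalid, 0.0, new - f_old)
    new_pft = pft_update(state.pft, delta_forest)
    diag = StepDiagnostics(
        year=state.year,
        alpha=alpha_by_region,
        sum_D=sum_D,
        sum_A=sum_A,
        sum_f=sum_f,
        clamped_cells=total_clamped,
        rebalance_iterations=max_iters_used,
    )
    return SimState(state.year + 1, new_cover, new_pft), diag


def run_simulation(
    initial: SimState,
    years: int,
    drivers: DriverStack,
    params: RiskParams,
    scenario: MacroScenario,
    perturbations=None,
    reforestation: bool = True,
    keep_risk: bool = False,
) -> SimulationResult:
    """Integrate the model ``years`` annual steps from the initial state.

    Returns the initial state plus one state per simulated year.  Risk
    is recomputed every year from the evolving cover; the population
    kernel mean is computed once (the driver maps are static).  If a
    :class:`~deforisk.ensemble.PerturbationConfig` is supplied, the
    physical parameters and/or the cover receive the configured
    seed-deterministic perturbations each year.
    """
    if years < 1:
        raise ValueError("years must be >= 1")
    p_bar = kernel_weighted_mean(drivers.population, params.l_p)
    states = [initial]
    diagnostics: list[StepDiagnostics] = []
    risk_history: list[RiskFields] = []
    state = initial
    for step in range(years):
        step_params = params
        if perturbations is not None:
            step_params = perturbations.perturb_params(params, year=state.year)
            state = SimState(
                state.year,
                perturbations.perturb_cover(state.cover, year=state.year,
                                            f_t=params.f_t),
                state.pft,
            )
        rf = compute_risk_fields(state.cover, drivers, step_params, p_bar=p_bar)
        if keep_risk:
            risk_history.append(rf)
        state, diag = annual_step(
            state, drivers, step_params, scenario,
            p_bar=p_bar, reforestation=reforestation, risk_fields=rf,
        )
        states.append(state)
        diagnostics.append(diag)
    return SimulationResult(states, diagnostics, risk_history if keep_risk else None)
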