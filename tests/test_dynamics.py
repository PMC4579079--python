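"""Annual stepping: reforestation, scale factor, allocation, conservation."""

import numpy as np
import pytest

from deforisk import (
    GridSpec,
    MacroScenario,
    RasterField,
    RiskParams,
    SimState,
    annual_step,
    gross_change,
    make_synthetic_landscape,
    pft_update,
    reforestation_rate,
    run_simulation,
    scale_factor,
)
from deforisk.ensemble import PerturbationConfig
from conftest import constant_field


class TestReforestationRate:
    def test_at_potential_no_regrowth(self, grid5, params):
        cover = constant_field(grid5, params.f_t, "fraction")
        p_bar = constant_field(grid5, 0.0, "people km-2")
        out = reforestation_rate(cover, p_bar, params)
        np.testing.assert_allclose(out.values, 0.0, atol=1e-15)

    def test_bare_ground_regrows_at_potential_over_timescale(self, grid5, params):
        cover = constant_field(grid5, 0.0, "fraction")
        p_bar = constant_field(grid5, 0.0, "people km-2")
        out = reforestation_rate(cover, p_bar, params)
        np.testing.assert_allclose(out.values, 0.86 / 60.0, rtol=1e-12)

    def test_cover_above_modified_potential_is_floored_at_zero(self, grid5, params):
        # dense population discounts the potential below current cover
        cover = constant_field(grid5, 0.80, "fraction")
        p_bar = constant_field(grid5, 1000.0, "people km-2")
        out = reforestation_rate(cover, p_bar, params)
        assert np.all(out.values == 0.0)
        assert 0.86 * np.exp(-1000.0 / params.tau_rp) < 0.80  # premise

    def test_nonnegative_everywhere(self, grid5, params):
        rng = np.random.default_rng(6)
        cover = RasterField(grid5, rng.uniform(0, 0.86, grid5.shape))
        p_bar = RasterField(grid5, rng.uniform(0, 500, grid5.shape))
        assert reforestation_rate(cover, p_bar, params).values.min() >= 0.0


class TestScaleFactor:
    def test_uniform_risk_reduces_to_macro_rate(self, grid5):
        cover = constant_field(grid5, 0.5, "fraction")
        risk = constant_field(grid5, 1.0)
        A = constant_field(grid5, 0.0)
        region = np.ones(grid5.shape, bool)
        alpha = scale_factor(-0.01, cover, risk, A, region)
        assert alpha == pytest.approx(-0.01, rel=1e-12)

    def test_two_cell_toy_closed_form(self):
        # f = (0.5, 0.5), r = (2, 1), A = 0, M = -0.01:
        # alpha = (-0.01 * 1.0) / (2*0.5 + 1*0.5) = -1/150
        grid = GridSpec(1, 2)
        cover = RasterField(grid, np.array([[0.5, 0.5]]))
        risk = RasterField(grid, np.array([[2.0, 1.0]]))
        A = RasterField(grid, np.zeros((1, 2)))
        alpha = scale_factor(-0.01, cover, risk, A, np.ones((1, 2), bool))
        assert alpha == pytest.approx(-0.01 / 1.5, rel=1e-12)
        D = gross_change(alpha, risk, cover)
        assert D.values[0, 0] == pytest.approx(alpha * 2.0 * 0.5, rel=1e-12)
        # conservation: sum(D) + sum(A) = M * sum(f)
        assert D.values.sum() == pytest.approx(-0.01 * 1.0, rel=1e-12)

    def test_reforestation_balances_demand_to_zero_alpha(self, grid5):
        cover = constant_field(grid5, 0.5, "fraction")
        risk = constant_field(grid5, 2.0)
        M = 0.004
        A = constant_field(grid5, M * 0.5)  # sum(A) = M * sum(f)
        alpha = scale_factor(M, cover, risk, A, np.ones(grid5.shape, bool))
        assert alpha == pytest.approx(0.0, abs=1e-15)

    def test_zero_weighted_cover_with_demand_raises(self, grid5):
        # bare region with nonzero reforestation: demand M*sum(f) - sum(A)
        # is nonzero but there is no risk-weighted cover to allocate it to
        cover = constant_field(grid5, 0.0, "fraction")
        risk = constant_field(grid5, 1.0)
        A = constant_field(grid5, 0.001)
        with pytest.raises(ValueError, match="cannot allocate"):
            scale_factor(-0.01, cover, risk, A, np.ones(grid5.shape, bool))


class TestGrossChange:
    def test_zero_cover_and_zero_alpha_give_zero(self, grid5):
        risk = constant_field(grid5, 3.0)
        zero_cover = constant_field(grid5, 0.0, "fraction")
        np.testing.assert_allclose(
            gross_change(-0.1, risk, zero_cover).values, 0.0
        )
        cover = constant_field(grid5, 0.5, "fraction")
        np.testing.assert_allclose(gross_change(0.0, risk, cover).values, 0.0)

    def test_allocation_proportional_to_risk_times_cover(self, grid5):
        rng = np.random.default_rng(8)
        risk = RasterField(grid5, rng.uniform(0.1, 5.0, grid5.shape))
        cover = RasterField(grid5, rng.uniform(0.1, 0.8, grid5.shape))
        D = gross_change(-0.02, risk, cover).values
        ratio = D / (risk.values * cover.values)
        np.testing.assert_allclose(ratio, -0.02, rtol=1e-12)


class TestPftUpdate:
    def test_zero_delta_unchanged(self):
        pft = np.stack([np.full((2, 2), 0.8), np.full((2, 2), 0.2)])
        out = pft_update(pft, np.zeros((2, 2)))
        np.testing.assert_array_equal(out, pft)

    def test_loss_moves_to_replacement_and_back(self):
        pft = np.stack([np.full((1, 1), 0.8), np.full((1, 1), 0.2)])
        lost = pft_update(pft, np.full((1, 1), -0.1))
        np.testing.assert_allclose(lost[0], 0.7)
        np.testing.assert_allclose(lost[1], 0.3)
        regrown = pft_update(lost, np.full((1, 1), 0.05))
        np.testing.assert_allclose(regrown[0], 0.75)
        np.testing.assert_allclose(regrown.sum(axis=0), 1.0)

    def test_negative_fraction_raises(self):
        pft = np.stack([np.full((1, 1), 0.8), np.full((1, 1), 0.2)])
        with pytest.raises(ValueError, match="outside"):
            pft_update(pft, np.full((1, 1), 0.5))


class TestAnnualStep:
    def test_null_step_leaves_cover_unchanged(self, landscape, params):
        cover, drivers, _ = landscape
        scen = MacroScenario.uniform(cover.grid, 0.0, [2001])
        state, diag = annual_step(
            SimState(2001, cover), drivers, params, scen, reforestation=False
        )
        np.testing.assert_array_equal(state.cover.values, cover.values)
        assert state.year == 2002

    def test_domain_total_follows_macro_rate(self, landscape, params):
        cover, drivers, _ = landscape
        M = -1e-4
        scen = MacroScenario.uniform(cover.grid, M, [2001])
        state, diag = annual_step(
            SimState(2001, cover), drivers, params, scen, reforestation=False
        )
        rel = (state.cover.sum() - cover.sum()) / cover.sum()
        assert rel == pytest.approx(M, rel=1e-6)

    def test_conservation_before_clamping_is_algebraic(self, landscape, params):
        cover, drivers, _ = landscape
        M = -1e-4
        scen = MacroScenario.uniform(cover.grid, M, [2001])
        _, diag = annual_step(SimState(2001, cover), drivers, params, scen)
        target = M * diag.sum_f[1]
        assert diag.sum_D[1] + diag.sum_A[1] == pytest.approx(target, rel=1e-12)

    def test_monotone_loss_with_reforestation_disabled(self, landscape, params):
        cover, drivers, _ = landscape
        scen = MacroScenario.uniform(cover.grid, -0.01, [2001])
        state, _ = annual_step(
            SimState(2001, cover), drivers, params, scen, reforestation=False
        )
        assert np.all(state.cover.values <= cover.values + 1e-15)

    def test_cover_stays_within_bounds(self, landscape, params):
        cover, drivers, _ = landscape
        scen = MacroScenario.uniform(cover.grid, -0.05, [2001])
        state, _ = annual_step(SimState(2001, cover), drivers, params, scen)
        assert state.cover.values.min() >= 0.0
        assert state.cover.values.max() <= params.f_t + 1e-12

    def test_clamped_residual_redistributed_three_cell_toy(self):
        # f = (0.01, 0.5, 0.5), r = (10, 1, 1), M = -0.5, A = 0.
        # First pass: alpha = -0.505/1.1; cell 1 would go negative, so it
        # clamps at 0 (delta -0.01). Residual -0.495 reallocated over the
        # free cells (weight 1.0): each loses 0.2475.  Hand-derived oracle.
        grid = GridSpec(1, 3)
        cover = RasterField(grid, np.array([[0.01, 0.5, 0.5]]))
        drivers = _uniform_drivers(grid)
        risk = RasterField(grid, np.array([[10.0, 1.0, 1.0]]))

        M = -0.5
        scen = MacroScenario.uniform(grid, M, [2001])
        params = RiskParams()
        state, diag = annual_step(
            SimState(2001, cover),
            drivers,
            params,
            scen,
            reforestation=False,
            risk_fields=_fixed_risk(risk),
        )
        np.testing.assert_allclose(
            state.cover.values, [[0.0, 0.2525, 0.2525]], atol=1e-12
        )
        total_change = state.cover.values.sum() - cover.values.sum()
        assert total_change == pytest.approx(M * 1.01, rel=1e-9)
        assert diag.clamped_cells == 1


def _uniform_drivers(grid):
    from deforisk import DriverStack

    zero = RasterField(grid, np.zeros(grid.shape))
    return DriverStack(
        road_distance=RasterField(grid, np.full(grid.shape, 50.0), units="km"),
        river_distance=RasterField(grid, np.full(grid.shape, 50.0), units="km"),
        population=zero.with_values(np.zeros(grid.shape), "people km-2"),
        park_mask=zero.copy(),
        logging_mask=zero.copy(),
    )


def _fixed_risk(total: RasterField):
    from deforisk import RiskFields

    one = total.with_values(np.ones(total.grid.shape))
    return RiskFields(one, one, one, one, one, total, total)


class TestRunSimulation:
    def test_year_labels_inclusive_of_initial_state(self, landscape, params):
        cover, drivers, _ = landscape
        scen = MacroScenario.uniform(cover.grid, -1e-4, range(2001, 2010))
        result = run_simulation(
            SimState(2001, cover), 9, drivers, params, scen, reforestation=False
        )
        assert result.years == list(range(2001, 2011))

    def test_static_run_all_states_identical(self, landscape, params):
        cover, drivers, _ = landscape
        scen = MacroScenario.uniform(cover.grid, 0.0, range(2001, 2004))
        result = run_simulation(
            SimState(2001, cover), 3, drivers, params, scen, reforestation=False
        )
        for state in result.states[1:]:
            np.testing.assert_array_equal(state.cover.values, cover.values)

    def test_stochastic_run_is_seed_deterministic(self, landscape, params):
        cover, drivers, _ = landscape
        scen = MacroScenario.uniform(cover.grid, -1e-3, range(2001, 2004))
        pert = PerturbationConfig(seed=5, ppe_amplitude=0.1, stochastic_sigma=0.02)
        runs = [
            run_simulation(
                SimState(2001, cover), 3, drivers, params, scen, perturbations=pert
            )
            for _ in range(2)
        ]
        np.testing.assert_array_equal(
            runs[0].states[-1].cover.values, runs[1].states[-1].cover.values
        )

    def test_diagnostics_table_has_row_per_region_year(self, landscape, params):
        cover, drivers, _ = landscape
        scen = MacroScenario.uniform(cover.grid, -1e-4, range(2001, 2004))
        result = run_simulation(
            SimState(2001, cover), 3, drivers, params, scen
        )
        table = result.diagnostics_table()
        assert len(table) == 3
        assert set(table.columns) >= {"year", "region", "alpha", "sum_D", "sum_A"}

    def test_missing_rate_for_year_raises(self, landscape, params):
        cover, drivers, _ = landscape
        scen = MacroScenario.uniform(cover.grid, -1e-4, [2001])
        with pytest.raises(KeyError, match="no rate"):
            run_simulation(SimState(2001, cover), 2, drivers, params, scen)
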