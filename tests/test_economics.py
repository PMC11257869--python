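"""Costing, utilities and discounted accumulation."""

import numpy as np
import pytest

from escea.economics import (
    AEItem,
    CEResult,
    DosingRule,
    EconSettings,
    Population,
    UtilitySet,
    accumulate,
    ae_burden,
    calvert_dose,
    discount_factor,
    drug_cost_per_cycle,
    drug_cost_vector,
)
from escea.markov import CohortTrace, CycleGrid, state_occupancy
from escea.survival import HazardRatio, ParametricSurvival, apply_hr


def immortal_trace(grid):
    occ = np.tile([1.0, 0.0, 0.0], (grid.n_cycles + 1, 1))
    return CohortTrace(occupancy=occ, times_months=grid.times_months())


class TestCalvert:
    @pytest.mark.parametrize("auc,crcl,expected", [(5, 70, 475), (5, 0, 125), (6, 70, 570)])
    def test_dose(self, auc, crcl, expected):
        assert calvert_dose(auc, crcl) == expected

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            calvert_dose(-5, 70)
        with pytest.raises(ValueError):
            calvert_dose(5, -1)


class TestDrugCost:
    def test_flat_rule(self):
        rule = DosingRule("x", "flat", 1000.0, 1000.0, 1000.0)
        assert drug_cost_per_cycle([rule], Population(), 0) == 1000.0

    def test_per_kg_uses_sex_weighted_weight(self):
        rule = DosingRule("serplulimab", "per_kg", 4.5, 1.0, 1.0)  # 1 USD/mg
        pop = Population(prop_male=1.0)
        assert drug_cost_per_cycle([rule], pop, 0) == pytest.approx(4.5 * 69.6)
        mixed = Population(prop_male=0.25)
        expected = 4.5 * (0.25 * 69.6 + 0.75 * 59.0)
        assert drug_cost_per_cycle([rule], mixed, 0) == pytest.approx(expected)

    def test_induction_phase_stops_after_max_cycles(self):
        rule = DosingRule("etoposide", "per_bsa", 300.0, 10.0, 100.0,
                          max_cycles=4, phase="induction_only")
        pop = Population()
        assert drug_cost_per_cycle([rule], pop, 3) > 0
        assert drug_cost_per_cycle([rule], pop, 4) == 0.0
        assert drug_cost_per_cycle([rule], pop, 5) == 0.0

    def test_ceil_to_pack_mode(self):
        rule = DosingRule("x", "flat", 450.0, 100.0, 200.0, ceil_to_pack=True)
        assert drug_cost_per_cycle([rule], Population(), 0) == 300.0  # 3 packs
        exact = DosingRule("x", "flat", 450.0, 100.0, 200.0)
        assert drug_cost_per_cycle([exact], Population(), 0) == pytest.approx(225.0)

    def test_vector_matches_per_cycle(self):
        rules = [
            DosingRule("a", "per_kg", 4.5, 820.0, 100.0),
            DosingRule("b", "auc_calvert", 5.0, 12.0, 450.0, max_cycles=4,
                       phase="induction_only"),
        ]
        pop = Population()
        vec = drug_cost_vector(rules, pop, 10)
        per = [drug_cost_per_cycle(rules, pop, k) for k in range(10)]
        assert np.allclose(vec, per)

    def test_unknown_basis_rejected(self):
        with pytest.raises(ValueError, match="basis"):
            DosingRule("x", "per_furlong", 1.0, 1.0, 1.0)


class TestAEBurden:
    def test_empty_list(self):
        assert ae_burden([]) == (0.0, 0.0)

    def test_worked_example(self):
        item = AEItem("anemia", 0.2, 500.0, 0.1, 36.525)
        cost, dq = ae_burden([item], 1.0)
        assert cost == pytest.approx(100.0)
        assert dq == pytest.approx(0.002)

    def test_frequency_capped_at_one(self):
        item = AEItem("anemia", 0.2, 500.0, 0.1, 36.525)
        cost, dq = ae_burden([item], HazardRatio(6.0, 6.0, 6.0, endpoint="AE"))
        assert cost == pytest.approx(500.0)
        assert dq == pytest.approx(0.01)

    def test_invalid_frequency_rejected(self):
        with pytest.raises(ValueError):
            AEItem("x", 1.2, 10.0, 0.1, 5.0)


class TestDiscount:
    def test_factor_is_one_at_cycle_zero(self):
        assert discount_factor(0, 0.05) == 1.0

    def test_zero_rate(self):
        assert np.all(discount_factor(np.arange(100), 0.0) == 1.0)

    def test_exactly_one_year(self):
        grid = CycleGrid(cycle_length_days=365.25 / 4)
        assert discount_factor(4, 0.05, grid) == pytest.approx(1 / 1.05, rel=1e-12)

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError):
            discount_factor(1, -0.01)


class TestAccumulate:
    def test_immortal_cohort_qalys_equal_horizon(self):
        grid = CycleGrid()
        res = accumulate(
            immortal_trace(grid),
            np.zeros(grid.n_cycles),
            UtilitySet(1.0, 1.0),
            EconSettings(discount_rate_annual=0.0),
            grid=grid,
        )
        assert res.total_cost == 0.0
        assert res.total_qalys == pytest.approx(20.0, abs=grid.cycle_years)
        assert res.total_lys == pytest.approx(res.total_qalys)

    def test_palliative_cost_counted_once(self):
        grid = CycleGrid(cycle_length_days=21, horizon_years=0.2)
        n = grid.n_cycles
        occ = np.tile([0.0, 0.0, 1.0], (n + 1, 1))
        occ[0] = [1.0, 0.0, 0.0]
        trace = CohortTrace(occupancy=occ, times_months=grid.times_months())
        res = accumulate(
            trace, np.zeros(n), UtilitySet(),
            EconSettings(discount_rate_annual=0.0, palliative_cost=1800.0),
            grid=grid,
        )
        assert res.total_cost == pytest.approx(1800.0)

    def test_death_conservation_and_palliative_total(self):
        grid = CycleGrid()
        os_m = ParametricSurvival("loglogistic", (-4.0, 1.6))
        pfs_m = ParametricSurvival("loglogistic", (-2.5, 1.8))
        trace = state_occupancy(lambda t: apply_hr(pfs_m, 1.0, t),
                                lambda t: apply_hr(os_m, 1.0, t), grid)
        settings = EconSettings(discount_rate_annual=0.0, palliative_cost=1000.0)
        res = accumulate(trace, np.zeros(grid.n_cycles), UtilitySet(), settings, grid=grid)
        total_deaths = trace.dead[-1]
        assert np.sum(np.diff(trace.dead)) == pytest.approx(total_deaths, abs=1e-12)
        assert res.total_cost == pytest.approx(1000.0 * total_deaths, rel=1e-9)

    def test_qaly_bound(self, demo_wb, demo_results):
        for r in demo_results:
            assert r.total_qalys <= demo_wb.utilities.u_pfd * 20.0

    def test_cost_monotone_in_unit_costs(self, demo_wb):
        from escea.pipeline import run_strategy, set_param

        base = run_strategy(demo_wb, demo_wb.strategies[1])[0]
        wb2 = set_param(demo_wb, "settings.bsc_cost_per_cycle",
                        demo_wb.settings.bsc_cost_per_cycle * 2)
        up = run_strategy(wb2, wb2.strategies[1])[0]
        assert up.total_cost >= base.total_cost
        assert up.total_qalys == pytest.approx(base.total_qalys)

    def test_discounting_lowers_totals(self, demo_wb):
        from escea.pipeline import run_strategy, set_param

        r5 = run_strategy(demo_wb, demo_wb.strategies[0])[0]
        wb0 = set_param(demo_wb, "settings.discount_rate_annual", 0.0)
        r0 = run_strategy(wb0, wb0.strategies[0])[0]
        assert r5.total_cost <= r0.total_cost
        assert r5.total_qalys <= r0.total_qalys

    def test_currency_conversion_roundtrip(self):
        s = EconSettings()
        assert s.usd(7.0467) == pytest.approx(1.0, rel=1e-12)
        assert s.usd(70467.0) == pytest.approx(10000.0, rel=1e-12)

    def test_mismatched_lengths_rejected(self):
        grid = CycleGrid()
        with pytest.raises(ValueError, match="length"):
            accumulate(immortal_trace(grid), np.zeros(5), UtilitySet(),
                       EconSettings(), grid=grid)

    def test_matches_brute_force_cycle_sum(self, demo_wb):
        """Vectorised accumulation equals a plain per-cycle Python loop."""
        from escea.economics import drug_cost_vector
        from escea.pipeline import run_strategy

        strat = demo_wb.strategy("serplulimab+chemotherapy")
        result, trace = run_strategy(demo_wb, strat)
        ae_cost, ae_dq = ae_burden(demo_wb.ae_items, strat.hr_ae)
        drug = drug_cost_vector(strat.dosing, demo_wb.population, demo_wb.grid.n_cycles)
        st = demo_wb.settings
        u = demo_wb.utilities
        cost = ae_cost
        qalys = -ae_dq
        dt = 21.0 / 365.25
        for k in range(demo_wb.grid.n_cycles):
            d = (1 + st.discount_rate_annual) ** (-k * 21.0 / 365.25)
            pfd, pd_, dead = trace.occupancy[k]
            dead_next = trace.occupancy[k + 1][2]
            cost += d * (
                pfd * (drug[k] + st.followup_cost_per_cycle + st.bsc_cost_per_cycle)
                + pd_ * (st.subsequent_cost_per_cycle + st.bsc_cost_per_cycle)
                + (dead_next - dead) * st.palliative_cost
            )
            qalys += d * dt * (pfd * u.u_pfd + pd_ * u.u_pd)
        assert result.total_cost == pytest.approx(cost, rel=1e-6)
        assert result.total_qalys == pytest.approx(qalys, rel=1e-6)


class TestCEResult:
    def test_qalys_cannot_exceed_lys(self):
        with pytest.raises(ValueError, match="life-years"):
            CEResult("x", 0.0, 2.0, total_lys=1.0)
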