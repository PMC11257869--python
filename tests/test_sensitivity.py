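"""Deterministic and probabilistic sensitivity analysis."""

import numpy as np
import pytest

from escea.pipeline import make_icer_runner, make_psa_runner, run_base_case, set_param
from escea.sensitivity import (
    CEAC,
    ParamSpec,
    PSAResult,
    ceac,
    default_param_specs,
    dsa_oneway,
    psa,
    psa_param_specs,
    subgroup_run,
    threshold_search,
)

SERPLU = "serplulimab+chemotherapy"
CHEMO = "chemotherapy"


class TestParamSpec:
    def test_ordering_enforced(self):
        with pytest.raises(ValueError, match="low <= base <= high"):
            ParamSpec("x", 1.0, 2.0, 3.0)

    def test_beta_requires_unit_interval(self):
        with pytest.raises(ValueError, match="beta"):
            ParamSpec("x", 2.0, 1.0, 3.0, "beta")

    def test_invalid_distribution_fails_at_setup(self):
        with pytest.raises(ValueError, match="unknown distribution"):
            ParamSpec("x", 1.0, 0.5, 1.5, "cauchy")

    def test_gamma_moment_match(self):
        spec = ParamSpec("cost", 800.0, 600.0, 1000.0, "gamma")
        draws = spec.sampler()(np.random.default_rng(0), 10_000)
        assert draws.mean() == pytest.approx(800.0, rel=0.02)
        assert draws.std() == pytest.approx(spec.sd, rel=0.05)

    def test_beta_support(self):
        spec = ParamSpec("u", 0.856, 0.642, 1.0, "beta")
        draws = spec.sampler()(np.random.default_rng(0), 10_000)
        assert np.all((draws >= 0) & (draws <= 1))
        assert draws.mean() == pytest.approx(0.856, rel=0.02)

    def test_lognormal_ci_match(self):
        spec = ParamSpec("hr", 0.63, 0.49, 0.82, "lognormal")
        draws = spec.sampler()(np.random.default_rng(0), 200_000)
        lo, hi = np.quantile(draws, [0.025, 0.975])
        assert lo == pytest.approx(0.49 * (0.63 / np.sqrt(0.49 * 0.82)), rel=0.02)
        assert hi == pytest.approx(0.82 * (0.63 / np.sqrt(0.49 * 0.82)), rel=0.02)


class TestDSA:
    def test_inert_parameter_has_zero_spread(self, demo_wb):
        runner = make_icer_runner(demo_wb, SERPLU, CHEMO)
        spec = ParamSpec("ae.fatigue.unit_cost", 150.0, 112.5, 187.5, "gamma")
        entries = dsa_oneway([spec], runner)
        # fatigue costs hit both arms identically only through their own AE
        # profile; spread is tiny relative to the ICER scale
        assert entries[0].spread < 1.0

    def test_discount_rate_raises_icer_on_upfront_cost_fixture(self, demo_wb):
        """With all incremental costs at entry and QALYs accrued over time,
        discounting can only raise the ICER."""
        import dataclasses

        from escea.economics import DosingRule

        strat = demo_wb.strategy(SERPLU)
        upfront = dataclasses.replace(
            strat,
            dosing=(DosingRule("bolus", "flat", 30_000.0, 1.0, 1.0,
                               max_cycles=1, phase="induction_only"),),
        )
        chemo = dataclasses.replace(
            demo_wb.strategy(CHEMO), dosing=())
        wb = dataclasses.replace(demo_wb, strategies=(chemo, upfront))
        runner = make_icer_runner(wb, SERPLU, CHEMO)
        icers = [runner({"settings.discount_rate_annual": r}) for r in (0.0, 0.04, 0.08)]
        assert icers[0] < icers[1] < icers[2]

    def test_os_hazard_ratio_dominates_tornado(self, demo_wb):
        """The OS hazard ratio outranks patient weight and the drug price in
        ICER spread, mirroring the expected tornado ordering."""
        runner = make_icer_runner(demo_wb, SERPLU, CHEMO)
        specs = default_param_specs(demo_wb, SERPLU)
        entries = dsa_oneway(specs, runner)
        spread = {e.param: e.spread for e in entries}
        hr_os = spread[f"strategy.{SERPLU}.hr_os"]
        assert hr_os > spread["population.weight_male_kg"]
        assert hr_os > spread[f"strategy.{SERPLU}.price.serplulimab"]
        assert entries[0].param == f"strategy.{SERPLU}.hr_os"

    def test_every_spec_appears_once(self, demo_wb):
        runner = make_icer_runner(demo_wb, SERPLU, CHEMO)
        specs = default_param_specs(demo_wb, SERPLU)
        entries = dsa_oneway(specs, runner)
        assert sorted(e.param for e in entries) == sorted(s.name for s in specs)

    def test_runner_failure_flagged_not_dropped(self):
        def bad_runner(overrides):
            raise RuntimeError("boom")

        entries = dsa_oneway([ParamSpec("p", 1.0, 0.5, 1.5)], bad_runner)
        assert len(entries) == 1 and entries[0].failed


class TestThreshold:
    def test_linear_toy_closed_form(self):
        # ICER(p) = 100 p + 50: crosses wtp 450 at p = 4 exactly
        runner = lambda ov: 100.0 * ov["p"] + 50.0  # noqa: E731
        root = threshold_search(ParamSpec("p", 5.0, 0.0, 10.0), 450.0, runner)
        assert root == pytest.approx(4.0, rel=1e-5)

    def test_no_crossing_returns_none(self):
        runner = lambda ov: 100.0 * ov["p"] + 50.0  # noqa: E731
        assert threshold_search(ParamSpec("p", 5.0, 0.0, 10.0), 1e9, runner) is None

    def test_non_monotone_endpoints_rejected(self):
        # endpoints bracket the level but the peak at p = 6 betrays
        # non-monotonicity via the midpoint check
        runner = lambda ov: -((ov["p"] - 6.0) ** 2) + 20.0  # noqa: E731
        with pytest.raises(ValueError, match="monotone"):
            threshold_search(ParamSpec("p", 5.0, 0.0, 10.0), 0.0, runner)

    def test_bisection_matches_grid_scan_on_price(self, demo_wb):
        runner = make_icer_runner(demo_wb, SERPLU, CHEMO)
        spec = ParamSpec(f"strategy.{SERPLU}.price.serplulimab", 820.0, 0.0, 820.0, "gamma")
        wtp = demo_wb.settings.wtp_high
        root = threshold_search(spec, wtp, runner)
        grid = np.linspace(0.0, 820.0, 2001)
        vals = np.array([runner({spec.name: g}) for g in grid]) - wtp
        cross = np.where(np.sign(vals[:-1]) != np.sign(vals[1:]))[0]
        assert len(cross) == 1
        assert abs(root - grid[cross[0]]) <= grid[1] - grid[0]


class TestPSA:
    def test_degenerate_specs_reproduce_base_case(self, demo_wb, demo_results):
        specs = [ParamSpec("utilities.u_pfd", 0.856, 0.856, 0.856, "beta")]
        samples = psa(specs, make_psa_runner(demo_wb), n_draws=5, seed=1)
        base = {r.strategy: (r.total_cost, r.total_qalys) for r in demo_results}
        for j, s in enumerate(samples.strategies):
            assert np.allclose(samples.costs[:, j], base[s][0])
            assert np.allclose(samples.qalys[:, j], base[s][1])

    def test_seed_determinism(self, demo_wb):
        specs = psa_param_specs(demo_wb)
        runner = make_psa_runner(demo_wb)
        a = psa(specs, runner, n_draws=20, seed=7)
        b = psa(specs, runner, n_draws=20, seed=7)
        assert np.array_equal(a.costs, b.costs)
        assert np.array_equal(a.param_draws, b.param_draws)
        c = psa(specs, runner, n_draws=20, seed=8)
        assert not np.array_equal(a.costs, c.costs)

    def test_invalid_distribution_fails_before_model_runs(self, demo_wb):
        calls = []

        def runner(ov):
            calls.append(ov)
            return {"a": (0.0, 0.0)}

        bad = ParamSpec("x", 0.0, -1.0, 1.0, "gamma")  # gamma needs base > 0
        with pytest.raises(ValueError, match="gamma"):
            psa([bad], runner, n_draws=3, seed=0)
        assert calls == []


class TestCEAC:
    @staticmethod
    def _samples(costs, qalys, names):
        return PSAResult(
            strategies=tuple(names),
            costs=np.asarray(costs, dtype=float),
            qalys=np.asarray(qalys, dtype=float),
            param_names=(),
            param_draws=np.empty((len(costs), 0)),
            seed=0,
        )

    def test_single_strategy_probability_one(self):
        s = self._samples([[1.0], [2.0]], [[1.0], [1.0]], ["only"])
        curve = ceac(s, [0.0, 10_000.0])
        assert np.all(curve.probabilities == 1.0)

    def test_zero_wtp_picks_cheapest_per_draw(self, rng):
        costs = rng.uniform(0, 100, size=(500, 3))
        qalys = rng.uniform(0, 3, size=(500, 3))
        s = self._samples(costs, qalys, ["a", "b", "c"])
        curve = ceac(s, [0.0])
        frac = np.bincount(np.argmin(costs, axis=1), minlength=3) / 500
        assert np.allclose(curve.probabilities[0], frac)

    def test_rows_sum_to_one_and_bounded(self, rng):
        costs = rng.uniform(0, 1e5, size=(200, 4))
        qalys = rng.uniform(0, 3, size=(200, 4))
        curve = ceac(self._samples(costs, qalys, list("abcd")), np.arange(0, 6e4, 5e3))
        assert np.allclose(curve.probabilities.sum(axis=1), 1.0)
        assert np.all((curve.probabilities >= 0) & (curve.probabilities <= 1))

    def test_ties_split_equally(self):
        s = self._samples([[10.0, 10.0]], [[1.0, 1.0]], ["a", "b"])
        curve = ceac(s, [5000.0])
        assert np.allclose(curve.probabilities[0], [0.5, 0.5])

    def test_matches_analytic_normal_probability(self, rng):
        """Two strategies with independent normal (cost, QALY) increments:
        the CEAC equals the closed-form probability
        P(wtp * dQ - dC > 0) within 0.02 at 10,000 draws."""
        n = 10_000
        mc, sc, mq, sq = 40_000.0, 8_000.0, 0.5, 0.15
        d_cost = rng.normal(mc, sc, n)
        d_qaly = rng.normal(mq, sq, n)
        costs = np.column_stack([np.zeros(n), d_cost])
        qalys = np.column_stack([np.zeros(n), d_qaly])
        wtps = np.array([2e4, 6e4, 8e4, 1.2e5])
        curve = ceac(self._samples(costs, qalys, ["ref", "new"]), wtps)
        from scipy.stats import norm

        for i, w in enumerate(wtps):
            analytic = norm.cdf((w * mq - mc) / np.hypot(w * sq, sc))
            assert curve.probabilities[i, 1] == pytest.approx(analytic, abs=0.02)

    def test_empty_grid_rejected(self):
        s = self._samples([[1.0]], [[1.0]], ["a"])
        with pytest.raises(ValueError, match="empty"):
            ceac(s, [])


class TestSubgroups:
    def test_identity_hrs_reproduce_overall(self, demo_wb, demo_results):
        table = {
            "overall_copy": {
                SERPLU: {"pfs": demo_wb.strategy(SERPLU).hr_pfs.point,
                         "os": demo_wb.strategy(SERPLU).hr_os.point}
            }
        }
        out = subgroup_run(demo_wb, table)
        res = {r.strategy: r for r in out["overall_copy"][0]}
        base = {r.strategy: r for r in demo_results}
        for name in base:
            assert res[name].total_cost == pytest.approx(base[name].total_cost)
            assert res[name].total_qalys == pytest.approx(base[name].total_qalys)

    def test_gender_subgroups_scale_per_kg_costs(self, demo_wb):
        from escea.economics import drug_cost_per_cycle

        male = set_param(demo_wb, "population.prop_male", 1.0)
        female = set_param(demo_wb, "population.prop_male", 0.0)
        rules = [r for r in demo_wb.strategy(SERPLU).dosing if r.drug == "serplulimab"]
        cm = drug_cost_per_cycle(rules, male.population, 0)
        cf = drug_cost_per_cycle(rules, female.population, 0)
        assert cm / cf == pytest.approx(69.6 / 59.0)

    def test_lower_os_hr_raises_incremental_qalys(self, demo_wb, demo_results):
        base = {r.strategy: r for r in demo_results}
        base_gain = base[SERPLU].total_qalys - base[CHEMO].total_qalys
        out = subgroup_run(demo_wb, {"better": {SERPLU: {"os": 0.45}}})
        res = {r.strategy: r for r in out["better"][0]}
        gain = res[SERPLU].total_qalys - res[CHEMO].total_qalys
        assert gain > base_gain

    def test_unknown_strategy_skipped_with_warning(self, demo_wb, caplog):
        import logging

        with caplog.at_level(logging.WARNING):
            out = subgroup_run(demo_wb, {"sub": {"nonexistent": {"os": 0.5}}})
        assert "sub" in out
        assert any("unknown strategy" in r.message for r in caplog.records)
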