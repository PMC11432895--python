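"""Decision tree, Markov engine, ICER, sensitivity analyses."""

import copy

import numpy as np
import pytest

import bimast as bm
from bimast.exceptions import EconConfigError
from bimast.health_econ import (
    STATES,
    EconOutcome,
    StrategyPerformance,
    evaluate_strategy,
)
from conftest import random_econ_config

_IDX = {s: i for i, s in enumerate(STATES)}


class TestDecisionTree:
    def test_perfect_test_has_no_false_negatives(self):
        perf = StrategyPerformance("x", 1.0, 1.0, 10.0)
        init, upfront = bm.build_decision_tree(
            perf, {"MLD": 0.83, "SLD": 0.14, "CC": 0.03}, referral_cost=400.0)
        assert init[_IDX["SLD_fn"]] == 0.0 and init[_IDX["CC_fn"]] == 0.0
        # upfront = test cost + referral for the true positives only
        assert upfront == pytest.approx(10.0 + 400.0 * 0.17)

    def test_us_lfts_false_negative_mass(self):
        """At sens 0.35 the missed-disease mass is 0.17 * 0.65 = 0.1105."""
        perf = StrategyPerformance("US_LFTS", 0.35, 0.65, 60.0)
        init, _ = bm.build_decision_tree(
            perf, {"MLD": 0.83, "SLD": 0.14, "CC": 0.03}, referral_cost=400.0)
        assert init[_IDX["SLD_fn"]] + init[_IDX["CC_fn"]] == pytest.approx(0.1105)
        assert init[_IDX["SLD_dx"]] == pytest.approx(0.14 * 0.35)
        assert init[_IDX["CC_dx"]] == pytest.approx(0.03 * 0.35)

    def test_mass_conservation_random_inputs(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            p = rng.dirichlet([5, 2, 1])
            prev = {"MLD": p[0], "SLD": p[1], "CC": p[2]}
            perf = StrategyPerformance("r", rng.random(), rng.random(), 10.0)
            init, _ = bm.build_decision_tree(perf, prev, referral_cost=100.0)
            assert init.sum() == pytest.approx(1.0, abs=1e-12)
            assert (init >= 0).all()

    def test_malformed_prevalence_rejected(self):
        perf = StrategyPerformance("x", 0.5, 0.5, 0.0)
        with pytest.raises(EconConfigError, match="prevalence"):
            bm.build_decision_tree(perf, {"MLD": 0.5, "SLD": 0.2, "CC": 0.2}, 0.0)


class TestMarkov:
    def test_single_alive_state_identity_chain(self, econ_config):
        """Utility 1, no discounting, no mortality: horizon QALYs exactly."""
        cfg = econ_config
        cfg.discount_rate = 0.0
        cfg.background_mortality = 0.0
        cfg.horizon = 5
        cfg.transitions = {s: {} for s in STATES[:-1]}
        cfg.state_utilities = {s: 1.0 for s in STATES} | {"DEAD": 0.0}
        init = np.zeros(len(STATES))
        init[_IDX["MLD"]] = 1.0
        res = bm.run_markov(init, cfg)
        assert res.qalys == pytest.approx(5.0, abs=1e-12)
        assert res.life_years == pytest.approx(5.0, abs=1e-12)

    def test_two_state_geometric_closed_form(self, econ_config):
        """alive->dead p=0.2/yr, 3.5% discounting: partial geometric sum."""
        cfg = econ_config
        cfg.discount_rate = 0.035
        cfg.background_mortality = 0.0
        cfg.horizon = 60
        cfg.transitions = {s: {} for s in STATES[:-1]}
        cfg.transitions["MLD"] = {"DEAD": 0.2}
        init = np.zeros(len(STATES))
        init[_IDX["MLD"]] = 1.0
        res = bm.run_markov(init, cfg)
        r = 0.8 / 1.035
        expected = (1 - r ** 60) / (1 - r)
        assert res.life_years == pytest.approx(expected, abs=1e-10)
        # at long horizons this approaches the infinite-series value 4.404
        assert res.life_years == pytest.approx(1 / (1 - r), abs=1e-4)

    def test_occupancy_conserved_every_cycle(self, econ_config):
        init = np.zeros(len(STATES))
        init[_IDX["SLD_fn"]] = 0.6
        init[_IDX["CC_dx"]] = 0.4
        res = bm.run_markov(init, econ_config)
        np.testing.assert_allclose(res.trace.sum(axis=1), 1.0, atol=1e-10)

    def test_dead_occupancy_monotone(self, econ_config):
        init = np.zeros(len(STATES))
        init[_IDX["CC_fn"]] = 1.0
        res = bm.run_markov(init, econ_config)
        dead = res.trace[:, _IDX["DEAD"]]
        assert (np.diff(dead) >= -1e-15).all()

    def test_discounting_identity_and_bound(self, econ_config):
        init = np.zeros(len(STATES))
        init[_IDX["MLD"]] = 1.0
        cfg0 = copy.deepcopy(econ_config)
        cfg0.discount_rate = 0.0
        undiscounted = bm.run_markov(init, cfg0)
        discounted = bm.run_markov(init, econ_config)
        assert discounted.qalys <= undiscounted.qalys
        assert discounted.cost <= undiscounted.cost
        # r=0 equals a plain per-cycle sum
        mat = cfg0.transition_matrix()
        occ = init.copy()
        total = 0.0
        u = np.array([cfg0.state_utilities[s] for s in STATES])
        for _ in range(cfg0.horizon):
            total += occ @ u
            occ = occ @ mat
        assert undiscounted.qalys == pytest.approx(total, abs=1e-12)

    def test_cohort_scaling_is_linear(self, econ_config):
        out1 = evaluate_strategy("BIMAST", econ_config)
        cfg2 = copy.deepcopy(econ_config)
        cfg2.cohort_size *= 2
        out2 = evaluate_strategy("BIMAST", cfg2)
        assert out2.qalys == pytest.approx(2 * out1.qalys)
        assert out2.life_years == pytest.approx(2 * out1.life_years)
        assert out2.cost_per_person == pytest.approx(out1.cost_per_person)

    def test_diagnosed_arm_lives_longer(self):
        """fn progression >= dx progression implies dx life expectancy >= fn."""
        rng = np.random.default_rng(7)
        for _ in range(20):
            cfg = random_econ_config(rng)
            init_dx = np.zeros(len(STATES))
            init_dx[_IDX["SLD_dx"]] = 1.0
            init_fn = np.zeros(len(STATES))
            init_fn[_IDX["SLD_fn"]] = 1.0
            assert (bm.run_markov(init_dx, cfg).life_years
                    >= bm.run_markov(init_fn, cfg).life_years - 1e-12)

    def test_non_stochastic_matrix_rejected(self, econ_config):
        econ_config.transitions["DC"]["DEAD"] = 1.5
        init = np.zeros(len(STATES))
        init[_IDX["MLD"]] = 1.0
        with pytest.raises(EconConfigError):
            econ_config.validate()

    def test_half_cycle_correction_brackets(self, econ_config):
        init = np.zeros(len(STATES))
        init[_IDX["CC_fn"]] = 1.0
        plain = bm.run_markov(init, econ_config)
        econ_config.half_cycle_correction = True
        half = bm.run_markov(init, econ_config)
        assert half.life_years < plain.life_years  # shrinking cohort


class TestIcer:
    def _outcome(self, cost_pp, qalys):
        return EconOutcome("x", 1000.0, qalys, cost_pp, 0.5, cohort_size=287)

    def test_equal_costs_give_zero(self):
        res = bm.icer(self._outcome(100.0, 150.0), self._outcome(100.0, 100.0))
        assert res.value == 0.0 and res.flag is None

    def test_arithmetic(self):
        soc = self._outcome(1000.0, 100.0)
        s = self._outcome(2000.0, 100.0 + 0.5 * 287)
        res = bm.icer(s, soc)
        assert res.value == pytest.approx(2000.0)

    def test_dominance_flags(self):
        soc = self._outcome(1000.0, 100.0)
        assert bm.icer(self._outcome(900.0, 150.0), soc).flag == "dominant"
        assert bm.icer(self._outcome(1100.0, 50.0), soc).flag == "dominated"
        assert bm.icer(self._outcome(1100.0, 100.0), soc).flag == "undefined"

    def test_soc_vs_itself_is_undefined(self, econ_config):
        table = bm.evaluate_strategies(econ_config)
        soc_row = table[table.strategy == "SOC"].iloc[0]
        assert soc_row.icer_flag == "undefined"


class TestBaseCase:
    def test_one_row_per_strategy(self, econ_config):
        table = bm.evaluate_strategies(econ_config)
        assert len(table) == 7
        assert set(table.strategy) == {"US_LFTS", "FIB4", "NFS", "BIMAST",
                                       "ELF", "TE", "SOC"}

    def test_ordering_properties(self, econ_config):
        """Elastography gains the most QALYs; every strategy gains some."""
        table = bm.evaluate_strategies(econ_config).set_index("strategy")
        gains = table["qalys_gained_vs_soc"].drop("SOC")
        assert gains.idxmax() == "TE"
        assert (gains > 0).all()

    def test_better_test_never_fewer_qalys(self):
        """Strictly better sens and spec at equal cost: QALYs non-decreasing."""
        rng = np.random.default_rng(19)
        for _ in range(10):
            cfg = random_econ_config(rng)
            sens, spec = rng.uniform(0.2, 0.7, 2)
            cfg.strategies = {
                "SOC": StrategyPerformance("SOC", 0.1, 0.9, 0.0),
                "worse": StrategyPerformance("worse", sens, spec, 5.0),
                "better": StrategyPerformance("better", min(sens + 0.2, 1.0),
                                              min(spec + 0.2, 1.0), 5.0),
            }
            table = bm.evaluate_strategies(cfg).set_index("strategy")
            assert table.loc["better", "qalys"] >= table.loc["worse", "qalys"] - 1e-9


class TestSensitivityAnalyses:
    def test_degenerate_range_gives_identical_icers(self, econ_config):
        table = bm.one_way_sensitivity(econ_config, "discount_rate", [0.035, 0.035])
        a = table[table.value == 0.035].groupby("strategy")["icer_vs_soc"].nunique()
        assert (a <= 1).all()

    def test_shorter_horizon_raises_icers(self, econ_config):
        """Less time to accrue benefit: 5-year ICERs exceed 40-year ICERs."""
        table = bm.one_way_sensitivity(econ_config, "horizon", [5, 40])
        wide = table.pivot(index="strategy", columns="value", values="icer_vs_soc")
        wide = wide.drop("SOC")
        assert (wide[5] > wide[40]).all()

    def test_cost_scaling_homogeneity(self, econ_config):
        """Scaling every cost by k scales every ICER by k."""
        base = bm.evaluate_strategies(econ_config).set_index("strategy")
        cfg = copy.deepcopy(econ_config)
        k = 3.0
        cfg.state_costs = {s: k * c for s, c in cfg.state_costs.items()}
        cfg.referral_cost *= k
        cfg.strategies = {
            n: StrategyPerformance(n, s.sensitivity, s.specificity, k * s.test_cost)
            for n, s in cfg.strategies.items()}
        scaled = bm.evaluate_strategies(cfg).set_index("strategy")
        for name in scaled.index.drop("SOC"):
            if np.isfinite(base.loc[name, "icer_vs_soc"]):
                assert scaled.loc[name, "icer_vs_soc"] == pytest.approx(
                    k * base.loc[name, "icer_vs_soc"])

    def test_invalid_grid_value_names_bound(self, econ_config):
        with pytest.raises(EconConfigError, match="background_mortality"):
            bm.one_way_sensitivity(econ_config, "background_mortality", [1.5])

    def test_unknown_path_rejected(self, econ_config):
        with pytest.raises(EconConfigError, match="not found"):
            bm.one_way_sensitivity(econ_config, "no.such.param", [0.1])


class TestPsaCeac:
    def test_seed_determinism(self, econ_config):
        a = bm.psa(econ_config, n_draws=5, seed=3)
        b = bm.psa(econ_config, n_draws=5, seed=3)
        np.testing.assert_array_equal(a.costs, b.costs)
        np.testing.assert_array_equal(a.qalys, b.qalys)
        c = bm.psa(econ_config, n_draws=5, seed=4)
        assert not np.array_equal(a.costs, c.costs)

    def test_degenerate_distributions_reproduce_base_case(self, econ_config):
        cfg = econ_config
        cfg.psa_distributions = {
            "state_costs.DC": {"dist": "fixed", "value": cfg.state_costs["DC"]},
            "referral_cost": {"dist": "fixed", "value": cfg.referral_cost},
        }
        result = bm.psa(cfg, n_draws=4, seed=0)
        base = bm.evaluate_strategies(cfg).set_index("strategy")
        for j, name in enumerate(result.strategies):
            assert np.allclose(result.qalys[:, j], base.loc[name, "qalys"])
            assert np.allclose(
                result.costs[:, j],
                base.loc[name, "cost_per_person"] * cfg.cohort_size)

    def test_draw_means_match_distribution_means(self, econ_config):
        """LLN: empirical PSA parameter means near analytic means (3 SE)."""
        rng = np.random.default_rng([0 & 0x7FFFFFFF, 202])
        n = 4000
        draws = {path: [] for path in econ_config.psa_distributions}
        from bimast.health_econ import _draw_psa_params
        for _ in range(n):
            for path, v in _draw_psa_params(econ_config, rng):
                draws[path].append(v)
        for path, dist in econ_config.psa_distributions.items():
            x = np.asarray(draws[path])
            if dist["dist"] == "beta":
                mean = dist["alpha"] / (dist["alpha"] + dist["beta"])
                var = (dist["alpha"] * dist["beta"]
                       / ((dist["alpha"] + dist["beta"]) ** 2
                          * (dist["alpha"] + dist["beta"] + 1)))
            else:
                mean = dist["shape"] * dist["scale"]
                var = dist["shape"] * dist["scale"] ** 2
            assert abs(x.mean() - mean) < 3 * np.sqrt(var / n), path

    def test_zero_draws_rejected(self, econ_config):
        with pytest.raises(EconConfigError):
            bm.psa(econ_config, n_draws=0)

    def test_ceac_limits(self, econ_config):
        econ_config.psa_distributions = {}
        result = bm.psa(econ_config, n_draws=3, seed=0)
        base = bm.evaluate_strategies(econ_config).set_index("strategy")
        curve = bm.ceac(result, [0.0, 1e9]).pivot(
            index="threshold", columns="strategy", values="probability")
        cheapest = (base["cost_per_person"]).idxmin()
        most_qalys = base["qalys"].idxmax()
        assert curve.loc[0.0, cheapest] == 1.0
        assert curve.loc[1e9, most_qalys] == 1.0
        np.testing.assert_allclose(curve.sum(axis=1), 1.0)

    def test_ceac_matches_normal_toy_oracle(self):
        """Two-strategy Gaussian toy: acceptability equals the closed-form
        probability that strategy A has the higher net monetary benefit."""
        from bimast.health_econ import PsaResult
        from scipy.stats import norm
        rng = np.random.default_rng(61)
        n = 20_000
        lam = 20_000.0
        qa = rng.normal(10.0, 1.0, n)
        qb = rng.normal(9.8, 1.0, n)
        ca = rng.normal(50_000.0, 5_000.0, n)
        cb = rng.normal(48_000.0, 5_000.0, n)
        res = PsaResult(strategies=["A", "B"],
                        costs=np.c_[ca, cb], qalys=np.c_[qa, qb], seed=0)
        curve = bm.ceac(res, [lam]).set_index("strategy")["probability"]
        # NMB_A - NMB_B ~ Normal(lam*0.2 - 2000, sqrt(2*(lam^2 + 5000^2)))
        mu = lam * 0.2 - 2000.0
        sd = np.sqrt(2 * (lam ** 2 + 5000.0 ** 2))
        expected = norm.cdf(mu / sd)
        se = np.sqrt(expected * (1 - expected) / n)
        assert abs(curve["A"] - expected) < 2 * se + 1e-9

    def test_empty_grid_rejected(self, econ_config):
        result = bm.psa(econ_config, n_draws=2, seed=0)
        with pytest.raises(EconConfigError):
            bm.ceac(result, [])


class TestConfigIO:
    def test_yaml_round_trip(self, tmp_path, econ_config):
        path = tmp_path / "econ.yaml"
        econ_config.to_yaml(path)
        back = bm.EconConfig.from_yaml(path)
        assert back.transitions == econ_config.transitions
        assert back.strategies == econ_config.strategies
        assert back.cet == econ_config.cet

    def test_fn_slower_than_dx_rejected(self, econ_config):
        econ_config.transitions["SLD_fn"]["CC_fn"] = 0.001
        with pytest.raises(EconConfigError, match="slower"):
            econ_config.validate()

    def test_missing_soc_rejected(self, econ_config):
        del econ_config.strategies["SOC"]
        with pytest.raises(EconConfigError, match="SOC"):
            econ_config.validate()

    def test_bad_psa_entry_rejected(self, econ_config):
        econ_config.psa_distributions["state_costs.DC"] = {"dist": "beta"}
        with pytest.raises(EconConfigError, match="beta"):
            econ_config.validate()
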