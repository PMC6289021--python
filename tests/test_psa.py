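"""Probabilistic analysis: distributions, reproducibility, CEAC properties."""

import numpy as np
import pytest
from scipy import stats

from vtecea.pipeline import totals_for_strategies
from vtecea.psa import (
    ParameterSampler,
    PSAConfig,
    assign_distributions,
    beta_moments,
    ceac,
    gamma_moments,
    lognormal_sigma_from_ci,
    run_psa,
)
from vtecea.types import ValidationError

FAST = PSAConfig()


class TestDistributionAssignment:
    def test_moment_matching_beta(self):
        a, b = beta_moments(0.0554, 0.0008)
        d = stats.beta(a, b)
        assert d.mean() == pytest.approx(0.0554, abs=1e-12)
        assert d.std() == pytest.approx(0.0008, abs=1e-12)

    def test_infeasible_beta_named(self):
        with pytest.raises(ValidationError, match="wild_param"):
            beta_moments(0.01, 0.5, "wild_param")

    def test_moment_matching_gamma(self):
        shape, scale = gamma_moments(457.0, 91.4)
        d = stats.gamma(shape, scale=scale)
        assert d.mean() == pytest.approx(457.0)
        assert d.std() == pytest.approx(91.4)

    def test_lognormal_sigma_from_interval(self):
        # quantile arithmetic: exp(log-scale 95% interval) spans the CrI
        sigma = lognormal_sigma_from_ci(0.727, 0.096, 2.59, fallback=0.5)
        assert sigma == pytest.approx((np.log(2.59) - np.log(0.096)) / 3.92)

    def test_families_cover_parameter_classes(self, ethr_inputs):
        specs = assign_distributions(ethr_inputs)
        families = {s.path: s.family for s in specs}
        assert families["baseline.total_dvt"] == "beta"
        assert families["cost_event.sympt_prox_dvt"] == "gamma"
        assert families["effect.rivaroxaban.dvt"] == "lognormal"
        assert families["utility.post_9mo"] == "beta"

    def test_proportionality_imputed_effects_share_draws(self, ethr_inputs):
        """One log-scale draw drives DVT and PE for flagged strategies."""
        sampler = ParameterSampler(ethr_inputs)
        draws = sampler.draw_all(np.random.default_rng(0), 500)
        # foot_pump_aes PE was imputed from the DVT effect
        dvt = draws["effect.foot_pump_aes.dvt"]
        pe = draws["effect.foot_pump_aes.pe"]
        r = np.corrcoef(np.log(dvt), np.log(pe))[0, 1]
        assert r == pytest.approx(1.0, abs=1e-12)

    def test_sampled_values_respect_domains(self, ethr_inputs):
        sampler = ParameterSampler(ethr_inputs)
        draws = sampler.draw_all(np.random.default_rng(1), 200)
        for i in (0, 57, 199):
            perturbed = sampler.materialize(draws, i)
            perturbed.validate()


class TestNoiseModel:
    def test_cost_draw_moments_match_spec(self, ethr_inputs):
        """Empirical mean/SE of 10,000 cost draws within 3 MC SEs of the
        20%-of-mean noise model."""
        sampler = ParameterSampler(ethr_inputs)
        draws = sampler.draw_all(np.random.default_rng(2), 10_000)
        x = draws["cost_event.sympt_prox_dvt"]
        mean, se = 457.0, 457.0 * 0.2
        assert abs(x.mean() - mean) < 3 * se / np.sqrt(len(x))
        assert x.std() == pytest.approx(se, rel=0.05)

    @pytest.mark.parametrize("n", [1_000, 10_000])
    def test_linear_toy_model_converges_to_analytic_mean(self, ethr_inputs, n):
        """A linear functional of sampled parameters converges to its
        analytic expectation (all families are mean-preserving except the
        median-parameterized lognormals, excluded here)."""
        sampler = ParameterSampler(ethr_inputs)
        draws = sampler.draw_all(np.random.default_rng(3), n)
        c1 = draws["cost_event.sympt_prox_dvt"]
        c2 = draws["cost_state.pts_severe_y1"]
        p = draws["baseline.total_dvt"]
        toy = 2.0 * c1 + 0.5 * c2 + 10_000.0 * p
        analytic = 2.0 * 457 + 0.5 * 3824 + 10_000 * 0.0554
        mc_se = toy.std(ddof=1) / np.sqrt(n)
        assert abs(toy.mean() - analytic) < 3 * mc_se


class TestRunPsa:
    def test_degenerate_distributions_reproduce_deterministic_run(self, ethr_inputs):
        fixed = run_psa(ethr_inputs, n_iter=2, seed=0, config=PSAConfig(all_fixed=True))
        q, c = totals_for_strategies(ethr_inputs)
        np.testing.assert_array_equal(fixed.qalys[0], q)
        np.testing.assert_array_equal(fixed.costs[0], c)
        np.testing.assert_array_equal(fixed.qalys[0], fixed.qalys[1])

    def test_same_seed_identical_outputs(self, ethr_inputs):
        a = run_psa(ethr_inputs, n_iter=40, seed=123)
        b = run_psa(ethr_inputs, n_iter=40, seed=123)
        np.testing.assert_array_equal(a.qalys, b.qalys)
        np.testing.assert_array_equal(a.costs, b.costs)
        assert a.summary.to_csv() == b.summary.to_csv()
        assert a.ceac_curve.to_csv() == b.ceac_curve.to_csv()

    def test_probabilities_most_ce_partition(self, etkr_inputs):
        s = run_psa(etkr_inputs, n_iter=60, seed=5)
        assert s.prob_most_ce.sum() == pytest.approx(1.0, abs=1e-9)
        assert (s.prob_most_ce >= 0).all()

    def test_rank_intervals_contain_deterministic_rank_when_degenerate(self, ethr_inputs):
        s = run_psa(ethr_inputs, n_iter=3, seed=0, config=PSAConfig(all_fixed=True))
        from vtecea.pipeline import evaluate_population

        det = evaluate_population(ethr_inputs).ce.table["rank"]
        for name in s.strategies:
            lo, hi = s.summary.loc[name, ["rank_lo", "rank_hi"]]
            assert lo <= det[name] <= hi

    def test_percentile_bounds_ordered(self, ethr_inputs):
        s = run_psa(ethr_inputs, n_iter=50, seed=9)
        assert (s.summary["qalys_lo"] <= s.summary["qalys_hi"]).all()
        assert (s.summary["cost_lo"] <= s.summary["cost_hi"]).all()

    def test_invalid_iteration_count(self, ethr_inputs):
        with pytest.raises(ValueError):
            run_psa(ethr_inputs, n_iter=0)

    def test_scatter_has_one_point_per_strategy_per_iteration(self, ethr_inputs):
        s = run_psa(ethr_inputs, n_iter=1, seed=0)
        scatter = s.scatter()
        assert len(scatter) == len(s.strategies)
        comp = scatter[scatter["strategy"] == s.comparator]
        assert (comp[["inc_cost", "inc_qalys"]] == 0).all().all()


class TestCeac:
    def test_single_iteration_gives_indicator_curves(self):
        q = np.array([[10.0, 9.0]])
        c = np.array([[100.0, 50.0]])
        curve = ceac(q, c, [0.0, 1_000.0, 100_000.0], ["a", "b"])
        # at tiny lambda the cheap one wins; at huge lambda the effective one
        assert curve.loc[0.0].tolist() == [0.0, 1.0]
        assert curve.loc[100_000.0].tolist() == [1.0, 0.0]
        assert set(np.unique(curve.to_numpy())) <= {0.0, 1.0}

    def test_rows_sum_to_one(self, ethr_inputs):
        s = run_psa(ethr_inputs, n_iter=30, seed=2)
        np.testing.assert_allclose(s.ceac_curve.sum(axis=1), 1.0, atol=1e-12)

    def test_matches_closed_form_normal_oracle(self):
        """Two strategies with iid-normal incremental NMB: the acceptability
        curve equals Phi(mean/sd) within Monte-Carlo error at n=10,000."""
        rng = np.random.default_rng(42)
        n, lam = 10_000, 20_000.0
        mu_q, sd_q = 0.02, 0.05
        inc_q = rng.normal(mu_q, sd_q, n)
        q = np.column_stack([np.zeros(n), inc_q])
        c = np.zeros((n, 2))
        curve = ceac(q, c, [lam], ["comparator", "new"])
        expected = stats.norm.cdf(mu_q * lam / (sd_q * lam))
        mc_err = 3 * np.sqrt(expected * (1 - expected) / n)
        assert curve.loc[lam, "new"] == pytest.approx(expected, abs=mc_err)

    def test_ceac_ordering_preserved_for_dominant_strategy(self):
        """A strategy whose NMB stochastically dominates the comparator's
        never has the lower acceptability."""
        rng = np.random.default_rng(0)
        n = 4_000
        base_q = rng.normal(10.0, 0.5, n)
        q = np.column_stack([base_q, base_q + 0.1])  # better in every draw
        c = np.column_stack([np.full(n, 500.0), np.full(n, 400.0)])
        curve = ceac(q, c, [0, 5_000, 20_000, 50_000], ["comp", "better"])
        assert (curve["better"] >= curve["comp"]).all()
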