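import numpy as np
import pytest

import survcea as sc
from survcea.psa import PSASettings, Sampler, fit_distribution, sample_param_set


class TestFitDistribution:
    def test_fixed_returns_base(self):
        s = fit_distribution(sc.ParamDistribution("x", 3.5, family="fixed"))
        rng = np.random.default_rng(0)
        assert {s(rng) for _ in range(5)} == {3.5}

    def test_beta_from_counts_has_count_mean(self):
        dist = sc.ParamDistribution(
            "resection", 0.38, 0.27, 0.48, family="beta", events=33, total=88
        )
        s = fit_distribution(dist)
        rng = np.random.default_rng(1)
        vals = np.array([s(rng) for _ in range(100_000)])
        assert vals.mean() == pytest.approx(33 / 88, abs=0.005)
        assert ((vals > 0) & (vals < 1)).all()

    def test_gamma_moment_matched_to_base(self):
        dist = sc.ParamDistribution("cect", 38_190, 28_643, 47_738, family="gamma")
        s = fit_distribution(dist)
        rng = np.random.default_rng(2)
        vals = np.array([s(rng) for _ in range(100_000)])
        assert vals.mean() == pytest.approx(38_190, rel=0.01)
        assert (vals > 0).all()

    def test_beta_moment_matched_to_base(self):
        dist = sc.ParamDistribution("utility", 0.74, 0.56, 0.93, family="beta")
        s = fit_distribution(dist)
        rng = np.random.default_rng(3)
        vals = np.array([s(rng) for _ in range(50_000)])
        assert vals.mean() == pytest.approx(0.74, abs=0.01)

    def test_infeasible_moments_raise_with_name(self):
        too_wide = sc.ParamDistribution("narrow", 0.5, -3.0, 4.0, family="beta")
        with pytest.raises(sc.ValidationError, match="narrow"):
            fit_distribution(too_wide)

    def test_bounds_must_bracket_base(self):
        with pytest.raises(sc.ValidationError):
            sc.ParamDistribution("bad", 0.9, 0.1, 0.5, family="beta")


class TestSampleParamSet:
    def test_collapsed_sampling_returns_base_values(self, params):
        rng = np.random.default_rng(0)
        ps = sample_param_set(params, rng, collapse=True)
        assert ps.rfs_primary.points == params.rfs_primary.points
        assert ps.os_chemo.points == params.os_chemo.points
        assert ps.costs == params.costs
        assert ps.utilities == params.utilities
        assert ps.rates == params.rates
        assert ps.theta == params.theta

    def test_anchor_monotonicity_enforced_in_every_draw(self, params):
        rng = np.random.default_rng(11)
        for _ in range(300):
            ps = sample_param_set(params, rng)
            for block in (ps.rfs_primary, ps.rfs_post_resection, ps.os_chemo):
                s = block.survival
                assert (np.diff(s) <= 1e-12).all()
                assert (s > 0).all() and (s <= 1).all()

    def test_surgery_shares_always_sum_to_one(self, params):
        rng = np.random.default_rng(12)
        for _ in range(200):
            ps = sample_param_set(params, rng)
            assert ps.rates.prop_hepatectomy + ps.rates.prop_pneumonectomy == pytest.approx(1.0)

    def test_sample_means_near_base_values(self, params):
        rng = np.random.default_rng(13)
        draws = {k: [] for k in ("cect", "chemo", "resection", "util_chemo", "s12")}
        for _ in range(2000):
            ps = sample_param_set(params, rng)
            draws["cect"].append(ps.costs.cect)
            draws["chemo"].append(ps.costs.chemotherapy_per_month)
            draws["resection"].append(ps.rates.resection_rate_at_first_recurrence)
            draws["util_chemo"].append(ps.utilities.under_chemotherapy)
            draws["s12"].append(ps.rfs_primary.survival[0])
        assert np.mean(draws["cect"]) == pytest.approx(38_190, rel=0.02)
        assert np.mean(draws["chemo"]) == pytest.approx(485_000, rel=0.02)
        # resection rate is sampled from its raw counts (33 of 88)
        assert np.mean(draws["resection"]) == pytest.approx(33 / 88, abs=0.38 * 0.02)
        assert np.mean(draws["util_chemo"]) == pytest.approx(0.25, rel=0.02)
        assert np.mean(draws["s12"]) == pytest.approx(0.479, rel=0.02)


class TestRunPsa:
    def test_single_draw_curve_is_indicator(self, params, strategies):
        settings = PSASettings(
            n_outer=1, n_inner=2000, wtp_grid=(0.0, 5e6), seed=4
        )
        result = sc.run_psa(params, strategies, settings)
        probs = result.ceac.probabilities
        assert set(np.unique(probs.to_numpy())) <= {0.0, 1.0}
        assert np.allclose(probs.sum(axis=1), 1.0)

    def test_collapsed_distributions_reproduce_base_case_exactly(
        self, params, strategies
    ):
        grid = (0.0, 5e6, 6e6)
        multi = sc.run_psa(
            params, strategies,
            PSASettings(n_outer=4, n_inner=2000, wtp_grid=grid, seed=4, collapse=True),
        )
        single = sc.run_psa(
            params, strategies,
            PSASettings(n_outer=1, n_inner=2000, wtp_grid=grid, seed=4, collapse=True),
        )
        # point-mass parameters + shared inner draws: every draw is the base case
        assert multi.ceac.probabilities.equals(single.ceac.probabilities)
        assert set(np.unique(multi.ceac.probabilities.to_numpy())) <= {0.0, 1.0}
        # and the WTP-0 winner is the cheapest strategy of that base case
        outcomes = single.outcomes
        cheapest = outcomes.loc[outcomes["cost_jpy"].idxmin(), "strategy"]
        winner = multi.ceac.probabilities.loc[0.0].idxmax()
        assert winner == cheapest

    def test_probabilities_sum_to_one_across_strategies(self, params, strategies):
        settings = PSASettings(
            n_outer=30, n_inner=1500, wtp_grid=(0.0, 2e6, 5e6, 8e6), seed=6
        )
        result = sc.run_psa(params, strategies, settings)
        probs = result.ceac.probabilities
        assert np.allclose(probs.sum(axis=1), 1.0)
        assert ((probs >= 0) & (probs <= 1)).all().all()
        assert result.outcomes.shape[0] == 30 * len(strategies)

    def test_same_seed_reproducible(self, params, strategies):
        settings = PSASettings(n_outer=5, n_inner=1000, wtp_grid=(5e6,), seed=42)
        a = sc.run_psa(params, strategies, settings)
        b = sc.run_psa(params, strategies, settings)
        assert a.ceac.probabilities.equals(b.ceac.probabilities)
        assert a.outcomes.equals(b.outcomes)
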