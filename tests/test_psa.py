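"""Distribution construction and Monte Carlo PSA behaviour."""

import numpy as np
import pytest
from scipy import stats

from snakebite_cea import run_country, run_psa, ceac
from snakebite_cea.psa import (
    PSA_FIELDS,
    beta_from_base_and_interval,
    beta_from_mean_cv,
    default_distribution_table,
    normal_cost_spec,
    point_mass,
    sample,
)


class TestBetaConstruction:
    def test_meta_analytic_effectiveness_fit(self):
        # pooled estimate 75% with reported interval (55%, 86%)
        spec = beta_from_base_and_interval(0.75, 0.55, 0.86)
        a, b = spec.params["a"], spec.params["b"]
        assert spec.method == "quantile_fit"
        assert a / (a + b) == pytest.approx(0.75, abs=1e-6)
        q_lo, q_hi = stats.beta.ppf([0.025, 0.975], a, b)
        # an asymmetric interval around a fixed mean is only approximately
        # matchable; 0.05 is the feasible bound for this case
        assert q_lo == pytest.approx(0.55, abs=0.05)
        assert q_hi == pytest.approx(0.86, abs=0.05)

    def test_base_on_bound_uses_pert(self):
        spec = beta_from_base_and_interval(0.85, 0.01, 0.85)
        assert spec.method == "pert"
        assert (spec.low, spec.high) == (0.01, 0.85)

    def test_degenerate_interval_rejected(self):
        with pytest.raises(ValueError, match="point_mass"):
            beta_from_base_and_interval(0.5, 0.5, 0.5)
        assert point_mass(0.5).family == "point"

    def test_ordering_violation_rejected(self):
        with pytest.raises(ValueError):
            beta_from_base_and_interval(0.4, 0.5, 0.9)

    def test_moment_beta_mean_and_cv(self):
        spec = beta_from_mean_cv(0.03, cv=0.25)
        a, b = spec.params["a"], spec.params["b"]
        assert a / (a + b) == pytest.approx(0.03)
        var = a * b / ((a + b) ** 2 * (a + b + 1))
        assert np.sqrt(var) / 0.03 == pytest.approx(0.25, rel=1e-6)


class TestNormalCostSpec:
    def test_defaults_and_point_mass(self):
        spec = normal_cost_spec(153.0)
        assert spec.params == {"mean": 153.0, "sd": pytest.approx(30.6)}
        assert normal_cost_spec(153.0, 0.0).family == "point"
        with pytest.raises(ValueError):
            normal_cost_spec(153.0, -1.0)

    def test_sampled_mean_matches_truncated_normal(self):
        mean, sd = 10.0, 8.0  # heavy truncation so the correction matters
        spec = normal_cost_spec(mean, sd)
        rng = np.random.default_rng(0)
        draws = sample(spec, rng, 10**6)
        assert draws.min() >= 0.0
        alpha = (0.0 - mean) / sd
        expected = mean + sd * stats.norm.pdf(alpha) / (1 - stats.norm.cdf(alpha))
        assert draws.mean() == pytest.approx(expected, rel=1e-2)


class TestDistributionTable:
    def test_covers_all_16_varied_inputs(self, benin, ga, ci):
        table = default_distribution_table(benin, ga, ci)
        assert set(table) == set(PSA_FIELDS)
        assert len(PSA_FIELDS) == 16
        for name, spec in table.items():
            assert spec.source_field == name

    def test_country_bounds_versus_global_envelope(self, by_id, ga, ci):
        nigeria = by_id["nigeria"]
        own = default_distribution_table(nigeria, ga, ci, use_country_bounds=True)
        glob = default_distribution_table(nigeria, ga, ci, use_country_bounds=False)
        assert own["av_eff_cv"].params != glob["av_eff_cv"].params


class TestRunPsa:
    def test_same_seed_is_identical(self, benin, ga, ci):
        a = run_psa(benin, ga, ci, n=2000, seed=42)
        b = run_psa(benin, ga, ci, n=2000, seed=42)
        assert a.percentile_2_5 == b.percentile_2_5
        assert a.prob_cost_effective == b.prob_cost_effective
        assert np.array_equal(a.icer_draws, b.icer_draws)

    def test_point_masses_reproduce_deterministic_icer(self, benin, ga, ci):
        det = run_country(benin, ga, ci).icer_per_daly
        dists = {
            "p_cv": point_mass(benin.p_cv),
            "p_cv_mort_untreated": point_mass(benin.p_cv_mort_untreated),
            "p_ncv_mort_untreated": point_mass(benin.p_ncv_mort_untreated),
            "av_eff_cv": point_mass(benin.av_eff_cv),
            "av_eff_ncv": point_mass(benin.av_eff_ncv),
            "p_ear_mono": point_mass(benin.p_ear_mono),
            "p_ear_poly": point_mass(benin.p_ear_poly),
            "p_ear_mort": point_mass(ga.p_ear_mort),
            "p_disabl": point_mass(ga.p_disabl),
            "dw_amputation": point_mass(ga.dw_amputation),
            "c_antivenom": point_mass(ci.c_antivenom),
            "c_20wbct": point_mass(ci.c_20wbct),
            "c_adv_reaction": point_mass(ci.c_adv_reaction),
            "c_supp_care": point_mass(ci.c_supp_care),
            "c_feed_transp": point_mass(ci.c_feed_transp),
            "c_refrg_transp": point_mass(ci.c_refrg_transp),
        }
        for seed in (1, 99):
            res = run_psa(benin, ga, ci, n=50, seed=seed, dists=dists)
            assert res.icer_draws == pytest.approx(det, rel=1e-12)

    def test_benin_highly_likely_cost_effective(self, benin, ga, ci):
        res = run_psa(benin, ga, ci, n=10_000, seed=3, wtp=751.0)
        assert res.prob_cost_effective > 0.95

    def test_monte_carlo_error_shrinks_with_n(self, benin, ga, ci):
        # SE of prob estimate ~ 1/sqrt(n): spread across seeds at n=1e3
        # should be roughly 3x the spread at n=1e4 (allow a loose factor)
        seeds = range(6)
        wtp = 120.0  # near the ICER median so the probability is informative
        spread = {
            n: np.std(
                [
                    run_psa(benin, ga, ci, n=n, seed=s, wtp=wtp).prob_cost_effective
                    for s in seeds
                ]
            )
            for n in (1_000, 10_000)
        }
        assert spread[1_000] > 1.5 * spread[10_000]

    def test_interval_contains_base_case(self, countries, ga, ci):
        for cp in countries:
            det = run_country(cp, ga, ci).icer_per_daly
            res = run_psa(cp, ga, ci, n=4000, seed=11, store_draws=False)
            assert res.percentile_2_5 <= det <= res.percentile_97_5, cp.country_id

    def test_invalid_n_rejected(self, benin, ga, ci):
        with pytest.raises(ValueError, match="n"):
            run_psa(benin, ga, ci, n=0, seed=1)


class TestCeac:
    def test_limits_and_monotonicity(self, benin, ga, ci):
        grid = [0.0, 50.0, 100.0, 200.0, 500.0, 1e9]
        curve = ceac(benin, ga, ci, n=4000, seed=5, wtp_grid=grid)
        probs = [p for _, p in curve]
        assert probs[0] == 0.0  # ICER draws are strictly positive
        assert probs[-1] == 1.0
        assert probs == sorted(probs)

    def test_unsorted_grid_rejected(self, benin, ga, ci):
        with pytest.raises(ValueError, match="sorted"):
            ceac(benin, ga, ci, n=10, seed=1, wtp_grid=[100.0, 50.0])
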