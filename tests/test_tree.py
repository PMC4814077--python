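"""Analytic decision-tree evaluation: branch algebra and arm expectations."""

from decimal import Decimal, ROUND_HALF_UP

import pytest
from hypothesis import given, settings, strategies as st

from snakebite_cea import (
    arm_expectation,
    branch_death_probability,
    effectiveness_from_counts,
    incremental,
    post_av_mortality,
)
from snakebite_cea.daly import daly_constants

probs = st.floats(min_value=0.0, max_value=1.0)


class TestPostAvMortality:
    def test_benin_carpet_viper_value(self):
        # 15% untreated mortality x (1 - 79.3% effectiveness) = 3.11%
        assert post_av_mortality(0.15, 0.793) == pytest.approx(0.03105)
        pct = Decimal(f"{100 * post_av_mortality(0.15, 0.793):.6f}")
        assert pct.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP) == Decimal("3.11")

    @settings(deadline=None, derandomize=True)
    @given(p=probs)
    def test_useless_and_perfect_antivenom(self, p):
        assert post_av_mortality(p, 0.0) == p
        assert post_av_mortality(p, 1.0) == 0.0

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            post_av_mortality(1.2, 0.5)


class TestEffectivenessFromCounts:
    def test_published_study_counts(self):
        # untreated 19/120 vs treated 78/6137 -> 92%; 8/66 vs 5/278 -> 85.2%
        assert effectiveness_from_counts(19, 120, 78, 6137) == pytest.approx(
            0.92, abs=5e-3
        )
        assert effectiveness_from_counts(8, 66, 5, 278) == pytest.approx(
            0.852, abs=5e-3
        )

    def test_no_treated_deaths_gives_full_effectiveness(self):
        assert effectiveness_from_counts(10, 100, 0, 50) == 1.0

    def test_undefined_when_no_untreated_deaths(self):
        with pytest.raises(ZeroDivisionError):
            effectiveness_from_counts(0, 100, 5, 50)

    def test_raw_negative_value_is_returned_unclipped(self):
        assert effectiveness_from_counts(5, 100, 20, 100) == pytest.approx(-3.0)

    def test_count_validation(self):
        with pytest.raises(ValueError):
            effectiveness_from_counts(5, 0, 1, 10)
        with pytest.raises(ValueError):
            effectiveness_from_counts(11, 10, 1, 10)


class TestBranchDeathProbability:
    def test_expanded_value(self):
        # independent expansion: pe*(m + (1-m)*p) + (1-pe)*p
        # = p + pe*m*(1-p) = 0.03105 + 0.033*0.01*0.96895
        p, pe, m = 0.03105, 0.033, 0.01
        expected = pe * (m + (1 - m) * p) + (1 - pe) * p
        assert expected == pytest.approx(0.0313698, abs=1e-6)
        assert branch_death_probability(p, pe, m) == pytest.approx(expected, rel=1e-12)

    @settings(deadline=None, derandomize=True)
    @given(p=probs, m=probs)
    def test_degenerate_ear_branches(self, p, m):
        assert branch_death_probability(p, 0.0, m) == p
        assert branch_death_probability(p, 1.0, 0.0) == pytest.approx(p)

    @settings(deadline=None, derandomize=True)
    @given(p=probs, pe=probs, m=probs)
    def test_result_is_a_probability_and_ear_never_helps(self, p, pe, m):
        out = branch_death_probability(p, pe, m)
        assert 0.0 <= out <= 1.0
        assert out >= p - 1e-15  # the reaction adds hazard, never removes it


class TestArmExpectation:
    def test_untreated_benin(self, benin, ga, ci):
        dc = daly_constants(benin, ga)
        arm = arm_expectation("untreated", benin, ga, ci, dc)
        assert arm.p_death == pytest.approx(0.85 * 0.15 + 0.15 * 0.273)  # 0.16845
        assert arm.expected_cost == 0.0
        assert arm.p_amputation == pytest.approx((1 - 0.16845) * 0.03)

    def test_treated_benin_cost_bundle(self, benin, ga, ci):
        dc = daly_constants(benin, ga)
        arm = arm_expectation("treated", benin, ga, ci, dc)
        assert arm.expected_cost == pytest.approx(237.375 + 0.033 * 1.875)

    def test_all_untreated_arms_cost_zero_in_base_case(self, countries, ga, ci):
        for cp in countries:
            dc = daly_constants(cp, ga)
            assert arm_expectation("untreated", cp, ga, ci, dc).expected_cost == 0.0

    def test_probabilities_valid_and_treatment_reduces_mortality(
        self, countries, ga, ci
    ):
        for cp in countries:
            dc = daly_constants(cp, ga)
            treated = arm_expectation("treated", cp, ga, ci, dc)
            untreated = arm_expectation("untreated", cp, ga, ci, dc)
            for arm in (treated, untreated):
                assert 0.0 <= arm.p_death <= 1.0
                assert arm.p_death + arm.p_amputation <= 1.0
                assert arm.expected_dalys >= 0.0
            assert treated.p_death <= untreated.p_death

    def test_unknown_arm_rejected(self, benin, ga, ci):
        with pytest.raises(ValueError, match="arm"):
            arm_expectation("placebo", benin, ga, ci, daly_constants(benin, ga))


class TestIncremental:
    def test_benin_deaths_averted(self, benin, ga, ci):
        dc = daly_constants(benin, ga)
        inc = incremental(
            arm_expectation("treated", benin, ga, ci, dc),
            arm_expectation("untreated", benin, ga, ci, dc),
        )
        assert inc.deaths_averted == pytest.approx(0.1186, abs=5e-4)
        # more survivors -> more people at amputation risk
        assert inc.amputations_averted < 0

    def test_identical_arms_give_zero_incremental(self, benin, ga, ci):
        dc = daly_constants(benin, ga)
        arm = arm_expectation("treated", benin, ga, ci, dc)
        inc = incremental(arm, arm)
        assert (
            inc.delta_cost,
            inc.deaths_averted,
            inc.amputations_averted,
            inc.dalys_averted,
        ) == (0.0, 0.0, 0.0, 0.0)

    def test_daly_decomposition_identity(self, countries, ga, ci):
        # dalys averted must equal deaths*yll + amputations*yld exactly
        for cp in countries:
            dc = daly_constants(cp, ga)
            inc = incremental(
                arm_expectation("treated", cp, ga, ci, dc),
                arm_expectation("untreated", cp, ga, ci, dc),
            )
            expected = (
                inc.deaths_averted * dc.yll_per_death
                + inc.amputations_averted * dc.yld_per_disability
            )
            assert inc.dalys_averted == pytest.approx(expected, abs=1e-12)
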