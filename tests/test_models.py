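"""The five judgment models: closed-form values, sensitivities, invariances."""

import math
from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from universalize import (
    CLAMP_HI,
    CLAMP_LO,
    ChoiceParams,
    DualRoleScenario,
    NormParams,
    RuleParams,
    ThresholdScenario,
    UtilityCurve,
    frustrated_means,
    make_idealized_threshold_curve,
    p_norm,
    p_outcome,
    p_pessimistic,
    p_rule,
    p_universalization,
    p_universalization_scoped,
    predict_curve,
)


def flat_scenario(value=1.0, n_total=20, ni=5, **kw):
    return ThresholdScenario(
        n_total=n_total, n_interested=ni,
        curve=UtilityCurve(n_total, (value,) * (n_total + 1)), **kw,
    )


class TestUniversalization:
    def test_equal_worlds_give_half(self):
        for tau in (0.1, 1.0, 17.0):
            assert p_universalization(flat_scenario(), ChoiceParams(tau, 0.0)) == 0.5

    def test_closed_form_unit_utility_gap(self, scenario_4_7):
        # U(0) - U(8) = 1 with the (4,7) idealized curve and ni=7
        assert p_universalization(scenario_4_7, ChoiceParams(1.0, 0.0)) == pytest.approx(
            1 / (1 + math.e), abs=1e-6
        )
        assert p_universalization(scenario_4_7, ChoiceParams(1.0, 0.0)) == pytest.approx(
            0.268941, abs=1e-6
        )

    def test_closed_form_negative_gap(self):
        # reversed coding: U(0) - U(m) = -1, tau = 2
        curve = UtilityCurve(20, tuple(0.0 if n == 0 else 1.0 for n in range(21)))
        s = ThresholdScenario(n_total=20, n_interested=5, curve=curve)
        assert p_universalization(s, ChoiceParams(2.0, 0.0)) == pytest.approx(0.880797, abs=1e-6)

    def test_include_actor_shifts_the_comparison_world(self, idealized_curves):
        s = ThresholdScenario(n_total=20, n_interested=4, curve=idealized_curves["4_7"],
                              harm_onset=4, collapse_point=7)
        p_with = p_universalization(s, ChoiceParams(3.0, 0.0), include_actor=True)
        p_without = p_universalization(s, ChoiceParams(3.0, 0.0), include_actor=False)
        assert p_without == 0.5          # U(4) is still on the high plateau
        assert p_with < p_without        # U(5) is inside the descent

    def test_universalized_world_cannot_exceed_group(self, idealized_curves):
        s = ThresholdScenario(n_total=20, n_interested=20, curve=idealized_curves["4_7"])
        with pytest.raises(ValueError, match="exceeds"):
            p_universalization(s, ChoiceParams(1.0, 0.0))

    def test_overflow_saturates_within_clamp(self, scenario_4_7):
        p = p_universalization(scenario_4_7, ChoiceParams(1e6, 0.0))
        assert CLAMP_LO <= p <= CLAMP_HI and np.isfinite(p)

    @settings(max_examples=100, deadline=None)
    @given(tau=st.floats(-30, 30), beta=st.floats(-10, 10), ni=st.integers(0, 19),
           value=st.floats(-5, 5))
    def test_constant_curve_prediction_independent_of_interest(self, tau, beta, ni, value):
        """With no threshold (flat utility) the model predicts no effect of
        the number of interested parties."""
        p1 = p_universalization(flat_scenario(value, ni=ni), ChoiceParams(tau, beta))
        p2 = p_universalization(flat_scenario(value, ni=0), ChoiceParams(tau, beta))
        assert p1 == pytest.approx(p2, abs=1e-12)

    @settings(max_examples=100, deadline=None)
    @given(tau=st.floats(0.01, 20), beta=st.floats(-5, 5))
    def test_monotone_nonincreasing_in_interest_for_positive_tau(
        self, idealized_curves, tau, beta
    ):
        s = ThresholdScenario(n_total=20, n_interested=0, curve=idealized_curves["4_7"],
                              harm_onset=4, collapse_point=7)
        probs = predict_curve("universalization", s, ChoiceParams(tau, beta), range(20))
        assert np.all(np.diff(probs) <= 1e-12)

    @settings(max_examples=100, deadline=None)
    @given(tau=st.floats(-20, 20), beta=st.floats(-5, 5), c=st.floats(-3, 3),
           ni=st.integers(0, 19))
    def test_sign_coding_equivalence(self, idealized_curves, tau, beta, c, ni):
        """Negating tau while reflecting U about a constant leaves the
        prediction unchanged."""
        curve = idealized_curves["4_7"]
        reflected = UtilityCurve(20, tuple(2 * c - v for v in curve.values))
        s1 = ThresholdScenario(n_total=20, n_interested=ni, curve=curve)
        s2 = ThresholdScenario(n_total=20, n_interested=ni, curve=reflected)
        p1 = p_universalization(s1, ChoiceParams(tau, beta))
        p2 = p_universalization(s2, ChoiceParams(-tau, beta))
        assert p1 == pytest.approx(p2, rel=1e-9)


class TestOutcomeAndPessimistic:
    def test_plateau_gives_half(self, scenario_4_7):
        assert p_outcome(scenario_4_7, ChoiceParams(1.0, 0.0)) == 0.5  # U(0)=U(1)

    def test_closed_form_unit_step(self):
        curve = UtilityCurve(20, tuple(1.0 if n == 0 else 0.0 for n in range(21)))
        s = ThresholdScenario(n_total=20, n_interested=3, curve=curve)
        assert p_outcome(s, ChoiceParams(1.0, 0.0)) == pytest.approx(0.268941, abs=1e-6)

    @settings(max_examples=100, deadline=None)
    @given(ni1=st.integers(0, 19), ni2=st.integers(0, 19),
           tau=st.floats(-10, 10), beta=st.floats(-5, 5))
    def test_outcome_blind_to_interested_parties(self, idealized_curves, ni1, ni2, tau, beta):
        params = ChoiceParams(tau, beta)
        s1 = ThresholdScenario(n_total=20, n_interested=ni1, curve=idealized_curves["4_7"])
        s2 = ThresholdScenario(n_total=20, n_interested=ni2, curve=idealized_curves["4_7"])
        assert p_outcome(s1, params) == p_outcome(s2, params)

    def test_pessimistic_dip_inside_threshold_only(self, idealized_curves):
        """The pessimistic model judges the action least acceptable where one
        more actor could plausibly tip the outcome: inside the harm range."""
        s = ThresholdScenario(n_total=20, n_interested=0, curve=idealized_curves["4_7"],
                              harm_onset=4, collapse_point=7)
        probs = predict_curve("pessimistic", s, ChoiceParams(3.0, 0.0), range(20))
        inside = [4, 5, 6]
        assert all(probs[n] < 0.5 for n in inside)
        assert all(probs[n] == 0.5 for n in range(20) if n not in inside)

    def test_pessimistic_closed_form_on_descent(self, idealized_curves):
        # ni=5 inside the (4,7) descent: U(5) - U(6) = 1/3, tau = 3
        s = ThresholdScenario(n_total=20, n_interested=5, curve=idealized_curves["4_7"])
        assert p_pessimistic(s, ChoiceParams(3.0, 0.0)) == pytest.approx(0.268941, abs=1e-6)

    def test_pessimistic_low_plateau_returns_to_half(self, idealized_curves):
        s = ThresholdScenario(n_total=20, n_interested=15, curve=idealized_curves["4_7"])
        assert p_pessimistic(s, ChoiceParams(3.0, 0.0)) == 0.5


class TestRuleAndNorm:
    def test_rule_definition_and_complement(self):
        assert p_rule(flat_scenario(rule_present=False), RuleParams(0.9)) == pytest.approx(0.9)
        assert p_rule(flat_scenario(rule_present=True), RuleParams(0.9)) == pytest.approx(0.1)
        for present in (False, True):
            assert p_rule(flat_scenario(rule_present=present), RuleParams(0.5)) == 0.5

    def test_norm_at_threshold_proportion_gives_half(self):
        s = flat_scenario(norm_count=10)  # np/n = 0.5
        assert p_norm(s, NormParams(4.0, 0.5)) == 0.5

    def test_norm_closed_form(self):
        s = flat_scenario(norm_count=20)  # np/n = 1, theta = 0.5, tau = 4
        assert p_norm(s, NormParams(4.0, 0.5)) == pytest.approx(0.119203, abs=1e-6)

    @settings(max_examples=100, deadline=None)
    @given(tau=st.floats(-20, 20), theta=st.floats(0.01, 0.99),
           norm_count=st.integers(0, 20), data=st.data())
    def test_norm_invariant_to_utility_curve(self, tau, theta, norm_count, data):
        values = data.draw(
            st.lists(st.floats(-10, 10), min_size=21, max_size=21)
        )
        s_flat = flat_scenario(norm_count=norm_count)
        s_other = replace(s_flat, curve=UtilityCurve(20, tuple(values)))
        params = NormParams(tau, theta)
        assert p_norm(s_flat, params) == p_norm(s_other, params)

    def test_theta_outside_open_interval_rejected(self):
        with pytest.raises(ValueError):
            NormParams(1.0, 0.0)
        with pytest.raises(ValueError):
            NormParams(1.0, 1.0)


class TestAllModelsBounded:
    @settings(max_examples=60, deadline=None)
    @given(tau=st.floats(-1e4, 1e4), beta=st.floats(-1e3, 1e3), ni=st.integers(0, 19))
    def test_probabilities_clamped_and_finite(self, idealized_curves, tau, beta, ni):
        s = ThresholdScenario(n_total=20, n_interested=ni, curve=idealized_curves["10_13"],
                              harm_onset=10, collapse_point=13, norm_count=ni)
        cp = ChoiceParams(tau, beta)
        values = [
            p_universalization(s, cp),
            p_outcome(s, cp),
            p_pessimistic(s, cp),
            p_rule(s, RuleParams(1.0)),
            p_norm(s, NormParams(tau, 0.5)),
        ]
        for p in values:
            assert CLAMP_LO <= p <= CLAMP_HI
            assert np.isfinite(p)


def tour_boat(ni, n_total=20):
    """Actor's utility unaffected by how many others act; others collapse."""
    actor = UtilityCurve(n_total, (1.0,) * (n_total + 1))
    others = make_idealized_threshold_curve(n_total, 4, 7, 1.0, 0.0)
    return DualRoleScenario(actor_curve=actor, others_curve=others,
                            n_total=n_total, n_interested=ni)


def fisherman(ni, n_total=20):
    """Actor shares the collapsing curve."""
    curve = make_idealized_threshold_curve(n_total, 4, 7, 1.0, 0.0)
    return DualRoleScenario(actor_curve=curve, others_curve=curve,
                            n_total=n_total, n_interested=ni)


class TestScopedUniversalization:
    def test_actor_scope_blind_to_interest_when_actor_unaffected(self):
        params = ChoiceParams(2.0, 0.0)
        p_low = p_universalization_scoped(tour_boat(0), params, "actor")
        p_high = p_universalization_scoped(tour_boat(19), params, "actor")
        assert p_low == p_high == 0.5

    def test_everyone_scope_still_sees_the_collapse(self):
        params = ChoiceParams(2.0, 0.0)
        p_low = p_universalization_scoped(tour_boat(0), params, "everyone")
        p_high = p_universalization_scoped(tour_boat(19), params, "everyone")
        assert p_high < p_low

    def test_identical_curves_sum_to_doubled_curve(self):
        params = ChoiceParams(1.5, -0.3)
        s = fisherman(10)
        doubled = UtilityCurve(20, tuple(2 * v for v in s.others_curve.values))
        from universalize import ThresholdScenario, p_universalization

        expected = p_universalization(
            ThresholdScenario(n_total=20, n_interested=10, curve=doubled), params
        )
        assert p_universalization_scoped(s, params, "everyone") == pytest.approx(expected)
        single = p_universalization(
            ThresholdScenario(n_total=20, n_interested=10, curve=s.actor_curve), params
        )
        assert p_universalization_scoped(s, params, "actor") == pytest.approx(single)

    def test_unknown_scope_rejected(self):
        with pytest.raises(ValueError, match="scope"):
            p_universalization_scoped(tour_boat(0), ChoiceParams(1.0, 0.0), "society")


class TestFrustratedMeans:
    def test_fisherman_goal_undermined(self):
        assert frustrated_means(fisherman(5)) is True

    def test_tour_boat_goal_intact(self):
        assert frustrated_means(tour_boat(5)) is False

    def test_constant_actor_curve_never_frustrated(self):
        s = DualRoleScenario(
            actor_curve=UtilityCurve(20, (2.0,) * 21),
            others_curve=UtilityCurve(20, (0.0,) * 21),
            n_total=20, n_interested=3,
        )
        assert frustrated_means(s) is False


class TestPredictCurve:
    def test_outcome_and_rule_constant_over_grid(self, scenario_4_7):
        grid = (0, 2, 7, 8, 13, 19)
        out = predict_curve("outcome", scenario_4_7, ChoiceParams(3.0, 0.5), grid)
        assert len(set(out)) == 1
        rule = predict_curve("rule", scenario_4_7, RuleParams(0.8), grid)
        assert len(set(rule)) == 1

    def test_universalization_largest_drop_spans_the_threshold(self, scenario_4_7):
        grid = (0, 2, 7, 8, 13, 19)
        probs = predict_curve("universalization", scenario_4_7, ChoiceParams(3.0, 0.0), grid)
        assert np.all(np.diff(probs) <= 1e-12)
        drops = -np.diff(probs)
        assert np.argmax(drops) == 1  # the 2 -> 7 gap spanning (4,7)

    def test_unknown_model_rejected(self, scenario_4_7):
        with pytest.raises(ValueError, match="model"):
            predict_curve("virtue", scenario_4_7, ChoiceParams(1.0, 0.0), (0, 1))

    def test_grid_outside_group_rejected(self, scenario_4_7):
        with pytest.raises(ValueError, match="grid"):
            predict_curve("universalization", scenario_4_7, ChoiceParams(1.0, 0.0), (0, 25))
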