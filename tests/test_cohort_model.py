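"""Decision tree, Markov transitions, and discounted cohort accounting."""

import numpy as np
import pytest

from hemovoi import (
    ModelConfig,
    default_strategies,
    evaluate_strategy,
    run_decision_tree,
    run_markov,
    sample_draw,
    transition_matrix,
)
from hemovoi.cohort_model import STATES
from hemovoi.parameters import ParameterDraw

ANNUITY_5Y_3PCT = sum(1.03 ** -(k - 1) for k in range(1, 6))  # 4.717098...


def modified(draw, **overrides):
    values = dict(draw.values)
    values.update(overrides)
    return ParameterDraw(values=values)


def zero_mortality_draw(point_draw):
    return modified(
        point_draw,
        mort_cv_year1=0.0, mort_cv_year2=0.0, mort_cv_year3=0.0,
        mort_stroke_first=0.0, mort_other=0.0,
        mort_after_recovery_other=0.0, recovery_other=0.0,
    )


class TestDecisionTree:
    def test_delivery_costs_from_table(self, table):
        routine, gdht = default_strategies(table)
        assert routine.delivery_cost == 11 + 27 + 117 == 155
        assert gdht.delivery_cost == 221 + 159 + 401 == 781

    def test_initial_distribution_maps_outcomes_to_states(self, point_draw, table):
        routine, _ = default_strategies(table)
        cost, initial = run_decision_tree(point_draw, routine)
        assert initial[STATES.index("dead")] == pytest.approx(0.129)
        assert initial[STATES.index("well")] == pytest.approx(0.398)
        assert initial[STATES.index("recovered")] == 0.0
        assert initial.sum() == pytest.approx(1.0)
        assert cost > 155

    def test_grouped_episode_costs_are_weighted_means(self, point_draw, table):
        """At the point estimates the routine short-term cost decomposes as
        delivery + sum of outcome probability x grouped episode cost."""
        routine, _ = default_strategies(table)
        cost, _ = run_decision_tree(point_draw, routine)
        cv = (7498 + 9903) / 2
        other = (8514 + 12197 + 8566 + 7617 + 10190 + 9900 + 7961) / 7
        expected = 155 + np.dot(
            [0.129, 0.065, 0.005, 0.403, 0.398],
            [9020, cv, 7550, other, 6753],
        )
        assert cost == pytest.approx(expected)

    def test_unit_relative_risks_leave_only_delivery_difference(
        self, point_draw, table
    ):
        draw = modified(point_draw, rr_complications=1.0, rr_mortality=1.0)
        routine, gdht = default_strategies(table)
        out_r = evaluate_strategy(draw, routine)
        out_g = evaluate_strategy(draw, gdht)
        assert out_g.cost - out_r.cost == pytest.approx(781 - 155)
        assert out_g.qalys == pytest.approx(out_r.qalys)


class TestTransitionMatrix:
    @pytest.mark.parametrize("cycle", [1, 2, 3, 4, 5])
    def test_rows_stochastic_and_dead_absorbing(self, point_draw, cycle):
        m = transition_matrix(point_draw, cycle)
        np.testing.assert_allclose(m.sum(axis=1), 1.0, atol=1e-12)
        assert (m >= 0).all()
        assert m[5, 5] == 1.0

    def test_cardiovascular_schedule_carried_forward(self, point_draw):
        deaths = [transition_matrix(point_draw, k)[1, 5] for k in (1, 2, 3, 4, 5)]
        assert deaths == [0.107, 0.058, 0.056, 0.056, 0.056]

    def test_stroke_first_year_then_cv_schedule(self, point_draw):
        deaths = [transition_matrix(point_draw, k)[2, 5] for k in (1, 2, 3)]
        assert deaths == [0.15, 0.058, 0.056]

    def test_stroke_follow_on_override(self, point_draw):
        config = ModelConfig(stroke_annual_mortality=0.2)
        assert transition_matrix(point_draw, 3, config)[2, 5] == 0.2
        assert transition_matrix(point_draw, 1, config)[2, 5] == 0.15

    def test_recovery_only_from_other_state(self, point_draw):
        m = transition_matrix(point_draw, 2)
        rec = STATES.index("recovered")
        assert m[3, rec] == pytest.approx(0.41)
        for src in (0, 1, 2, 5):
            assert m[src, rec] == 0.0


class TestRunMarkov:
    def test_zero_mortality_closed_form_qalys(self, point_draw):
        """With all mortality off, a well cohort accrues utility times the
        5-year annuity factor at 3%: w x 4.7171."""
        draw = zero_mortality_draw(point_draw)
        config = ModelConfig(standard_annual_mortality=0.0)
        initial = [1, 0, 0, 0, 0, 0]
        _, outcome = run_markov(initial, draw, 5, 0.03, config)
        w = draw["utility_well"]
        assert outcome.qalys == pytest.approx(w * ANNUITY_5Y_3PCT, abs=1e-9)
        assert round(w * ANNUITY_5Y_3PCT / w, 4) == 4.7171

    def test_all_dead_cohort_accrues_no_qalys(self, point_draw):
        trace, outcome = run_markov([0, 0, 0, 0, 0, 1], point_draw, 5, 0.03)
        assert outcome.qalys == 0.0
        # only the one-off first-year cost for in-hospital deaths accrues
        assert outcome.cost == pytest.approx(point_draw["cost_year1_death"])
        assert (trace.occupancy[:, 5] == 1.0).all()

    def test_mass_conserved_and_death_monotone(self, table, rng):
        for _ in range(20):
            draw = sample_draw(table, rng)
            initial = draw.outcome_vector[[4, 1, 2, 3, 0]]
            initial = np.insert(initial, 4, 0.0)
            trace, _ = run_markov(initial, draw, 5, 0.03)
            np.testing.assert_allclose(
                trace.occupancy.sum(axis=1), 1.0, atol=1e-9
            )
            assert (np.diff(trace.occupancy[:, 5]) >= -1e-12).all()
            assert (trace.occupancy >= -1e-12).all()

    def test_discounting_never_increases_totals(self, point_draw):
        initial = [0.398, 0.065, 0.005, 0.403, 0.0, 0.129]
        _, undiscounted = run_markov(initial, point_draw, 5, 0.0)
        _, discounted = run_markov(initial, point_draw, 5, 0.03)
        assert discounted.cost <= undiscounted.cost
        assert discounted.qalys <= undiscounted.qalys

    def test_one_cycle_no_discount_hand_oracle(self, point_draw):
        """A 1-cycle horizon with discount 0 reproduces the brute-force
        expectation over the six states."""
        initial = np.array([0.398, 0.065, 0.005, 0.403, 0.0, 0.129])
        _, outcome = run_markov(initial, point_draw, 1, 0.0)
        utils = np.array([0.74, 0.74 - 0.19, 0.74 - 0.35, 0.74 - 0.15, 0.66, 0.0])
        costs = np.array([147, 7673, 7512, 7314, 396, 0.0])
        assert outcome.qalys == pytest.approx(float(initial @ utils))
        assert outcome.cost == pytest.approx(
            float(initial @ costs) + 0.129 * 4837
        )

    def test_qalys_monotone_nonincreasing_in_mortality(self, point_draw, table):
        """Bumping any mortality input never increases QALYs."""
        _, gdht = default_strategies(table)
        base = evaluate_strategy(point_draw, gdht).qalys
        for name in (
            "mort_cv_year1", "mort_cv_year2", "mort_cv_year3",
            "mort_stroke_first", "mort_other",
            "mort_after_recovery_other", "rr_mortality",
        ):
            bumped = modified(point_draw, **{name: point_draw[name] + 0.05})
            assert evaluate_strategy(bumped, gdht).qalys <= base + 1e-12
        high_standard = ModelConfig(standard_annual_mortality=0.2)
        assert evaluate_strategy(point_draw, gdht, config=high_standard).qalys < base

    def test_death_cost_every_cycle_option_adds_cost(self, point_draw):
        initial = [0.398, 0.065, 0.005, 0.403, 0.0, 0.129]
        _, base = run_markov(initial, point_draw, 5, 0.03)
        _, with_option = run_markov(
            initial, point_draw, 5, 0.03, ModelConfig(death_cost_every_cycle=True)
        )
        assert with_option.cost > base.cost
        assert with_option.qalys == base.qalys

    def test_bad_inputs_rejected(self, point_draw):
        with pytest.raises(ValueError, match="simplex"):
            run_markov([1, 1, 0, 0, 0, 0], point_draw, 5, 0.03)
        with pytest.raises(ValueError, match="horizon"):
            run_markov([1, 0, 0, 0, 0, 0], point_draw, 0, 0.03)


class TestEvaluateStrategy:
    def test_point_estimate_evaluation_is_deterministic(self, point_draw, table):
        routine, _ = default_strategies(table)
        a = evaluate_strategy(point_draw, routine)
        b = evaluate_strategy(point_draw, routine)
        assert a == b

    def test_gdht_dominates_at_point_estimates(self, point_draw, table):
        """At the tabulated point estimates GDHT is less costly and more
        effective than routine care (the dominant quadrant)."""
        routine, gdht = default_strategies(table)
        out_r = evaluate_strategy(point_draw, routine)
        out_g = evaluate_strategy(point_draw, gdht)
        assert out_g.cost < out_r.cost
        assert out_g.qalys > out_r.qalys
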