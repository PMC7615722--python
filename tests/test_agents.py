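"""Behavior of the generative choice models."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from habitlab import agents, task_designs as td
from habitlab.agents import (
    ModelParams,
    RLState,
    TwoStepParams,
    TwoStepState,
    choice_probability,
    ck_update,
    habit_weight,
    rl_update,
    simulate_task,
    simulate_unrewarded_training,
    two_step_probability,
    two_step_update,
)

unit = st.floats(0.0, 1.0, allow_nan=False)
beta = st.floats(0.0, 10.0, allow_nan=False)


def state_ab(q_a=0.5, q_b=0.5, ck_a=0.5, ck_b=0.5):
    return RLState(q={"a": q_a, "b": q_b}, ck={"a": ck_a, "b": ck_b})


class TestChoiceProbability:
    def test_indifference_cases(self):
        assert choice_probability(state_ab(), ModelParams("random"), "a", "b") == 0.5
        p = ModelParams("rl_ck", alpha_q=0.1, beta_q=0.0, alpha_h=0.1, beta_h=0.0)
        assert choice_probability(state_ab(0.9, 0.1, 0.9, 0.1), p, "a", "b") == 0.5
        p = ModelParams("rl_ck", alpha_q=0.1, beta_q=7.0, alpha_h=0.1, beta_h=3.0)
        assert choice_probability(state_ab(0.3, 0.3, 0.6, 0.6), p, "a", "b") == 0.5

    def test_unknown_stimulus_rejected(self):
        with pytest.raises(KeyError):
            choice_probability(state_ab(), ModelParams("random"), "a", "zzz")

    @given(q_a=unit, q_b=unit, ck_a=unit, ck_b=unit, bq=beta, bh=beta)
    @settings(max_examples=60, deadline=None)
    def test_probabilities_sum_to_one(self, q_a, q_b, ck_a, ck_b, bq, bh):
        p = ModelParams("rl_ck", alpha_q=0.1, beta_q=bq, alpha_h=0.1, beta_h=bh)
        s = state_ab(q_a, q_b, ck_a, ck_b)
        left = choice_probability(s, p, "a", "b")
        right = choice_probability(s, p, "b", "a")
        assert left + right == pytest.approx(1.0, abs=1e-12)

    def test_monotone_in_kernel_weight(self):
        s = state_ab(ck_a=0.8, ck_b=0.2)
        probs = [
            choice_probability(
                s, ModelParams("ck", alpha_h=0.1, beta_h=bh), "a", "b"
            )
            for bh in (1.0, 3.0, 6.0, 9.0)
        ]
        assert all(a < b for a, b in zip(probs, probs[1:]))

    def test_reduced_model_equal_weighting_at_five(self):
        # beta_h = 5 implies beta_q = 5: equal weight on Q and CK differences
        p = ModelParams("rl_ck_reduced", alpha_q=0.1, alpha_h=0.1, beta_h=5.0)
        assert p.effective_beta_q == p.effective_beta_h == 5.0
        swapped_q = choice_probability(state_ab(0.7, 0.3, 0.4, 0.6), p, "a", "b")
        swapped_ck = choice_probability(state_ab(0.4, 0.6, 0.7, 0.3), p, "a", "b")
        assert swapped_q == pytest.approx(swapped_ck)

    def test_reduced_model_rejects_explicit_beta_q(self):
        with pytest.raises(ValueError):
            ModelParams("rl_ck_reduced", alpha_q=0.1, beta_q=3.0, alpha_h=0.1, beta_h=5.0)

    @given(bh=beta)
    @settings(max_examples=30, deadline=None)
    def test_reduced_temperatures_sum_to_ten(self, bh):
        p = ModelParams("rl_ck_reduced", alpha_q=0.2, alpha_h=0.2, beta_h=bh)
        assert p.effective_beta_q + p.effective_beta_h == pytest.approx(10.0)


class TestRLUpdate:
    def test_single_delta_step(self):
        s = state_ab(q_a=0.0, q_b=0.0)
        out = rl_update(s, "a", "b", 5 / 9, 1 / 9, alpha_q=0.5)
        assert out.q["a"] == pytest.approx(5 / 18)
        assert out.q["b"] == pytest.approx(1 / 18)
        assert s.q["a"] == 0.0  # input state untouched

    def test_zero_rate_is_identity(self):
        s = state_ab(q_a=0.3, q_b=0.9)
        out = rl_update(s, "a", "b", 1.0, 0.0, alpha_q=0.0)
        assert out.q == s.q

    def test_chosen_only_leaves_unchosen(self):
        s = state_ab(q_a=0.0, q_b=0.4)
        out = rl_update(s, "a", "b", 1.0, 0.0, alpha_q=0.5, feedback="chosen_only")
        assert out.q["a"] == 0.5 and out.q["b"] == 0.4

    def test_geometric_convergence_to_reward(self):
        # q approaches r as (1 - alpha)^k: oracle bound checked explicitly
        s = state_ab(q_a=0.0, q_b=0.0)
        r = 7 / 9
        for k in range(40):
            expect = r * (1 - 0.5**k)
            assert s.q["a"] == pytest.approx(expect, abs=1e-12)
            s = rl_update(s, "a", "b", r, 0.0, alpha_q=0.5, feedback="chosen_only")
        assert abs(s.q["a"] - r) < 1e-6

    def test_bad_alpha_rejected(self):
        with pytest.raises(ValueError):
            rl_update(state_ab(), "a", "b", 0.5, 0.5, alpha_q=1.5)


class TestCKUpdate:
    def test_single_step_from_zero(self):
        s = state_ab(ck_a=0.0, ck_b=0.0)
        out = ck_update(s, "a", "b", alpha_h=0.2)
        assert out.ck["a"] == pytest.approx(0.2)
        assert out.ck["b"] == 0.0

    def test_fixed_point_under_repetition(self):
        s = state_ab()
        for _ in range(200):
            s = ck_update(s, "a", "b", alpha_h=0.3)
        assert s.ck["a"] == pytest.approx(1.0, abs=1e-6)
        assert s.ck["b"] == pytest.approx(0.0, abs=1e-6)

    def test_alternation_converges_to_half(self):
        # equal choice of both options: kernels hover around 0.5 for small rates
        s = state_ab(ck_a=0.0, ck_b=1.0)
        for i in range(2000):
            chosen, unchosen = ("a", "b") if i % 2 == 0 else ("b", "a")
            s = ck_update(s, chosen, unchosen, alpha_h=0.02)
        assert s.ck["a"] == pytest.approx(0.5, abs=0.05)
        assert s.ck["b"] == pytest.approx(0.5, abs=0.05)

    def test_absent_stimuli_unchanged(self):
        s = RLState(q={"a": 0.5, "b": 0.5, "c": 0.5}, ck={"a": 0.5, "b": 0.5, "c": 0.9})
        out = ck_update(s, "a", "b", alpha_h=0.5)
        assert out.ck["c"] == 0.9


class TestSimulateTask:
    def test_greedy_value_learner_prefers_higher_value(self, reward_map):
        params = ModelParams("rl", alpha_q=0.5, beta_q=10.0)
        state = None
        for day in range(1, 6):
            schedule = td.build_reward_pairs_training_session(day, 1)
            log, state = agents.simulate_task(
                params, schedule, reward_map, seed=day, state=state
            )
        correct = [
            row.chosen_stim
            == max((row.left_stim, row.right_stim), key=reward_map.get)
            for row in log.itertuples()
        ]
        # all training pairs differ by 2 points, so once values are learned
        # the softmax ceiling is sigmoid(beta * 2/9) ~ 0.902 at beta = 10
        ceiling = 1.0 / (1.0 + math.exp(-10.0 * 2.0 / 9.0))
        assert np.mean(correct) > 0.85
        assert np.mean(correct) == pytest.approx(ceiling, abs=0.05)

    def test_random_agent_left_rate(self, reward_map):
        schedule = td.build_reward_pairs_training_session(1, 2)
        log, _ = simulate_task(ModelParams("random"), schedule, reward_map, seed=3)
        rate = (log["choice_side"] == "left").mean()
        assert abs(rate - 0.5) < 4 * 0.5 / math.sqrt(160)

    def test_kernel_agent_prefers_frequent_in_same_reward_test(self, reward_map):
        params = ModelParams("rl_ck", alpha_q=0.4, beta_q=8.0, alpha_h=0.1, beta_h=5.0)
        props = []
        for seed in range(8):
            state = None
            for day in range(1, 6):
                schedule = td.build_reward_pairs_training_session(day, seed)
                _, state = simulate_task(
                    params, schedule, reward_map, seed=seed * 10 + day, state=state
                )
            log, _ = simulate_task(
                params, td.build_reward_pairs_test(seed), None,
                seed=seed + 500, state=state,
            )
            for freq, rare in td.same_reward_pairs():
                pair = log[
                    ((log.left_stim == freq) & (log.right_stim == rare))
                    | ((log.left_stim == rare) & (log.right_stim == freq))
                ]
                props.append((pair.chosen_stim == freq).mean())
        assert np.mean(props) > 0.5

    def test_training_log_carries_both_outcomes(self, short_rp_log, reward_map):
        row = short_rp_log.iloc[0]
        assert row.outcome_points_left == reward_map[row.left_stim]
        assert row.outcome_points_right == reward_map[row.right_stim]


class TestUnrewardedTraining:
    def test_full_compliance_follows_cue(self):
        schedule = td.build_unrewarded_training_session(1, 5)
        log, _ = simulate_unrewarded_training(1.0, schedule, seed=1)
        for row in log.itertuples():
            cued = row.left_stim if row.cue_side == "left" else row.right_stim
            assert row.chosen_stim == cued

    def test_kernel_separates_frequent_from_rare(self):
        state = None
        for day in range(1, 6):
            schedule = td.build_unrewarded_training_session(day, 6)
            _, state = simulate_unrewarded_training(
                1.0, schedule, seed=day, alpha_h=0.1, state=state
            )
        assert state.ck["uA"] > state.ck["uB"]
        assert abs(state.ck["uC"] - state.ck["uD"]) < abs(
            state.ck["uA"] - state.ck["uB"]
        )

    def test_miss_rate(self):
        schedule = td.build_unrewarded_training_session(1, 7)
        log, _ = simulate_unrewarded_training(1.0, schedule, seed=2, miss_prob=0.1)
        assert log["missed"].sum() == pytest.approx(24, abs=15)
        missed_rows = log[log["missed"] == 1]
        assert missed_rows["chosen_stim"].isna().all()

    def test_compliance_bounds(self):
        schedule = td.build_unrewarded_training_session(1, 7)
        with pytest.raises(ValueError):
            simulate_unrewarded_training(0.3, schedule)


class TestTwoStepHybrid:
    def test_model_based_limit_identical_across_states(self):
        # with w=1 the two equivalent initial states give identical policies
        p = TwoStepParams(alpha=0.3, beta=4.0, lam=0.5, pi=0.0, rho=0.0, w=1.0)
        s = TwoStepState(v=np.array([1.0, -1.0]), q_mf=np.array([[5.0, -5.0], [0.0, 0.0]]))
        assert two_step_probability(p, s, 0, 0, 1) == pytest.approx(
            two_step_probability(p, s, 1, 2, 3)
        )

    def test_model_free_limit_no_transfer(self):
        # an outcome in state 0 leaves state 1's model-free values untouched
        p = TwoStepParams(alpha=0.5, beta=4.0, lam=0.0, pi=0.0, rho=0.0, w=0.0)
        s = TwoStepState()
        s2 = two_step_update(p, s, 0, 0, 0, reward=5.0)
        assert np.all(s2.q_mf[1] == 0.0)
        # but the alien value does change (that is the model-based pathway)
        assert s2.v[0] != 0.0

    def test_symmetric_values_give_half(self):
        p = TwoStepParams(alpha=0.3, beta=6.0, lam=0.5, pi=0.0, rho=0.0, w=0.4)
        s = TwoStepState()
        assert two_step_probability(p, s, 0, 0, 1) == 0.5

    def test_habit_weight_is_inverted_w(self):
        assert habit_weight(0.3) == pytest.approx(0.7)
        assert habit_weight(1.0) == 0.0
        with pytest.raises(ValueError):
            habit_weight(1.5)

    def test_update_follows_sarsa_lambda(self):
        p = TwoStepParams(alpha=0.5, beta=1.0, lam=0.5, pi=0.0, rho=0.0, w=0.5)
        s = TwoStepState()
        s2 = two_step_update(p, s, 0, 0, 0, reward=4.0)
        # delta1 = 0, delta2 = 4: v += .5*4, q_mf += .5*.5*4
        assert s2.v[0] == pytest.approx(2.0)
        assert s2.q_mf[0, 0] == pytest.approx(1.0)
        assert (s2.prev_alien, s2.prev_key) == (0, 0)

    def test_simulated_choices_track_walk(self):
        config = td.TwoStepConfig(n_trials=300)
        walks = td.build_two_step_walks(config, 9)
        p = TwoStepParams(alpha=0.7, beta=5.0, lam=0.5, pi=0.0, rho=0.0, w=1.0)
        log = agents.simulate_two_step(p, walks, seed=10)
        # a model-based agent with high beta should visit the better alien often
        better = walks.argmax(axis=0)
        hit = (log["alien"].to_numpy() == better).mean()
        assert hit > 0.6
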