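"""Habit-score formulas, questionnaire scoring, and the log pipeline."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from habitlab import scores
from habitlab.scores import (
    bai,
    cohs_scores,
    dgrd_ratio,
    dval_choice_score,
    dval_rt_switch_cost,
    dval_scores,
    htq_scores,
    reward_pairs_choice_score,
    reward_pairs_rating_score,
    reward_pairs_rt_score,
    srhi_score,
    training_effect,
    unrewarded_choice_score,
    unrewarded_rating_score,
    unrewarded_rt_score,
)

prop = st.floats(0.0, 1.0, allow_nan=False)


class TestRewardPairsScores:
    @pytest.mark.parametrize(
        "pairs, expected",
        [
            ([(1.0, 0.0)] * 3, 1.0),
            ([(0.5, 0.5)] * 3, 0.0),
            ([(0.75, 0.25), (0.5, 0.5), (1.0, 0.0)], 0.5),
            ([(0.0, 1.0)] * 3, -1.0),
        ],
    )
    def test_choice_score(self, pairs, expected):
        assert reward_pairs_choice_score(pairs) == pytest.approx(expected)

    def test_choice_score_missing_pair(self):
        assert math.isnan(reward_pairs_choice_score([(0.5, 0.5), (math.nan, 0.5), (1, 0)]))

    @pytest.mark.parametrize(
        "pairs, expected",
        [
            ([(0.8, 0.0)] * 3, 0.8),  # window bound: max score 0.8 s
            ([(0.45, 0.45)] * 3, 0.0),
            ([(0.6, 0.5)] * 3, 0.1),
        ],
    )
    def test_rt_score(self, pairs, expected):
        assert reward_pairs_rt_score(pairs) == pytest.approx(expected)

    @pytest.mark.parametrize(
        "pairs, expected",
        [
            ([(20.0, 0.0)] * 3, 20.0),
            ([(0.0, 0.0)] * 3, 0.0),
            ([(30.0, -10.0), (0.0, 0.0), (10.0, 10.0)], 40.0 / 3),
        ],
    )
    def test_rating_score(self, pairs, expected):
        assert reward_pairs_rating_score(pairs) == pytest.approx(expected)

    @given(p=st.lists(st.tuples(prop, prop), min_size=3, max_size=3))
    @settings(max_examples=50, deadline=None)
    def test_choice_score_antisymmetric_under_swap(self, p):
        swapped = [(b, a) for a, b in p]
        assert reward_pairs_choice_score(p) == pytest.approx(
            -reward_pairs_choice_score(swapped)
        )

    def test_wrong_pair_count_rejected(self):
        with pytest.raises(ValueError):
            reward_pairs_choice_score([(1.0, 0.0)] * 2)


class TestUnrewardedScores:
    def test_examples(self):
        assert unrewarded_choice_score(1.0, 0.0) == 1.0
        assert unrewarded_rt_score(0.4, 0.4) == 0.0
        assert unrewarded_rating_score(10.0, -5.0) == 15.0

    @given(a=prop, b=prop)
    @settings(max_examples=50, deadline=None)
    def test_antisymmetry(self, a, b):
        assert unrewarded_choice_score(a, b) == pytest.approx(
            -unrewarded_choice_score(b, a)
        )


class TestDevaluationScores:
    def test_choice_examples(self):
        assert dval_choice_score(0.0, 1.0) == -1.0  # perfect goal-directed switch
        assert dval_choice_score(0.6, 0.6) == 0.0  # habitual perseveration

    def test_rt_switch_cost(self):
        assert dval_rt_switch_cost(0.55, 0.45) == pytest.approx(0.10)
        assert math.isnan(dval_rt_switch_cost(math.nan, 0.45))

    def test_condition_average(self):
        out = dval_scores(
            high={"p_test": 0.2, "p_train": 1.0, "mdn_switch_test": 0.6, "mdn_train": 0.5},
            low={"p_test": 0.4, "p_train": 0.8, "mdn_switch_test": 0.5, "mdn_train": 0.5},
        )
        assert out["choice_high"] == pytest.approx(-0.8)
        assert out["choice_low"] == pytest.approx(-0.4)
        assert out["choice"] == pytest.approx(-0.6)
        assert out["rt_switch_cost"] == pytest.approx(0.05)


class TestFreeOperantScores:
    def test_bai_examples(self):
        assert bai(2.0, 1.8, 2.0, 1.0) == pytest.approx(0.8)
        assert bai(1.5, 1.5, 2.0, 2.0) == 0.0
        assert bai(2.0, 1.0, 2.0, 1.0) == 0.0  # equal drops: insensitive

    def test_bai_antisymmetric_under_condition_swap(self):
        assert bai(2.0, 1.8, 2.0, 1.0) == -bai(2.0, 1.0, 2.0, 1.8)

    def test_dgrd_examples(self):
        assert dgrd_ratio(2.0, 2.0) == 0.5
        assert dgrd_ratio(0.0, 3.0) == 0.0
        assert dgrd_ratio(3.0, 1.0) == 0.75
        assert math.isnan(dgrd_ratio(0.0, 0.0))
        with pytest.raises(ValueError):
            dgrd_ratio(-1.0, 1.0)

    def test_dgrd_swap_mirrors_around_half(self):
        assert dgrd_ratio(3.0, 1.0) == pytest.approx(1.0 - dgrd_ratio(1.0, 3.0))

    def test_training_effect(self):
        assert training_effect(0.2, 0.6, 2) == pytest.approx(0.2)
        assert training_effect(0.5, 0.5, 2) == 0.0
        assert training_effect(0.2, 0.4, 1) == pytest.approx(0.2)
        assert math.isnan(training_effect(math.nan, 0.4))


class TestQuestionnaires:
    def test_srhi_ceiling(self):
        assert srhi_score(np.full((11, 12), 6)) == 1.0

    def test_srhi_frequency_filter(self):
        responses = np.zeros((11, 12))
        responses[:2, 0] = 6  # only two behaviors pass the frequency filter
        assert math.isnan(srhi_score(responses))

    def test_srhi_three_frequent_behaviors(self):
        responses = np.zeros((11, 12))
        responses[:3, :] = 3  # item sum 36 -> 0.5 each; frequency item = 3
        assert srhi_score(responses) == pytest.approx(0.5)

    def test_srhi_range_check(self):
        bad = np.full((11, 12), 7)
        with pytest.raises(ValueError):
            srhi_score(bad)

    def test_cohs(self):
        assert cohs_scores(np.full(27, 5)) == (5.0, 5.0)
        items = np.ones(27)
        items[:11] = 5  # automaticity items maxed, routine at floor
        assert cohs_scores(items) == (5.0, 1.0)
        with pytest.raises(ValueError):
            cohs_scores(np.ones(20))

    def test_htq(self):
        assert htq_scores(np.full(11, 6)) == (66.0, 24.0, 24.0, 18.0)
        assert htq_scores(np.zeros(11)) == (0.0, 0.0, 0.0, 0.0)
        with pytest.raises(ValueError):
            htq_scores(np.full(11, 6), subscales={"compulsivity": range(11)})


def make_test_log(choices, rts_ms=None, freq="s3f", rare="s3r"):
    """Minimal same-reward-pair test log: one row per choice."""
    rows = []
    for i, chosen in enumerate(choices):
        rows.append(
            {
                "participant_id": "p1",
                "task": "reward_pairs",
                "phase": "test",
                "day": 5,
                "trial_number": i + 1,
                "left_stim": freq if i % 2 == 0 else rare,
                "right_stim": rare if i % 2 == 0 else freq,
                "cue_side": "none",
                "response_window_ms": 800,
                "choice_side": "left" if (i % 2 == 0) == (chosen == freq) else "right",
                "chosen_stim": chosen,
                "outcome_points_left": None,
                "outcome_points_right": None,
                "rt_ms": None if rts_ms is None else rts_ms[i],
                "missed": 0,
            }
        )
    return pd.DataFrame(rows)


class TestLogPipeline:
    def test_choice_proportions_from_log(self):
        frames = []
        for freq, rare in [("s3f", "s3r"), ("s5f", "s5r"), ("s7f", "s7r")]:
            frames.append(make_test_log([freq] * 9 + [rare] * 3, freq=freq, rare=rare))
        log = pd.concat(frames, ignore_index=True)
        out = scores.reward_pairs_scores_from_log(log)
        assert out["choice"] == pytest.approx((0.75 - 0.25))

    def test_rt_medians_discard_fast_trials(self):
        rts = [600, 600, 600, 610, 620, 20, 400, 400, 400, 410, 420, 30]
        choices = ["s3r"] * 6 + ["s3f"] * 6
        log = make_test_log(choices, rts_ms=rts)
        out = scores.reward_pairs_scores_from_log(log)
        # the 20/30 ms trials drop; five RTs remain per cell, medians 600/400 ms
        assert out["pair_medians"][0] == pytest.approx((0.6, 0.4))

    def test_cell_below_min_trials_is_missing(self):
        log = make_test_log(["s3f"] * 10 + ["s3r"] * 2, rts_ms=[400] * 12)
        out = scores.reward_pairs_scores_from_log(log)
        assert math.isnan(out["pair_medians"][0][0])

    def test_scores_survive_csv_roundtrip(self, tmp_path):
        from habitlab import io
        from habitlab.synthetic_cohort import CohortConfig, generate_cohort

        cohort = generate_cohort(CohortConfig(n_participants=2, seed=3, days=1))
        direct = scores.score_cohort(cohort.trial_logs, cohort.ratings)
        io.write_trial_log(cohort.trial_logs, tmp_path / "logs.csv")
        io.write_ratings(cohort.ratings, tmp_path / "ratings.csv")
        back = scores.score_cohort(
            io.read_trial_log(tmp_path / "logs.csv"),
            io.read_ratings(tmp_path / "ratings.csv"),
        )
        pd.testing.assert_frame_equal(direct, back)
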