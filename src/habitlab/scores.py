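"""Per-participant habit scores and questionnaire scoring.

Every score follows a printed formula from the study design:

- Reward Pairs / Unrewarded Habit choice, RT, and rating scores contrast
  the *frequent* and *rare* member of the same-reward (or 80/20) pairs:
  ``p(choose|frequent) - p(choose|rare)``, ``Mdn(RT|rare) -
  Mdn(RT|frequent)`` (seconds), and the differential pre-to-post rating
  change; Reward Pairs averages over its three same-reward pairs.
- Outcome devaluation (announced): ``DVAL choice = p(devalued|test) -
  p(devalued|training)`` and an RT switch cost.
- Outcome devaluation (satiation): the behavioral adaptation index (BAI),
  the differential change in button presses per second for valued vs.
  devalued outcomes.
- Contingency degradation: the ratio of responding in degraded blocks to
  total responding; 0.5 means degradation-insensitive (habitual).
- Training effects: (last-day score - first-day score) / divisor.
- SRHI / COHS / HTQ questionnaire scores.

Missing inputs propagate as ``NaN`` — never as silent zeros.  RT inputs
are seconds inside formulas; trial logs store integer milliseconds and
trials faster than 50 ms are discarded before aggregation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .task_designs import same_reward_pairs

__all__ = [
    "ScoreSet",
    "MIN_RT_S",
    "reward_pairs_choice_score",
    "reward_pairs_rt_score",
    "reward_pairs_rating_score",
    "unrewarded_choice_score",
    "unrewarded_rt_score",
    "unrewarded_rating_score",
    "dval_choice_score",
    "dval_rt_switch_cost",
    "dval_scores",
    "bai",
    "dgrd_ratio",
    "training_effect",
    "srhi_score",
    "cohs_scores",
    "htq_scores",
    "reward_pairs_scores_from_log",
    "unrewarded_scores_from_log",
    "rating_deltas",
    "score_participant",
    "score_cohort",
]

MIN_RT_S = 0.05  # trials faster than 50 ms are discarded
_MIN_CELL_TRIALS = 3  # minimum completed trials for a median RT cell


@dataclass
class ScoreSet:
    """All habit scores of one participant (NaN where not computable)."""

    participant_id: str = ""
    rp_choice: float = math.nan
    rp_rt: float = math.nan
    rp_rating: float = math.nan
    uh_choice: float = math.nan
    uh_rt: float = math.nan
    uh_rating: float = math.nan
    dval_choice: float = math.nan
    dval_rt_switch_cost: float = math.nan
    bai: float = math.nan
    dgrd_ratio: float = math.nan
    rp_choice_training_effect: float = math.nan
    rp_rt_training_effect: float = math.nan
    uh_choice_training_effect: float = math.nan
    uh_rt_training_effect: float = math.nan
    dgrd_training_effect: float = math.nan

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}


def _nan_if_missing(*values: float | None) -> bool:
    return any(v is None or (isinstance(v, float) and math.isnan(v)) for v in values)


def _check_proportion(p: float, name: str) -> None:
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"{name} must be a proportion in [0, 1], got {p}")


# ---------------------------------------------------------------------------
# Formula-level scores


def reward_pairs_choice_score(
    pair_proportions: Sequence[tuple[float, float]],
) -> float:
    """Mean over the three same-reward pairs of p(frequent) - p(rare).

    ``pair_proportions`` holds (p_frequent, p_rare) per pair, computed over
    that pair's test trials.  Range [-1, 1]; positive values mean the
    previously more frequently chosen stimulus is preferred.
    """
    if len(pair_proportions) != 3:
        raise ValueError("expected choice proportions for exactly 3 same-reward pairs")
    diffs = []
    for p_freq, p_rare in pair_proportions:
        if _nan_if_missing(p_freq, p_rare):
            return math.nan
        _check_proportion(p_freq, "p_frequent")
        _check_proportion(p_rare, "p_rare")
        diffs.append(p_freq - p_rare)
    return float(np.mean(diffs))


def reward_pairs_rt_score(pair_medians: Sequence[tuple[float, float]]) -> float:
    """Mean over pairs of Mdn(RT|rare) - Mdn(RT|frequent), in seconds.

    Positive scores mean faster responses when choosing the previously
    frequent stimulus.  With medians confined to the 0.8 s response
    window the score is bounded by +-0.8.
    """
    if len(pair_medians) != 3:
        raise ValueError("expected RT medians for exactly 3 same-reward pairs")
    diffs = []
    for mdn_rare, mdn_freq in pair_medians:
        if _nan_if_missing(mdn_rare, mdn_freq):
            return math.nan
        diffs.append(mdn_rare - mdn_freq)
    return float(np.mean(diffs))


def reward_pairs_rating_score(pair_deltas: Sequence[tuple[float, float]]) -> float:
    """Mean over pairs of the differential post-minus-pre rating change
    (frequent minus rare), on the 0-100 rating scale."""
    if len(pair_deltas) != 3:
        raise ValueError("expected rating changes for exactly 3 same-reward pairs")
    diffs = []
    for d_freq, d_rare in pair_deltas:
        if _nan_if_missing(d_freq, d_rare):
            return math.nan
        diffs.append(d_freq - d_rare)
    return float(np.mean(diffs))


def unrewarded_choice_score(p_frequent: float, p_rare: float) -> float:
    """p(choose frequent) - p(choose rare) over 80/20-pair test trials."""
    if _nan_if_missing(p_frequent, p_rare):
        return math.nan
    _check_proportion(p_frequent, "p_frequent")
    _check_proportion(p_rare, "p_rare")
    return p_frequent - p_rare


def unrewarded_rt_score(mdn_rare: float, mdn_frequent: float) -> float:
    """Mdn(RT|rare) - Mdn(RT|frequent) in seconds for the 80/20 pair."""
    if _nan_if_missing(mdn_rare, mdn_frequent):
        return math.nan
    return mdn_rare - mdn_frequent


def unrewarded_rating_score(delta_frequent: float, delta_rare: float) -> float:
    """Differential pre-to-post rating change, frequent minus rare."""
    if _nan_if_missing(delta_frequent, delta_rare):
        return math.nan
    return delta_frequent - delta_rare


def dval_choice_score(p_test: float, p_train: float) -> float:
    """p(choose devalued|test) - p(choose devalued|final training block).

    -1 is perfect goal-directed switching after devaluation, 0 habitual
    perseveration.
    """
    if _nan_if_missing(p_test, p_train):
        return math.nan
    _check_proportion(p_test, "p_test")
    _check_proportion(p_train, "p_train")
    return p_test - p_train


def dval_rt_switch_cost(mdn_switch_test: float, mdn_train: float) -> float:
    """Mdn(RT|switch to non-devalued, test) - Mdn(RT|to-be-devalued,
    training), in seconds; positive = slower when overriding the habit."""
    if _nan_if_missing(mdn_switch_test, mdn_train):
        return math.nan
    return mdn_switch_test - mdn_train


def dval_scores(
    high: Mapping[str, float], low: Mapping[str, float]
) -> dict[str, float]:
    """Devaluation scores per condition (previously high/low valued
    outcome) and their unweighted average.

    Each condition mapping needs keys ``p_test``, ``p_train``,
    ``mdn_switch_test``, ``mdn_train``.
    """
    out: dict[str, float] = {}
    for name, cond in (("high", high), ("low", low)):
        out[f"choice_{name}"] = dval_choice_score(cond["p_test"], cond["p_train"])
        out[f"rt_{name}"] = dval_rt_switch_cost(
            cond["mdn_switch_test"], cond["mdn_train"]
        )
    out["choice"] = float(np.mean([out["choice_high"], out["choice_low"]]))
    out["rt_switch_cost"] = float(np.mean([out["rt_high"], out["rt_low"]]))
    return out


def bai(
    valued_pre: float, valued_post: float, devalued_pre: float, devalued_post: float
) -> float:
    """Behavioral adaptation index from mean button presses per second.

    ``(valued_post - valued_pre) - (devalued_post - devalued_pre)``; zero
    means devaluation-insensitive (habitual) responding.
    """
    for name, rate in (
        ("valued_pre", valued_pre),
        ("valued_post", valued_post),
        ("devalued_pre", devalued_pre),
        ("devalued_post", devalued_post),
    ):
        if _nan_if_missing(rate):
            return math.nan
        if rate < 0:
            raise ValueError(f"{name} must be a non-negative rate")
    return (valued_post - valued_pre) - (devalued_post - devalued_pre)


def dgrd_ratio(mean_degraded: float, mean_nondegraded: float) -> float:
    """Responding in degraded blocks relative to total responding,
    m_deg / (m_deg + m_nondeg), over the last day's blocks.

    0.5 indicates equal responding (contingency-insensitive, habitual);
    values near 0 indicate sensitivity to degradation.  Both means zero ->
    NaN (undefined).
    """
    if _nan_if_missing(mean_degraded, mean_nondegraded):
        return math.nan
    if mean_degraded < 0 or mean_nondegraded < 0:
        raise ValueError("response means must be non-negative")
    total = mean_degraded + mean_nondegraded
    if total == 0:
        return math.nan
    return mean_degraded / total


def training_effect(first_day: float, last_day: float, divisor: float = 2.0) -> float:
    """(last - first) / divisor; divisor 2 for the choice/RT scores,
    1 for the degradation ratio."""
    if _nan_if_missing(first_day, last_day):
        return math.nan
    return (last_day - first_day) / divisor


# ---------------------------------------------------------------------------
# Questionnaires


def srhi_score(
    responses,
    freq_item: int = 0,
    *,
    freq_threshold: int = 3,
    min_behaviors: int = 3,
) -> float:
    """Self-Report Habit Index over 11 behaviors x 12 items (0-6 scale).

    Each behavior's score is its item sum divided by 72.  Only behaviors
    whose "I do frequently" item (column ``freq_item``) is at least
    ``freq_threshold`` count; fewer than ``min_behaviors`` such behaviors
    yield NaN.  Items must already be recoded so higher = stronger habit.
    """
    arr = np.asarray(responses, dtype=float)
    if arr.shape != (11, 12):
        raise ValueError(f"expected 11 behaviors x 12 items, got {arr.shape}")
    if np.any((arr < 0) | (arr > 6)):
        raise ValueError("SRHI item responses must be on the 0-6 scale")
    frequent = arr[:, freq_item] >= freq_threshold
    if frequent.sum() < min_behaviors:
        return math.nan
    per_behavior = arr[frequent].sum(axis=1) / 72.0
    return float(per_behavior.mean())


def cohs_scores(
    items, automaticity_items: Sequence[int] = tuple(range(11))
) -> tuple[float, float]:
    """Creature of Habit Scale: (automaticity, routine) subscale means.

    27 items on a 1-5 scale; 11 automaticity items (indices given by
    ``automaticity_items``, the published item key), the remaining 16 form
    the routine subscale.  The subscales are not combined.
    """
    arr = np.asarray(items, dtype=float)
    if arr.shape != (27,):
        raise ValueError(f"expected 27 COHS items, got shape {arr.shape}")
    if np.any((arr < 1) | (arr > 5)):
        raise ValueError("COHS item responses must be on the 1-5 scale")
    auto_idx = np.zeros(27, dtype=bool)
    auto_idx[list(automaticity_items)] = True
    if auto_idx.sum() != 11:
        raise ValueError("automaticity subscale must contain 11 items")
    return float(arr[auto_idx].mean()), float(arr[~auto_idx].mean())


def htq_scores(
    items,
    subscales: Mapping[str, Sequence[int]] | None = None,
) -> tuple[float, float, float, float]:
    """Habitual Tendencies Questionnaire: (total, compulsivity, regularity,
    aversion to novelty).

    11 items on a 0-6 scale (novelty items reverse-coded upstream); the
    total is the item sum, the subscales are sums over 4/4/3 items.
    """
    arr = np.asarray(items, dtype=float)
    if arr.shape != (11,):
        raise ValueError(f"expected 11 HTQ items, got shape {arr.shape}")
    if np.any((arr < 0) | (arr > 6)):
        raise ValueError("HTQ item responses must be on the 0-6 scale")
    if subscales is None:
        subscales = {
            "compulsivity": (0, 1, 2, 3),
            "regularity": (4, 5, 6, 7),
            "aversion_to_novelty": (8, 9, 10),
        }
    sizes = sorted(len(v) for v in subscales.values())
    covered = sorted(i for v in subscales.values() for i in v)
    if sizes != [3, 4, 4] or covered != list(range(11)):
        raise ValueError("HTQ subscales must partition the 11 items into 4/4/3")
    total = float(arr.sum())
    comp = float(arr[list(subscales["compulsivity"])].sum())
    reg = float(arr[list(subscales["regularity"])].sum())
    nov = float(arr[list(subscales["aversion_to_novelty"])].sum())
    return total, comp, reg, nov


# ---------------------------------------------------------------------------
# Log-level pipeline


def _completed(log: pd.DataFrame) -> pd.DataFrame:
    missed = pd.to_numeric(log["missed"], errors="coerce").fillna(0).astype(int)
    return log[(missed == 0) & log["chosen_stim"].notna()]


def _median_rt_s(log: pd.DataFrame) -> float:
    """Median RT in seconds over completed trials, discarding RTs < 50 ms;
    NaN below the minimum cell count."""
    rt = pd.to_numeric(log["rt_ms"], errors="coerce").dropna() / 1000.0
    rt = rt[rt >= MIN_RT_S]
    if len(rt) < _MIN_CELL_TRIALS:
        return math.nan
    return float(rt.median())


def _pair_trials(log: pd.DataFrame, a: str, b: str) -> pd.DataFrame:
    return log[
        ((log["left_stim"] == a) & (log["right_stim"] == b))
        | ((log["left_stim"] == b) & (log["right_stim"] == a))
    ]


def reward_pairs_scores_from_log(test_log: pd.DataFrame) -> dict[str, float]:
    """Choice and RT scores from a Reward Pairs test-phase log.

    Choice proportions condition on the same-reward-pair test trials (12
    presentations per pair); RT medians are taken per pair over trials in
    which the frequent vs. the rare member was chosen.
    """
    completed = _completed(test_log)
    proportions, medians = [], []
    for freq, rare in same_reward_pairs():
        trials = _pair_trials(completed, freq, rare)
        if len(trials) == 0:
            proportions.append((math.nan, math.nan))
            medians.append((math.nan, math.nan))
            continue
        p_freq = float((trials["chosen_stim"] == freq).mean())
        proportions.append((p_freq, 1.0 - p_freq))
        medians.append(
            (
                _median_rt_s(trials[trials["chosen_stim"] == rare]),
                _median_rt_s(trials[trials["chosen_stim"] == freq]),
            )
        )
    return {
        "choice": reward_pairs_choice_score(proportions),
        "rt": reward_pairs_rt_score(medians),
        "pair_proportions": proportions,
        "pair_medians": medians,
    }


def unrewarded_scores_from_log(
    test_log: pd.DataFrame, frequent: str = "uA", rare: str = "uB"
) -> dict[str, float]:
    """Choice and RT scores from an Unrewarded Habit test-phase log.

    Uses all test trials presenting the 80/20 pair, regardless of
    presentation location.
    """
    completed = _completed(test_log)
    trials = _pair_trials(completed, frequent, rare)
    if len(trials) == 0:
        return {"choice": math.nan, "rt": math.nan}
    p_freq = float((trials["chosen_stim"] == frequent).mean())
    return {
        "choice": unrewarded_choice_score(p_freq, 1.0 - p_freq),
        "rt": unrewarded_rt_score(
            _median_rt_s(trials[trials["chosen_stim"] == rare]),
            _median_rt_s(trials[trials["chosen_stim"] == frequent]),
        ),
    }


def rating_deltas(ratings: pd.DataFrame) -> dict[str, float]:
    """Post-minus-pre rating change per stimulus, averaging duplicate
    ratings within each timepoint."""
    means = (
        ratings.groupby(["stimulus", "timepoint"])["rating"].mean().unstack()
    )
    out = {}
    for stim, row in means.iterrows():
        pre = row.get("pre", math.nan)
        post = row.get("post", math.nan)
        out[stim] = float(post - pre)
    return out


def _rating_scores(ratings: pd.DataFrame | None) -> tuple[float, float]:
    if ratings is None or len(ratings) == 0:
        return math.nan, math.nan
    deltas = rating_deltas(ratings)
    rp_pairs = [
        (deltas.get(freq, math.nan), deltas.get(rare, math.nan))
        for freq, rare in same_reward_pairs()
    ]
    rp = reward_pairs_rating_score(rp_pairs)
    uh = unrewarded_rating_score(
        deltas.get("uA", math.nan), deltas.get("uB", math.nan)
    )
    return rp, uh


def score_participant(
    trial_logs: pd.DataFrame, ratings: pd.DataFrame | None = None
) -> ScoreSet:
    """Compute a participant's ScoreSet from their trial logs (and
    optionally ratings).

    Test phases on day 1 (pre-training) and the final day feed the
    training-effect scores; devaluation and degradation scores require
    aggregate inputs not present in trial logs and stay NaN here.
    """
    pid = ""
    ids = trial_logs["participant_id"].dropna().unique()
    if len(ids) == 1:
        pid = str(ids[0])
    out = ScoreSet(participant_id=pid)

    def task_test(task: str, day_filter) -> pd.DataFrame:
        mask = (trial_logs["task"] == task) & (trial_logs["phase"] == "test")
        sub = trial_logs[mask]
        days = pd.to_numeric(sub["day"], errors="coerce")
        return sub[day_filter(days)]

    rp_final = task_test("reward_pairs", lambda d: d == d.max())
    if len(rp_final):
        s = reward_pairs_scores_from_log(rp_final)
        out.rp_choice, out.rp_rt = s["choice"], s["rt"]
    rp_first = task_test("reward_pairs", lambda d: d == 1)
    if len(rp_first) and not rp_first.equals(rp_final):
        s1 = reward_pairs_scores_from_log(rp_first)
        out.rp_choice_training_effect = training_effect(s1["choice"], out.rp_choice)
        out.rp_rt_training_effect = training_effect(s1["rt"], out.rp_rt)

    uh_final = task_test("unrewarded_habit", lambda d: d == d.max())
    if len(uh_final):
        s = unrewarded_scores_from_log(uh_final)
        out.uh_choice, out.uh_rt = s["choice"], s["rt"]
    uh_first = task_test("unrewarded_habit", lambda d: d == 1)
    if len(uh_first) and not uh_first.equals(uh_final):
        s1 = unrewarded_scores_from_log(uh_first)
        out.uh_choice_training_effect = training_effect(s1["choice"], out.uh_choice)
        out.uh_rt_training_effect = training_effect(s1["rt"], out.uh_rt)

    out.rp_rating, out.uh_rating = _rating_scores(ratings)
    return out


def score_cohort(
    trial_logs: pd.DataFrame, ratings: pd.DataFrame | None = None
) -> pd.DataFrame:
    """One ScoreSet row per participant."""
    rows = []
    for pid, logs in trial_logs.groupby("participant_id", sort=True):
        sub_ratings = None
        if ratings is not None and len(ratings):
            sub_ratings = ratings[ratings["participant_id"] == pid]
        rows.append(score_participant(logs, sub_ratings).to_dict())
    return pd.DataFrame(rows)
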