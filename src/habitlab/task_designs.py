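"""Seeded trial-schedule generators for the habit tasks.

Three bespoke paradigms are covered:

Reward Pairs
    Eight stimuli with deterministic rewards drawn from {1, 3, 3, 5, 5, 7,
    7, 9} points.  At each of the intermediate reward levels (3, 5, 7) one
    stimulus is *frequent* (paired mostly with a less valuable partner, so a
    reward maximizer chooses it often) and one is *rare* (the reverse).
    Training runs on five days with 160 trials per session; the test phase
    presents every pair of stimuli, including — for the first time — the
    same-reward pairs.

Unrewarded Habit
    Two stimulus pairs, no rewards.  During training a cue instructs which
    stimulus to select: 80/20 within one pair, 50/50 within the other.
    Five sessions of 240 trials yield 600 training trials per pair.  The
    test phase allows free choice among all stimulus combinations.

Two-step task
    Two equivalent initial states, each offering two spaceships that fly
    deterministically to one of two aliens.  Alien payoffs follow an
    integer Gaussian random walk with reflecting boundaries.

All generators are pure functions of their seed: the multiset of trial
types is fixed by the design and only the ordering (and tie-breaking side
assignments) is randomized.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Stimulus",
    "TrialSpec",
    "TwoStepConfig",
    "REWARD_PAIRS_WINDOW_MS",
    "UNREWARDED_WINDOW_MS",
    "reward_pairs_stimuli",
    "reward_pairs_reward_map",
    "same_reward_pairs",
    "unrewarded_stimuli",
    "build_reward_pairs_training_session",
    "build_reward_pairs_test",
    "build_unrewarded_training_session",
    "build_unrewarded_test",
    "build_two_step_walks",
    "schedule_to_frame",
]

REWARD_PAIRS_WINDOW_MS = 800
UNREWARDED_WINDOW_MS = 500

TRAINING_DAYS = (1, 2, 3, 4, 5)


@dataclass(frozen=True)
class Stimulus:
    """One choice option.

    ``reward_value`` is the deterministic number of points the stimulus
    yields (absent for the Unrewarded Habit task).  ``role`` encodes the
    design cell: ``extreme``/``frequent``/``rare`` for Reward Pairs,
    ``freq80``/``rare20``/``even50a``/``even50b`` for Unrewarded Habit.
    ``fixed_side`` is set only for Unrewarded Habit stimuli, whose screen
    position is constant within a participant.
    """

    id: str
    reward_value: int | None = None
    role: str = ""
    fixed_side: str | None = None


@dataclass
class TrialSpec:
    """One scheduled trial.

    ``cue_side`` is ``"none"`` except during Unrewarded Habit training,
    where it points at the instructed stimulus.  ``segment`` is an internal
    tag for the composition of test phases (e.g. ``"switched"`` for
    switched-location trials); it is not part of the on-disk schema.
    """

    index: int
    phase: str
    day: int
    left: str
    right: str
    cue_side: str = "none"
    response_window_ms: int = REWARD_PAIRS_WINDOW_MS
    segment: str = ""

    def pair(self) -> frozenset[str]:
        return frozenset((self.left, self.right))


@dataclass(frozen=True)
class TwoStepConfig:
    """Structure of the sequential Markov decision task.

    Spaceships are indexed 0..3 (A, B in initial state 0; C, D in state 1).
    A and C fly to alien 0, B and D to alien 1, making the two initial
    states equivalent under the transition model.
    """

    n_trials: int = 200
    walk_sd: float = 2.0
    walk_min: int = -4
    walk_max: int = 5
    transition: Mapping[tuple[int, int], int] = field(
        default_factory=lambda: {(0, 0): 0, (0, 1): 1, (1, 2): 0, (1, 3): 1}
    )


# ---------------------------------------------------------------------------
# Stimulus sets


def reward_pairs_stimuli() -> list[Stimulus]:
    """The eight Reward Pairs stimuli with reward multiset {1,3,3,5,5,7,7,9}."""
    return [
        Stimulus("s1", 1, "extreme"),
        Stimulus("s3f", 3, "frequent"),
        Stimulus("s3r", 3, "rare"),
        Stimulus("s5f", 5, "frequent"),
        Stimulus("s5r", 5, "rare"),
        Stimulus("s7f", 7, "frequent"),
        Stimulus("s7r", 7, "rare"),
        Stimulus("s9", 9, "extreme"),
    ]


def reward_pairs_reward_map() -> dict[str, int]:
    return {s.id: s.reward_value for s in reward_pairs_stimuli()}


def same_reward_pairs() -> list[tuple[str, str]]:
    """(frequent, rare) stimulus ids of the three same-reward pairs."""
    return [("s3f", "s3r"), ("s5f", "s5r"), ("s7f", "s7r")]


def unrewarded_stimuli(sides: Mapping[str, str] | None = None) -> list[Stimulus]:
    """The four Unrewarded Habit stimuli with fixed screen sides.

    ``sides`` maps stimulus id to ``"left"``/``"right"``; within a pair the
    two stimuli must sit on opposite sides.  Defaults to a canonical
    assignment (varied across participants in a real study).
    """
    default = {"uA": "left", "uB": "right", "uC": "left", "uD": "right"}
    sides = dict(default if sides is None else sides)
    for a, b in (("uA", "uB"), ("uC", "uD")):
        if sides[a] == sides[b]:
            raise ValueError(f"stimuli {a} and {b} must occupy opposite sides")
    return [
        Stimulus("uA", None, "freq80", sides["uA"]),
        Stimulus("uB", None, "rare20", sides["uB"]),
        Stimulus("uC", None, "even50a", sides["uC"]),
        Stimulus("uD", None, "even50b", sides["uD"]),
    ]


# Training pairings: (stimulus a, stimulus b, trials per session).  Each
# frequent stimulus meets its value-2 neighbor 30 times and its value+2
# neighbor 10 times; rare stimuli the reverse.  Row/column sums give every
# stimulus exactly 40 appearances and session earnings between 640
# (always choosing the lower value) and 960 (always the higher value).
_RP_TRAINING_PAIRS: list[tuple[str, str, int]] = [
    ("s1", "s3f", 30),
    ("s1", "s3r", 10),
    ("s3f", "s5r", 10),
    ("s3r", "s5f", 30),
    ("s5f", "s7r", 10),
    ("s5r", "s7f", 30),
    ("s7f", "s9", 10),
    ("s7r", "s9", 30),
]


def _rng(seed: int, *stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), *stream]))


def _sided_trials(
    a: str, b: str, count: int, rng: np.random.Generator
) -> list[tuple[str, str]]:
    """``count`` (left, right) tuples with each orientation count//2 times;
    an odd remainder is assigned by a seeded coin flip."""
    half = count // 2
    trials = [(a, b)] * half + [(b, a)] * half
    if count % 2:
        trials.append((a, b) if rng.random() < 0.5 else (b, a))
    return trials


def _finalize(
    sided: list[tuple[str, str, str]],
    rng: np.random.Generator,
    phase: str,
    day: int,
    window_ms: int,
    shuffle: bool = True,
) -> list[TrialSpec]:
    if shuffle:
        order = rng.permutation(len(sided))
        sided = [sided[i] for i in order]
    return [
        TrialSpec(
            index=i,
            phase=phase,
            day=day,
            left=left,
            right=right,
            response_window_ms=window_ms,
            segment=seg,
        )
        for i, (left, right, seg) in enumerate(sided)
    ]


# ---------------------------------------------------------------------------
# Reward Pairs


def build_reward_pairs_training_session(day: int, seed: int) -> list[TrialSpec]:
    """One 160-trial Reward Pairs training session.

    The unordered-pair multiset is fixed by the design (see
    ``_RP_TRAINING_PAIRS``); ordering and left/right assignment are the only
    seed-dependent choices.  Each stimulus appears on each side on exactly
    half of its trials.
    """
    if day not in TRAINING_DAYS:
        raise ValueError(f"day must be in {TRAINING_DAYS}, got {day!r}")
    rng = _rng(seed, 1, day)
    sided = [
        (left, right, "")
        for a, b, count in _RP_TRAINING_PAIRS
        for left, right in _sided_trials(a, b, count, rng)
    ]
    return _finalize(sided, rng, "training", day, REWARD_PAIRS_WINDOW_MS)


def build_reward_pairs_test(seed: int, day: int = 5) -> list[TrialSpec]:
    """The 136-trial Reward Pairs test phase.

    Every one of the C(8,2)=28 unordered stimulus pairs appears four times;
    the three same-reward pairs get eight additional trials each (12 total).
    No outcomes are shown during test, so the schedule carries no rewards.
    ``day=1`` generates the pre-training baseline test phase.
    """
    rng = _rng(seed, 2, day)
    ids = [s.id for s in reward_pairs_stimuli()]
    extra = {frozenset(p) for p in same_reward_pairs()}
    sided: list[tuple[str, str, str]] = []
    for i, a in enumerate(ids):
        for b in ids[i + 1 :]:
            count = 12 if frozenset((a, b)) in extra else 4
            seg = "same_reward" if frozenset((a, b)) in extra else ""
            sided.extend((l, r, seg) for l, r in _sided_trials(a, b, count, rng))
    return _finalize(sided, rng, "test", day, REWARD_PAIRS_WINDOW_MS)


# ---------------------------------------------------------------------------
# Unrewarded Habit

_UH_PAIRS = (("uA", "uB"), ("uC", "uD"))
_UH_CUE_COUNTS = {("uA", "uB"): (16, 4), ("uC", "uD"): (10, 10)}  # per 20-trial block


def _uh_sides(sides: Mapping[str, str] | None) -> dict[str, str]:
    return {s.id: s.fixed_side for s in unrewarded_stimuli(sides)}


def build_unrewarded_training_session(
    day: int, seed: int, sides: Mapping[str, str] | None = None
) -> list[TrialSpec]:
    """One 240-trial Unrewarded Habit training session.

    Six 20-trial blocks per pair, blocks alternating between the pairs
    (starting pair seeded).  Within each 80/20-pair block the cue points at
    the frequent stimulus on 16 of 20 trials; within each even-pair block
    on 10 of 20.  Stimulus sides are fixed within a participant.
    """
    if day not in TRAINING_DAYS:
        raise ValueError(f"day must be in {TRAINING_DAYS}, got {day!r}")
    rng = _rng(seed, 3, day)
    side_of = _uh_sides(sides)

    first = int(rng.integers(2))
    block_pairs = [_UH_PAIRS[(first + i) % 2] for i in range(12)]
    sided: list[tuple[str, str, str]] = []
    for a, b in block_pairs:
        n_a, n_b = _UH_CUE_COUNTS[(a, b)]
        cued = [a] * n_a + [b] * n_b
        rng.shuffle(cued)
        left, right = (a, b) if side_of[a] == "left" else (b, a)
        sided.extend((left, right, c) for c in cued)

    trials = _finalize(
        sided, rng, "training", day, UNREWARDED_WINDOW_MS, shuffle=False
    )
    for t in trials:
        t.cue_side = "left" if side_of[t.segment] == "left" else "right"
        t.segment = ""
    return trials


def build_unrewarded_test(
    seed: int, sides: Mapping[str, str] | None = None, day: int = 5
) -> list[TrialSpec]:
    """The 64-trial Unrewarded Habit test phase.

    Composition: 10 trials of each trained pair in trained locations first
    (segment ``"initial"``); then each of the four stimuli paired with each
    other four times with balanced locations (24 trials, segment
    ``"all_pairs"``) randomly interleaved with 10 switched-location trials
    of each trained pair (segment ``"switched"``).
    """
    rng = _rng(seed, 4, day)
    side_of = _uh_sides(sides)

    def trained(a: str, b: str) -> tuple[str, str]:
        return (a, b) if side_of[a] == "left" else (b, a)

    def switched(a: str, b: str) -> tuple[str, str]:
        l, r = trained(a, b)
        return (r, l)

    initial = [(*trained(a, b), "initial") for a, b in _UH_PAIRS for _ in range(10)]
    rng.shuffle(initial)

    mixed: list[tuple[str, str, str]] = []
    ids = [s.id for s in unrewarded_stimuli(sides)]
    for i, a in enumerate(ids):
        for b in ids[i + 1 :]:
            mixed.extend((l, r, "all_pairs") for l, r in _sided_trials(a, b, 4, rng))
    mixed.extend((*switched(a, b), "switched") for a, b in _UH_PAIRS for _ in range(10))
    rng.shuffle(mixed)

    return _finalize(
        initial + mixed, rng, "test", day, UNREWARDED_WINDOW_MS, shuffle=False
    )


# ---------------------------------------------------------------------------
# Two-step random walks


def build_two_step_walks(config: TwoStepConfig, seed: int) -> np.ndarray:
    """Integer payoff sequences for the two aliens, shape ``(2, n_trials)``.

    Each walk starts at 0 and adds mean-zero Gaussian steps (sd
    ``walk_sd``); excursions beyond ``[walk_min, walk_max]`` are reflected
    back into range, and the emitted values are rounded to integers.
    """
    if config.n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    rng = _rng(seed, 5)
    lo, hi = float(config.walk_min), float(config.walk_max)
    steps = rng.normal(0.0, config.walk_sd, size=(2, config.n_trials))
    walks = np.empty((2, config.n_trials), dtype=np.int64)
    for alien in range(2):
        x = 0.0
        for t in range(config.n_trials):
            x += steps[alien, t]
            while x < lo or x > hi:
                if x > hi:
                    x = 2 * hi - x
                if x < lo:
                    x = 2 * lo - x
            walks[alien, t] = int(np.rint(x))
    return walks


# ---------------------------------------------------------------------------
# Export


def schedule_to_frame(
    trials: Sequence[TrialSpec], participant_id: str = "", task: str = ""
) -> pd.DataFrame:
    """Render a schedule in the trial-log CSV schema (response columns empty).

    Trial indices are 0-based internally and exported 1-based in the
    ``trial_number`` column.
    """
    from .io import TRIAL_LOG_COLUMNS

    rows = [
        {
            "participant_id": participant_id,
            "task": task,
            "phase": t.phase,
            "day": t.day,
            "trial_number": t.index + 1,
            "left_stim": t.left,
            "right_stim": t.right,
            "cue_side": t.cue_side,
            "response_window_ms": t.response_window_ms,
        }
        for t in trials
    ]
    frame = pd.DataFrame(rows)
    for col in TRIAL_LOG_COLUMNS:
        if col not in frame.columns:
            frame[col] = pd.NA
    return frame[TRIAL_LOG_COLUMNS]
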