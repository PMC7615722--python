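"""Generative choice models for the habit tasks.

Two model families are implemented:

1.  Binary-choice learners for the Reward Pairs / Unrewarded Habit tasks,
    combining a delta-rule Q-learner over stimulus values with a *choice
    kernel* (CK) that tracks recent choice frequency:

    .. math::

        Q_s \\leftarrow Q_s + \\alpha_q (r_s - Q_s), \\qquad
        CK_s \\leftarrow CK_s + \\alpha_h (\\mathbb{1}[s\\text{ chosen}] - CK_s)

    with a logistic choice rule
    ``P(left) = sigmoid(beta_q (Q_L - Q_R) + beta_h (CK_L - CK_R))``.
    Rewards are rescaled to [0, 1] by dividing points by 9 so that Q and CK
    share a scale; under the reduced model's constraint ``beta_q = 10 -
    beta_h`` a value of ``beta_h = 5`` then weights the two systems
    equally.  Candidate models: ``random`` (P = 0.5, no parameters),
    ``rl`` (Q only), ``ck`` (kernel only), ``rl_ck`` (both, four free
    parameters), and ``rl_ck_reduced`` (both, with the tied temperatures).

2.  The hybrid model-based/model-free learner for the two-step task, with
    learning rate ``alpha``, inverse temperature ``beta``, eligibility
    trace ``lam``, target-perseveration weight ``pi``, response-key
    stickiness ``rho``, and model-based weight ``w``.  The habit measure
    reported from fits is ``1 - w`` (larger = more model-free).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .task_designs import TrialSpec, TwoStepConfig

__all__ = [
    "MODEL_IDS",
    "FREE_PARAMS",
    "ModelParams",
    "RLState",
    "TwoStepParams",
    "TwoStepState",
    "choice_probability",
    "rl_update",
    "ck_update",
    "simulate_task",
    "simulate_unrewarded_training",
    "two_step_probability",
    "two_step_update",
    "two_step_hybrid_step",
    "simulate_two_step",
    "habit_weight",
    "REWARD_SCALE",
]

MODEL_IDS = ("random", "rl", "ck", "rl_ck", "rl_ck_reduced")

#: Free parameters of each candidate model, in canonical order.
FREE_PARAMS: dict[str, tuple[str, ...]] = {
    "random": (),
    "rl": ("alpha_q", "beta_q"),
    "ck": ("alpha_h", "beta_h"),
    "rl_ck": ("alpha_q", "beta_q", "alpha_h", "beta_h"),
    "rl_ck_reduced": ("alpha_q", "alpha_h", "beta_h"),
}

#: Points are divided by this to bring rewards onto the [0, 1] scale of CK.
REWARD_SCALE = 9.0

_BETA_SUM = 10.0  # reduced model: beta_q + beta_h = 10


def _check_unit(name: str, value: float) -> None:
    if not 0.0 <= value <= 1.0:
        raise ValueError(f"{name} must be in [0, 1], got {value}")


@dataclass(frozen=True)
class ModelParams:
    """Parameters of one binary-choice model.

    Unused parameters of the chosen ``model_id`` may be left ``None``.
    For ``rl_ck_reduced``, ``beta_q`` is not free: it is derived as
    ``10 - beta_h`` and must not be supplied.
    """

    model_id: str
    alpha_q: float | None = None
    beta_q: float | None = None
    alpha_h: float | None = None
    beta_h: float | None = None

    def __post_init__(self) -> None:
        if self.model_id not in MODEL_IDS:
            raise ValueError(f"unknown model_id {self.model_id!r}")
        if self.model_id == "rl_ck_reduced" and self.beta_q is not None:
            raise ValueError("beta_q is tied to 10 - beta_h in the reduced model")
        for name in FREE_PARAMS[self.model_id]:
            value = getattr(self, name)
            if value is None:
                raise ValueError(f"model {self.model_id!r} requires {name}")
            if name.startswith("alpha"):
                _check_unit(name, value)
            elif not 0.0 <= value <= _BETA_SUM:
                raise ValueError(f"{name} must be in [0, 10], got {value}")

    @property
    def effective_beta_q(self) -> float:
        """Weight on the Q-value difference in the choice rule."""
        if self.model_id in ("random", "ck"):
            return 0.0
        if self.model_id == "rl_ck_reduced":
            return _BETA_SUM - self.beta_h
        return float(self.beta_q)

    @property
    def effective_beta_h(self) -> float:
        """Weight on the choice-kernel difference in the choice rule."""
        if self.model_id in ("random", "rl"):
            return 0.0
        return float(self.beta_h)

    def free_values(self) -> dict[str, float]:
        return {name: float(getattr(self, name)) for name in FREE_PARAMS[self.model_id]}


@dataclass
class RLState:
    """Learned values: ``q`` from outcomes, ``ck`` from choice frequency."""

    q: dict[str, float]
    ck: dict[str, float]

    @classmethod
    def initial(
        cls, stimuli: Sequence[str], q0: float = 0.5, ck0: float = 0.5
    ) -> "RLState":
        return cls(q={s: q0 for s in stimuli}, ck={s: ck0 for s in stimuli})

    def copy(self) -> "RLState":
        return RLState(q=dict(self.q), ck=dict(self.ck))


def choice_probability(
    state: RLState, params: ModelParams, left: str, right: str
) -> float:
    """Probability of choosing the left stimulus under the logistic rule."""
    for s in (left, right):
        if s not in state.q or s not in state.ck:
            raise KeyError(f"unknown stimulus {s!r}")
    if params.model_id == "random":
        return 0.5
    x = params.effective_beta_q * (state.q[left] - state.q[right])
    x += params.effective_beta_h * (state.ck[left] - state.ck[right])
    if x >= 0:
        return 1.0 / (1.0 + math.exp(-x))
    ex = math.exp(x)
    return ex / (1.0 + ex)


def rl_update(
    state: RLState,
    chosen: str,
    unchosen: str,
    r_chosen: float,
    r_unchosen: float,
    alpha_q: float,
    feedback: str = "both",
) -> RLState:
    """Delta-rule update of Q-values from rescaled rewards in [0, 1].

    ``feedback`` selects which stimuli are updated: ``"both"`` (training,
    where both outcomes are displayed), ``"chosen_only"``, or ``"none"``
    (test phase, outcomes hidden).  Returns a new state.
    """
    _check_unit("alpha_q", alpha_q)
    new = state.copy()
    if feedback == "both":
        new.q[chosen] += alpha_q * (r_chosen - new.q[chosen])
        new.q[unchosen] += alpha_q * (r_unchosen - new.q[unchosen])
    elif feedback == "chosen_only":
        new.q[chosen] += alpha_q * (r_chosen - new.q[chosen])
    elif feedback != "none":
        raise ValueError(f"unknown feedback mode {feedback!r}")
    return new


def ck_update(state: RLState, chosen: str, unchosen: str, alpha_h: float) -> RLState:
    """Choice-kernel update: chosen moves toward 1, unchosen toward 0.

    Applied on every completed trial of both training and test phases —
    choosing happens even when outcomes are hidden.  Stimuli not on screen
    keep their kernel values.
    """
    _check_unit("alpha_h", alpha_h)
    new = state.copy()
    new.ck[chosen] += alpha_h * (1.0 - new.ck[chosen])
    new.ck[unchosen] += alpha_h * (0.0 - new.ck[unchosen])
    return new


def _log_row(
    trial: TrialSpec,
    participant_id: str,
    task: str,
) -> dict:
    return {
        "participant_id": participant_id,
        "task": task,
        "phase": trial.phase,
        "day": trial.day,
        "trial_number": trial.index + 1,
        "left_stim": trial.left,
        "right_stim": trial.right,
        "cue_side": trial.cue_side,
        "response_window_ms": trial.response_window_ms,
        "choice_side": None,
        "chosen_stim": None,
        "outcome_points_left": None,
        "outcome_points_right": None,
        "rt_ms": None,
        "missed": 0,
    }


def simulate_task(
    params: ModelParams,
    schedule: Sequence[TrialSpec],
    reward_map: Mapping[str, int] | None = None,
    seed: int = 0,
    *,
    state: RLState | None = None,
    feedback: str = "both",
    q0: float = 0.5,
    ck0: float = 0.5,
    participant_id: str = "sim",
    task: str = "reward_pairs",
) -> tuple[pd.DataFrame, RLState]:
    """Sample choices for a schedule and return (log, final state).

    Training trials deliver the rewards from ``reward_map`` and update Q
    according to ``feedback``; test trials show no outcomes (no Q update).
    The choice kernel updates on every completed trial.  The returned log
    follows the trial-log schema plus two diagnostic columns ``q_diff``
    and ``ck_diff`` (chosen minus unchosen, before the update) used by the
    synthetic response-time model; they are dropped on export.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 11]))
    stimuli = sorted({t.left for t in schedule} | {t.right for t in schedule})
    if state is None:
        state = RLState.initial(stimuli, q0=q0, ck0=ck0)
    else:
        state = state.copy()
        missing = [s for s in stimuli if s not in state.q]
        if missing:
            raise ValueError(f"state lacks stimuli {missing}")
    if reward_map is not None:
        missing = [s for s in stimuli if s not in reward_map]
        if missing:
            raise ValueError(f"reward_map lacks stimuli {missing}")

    rows = []
    for trial in schedule:
        row = _log_row(trial, participant_id, task)
        p_left = choice_probability(state, params, trial.left, trial.right)
        choose_left = rng.random() < p_left
        chosen, unchosen = (
            (trial.left, trial.right) if choose_left else (trial.right, trial.left)
        )
        row["choice_side"] = "left" if choose_left else "right"
        row["chosen_stim"] = chosen
        row["q_diff"] = state.q[chosen] - state.q[unchosen]
        row["ck_diff"] = state.ck[chosen] - state.ck[unchosen]

        training = trial.phase == "training" and reward_map is not None
        if training:
            row["outcome_points_left"] = reward_map[trial.left]
            row["outcome_points_right"] = reward_map[trial.right]
        state = ck_update(state, chosen, unchosen, params.alpha_h or 0.0)
        if training and params.alpha_q is not None:
            state = rl_update(
                state,
                chosen,
                unchosen,
                reward_map[chosen] / REWARD_SCALE,
                reward_map[unchosen] / REWARD_SCALE,
                params.alpha_q,
                feedback=feedback,
            )
        rows.append(row)
    return pd.DataFrame(rows), state


def simulate_unrewarded_training(
    compliance: float,
    schedule: Sequence[TrialSpec],
    seed: int = 0,
    *,
    alpha_h: float = 0.2,
    miss_prob: float = 0.0,
    state: RLState | None = None,
    participant_id: str = "sim",
) -> tuple[pd.DataFrame, RLState]:
    """Simulate instructed-choice training: cued stimulus chosen with
    probability ``compliance``; missed trials leave choice fields empty and
    trigger no kernel update."""
    if not 0.5 <= compliance <= 1.0:
        raise ValueError("compliance must be in [0.5, 1]")
    if not 0.0 <= miss_prob < 0.5:
        raise ValueError("miss_prob must be in [0, 0.5)")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 12]))
    stimuli = sorted({t.left for t in schedule} | {t.right for t in schedule})
    state = RLState.initial(stimuli) if state is None else state.copy()

    rows = []
    for trial in schedule:
        row = _log_row(trial, participant_id, "unrewarded_habit")
        if rng.random() < miss_prob:
            row["missed"] = 1
            rows.append(row)
            continue
        cued = trial.left if trial.cue_side == "left" else trial.right
        other = trial.right if trial.cue_side == "left" else trial.left
        chosen, unchosen = (cued, other) if rng.random() < compliance else (other, cued)
        row["choice_side"] = "left" if chosen == trial.left else "right"
        row["chosen_stim"] = chosen
        row["q_diff"] = 0.0
        row["ck_diff"] = state.ck[chosen] - state.ck[unchosen]
        state = ck_update(state, chosen, unchosen, alpha_h)
        rows.append(row)
    return pd.DataFrame(rows), state


# ---------------------------------------------------------------------------
# Two-step hybrid learner


@dataclass(frozen=True)
class TwoStepParams:
    """Free parameters of the hybrid model-based/model-free learner."""

    alpha: float
    beta: float
    lam: float
    pi: float
    rho: float
    w: float

    def __post_init__(self) -> None:
        _check_unit("alpha", self.alpha)
        _check_unit("lam", self.lam)
        _check_unit("w", self.w)
        if self.beta < 0:
            raise ValueError("beta must be >= 0")


def habit_weight(w: float) -> float:
    """Reported habit measure: the inverted model-based weight, ``1 - w``."""
    _check_unit("w", w)
    return 1.0 - w


@dataclass
class TwoStepState:
    """Cached values for the hybrid learner.

    ``q_mf[s, a]`` is the model-free value of ship ``a`` (0 = first ship of
    the state) in initial state ``s``; ``v[alien]`` the second-stage value.
    ``prev_alien``/``prev_key`` feed the perseveration and key-stickiness
    terms (-1 before the first choice).
    """

    q_mf: np.ndarray = field(default_factory=lambda: np.zeros((2, 2)))
    v: np.ndarray = field(default_factory=lambda: np.zeros(2))
    prev_alien: int = -1
    prev_key: int = -1

    def copy(self) -> "TwoStepState":
        return TwoStepState(self.q_mf.copy(), self.v.copy(), self.prev_alien, self.prev_key)


def _ship_alien(ship: int) -> int:
    # ships A, C (0, 2) -> alien 0; B, D (1, 3) -> alien 1
    return ship % 2


def two_step_probability(
    params: TwoStepParams,
    state: TwoStepState,
    start_state: int,
    left_ship: int,
    right_ship: int,
) -> float:
    """P(choose the left ship).

    The net value is ``w * Q_mb + (1 - w) * Q_mf`` with ``Q_mb(s, a) =
    V(alien reached by a)``; the logit adds ``pi`` for repeating the
    previously visited alien and ``rho`` for repeating the previous
    response key (left = key 0, right = key 1).
    """

    def logit(ship: int, key: int) -> float:
        a = ship - 2 * start_state
        q_mb = state.v[_ship_alien(ship)]
        q_net = params.w * q_mb + (1.0 - params.w) * state.q_mf[start_state, a]
        x = params.beta * q_net
        if state.prev_alien >= 0 and _ship_alien(ship) == state.prev_alien:
            x += params.pi
        if state.prev_key >= 0 and key == state.prev_key:
            x += params.rho
        return x

    d = logit(left_ship, 0) - logit(right_ship, 1)
    if d >= 0:
        return 1.0 / (1.0 + math.exp(-d))
    ed = math.exp(d)
    return ed / (1.0 + ed)


def two_step_update(
    params: TwoStepParams,
    state: TwoStepState,
    start_state: int,
    ship: int,
    key: int,
    reward: float,
) -> TwoStepState:
    """SARSA(lambda) update after observing the alien's payoff."""
    new = state.copy()
    a = ship - 2 * start_state
    alien = _ship_alien(ship)
    delta1 = new.v[alien] - new.q_mf[start_state, a]
    new.q_mf[start_state, a] += params.alpha * delta1
    delta2 = reward - new.v[alien]
    new.v[alien] += params.alpha * delta2
    new.q_mf[start_state, a] += params.alpha * params.lam * delta2
    new.prev_alien = alien
    new.prev_key = key
    return new


def two_step_hybrid_step(
    params: TwoStepParams,
    state: TwoStepState,
    trial: Mapping[str, int | float],
    rng: np.random.Generator | None = None,
) -> tuple[int, TwoStepState]:
    """Sample one choice and apply the update.

    ``trial`` needs ``start_state``, ``left_ship``, ``right_ship`` and
    ``reward`` (the payoff of whichever alien is reached; with the
    deterministic transitions both ships' payoffs are known, so ``reward``
    may be a mapping alien -> points).  Returns (chosen ship, new state).
    """
    rng = np.random.default_rng() if rng is None else rng
    s = int(trial["start_state"])
    left, right = int(trial["left_ship"]), int(trial["right_ship"])
    p_left = two_step_probability(params, state, s, left, right)
    choose_left = rng.random() < p_left
    ship = left if choose_left else right
    key = 0 if choose_left else 1
    reward = trial["reward"]
    if isinstance(reward, Mapping):
        reward = reward[_ship_alien(ship)]
    state = two_step_update(params, state, s, ship, key, float(reward))
    return ship, state


def simulate_two_step(
    params: TwoStepParams,
    walks: np.ndarray,
    seed: int = 0,
    *,
    participant_id: str = "sim",
) -> pd.DataFrame:
    """Simulate a full two-step session against pre-generated alien walks.

    The initial state of each trial is drawn uniformly, as is the screen
    side of each ship.  Returns a log in the two-step CSV schema.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 13]))
    n_trials = walks.shape[1]
    state = TwoStepState()
    rows = []
    for t in range(n_trials):
        s = int(rng.integers(2))
        ships = [2 * s, 2 * s + 1]
        if rng.random() < 0.5:
            ships.reverse()
        left, right = ships
        p_left = two_step_probability(params, state, s, left, right)
        choose_left = rng.random() < p_left
        ship = left if choose_left else right
        alien = _ship_alien(ship)
        points = int(walks[alien, t])
        state = two_step_update(
            params, state, s, ship, 0 if choose_left else 1, float(points)
        )
        rows.append(
            {
                "participant_id": participant_id,
                "trial_number": t + 1,
                "start_state": s,
                "left_ship": left,
                "right_ship": right,
                "choice_side": "left" if choose_left else "right",
                "chosen_ship": ship,
                "alien": alien,
                "points": points,
                "rt_ms": None,
                "missed": 0,
            }
        )
    return pd.DataFrame(rows)
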