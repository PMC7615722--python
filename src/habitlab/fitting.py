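"""Maximum-likelihood fitting of the candidate choice models.

The likelihood replays a participant's chronologically ordered log — five
training sessions plus the test phase, with the learning state carried
across sessions — and scores each completed free-choice trial.  Missed
trials contribute neither likelihood nor learning updates; instructed
(cued) trials of the Unrewarded Habit training update the choice kernel
but are excluded from the likelihood.

Optimization is bounded multi-start L-BFGS-B from seeded uniform draws
within the parameter bounds; the lowest-nll start wins, ties broken by
start index.  AIC = 2k + 2 nll and BIC = k ln(n) + 2 nll with n the number
of likelihood-contributing trials.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize

from . import _likelihood
from .agents import (
    FREE_PARAMS,
    MODEL_IDS,
    REWARD_SCALE,
    ModelParams,
    RLState,
    TwoStepParams,
    choice_probability,
    ck_update,
    rl_update,
)

__all__ = [
    "FitResult",
    "InsufficientTrialsError",
    "PARAM_BOUNDS",
    "TWO_STEP_BOUNDS",
    "encode_choice_log",
    "nll",
    "nll_reference",
    "two_step_nll",
    "fit_mle",
    "fit_two_step_mle",
    "information_criteria",
]

#: Bounds of the free parameters of the binary-choice models.
PARAM_BOUNDS: dict[str, tuple[float, float]] = {
    "alpha_q": (0.0, 1.0),
    "beta_q": (0.0, 10.0),
    "alpha_h": (0.0, 1.0),
    "beta_h": (0.0, 10.0),
}

#: Bounds of the two-step hybrid parameters (alpha, beta, lam, pi, rho, w).
TWO_STEP_BOUNDS: list[tuple[float, float]] = [
    (0.0, 1.0),
    (0.0, 20.0),
    (0.0, 1.0),
    (-5.0, 5.0),
    (-5.0, 5.0),
    (0.0, 1.0),
]

_OPT_TOL = 1e-8
_OPT_MAXITER = 500


class InsufficientTrialsError(ValueError):
    """Too few completed trials to attempt a fit (distinct from a fit that
    ran but failed to converge)."""


@dataclass
class FitResult:
    """MLE output for one participant x model."""

    participant_id: str
    model_id: str
    params: dict[str, float]
    nll: float
    n_params: int
    n_trials: int
    aic: float
    bic: float
    n_starts: int
    best_start_index: int
    converged: bool
    seed: int

    def to_dict(self) -> dict:
        return {
            "participant_id": self.participant_id,
            "model_id": self.model_id,
            "params": dict(self.params),
            "nll": self.nll,
            "n_params": self.n_params,
            "n_trials": self.n_trials,
            "aic": self.aic,
            "bic": self.bic,
            "n_starts": self.n_starts,
            "best_start_index": self.best_start_index,
            "converged": self.converged,
            "seed": self.seed,
        }


def information_criteria(nll: float, n_params: int, n_trials: int) -> tuple[float, float]:
    """(AIC, BIC) from a negative log-likelihood in nats."""
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    aic = 2.0 * n_params + 2.0 * nll
    bic = n_params * math.log(n_trials) + 2.0 * nll
    return aic, bic


@dataclass
class EncodedLog:
    """Array view of a trial log, ready for the compiled kernels."""

    stimuli: list[str]
    left: np.ndarray
    right: np.ndarray
    choice: np.ndarray
    r_left: np.ndarray
    r_right: np.ndarray
    feedback: np.ndarray
    in_likelihood: np.ndarray

    @property
    def n_likelihood_trials(self) -> int:
        return int(((self.choice >= 0) & (self.in_likelihood == 1)).sum())


def encode_choice_log(
    logs: pd.DataFrame, feedback: str = "both", fit_scope: str = "all"
) -> EncodedLog:
    """Turn a trial-log frame into arrays for likelihood evaluation.

    Rows must be chronologically ordered (day, then trial within phase).
    Training rows with recorded outcomes produce Q-feedback according to
    ``feedback``; cued rows never enter the likelihood.  ``fit_scope`` is
    ``"all"`` (training + test) or ``"test_only"``.
    """
    if fit_scope not in ("all", "test_only"):
        raise ValueError(f"unknown fit_scope {fit_scope!r}")
    fb_code = {"both": 2, "chosen_only": 1, "none": 0}[feedback]
    stimuli = sorted(
        set(logs["left_stim"].dropna()) | set(logs["right_stim"].dropna())
    )
    index = {s: i for i, s in enumerate(stimuli)}
    n = len(logs)
    left = np.empty(n, dtype=np.int64)
    right = np.empty(n, dtype=np.int64)
    choice = np.empty(n, dtype=np.int64)
    r_left = np.zeros(n)
    r_right = np.zeros(n)
    fb = np.zeros(n, dtype=np.int64)
    lik = np.zeros(n, dtype=np.int64)
    for t, row in enumerate(logs.itertuples(index=False)):
        left[t] = index[row.left_stim]
        right[t] = index[row.right_stim]
        missed = bool(row.missed) if not pd.isna(row.missed) else pd.isna(row.choice_side)
        if missed or pd.isna(row.choice_side):
            choice[t] = -1
            continue
        choice[t] = 0 if row.choice_side == "left" else 1
        has_outcome = not pd.isna(row.outcome_points_left)
        if has_outcome:
            fb[t] = fb_code
            r_left[t] = float(row.outcome_points_left) / REWARD_SCALE
            r_right[t] = float(row.outcome_points_right) / REWARD_SCALE
        cued = isinstance(row.cue_side, str) and row.cue_side in ("left", "right")
        in_scope = fit_scope == "all" or row.phase == "test"
        lik[t] = int(in_scope and not cued)
    return EncodedLog(stimuli, left, right, choice, r_left, r_right, fb, lik)


def _kernel_args(model_id: str, values: Mapping[str, float]) -> tuple[float, float, float, float]:
    params = ModelParams(model_id=model_id, **{k: values[k] for k in FREE_PARAMS[model_id]})
    return (
        values.get("alpha_q", 0.0),
        params.effective_beta_q,
        values.get("alpha_h", 0.0),
        params.effective_beta_h,
    )


def nll(
    model_id: str,
    params: ModelParams | Mapping[str, float],
    logs: pd.DataFrame | EncodedLog,
    *,
    feedback: str = "both",
    fit_scope: str = "all",
    q0: float = 0.5,
    ck0: float = 0.5,
) -> float:
    """Negative log-likelihood (nats) of a participant's log under a model."""
    if model_id not in MODEL_IDS:
        raise ValueError(f"unknown model_id {model_id!r}")
    enc = (
        logs
        if isinstance(logs, EncodedLog)
        else encode_choice_log(logs, feedback=feedback, fit_scope=fit_scope)
    )
    if model_id == "random":
        return enc.n_likelihood_trials * math.log(2.0)
    values = params.free_values() if isinstance(params, ModelParams) else dict(params)
    for name in FREE_PARAMS[model_id]:
        lo, hi = PARAM_BOUNDS[name]
        if not lo <= values[name] <= hi:
            raise ValueError(f"{name}={values[name]} outside [{lo}, {hi}]")
    alpha_q, beta_q, alpha_h, beta_h = _kernel_args(model_id, values)
    return float(
        _likelihood.choice_nll_kernel(
            enc.left,
            enc.right,
            enc.choice,
            enc.r_left,
            enc.r_right,
            enc.feedback,
            enc.in_likelihood,
            len(enc.stimuli),
            alpha_q,
            beta_q,
            alpha_h,
            beta_h,
            q0,
            ck0,
        )
    )


def nll_reference(
    model_id: str,
    params: ModelParams,
    logs: pd.DataFrame,
    *,
    feedback: str = "both",
    fit_scope: str = "all",
    q0: float = 0.5,
    ck0: float = 0.5,
) -> float:
    """Pure-Python replayed likelihood built from the agent primitives.

    Slower than :func:`nll` but shares no code with the compiled kernel;
    the test suite checks the two against each other.
    """
    stimuli = sorted(set(logs["left_stim"].dropna()) | set(logs["right_stim"].dropna()))
    state = RLState.initial(stimuli, q0=q0, ck0=ck0)
    total = 0.0
    for row in logs.itertuples(index=False):
        missed = (not pd.isna(row.missed) and bool(row.missed)) or pd.isna(row.choice_side)
        if missed:
            continue
        chosen = row.chosen_stim
        unchosen = row.right_stim if chosen == row.left_stim else row.left_stim
        cued = isinstance(row.cue_side, str) and row.cue_side in ("left", "right")
        in_scope = fit_scope == "all" or row.phase == "test"
        if in_scope and not cued:
            p_left = choice_probability(state, params, row.left_stim, row.right_stim)
            p = p_left if row.choice_side == "left" else 1.0 - p_left
            total -= math.log(max(p, 1e-300))
        state = ck_update(state, chosen, unchosen, params.alpha_h or 0.0)
        if not pd.isna(row.outcome_points_left) and params.alpha_q is not None:
            r = {
                row.left_stim: float(row.outcome_points_left) / REWARD_SCALE,
                row.right_stim: float(row.outcome_points_right) / REWARD_SCALE,
            }
            state = rl_update(
                state, chosen, unchosen, r[chosen], r[unchosen],
                params.alpha_q, feedback=feedback,
            )
    return total


def two_step_nll(params: TwoStepParams | Sequence[float], logs: pd.DataFrame) -> float:
    """Negative log-likelihood of a two-step log under the hybrid learner."""
    if isinstance(params, TwoStepParams):
        vec = (params.alpha, params.beta, params.lam, params.pi, params.rho, params.w)
    else:
        vec = tuple(float(v) for v in params)
    choice = np.where(
        logs["missed"].fillna(0).astype(int).to_numpy() == 1,
        -1,
        np.where(logs["choice_side"].to_numpy() == "left", 0, 1),
    ).astype(np.int64)
    return float(
        _likelihood.two_step_nll_kernel(
            logs["start_state"].to_numpy(dtype=np.int64),
            logs["left_ship"].to_numpy(dtype=np.int64),
            logs["right_ship"].to_numpy(dtype=np.int64),
            choice,
            logs["points"].to_numpy(dtype=np.float64),
            *vec,
        )
    )


def _multi_start(
    objective,
    bounds: list[tuple[float, float]],
    n_starts: int,
    seed: int,
) -> tuple[np.ndarray, float, int, bool]:
    rng = np.random.default_rng(np.random.SeedSequence([seed, 21]))
    best_x, best_f, best_i = None, np.inf, -1
    any_success = False
    lo = np.array([b[0] for b in bounds])
    hi = np.array([b[1] for b in bounds])
    for i in range(n_starts):
        x0 = lo + rng.random(len(bounds)) * (hi - lo)
        res = optimize.minimize(
            objective,
            x0,
            method="L-BFGS-B",
            bounds=bounds,
            options={"ftol": _OPT_TOL, "maxiter": _OPT_MAXITER},
        )
        any_success = any_success or bool(res.success)
        if res.fun < best_f - 1e-12:
            best_x, best_f, best_i = res.x, float(res.fun), i
    return best_x, best_f, best_i, any_success


def fit_mle(
    model_id: str,
    logs: pd.DataFrame,
    n_starts: int = 10,
    seed: int = 0,
    *,
    min_trials: int = 30,
    feedback: str = "both",
    fit_scope: str = "all",
    q0: float = 0.5,
    ck0: float = 0.5,
    participant_id: str | None = None,
) -> FitResult:
    """Fit one binary-choice model to one participant's log by MLE."""
    if model_id not in MODEL_IDS:
        raise ValueError(f"unknown model_id {model_id!r}")
    if participant_id is None:
        ids = logs["participant_id"].dropna().unique()
        participant_id = str(ids[0]) if len(ids) else ""
    enc = encode_choice_log(logs, feedback=feedback, fit_scope=fit_scope)
    n = enc.n_likelihood_trials
    if n < min_trials:
        raise InsufficientTrialsError(
            f"{n} likelihood-contributing trials < floor of {min_trials}"
        )
    names = FREE_PARAMS[model_id]
    if not names:  # random model: closed form
        value = n * math.log(2.0)
        aic, bic = information_criteria(value, 0, n)
        return FitResult(
            participant_id, model_id, {}, value, 0, n, aic, bic, 0, -1, True, seed
        )

    def objective(x: np.ndarray) -> float:
        values = dict(zip(names, x))
        alpha_q, beta_q, alpha_h, beta_h = _kernel_args(model_id, values)
        return _likelihood.choice_nll_kernel(
            enc.left, enc.right, enc.choice, enc.r_left, enc.r_right,
            enc.feedback, enc.in_likelihood, len(enc.stimuli),
            alpha_q, beta_q, alpha_h, beta_h, q0, ck0,
        )

    bounds = [PARAM_BOUNDS[name] for name in names]
    best_x, best_f, best_i, ok = _multi_start(objective, bounds, n_starts, seed)
    params = dict(zip(names, map(float, best_x)))
    aic, bic = information_criteria(best_f, len(names), n)
    return FitResult(
        participant_id, model_id, params, best_f, len(names), n,
        aic, bic, n_starts, best_i, ok, seed,
    )


def fit_two_step_mle(
    logs: pd.DataFrame,
    n_starts: int = 10,
    seed: int = 0,
    *,
    min_trials: int = 30,
    participant_id: str | None = None,
) -> FitResult:
    """Fit the hybrid learner to a two-step log by MLE.

    The fitted ``w`` is reported alongside the inverted habit measure
    ``1 - w`` (key ``habit_weight`` in ``params``).
    """
    if participant_id is None:
        ids = logs["participant_id"].dropna().unique()
        participant_id = str(ids[0]) if len(ids) else ""
    completed = int((logs["missed"].fillna(0).astype(int) == 0).sum())
    if completed < min_trials:
        raise InsufficientTrialsError(
            f"{completed} completed trials < floor of {min_trials}"
        )
    objective = lambda x: two_step_nll(x, logs)
    best_x, best_f, best_i, ok = _multi_start(objective, TWO_STEP_BOUNDS, n_starts, seed)
    names = ("alpha", "beta", "lam", "pi", "rho", "w")
    params = dict(zip(names, map(float, best_x)))
    params["habit_weight"] = 1.0 - params["w"]
    aic, bic = information_criteria(best_f, 6, completed)
    return FitResult(
        participant_id, "twostep_hybrid", params, best_f, 6, completed,
        aic, bic, n_starts, best_i, ok, seed,
    )
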