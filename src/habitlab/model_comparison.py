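"""Group-level model selection and recovery harnesses.

Individual-level evidence uses absolute BIC differences (0-6 insufficient,
6-10 strong, >10 very strong).  Group-level selection treats the model
identity as a random effect across participants: subject-wise log model
evidences (approximated as -AIC/2, optionally -BIC/2) feed a variational
Dirichlet scheme whose posterior yields expected model frequencies and
exceedance probabilities — the probability that each model is the most
frequent in the population.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import special, stats

__all__ = [
    "BMSResult",
    "bic_evidence_category",
    "group_bms",
    "log_evidence_from_fits",
    "model_recovery",
    "default_param_priors",
    "draw_params",
]


def bic_evidence_category(delta_bic: float) -> str:
    """Classify an absolute BIC difference.

    [0, 6) -> ``insufficient``; [6, 10] -> ``strong``; > 10 ->
    ``very_strong`` evidence for the lower-BIC model.
    """
    if delta_bic < 0:
        raise ValueError("delta_bic must be an absolute (non-negative) difference")
    if delta_bic < 6:
        return "insufficient"
    if delta_bic <= 10:
        return "strong"
    return "very_strong"


@dataclass
class BMSResult:
    """Posterior of random-effects Bayesian model selection."""

    alpha: np.ndarray
    expected_freq: np.ndarray
    exceedance: np.ndarray
    n_subjects: int
    n_samples: int
    seed: int
    converged: bool

    def to_dict(self) -> dict:
        return {
            "alpha": self.alpha.tolist(),
            "expected_freq": self.expected_freq.tolist(),
            "exceedance": self.exceedance.tolist(),
            "n_subjects": self.n_subjects,
            "n_samples": self.n_samples,
            "seed": self.seed,
            "converged": self.converged,
        }


def group_bms(
    log_evidence: np.ndarray,
    n_samples: int = 100_000,
    seed: int = 0,
    *,
    prior_alpha: float = 1.0,
    tol: float = 1e-6,
    max_iter: int = 10_000,
) -> BMSResult:
    """Random-effects model selection over an N x K log-evidence matrix.

    Variational scheme: starting from a uniform Dirichlet, iterate

        u_nk ∝ exp(L_nk + psi(alpha_k) - psi(sum alpha)),  row-normalized
        alpha = prior + column sums of u

    until the concentration stabilizes.  Exceedance probabilities come
    from Monte-Carlo draws of the posterior Dirichlet (analytic Beta CDF
    for K = 2).  Adding a per-subject constant to a row of ``log_evidence``
    leaves the result unchanged.
    """
    L = np.asarray(log_evidence, dtype=float)
    if L.ndim != 2 or L.shape[1] < 2:
        raise ValueError("log_evidence must be N x K with K >= 2")
    if not np.all(np.isfinite(L)):
        raise ValueError("log_evidence contains non-finite values")
    n, k = L.shape
    L = L - L.max(axis=1, keepdims=True)  # per-row shift: invariant, stabilizes exp

    alpha = np.full(k, prior_alpha)
    converged = False
    for _ in range(max_iter):
        log_u = L + special.digamma(alpha) - special.digamma(alpha.sum())
        log_u -= log_u.max(axis=1, keepdims=True)
        u = np.exp(log_u)
        u /= u.sum(axis=1, keepdims=True)
        new_alpha = prior_alpha + u.sum(axis=0)
        if np.max(np.abs(new_alpha - alpha)) < tol:
            alpha = new_alpha
            converged = True
            break
        alpha = new_alpha
    if n == 0:
        alpha = np.full(k, prior_alpha)
        converged = True

    expected = alpha / alpha.sum()
    if k == 2:
        # P(x1 > x2) for Dirichlet(a1, a2) is P(Beta(a1, a2) > 1/2)
        p1 = float(stats.beta.sf(0.5, alpha[0], alpha[1]))
        exceedance = np.array([p1, 1.0 - p1])
    else:
        rng = np.random.default_rng(np.random.SeedSequence([seed, 31]))
        draws = rng.dirichlet(alpha, size=n_samples)
        winners = np.argmax(draws, axis=1)
        exceedance = np.bincount(winners, minlength=k) / n_samples
    return BMSResult(alpha, expected, exceedance, n, n_samples, seed, converged)


def log_evidence_from_fits(
    fits: Sequence[Mapping], criterion: str = "aic"
) -> tuple[np.ndarray, list[str], list[str]]:
    """Pivot FitResult records into an N x K log-evidence matrix.

    The per-subject log model evidence is approximated as ``-AIC/2``
    (``criterion="aic"``, the registered choice) or ``-BIC/2``.
    Returns (matrix, participant ids, model ids).
    """
    if criterion not in ("aic", "bic"):
        raise ValueError("criterion must be 'aic' or 'bic'")
    frame = pd.DataFrame(
        [
            {
                "participant_id": f["participant_id"],
                "model_id": f["model_id"],
                "value": -0.5 * float(f[criterion]),
            }
            for f in fits
        ]
    )
    pivot = frame.pivot(index="participant_id", columns="model_id", values="value")
    if pivot.isna().any().any():
        raise ValueError("every participant needs a fit for every model")
    return pivot.to_numpy(), list(pivot.index), list(pivot.columns)


# ---------------------------------------------------------------------------
# Recovery


def default_param_priors() -> dict[str, tuple]:
    """Sampling distributions for generating parameters in recovery runs:
    learning rates Beta(2, 2), inverse temperatures Uniform(1, 9)."""
    return {
        "alpha_q": ("beta", 2.0, 2.0),
        "beta_q": ("uniform", 1.0, 9.0),
        "alpha_h": ("beta", 2.0, 2.0),
        "beta_h": ("uniform", 1.0, 9.0),
    }


def _draw(spec: tuple, rng: np.random.Generator) -> float:
    family, a, b = spec
    if family == "beta":
        return float(rng.beta(a, b))
    if family == "uniform":
        return float(rng.uniform(a, b))
    if family == "constant":
        return float(a)
    raise ValueError(f"unknown prior family {family!r}")


def draw_params(
    model_id: str, priors: Mapping[str, tuple], rng: np.random.Generator
):
    """Draw a ModelParams for ``model_id`` from per-parameter priors."""
    from .agents import FREE_PARAMS, ModelParams

    values = {name: _draw(priors[name], rng) for name in FREE_PARAMS[model_id]}
    return ModelParams(model_id=model_id, **values)


def model_recovery(
    model_set: Sequence[str],
    n_subjects: int,
    schedule_config: Mapping | None = None,
    param_priors: Mapping[str, tuple] | None = None,
    seed: int = 0,
    *,
    n_starts: int = 5,
    progress: Callable[[str], None] | None = None,
) -> pd.DataFrame:
    """Simulate-and-refit confusion matrix over a model set.

    For each generating model, ``n_subjects`` synthetic participants play
    the Reward Pairs task (``schedule_config``: ``days`` training sessions
    plus the test phase, default 5), all models in ``model_set`` are fit,
    and each subject is assigned to the lowest-BIC model.  Rows index the
    generating model, columns the selected model; rows sum to 1.
    """
    from .agents import simulate_task
    from .fitting import fit_mle
    from .task_designs import (
        build_reward_pairs_test,
        build_reward_pairs_training_session,
        reward_pairs_reward_map,
    )

    priors = dict(default_param_priors(), **(param_priors or {}))
    config = dict(schedule_config or {})
    days = int(config.get("days", 5))
    include_test = bool(config.get("include_test", True))
    reward_map = reward_pairs_reward_map()

    confusion = pd.DataFrame(0.0, index=list(model_set), columns=list(model_set))
    rng = np.random.default_rng(np.random.SeedSequence([seed, 41]))
    for gen_model in model_set:
        for j in range(n_subjects):
            sub_seed = int(rng.integers(2**31 - 1))
            params = draw_params(gen_model, priors, rng)
            logs = []
            state = None
            for day in range(1, days + 1):
                schedule = build_reward_pairs_training_session(day, sub_seed)
                log, state = simulate_task(
                    params, schedule, reward_map, seed=sub_seed + day, state=state
                )
                logs.append(log)
            if include_test:
                schedule = build_reward_pairs_test(sub_seed)
                log, state = simulate_task(
                    params, schedule, None, seed=sub_seed + 99, state=state
                )
                logs.append(log)
            full = pd.concat(logs, ignore_index=True)
            best_model, best_bic = None, np.inf
            for fit_model in model_set:
                res = fit_mle(fit_model, full, n_starts=n_starts, seed=sub_seed)
                if res.bic < best_bic:
                    best_model, best_bic = fit_model, res.bic
            confusion.loc[gen_model, best_model] += 1.0
            if progress is not None:
                progress(f"{gen_model} subject {j + 1}/{n_subjects}")
    return confusion / n_subjects
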