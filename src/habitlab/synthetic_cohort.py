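"""Synthetic participant cohorts with the statistical structure the
analyses assume.

Each synthetic participant is assigned a generating choice model and
parameters, plays the full Reward Pairs protocol (day-1 baseline test,
five training sessions, final test) and the full Unrewarded Habit
protocol (baseline test, five instructed sessions, final test), and
produces response times, stimulus ratings, and questionnaire responses:

- RTs are drawn from a log-scale Gaussian whose mean decreases with the
  chosen-minus-unchosen value difference and choice-kernel difference,
  truncated to (50 ms, response window] — matching the assumptions of the
  log-RT analyses, with no claim to model the human RT mechanism.
- Post ratings regress toward ``w_pre * pre`` plus value and
  choice-frequency contributions with Gaussian noise, clipped to [0, 100].
- Questionnaire items load on a single latent habit trait (loadings
  configurable to zero).

The ground-truth table records every generating model and parameter so
that recovery experiments can close the loop.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .agents import (
    FREE_PARAMS,
    ModelParams,
    RLState,
    simulate_task,
    simulate_unrewarded_training,
)
from .model_comparison import default_param_priors, draw_params
from .task_designs import (
    REWARD_PAIRS_WINDOW_MS,
    UNREWARDED_WINDOW_MS,
    build_reward_pairs_test,
    build_reward_pairs_training_session,
    build_unrewarded_test,
    build_unrewarded_training_session,
    reward_pairs_reward_map,
    reward_pairs_stimuli,
    unrewarded_stimuli,
)

__all__ = [
    "RTModel",
    "RatingModel",
    "CohortConfig",
    "CohortData",
    "habitized_param_priors",
    "generate_cohort",
    "recovery_experiment",
    "validate_recovery_report",
]


def habitized_param_priors() -> dict[str, tuple]:
    """Parameter regime in which the choice-kernel habit expresses itself.

    The frequency manipulation of the training schedules presupposes
    value-guided training choices: only a reward-maximizing learner
    actually chooses the *frequent* member of a same-reward pair more
    often.  A kernel weight large enough to dominate training makes the
    agent perseverate on arbitrary stimuli and destroys the manipulation,
    while a fast kernel (large alpha_h) forgets the training frequencies
    within a few test trials.  The habitized regime therefore combines a
    high value weight (beta_q in [6, 9]), a slow persistent kernel
    (alpha_h in [0.05, 0.3], the range typical of human kernel fits), and
    a moderate kernel weight (beta_h in [3, 7], bracketing the
    equal-weighting point 5).
    """
    return {
        "alpha_q": ("beta", 2.0, 2.0),
        "beta_q": ("uniform", 6.0, 9.0),
        "alpha_h": ("uniform", 0.05, 0.3),
        "beta_h": ("uniform", 3.0, 7.0),
    }


@dataclass(frozen=True)
class RTModel:
    """Log-scale Gaussian response-time model.

    ``log RT_ms ~ N(mu0_log_ms - b_value * dQ - b_freq * dCK, sigma_log)``
    with dQ/dCK the chosen-minus-unchosen value and kernel differences,
    truncated to (50 ms, response window].
    """

    mu0_log_ms: float = math.log(420.0)
    b_value: float = 0.25
    b_freq: float = 0.25
    sigma_log: float = 0.20
    miss_prob: float = 0.03

    def __post_init__(self) -> None:
        if not 0.0 <= self.miss_prob < 0.5:
            raise ValueError("miss_prob must be in [0, 0.5)")


@dataclass(frozen=True)
class RatingModel:
    """Post = clip(w_pre * pre + w_value * 100 * value + w_freq * 100 * ck
    + noise, 0, 100); value on the [0, 1] points/9 scale."""

    w_pre: float = 0.7
    w_value: float = 0.3
    w_freq: float = 0.15
    sigma: float = 5.0


@dataclass(frozen=True)
class CohortConfig:
    """Data-generating configuration for a synthetic cohort.

    Defaults: four-model mixture over the registered comparison set,
    learning rates Beta(2, 2), inverse temperatures Uniform(1, 9),
    compliance Beta(20, 2), five training days per task.
    """

    n_participants: int = 50
    seed: int = 0
    model_mixture: Mapping[str, float] = field(
        default_factory=lambda: {"random": 0.25, "rl": 0.25, "ck": 0.25, "rl_ck": 0.25}
    )
    param_priors: Mapping[str, tuple] = field(default_factory=default_param_priors)
    rt_model: RTModel = field(default_factory=RTModel)
    rating_model: RatingModel = field(default_factory=RatingModel)
    compliance_prior: tuple = ("beta", 20.0, 2.0)
    questionnaire_loading: float = 0.5
    days: int = 5
    include_baseline_test: bool = True

    def __post_init__(self) -> None:
        total = sum(self.model_mixture.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"model mixture must sum to 1, sums to {total}")


@dataclass
class CohortData:
    """All files of a synthetic cohort, as in-memory frames."""

    trial_logs: pd.DataFrame
    ratings: pd.DataFrame
    questionnaires: pd.DataFrame
    ground_truth: pd.DataFrame


def _draw_rt(
    rng: np.random.Generator, model: RTModel, q_diff: float, ck_diff: float, window_ms: int
) -> int:
    mu = model.mu0_log_ms - model.b_value * q_diff - model.b_freq * ck_diff
    rt = math.exp(rng.normal(mu, model.sigma_log))
    return int(min(max(rt, 51.0), float(window_ms)))


def _fill_rts(
    log: pd.DataFrame, rng: np.random.Generator, model: RTModel, window_ms: int
) -> pd.DataFrame:
    rts, missed = [], []
    for row in log.itertuples(index=False):
        if row.missed == 1 or pd.isna(row.chosen_stim):
            rts.append(None)
            missed.append(1)
            continue
        if rng.random() < model.miss_prob:
            rts.append(None)
            missed.append(1)
            continue
        rts.append(_draw_rt(rng, model, row.q_diff or 0.0, row.ck_diff or 0.0, window_ms))
        missed.append(0)
    out = log.copy()
    out["rt_ms"] = rts
    out["missed"] = missed
    # a missed trial records no choice
    lost = out["missed"] == 1
    out.loc[lost, ["choice_side", "chosen_stim"]] = None
    return out


def _likert(rng: np.random.Generator, mean: float, lo: int, hi: int, size: int) -> np.ndarray:
    vals = np.rint(rng.normal(mean, 1.0, size=size))
    return np.clip(vals, lo, hi).astype(int)


def _questionnaires(
    rng: np.random.Generator, pid: str, trait: float, loading: float
) -> list[dict]:
    rows = []
    # SRHI: 11 behaviors x 12 items on 0-6
    base = rng.normal(3.0 + loading * trait, 0.8, size=11)
    for b in range(11):
        items = _likert(rng, base[b], 0, 6, 12)
        for i, v in enumerate(items):
            rows.append(
                {
                    "participant_id": pid,
                    "instrument": "srhi",
                    "item": b * 12 + i + 1,
                    "response": int(v),
                }
            )
    # COHS: 27 items on 1-5
    for i, v in enumerate(_likert(rng, 3.0 + 0.6 * loading * trait, 1, 5, 27)):
        rows.append(
            {"participant_id": pid, "instrument": "cohs", "item": i + 1, "response": int(v)}
        )
    # HTQ: 11 items on 0-6 (novelty items assumed recoded)
    for i, v in enumerate(_likert(rng, 3.0 + loading * trait, 0, 6, 11)):
        rows.append(
            {"participant_id": pid, "instrument": "htq", "item": i + 1, "response": int(v)}
        )
    return rows


def generate_cohort(config: CohortConfig) -> CohortData:
    """Generate the complete synthetic dataset for one cohort.

    Output is a pure function of ``config`` (including its seed).
    """
    model_ids = list(config.model_mixture.keys())
    mixture = np.array([config.model_mixture[m] for m in model_ids])
    reward_map = reward_pairs_reward_map()
    rp_value = {s.id: (s.reward_value or 0) / 9.0 for s in reward_pairs_stimuli()}

    logs, ratings, questionnaires, truth = [], [], [], []
    for i in range(config.n_participants):
        pid = f"p{i + 1:03d}"
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 51, i]))
        sub_seed = int(rng.integers(2**31 - 1))
        model_id = model_ids[rng.choice(len(model_ids), p=mixture)]
        params = draw_params(model_id, dict(config.param_priors), rng)
        compliance = min(
            1.0, max(0.5, rng.beta(config.compliance_prior[1], config.compliance_prior[2]))
        )
        trait = float(rng.normal())

        truth.append({"participant_id": pid, "model_id": model_id, "param": "compliance", "value": compliance})
        for name, value in params.free_values().items():
            truth.append({"participant_id": pid, "model_id": model_id, "param": name, "value": value})

        # --- pre-study ratings: two per stimulus, centered on 50
        all_stims = [s.id for s in reward_pairs_stimuli()] + [
            s.id for s in unrewarded_stimuli()
        ]
        pre_rating = {s: float(np.clip(rng.normal(50, 10), 0, 100)) for s in all_stims}
        for s in all_stims:
            task = "reward_pairs" if s.startswith("s") else "unrewarded_habit"
            for _ in range(2):
                ratings.append(
                    {
                        "participant_id": pid,
                        "task": task,
                        "stimulus": s,
                        "timepoint": "pre",
                        "rating": float(np.clip(pre_rating[s] + rng.normal(0, 2), 0, 100)),
                    }
                )

        # --- Reward Pairs protocol
        rp_logs = []
        state: RLState | None = None
        if config.include_baseline_test:
            log, state = simulate_task(
                params,
                build_reward_pairs_test(sub_seed, day=1),
                None,
                seed=sub_seed + 500,
                participant_id=pid,
            )
            rp_logs.append(log)
            state = None  # baseline choices leave no residue: training starts fresh
        for day in range(1, config.days + 1):
            log, state = simulate_task(
                params,
                build_reward_pairs_training_session(day, sub_seed),
                reward_map,
                seed=sub_seed + day,
                state=state,
                participant_id=pid,
            )
            rp_logs.append(log)
        log, rp_state = simulate_task(
            params,
            build_reward_pairs_test(sub_seed, day=config.days),
            None,
            seed=sub_seed + 600,
            state=state,
            participant_id=pid,
        )
        rp_logs.append(log)
        rp_frame = pd.concat(rp_logs, ignore_index=True)
        rp_frame = _fill_rts(rp_frame, rng, config.rt_model, REWARD_PAIRS_WINDOW_MS)
        logs.append(rp_frame)

        # --- Unrewarded Habit protocol
        alpha_h = params.alpha_h if params.alpha_h is not None else 0.2
        uh_logs = []
        if config.include_baseline_test:
            log, _ = simulate_task(
                params,
                build_unrewarded_test(sub_seed, day=1),
                None,
                seed=sub_seed + 700,
                participant_id=pid,
                task="unrewarded_habit",
            )
            uh_logs.append(log)
        uh_state: RLState | None = None
        for day in range(1, config.days + 1):
            log, uh_state = simulate_unrewarded_training(
                compliance,
                build_unrewarded_training_session(day, sub_seed),
                seed=sub_seed + 100 + day,
                alpha_h=alpha_h,
                miss_prob=config.rt_model.miss_prob,
                state=uh_state,
                participant_id=pid,
            )
            uh_logs.append(log)
        log, uh_state = simulate_task(
            params,
            build_unrewarded_test(sub_seed, day=config.days),
            None,
            seed=sub_seed + 800,
            state=uh_state,
            participant_id=pid,
            task="unrewarded_habit",
        )
        uh_logs.append(log)
        uh_frame = pd.concat(uh_logs, ignore_index=True)
        uh_frame = _fill_rts(uh_frame, rng, config.rt_model, UNREWARDED_WINDOW_MS)
        logs.append(uh_frame)

        # --- post ratings from final learned state
        rm = config.rating_model
        for s in all_stims:
            task = "reward_pairs" if s.startswith("s") else "unrewarded_habit"
            ck = rp_state.ck.get(s, uh_state.ck.get(s, 0.5)) if s.startswith("s") else uh_state.ck.get(s, 0.5)
            mu = (
                rm.w_pre * pre_rating[s]
                + rm.w_value * 100.0 * rp_value.get(s, 0.0)
                + rm.w_freq * 100.0 * ck
            )
            for _ in range(2):
                ratings.append(
                    {
                        "participant_id": pid,
                        "task": task,
                        "stimulus": s,
                        "timepoint": "post",
                        "rating": float(np.clip(mu + rng.normal(0, rm.sigma), 0, 100)),
                    }
                )

        questionnaires.extend(
            _questionnaires(rng, pid, trait, config.questionnaire_loading)
        )

    trial_logs = pd.concat(logs, ignore_index=True).drop(columns=["q_diff", "ck_diff"])
    return CohortData(
        trial_logs=trial_logs,
        ratings=pd.DataFrame(ratings),
        questionnaires=pd.DataFrame(questionnaires),
        ground_truth=pd.DataFrame(truth),
    )


# ---------------------------------------------------------------------------
# Recovery experiment

RECOVERY_REPORT_SCHEMA = {
    "n_subjects": int,
    "models": list,
    "param_correlations": dict,
    "confusion": dict,
    "seed": int,
}


def validate_recovery_report(report: Mapping) -> None:
    """Raise if a recovery report does not match the expected schema."""
    for key, typ in RECOVERY_REPORT_SCHEMA.items():
        if key not in report:
            raise ValueError(f"recovery report missing key {key!r}")
        if not isinstance(report[key], typ):
            raise ValueError(f"recovery report key {key!r} must be {typ.__name__}")
    for param, entry in report["param_correlations"].items():
        for k in ("r", "ci_low", "ci_high", "n"):
            if k not in entry:
                raise ValueError(f"param_correlations[{param!r}] missing {k!r}")


def _corr_ci(x: np.ndarray, y: np.ndarray) -> dict:
    """Pearson r with a Fisher-z 95% CI."""
    n = len(x)
    r = float(np.corrcoef(x, y)[0, 1])
    if n < 4 or abs(r) >= 1.0:
        return {"r": r, "ci_low": math.nan, "ci_high": math.nan, "n": n}
    z = math.atanh(r)
    se = 1.0 / math.sqrt(n - 3)
    return {
        "r": r,
        "ci_low": math.tanh(z - 1.959963984540054 * se),
        "ci_high": math.tanh(z + 1.959963984540054 * se),
        "n": n,
    }


def recovery_experiment(
    config: CohortConfig,
    *,
    fit_models: tuple[str, ...] | None = None,
    n_starts: int = 5,
    seed: int | None = None,
) -> dict:
    """Generate a cohort, fit every candidate model to every participant,
    and report generating-vs-recovered parameter correlations plus the
    model confusion matrix (selection by lowest BIC).

    Only the Reward Pairs protocol is fit (training + test, learning state
    carried across sessions).
    """
    from .fitting import fit_mle

    if config.n_participants < 20:
        raise ValueError("recovery experiments need n_participants >= 20")
    seed = config.seed if seed is None else seed
    cohort = generate_cohort(config)
    fit_models = fit_models or tuple(config.model_mixture.keys())

    rp = cohort.trial_logs[cohort.trial_logs["task"] == "reward_pairs"]
    truth = cohort.ground_truth
    recovered: list[dict] = []
    confusion: dict[str, dict[str, int]] = {}
    for idx, (pid, logs) in enumerate(rp.groupby("participant_id", sort=True)):
        gen_model = truth.loc[truth["participant_id"] == pid, "model_id"].iloc[0]
        best_model, best_bic, best_params = None, np.inf, {}
        for model_id in fit_models:
            res = fit_mle(model_id, logs, n_starts=n_starts, seed=seed + idx)
            if res.bic < best_bic:
                best_model, best_bic = model_id, res.bic
            if model_id == gen_model:
                best_params = res.params
        confusion.setdefault(gen_model, {})[best_model] = (
            confusion.setdefault(gen_model, {}).get(best_model, 0) + 1
        )
        for name, value in best_params.items():
            recovered.append(
                {"participant_id": pid, "param": name, "recovered": value}
            )

    rec = pd.DataFrame(recovered)
    correlations = {}
    if len(rec):
        merged = rec.merge(
            truth.rename(columns={"value": "generating"}),
            on=["participant_id", "param"],
        )
        for param, grp in merged.groupby("param"):
            if grp["generating"].std() > 0 and grp["recovered"].std() > 0:
                correlations[param] = _corr_ci(
                    grp["generating"].to_numpy(), grp["recovered"].to_numpy()
                )
    report = {
        "n_subjects": int(config.n_participants),
        "models": list(fit_models),
        "param_correlations": correlations,
        "confusion": confusion,
        "seed": int(seed),
    }
    validate_recovery_report(report)
    return report
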