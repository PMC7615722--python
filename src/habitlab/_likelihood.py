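"""Compiled likelihood kernels.

The replayed likelihood walks a chronologically ordered log, updating the
learning state from the *observed* choices and outcomes while accumulating
``-log P(observed choice)`` over the trials that contribute to the
likelihood.  Missed trials advance nothing; instructed (cued) trials update
learning but are excluded from the likelihood, because the instructed
choice is not generated by the participant's choice policy.

Plain-Python reference implementations (used as independent oracles in the
test suite) live in :mod:`habitlab.fitting`.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["choice_nll_kernel", "two_step_nll_kernel"]


@njit(cache=False)
def _log1pexp(z: float) -> float:
    # -log(sigmoid(z)) = log(1 + exp(-z)), numerically stable
    if z < -35.0:
        return -z
    if z > 35.0:
        return 0.0
    return np.log1p(np.exp(-z))


@njit(cache=False)
def choice_nll_kernel(
    left: np.ndarray,
    right: np.ndarray,
    choice: np.ndarray,
    r_left: np.ndarray,
    r_right: np.ndarray,
    feedback: np.ndarray,
    in_likelihood: np.ndarray,
    n_stim: int,
    alpha_q: float,
    beta_q: float,
    alpha_h: float,
    beta_h: float,
    q0: float,
    ck0: float,
) -> float:
    """Negative log-likelihood of a binary-choice log.

    choice: 0 = left, 1 = right, -1 = missed.
    feedback: 2 = both outcomes shown, 1 = chosen only, 0 = none.
    in_likelihood: 1 if the trial's choice enters the likelihood.
    """
    q = np.full(n_stim, q0)
    ck = np.full(n_stim, ck0)
    nll = 0.0
    for t in range(left.shape[0]):
        c = choice[t]
        if c < 0:
            continue
        l = left[t]
        r = right[t]
        if in_likelihood[t] == 1:
            x = beta_q * (q[l] - q[r]) + beta_h * (ck[l] - ck[r])
            nll += _log1pexp(x if c == 0 else -x)
        if c == 0:
            ch, un = l, r
        else:
            ch, un = r, l
        ck[ch] += alpha_h * (1.0 - ck[ch])
        ck[un] -= alpha_h * ck[un]
        if feedback[t] == 2:
            q[l] += alpha_q * (r_left[t] - q[l])
            q[r] += alpha_q * (r_right[t] - q[r])
        elif feedback[t] == 1:
            rc = r_left[t] if c == 0 else r_right[t]
            q[ch] += alpha_q * (rc - q[ch])
    return nll


@njit(cache=False)
def two_step_nll_kernel(
    start_state: np.ndarray,
    left_ship: np.ndarray,
    right_ship: np.ndarray,
    choice: np.ndarray,
    points: np.ndarray,
    alpha: float,
    beta: float,
    lam: float,
    pi: float,
    rho: float,
    w: float,
) -> float:
    """Negative log-likelihood of a two-step log under the hybrid learner."""
    q_mf = np.zeros((2, 2))
    v = np.zeros(2)
    prev_alien = -1
    prev_key = -1
    nll = 0.0
    for t in range(start_state.shape[0]):
        c = choice[t]
        if c < 0:
            continue
        s = start_state[t]
        x = 0.0
        for side in range(2):
            ship = left_ship[t] if side == 0 else right_ship[t]
            a = ship - 2 * s
            alien = ship % 2
            q_net = w * v[alien] + (1.0 - w) * q_mf[s, a]
            logit = beta * q_net
            if prev_alien >= 0 and alien == prev_alien:
                logit += pi
            if prev_key >= 0 and side == prev_key:
                logit += rho
            x += logit if side == 0 else -logit
        nll += _log1pexp(x if c == 0 else -x)

        ship = left_ship[t] if c == 0 else right_ship[t]
        a = ship - 2 * s
        alien = ship % 2
        delta1 = v[alien] - q_mf[s, a]
        q_mf[s, a] += alpha * delta1
        delta2 = points[t] - v[alien]
        v[alien] += alpha * delta2
        q_mf[s, a] += alpha * lam * delta2
        prev_alien = alien
        prev_key = c
    return nll
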