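"""Analytic power for the independent-groups t test.

Power is evaluated under the noncentral t distribution with
``df = n_total - 2`` and noncentrality ``d * sqrt(n_total / 4)`` (equal
allocation), the same computation G*Power performs for this design; no
normal approximation is used, because the approximation can flip the
required sample size at the boundary.
"""

from __future__ import annotations

from dataclasses import dataclass

from scipy import stats

__all__ = ["PowerSpec", "power_two_sample_t", "required_n_two_sample_t"]


@dataclass(frozen=True)
class PowerSpec:
    """Inputs of a two-sample t-test power analysis."""

    effect_size_d: float
    alpha: float = 0.05
    target_power: float = 0.95
    tails: int = 2

    def __post_init__(self) -> None:
        if self.effect_size_d <= 0:
            raise ValueError("effect_size_d must be > 0")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if not 0 < self.target_power < 1:
            raise ValueError("target_power must be in (0, 1)")
        if self.tails not in (1, 2):
            raise ValueError("tails must be 1 or 2")


def power_two_sample_t(n_total: int, d: float, alpha: float = 0.05, tails: int = 2) -> float:
    """Power of the independent-groups t test with equal group sizes.

    ``P(|T'| > t_crit)`` where ``T'`` is noncentral t with ``n_total - 2``
    degrees of freedom and noncentrality ``d * sqrt(n_total / 4)``.
    """
    if n_total % 2:
        raise ValueError("n_total must be even (equal groups assumed)")
    if n_total < 4:
        raise ValueError("n_total must be at least 4")
    if d < 0:
        raise ValueError("d must be non-negative")
    if tails not in (1, 2):
        raise ValueError("tails must be 1 or 2")
    df = n_total - 2
    nc = d * (n_total / 4.0) ** 0.5
    if tails == 2:
        t_crit = stats.t.ppf(1.0 - alpha / 2.0, df)
        return float(stats.nct.sf(t_crit, df, nc) + stats.nct.cdf(-t_crit, df, nc))
    t_crit = stats.t.ppf(1.0 - alpha, df)
    return float(stats.nct.sf(t_crit, df, nc))


def required_n_two_sample_t(
    d: float,
    alpha: float = 0.05,
    target_power: float = 0.95,
    tails: int = 2,
    *,
    max_n: int = 100_000,
) -> int:
    """Smallest even total N whose power reaches ``target_power``."""
    spec = PowerSpec(d, alpha, target_power, tails)  # validates inputs
    for n_total in range(4, max_n + 1, 2):
        if power_two_sample_t(n_total, spec.effect_size_d, spec.alpha, spec.tails) >= spec.target_power:
            return n_total
    raise ValueError(f"target power {target_power} not attainable below N={max_n}")
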