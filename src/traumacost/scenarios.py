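"""Policy scenarios: initial severity distributions under trauma exposure.

Each policy is characterized by the fraction of children assumed to
experience one additional policy-related trauma: 0% under No Detention
(families released into the community), 50% under Family Detention and
100% under Zero Tolerance (forced child-parent separation). For the
exposed fraction, the baseline severity distribution is shifted under the
proportional-odds model: each additional trauma multiplies the cumulative
odds of occupying a more severe state by the per-trauma odds ratio.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .severity import TraumaEffect

__all__ = ["SeverityDistribution", "PolicyScenario", "shift_distribution",
           "initial_distribution", "DEFAULT_SCENARIOS"]

_SUM_TOL = 1e-12


@dataclass(frozen=True)
class SeverityDistribution:
    """Probability vector over the four severity states plus absorbing Dead."""

    probs: tuple[float, float, float, float, float]

    def __post_init__(self) -> None:
        p = np.asarray(self.probs, dtype=float)
        if p.shape != (5,):
            raise ValueError("distribution needs 5 entries (Q1..Q4, Dead)")
        if np.any(p < -_SUM_TOL):
            raise ValueError(f"negative probability in {self.probs}")
        if abs(p.sum() - 1.0) > 1e-9:
            raise ValueError(f"probabilities sum to {p.sum()}, not 1")

    @classmethod
    def from_living(cls, living: Sequence[float], dead: float = 0.0) -> "SeverityDistribution":
        living = np.asarray(living, dtype=float)
        if living.shape != (4,):
            raise ValueError("living part needs 4 entries")
        return cls(tuple(np.append(living, dead)))

    @classmethod
    def from_counts(cls, counts: Sequence[int]) -> "SeverityDistribution":
        c = np.asarray(counts, dtype=float)
        return cls(tuple(np.append(c / c.sum(), 0.0)))

    @property
    def living(self) -> np.ndarray:
        return np.asarray(self.probs[:4], dtype=float)

    @property
    def dead(self) -> float:
        return float(self.probs[4])

    def as_array(self) -> np.ndarray:
        return np.asarray(self.probs, dtype=float)

    def mean_state(self) -> float:
        """Expected severity state (1..4) among the living."""
        living = self.living
        return float(np.dot(living / living.sum(), np.arange(1, 5)))


@dataclass(frozen=True)
class PolicyScenario:
    """A border-control policy as an additional-trauma exposure assumption."""

    name: str
    exposed_fraction: float
    extra_traumas: int = 1

    def __post_init__(self) -> None:
        if not 0.0 <= self.exposed_fraction <= 1.0:
            raise ValueError("exposed_fraction must be in [0, 1]")
        if self.extra_traumas < 0:
            raise ValueError("extra_traumas must be >= 0")


DEFAULT_SCENARIOS = (
    PolicyScenario("NoDetention", 0.0),
    PolicyScenario("FamilyDetention", 0.5),
    PolicyScenario("ZeroTolerance", 1.0),
)


def shift_distribution(base: SeverityDistribution, or_value: float,
                       k_traumas: int = 1) -> SeverityDistribution:
    """Shift a severity distribution by ``k_traumas`` on the odds scale.

    Under proportional odds, for each cut k the cumulative odds of being
    above state k are multiplied by ``or_value ** k_traumas``: with
    G_k = P(state > k | alive),

        G'_k = OR^m G_k / (1 - G_k + OR^m G_k).

    The Dead mass is untouched; the living part is transformed
    conditionally on being alive.
    """
    if or_value <= 0:
        raise ValueError("or_value must be positive")
    if k_traumas < 0:
        raise ValueError("k_traumas must be >= 0")
    if or_value == 1.0 or k_traumas == 0:
        return base
    living = base.living
    alive = living.sum()
    if alive <= 0:
        return base
    cond = living / alive
    g = 1.0 - np.cumsum(cond)[:3]  # P(state > k), k = 1..3
    g = np.clip(g, 0.0, 1.0)
    mult = or_value**k_traumas
    g_new = mult * g / (1.0 - g + mult * g)
    cum_new = np.append(1.0 - g_new, 1.0)  # P(state <= k), k = 1..4
    cond_new = np.diff(cum_new, prepend=0.0)
    return SeverityDistribution(tuple(np.append(cond_new * alive, base.dead)))


def initial_distribution(base: SeverityDistribution, scenario: PolicyScenario,
                         effect: TraumaEffect | float) -> SeverityDistribution:
    """Starting distribution for a policy: exposure-fraction mixture.

    A fraction ``exposed_fraction`` of the cohort is shifted by the
    per-trauma odds ratio (point estimate of ``effect``, or a bare float
    for CI-bound runs); the remainder keeps the baseline distribution.
    """
    or_value = effect.or_point if isinstance(effect, TraumaEffect) else float(effect)
    f = scenario.exposed_fraction
    if f == 0.0:
        return base
    shifted = shift_distribution(base, or_value, scenario.extra_traumas)
    if f == 1.0:
        return shifted
    mixed = (1.0 - f) * base.as_array() + f * shifted.as_array()
    return SeverityDistribution(tuple(mixed))
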