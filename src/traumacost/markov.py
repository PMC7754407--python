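"""Annual-cycle Markov cohort model over the severity states.

The cohort's probability mass moves among the four severity states by a
configurable annual transition matrix (advancing-progression by default:
living mass can stay or move toward more severe states, never recover),
then an age-based fraction of all living mass moves to the absorbing Dead
state. No excess mortality is attached to more severe states. Cycles are
one year; the cohort's representative age advances by one per cycle.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .scenarios import SeverityDistribution

__all__ = ["TransitionModel", "MortalityTable", "Trajectory", "step", "run_trajectory"]


@dataclass(frozen=True)
class TransitionModel:
    """4x4 annual transition matrix over living severity states."""

    matrix: tuple  # 4 rows of 4
    progression_only: bool = True

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (4, 4):
            raise ValueError("transition matrix must be 4x4")
        if np.any(m < 0):
            raise ValueError("transition probabilities must be non-negative")
        if np.any(np.abs(m.sum(axis=1) - 1.0) > 1e-12):
            raise ValueError("transition matrix rows must sum to 1")
        if self.progression_only and np.any(np.tril(m, k=-1) > 0):
            raise ValueError("progression-only matrix has mass below the diagonal")

    def as_array(self) -> np.ndarray:
        return np.asarray(self.matrix, dtype=float)

    @classmethod
    def identity(cls) -> "TransitionModel":
        return cls(tuple(map(tuple, np.eye(4))))


@dataclass(frozen=True)
class MortalityTable:
    """Annual probability of death by single year of age."""

    qx: Mapping[int, float]

    def __post_init__(self) -> None:
        for age, q in self.qx.items():
            if not 0.0 <= q <= 1.0:
                raise ValueError(f"mortality at age {age} outside [0, 1]: {q}")

    def at_age(self, age: int) -> float:
        try:
            return float(self.qx[int(age)])
        except KeyError:
            raise ValueError(
                f"mortality table has no entry for age {age}; extend the table "
                f"to cover every age reachable within the horizon"
            ) from None


@dataclass
class Trajectory:
    """State-occupancy distributions at each cycle boundary t = 0..T."""

    distributions: list[SeverityDistribution]
    ages: list[int] = field(default_factory=list)

    @property
    def horizon(self) -> int:
        return len(self.distributions) - 1

    def occupancy_matrix(self) -> np.ndarray:
        """(T+1) x 5 array of state occupancy over cycle boundaries."""
        return np.vstack([d.as_array() for d in self.distributions])

    def to_frame(self) -> pd.DataFrame:
        states = ["Q1", "Q2", "Q3", "Q4", "Dead"]
        rows = [
            {"cycle": t, "state": s, "probability": d.probs[j]}
            for t, d in enumerate(self.distributions)
            for j, s in enumerate(states)
        ]
        return pd.DataFrame(rows)


def step(dist: SeverityDistribution, tm: TransitionModel, mort: float) -> SeverityDistribution:
    """One annual cycle: state transitions among the living, then mortality.

    The living mass first redistributes by the transition matrix; then a
    fraction ``mort`` of all living mass moves to Dead. Dead is absorbing.
    """
    if not 0.0 <= mort <= 1.0:
        raise ValueError(f"mortality probability outside [0, 1]: {mort}")
    living = dist.living @ tm.as_array()
    dead = dist.dead + living.sum() * mort
    living = living * (1.0 - mort)
    return SeverityDistribution(tuple(np.append(living, dead)))


def run_trajectory(init: SeverityDistribution, tm: TransitionModel,
                   mort: MortalityTable, start_age: int, horizon: int) -> Trajectory:
    """Run ``horizon`` annual cycles from ``init`` at ``start_age``.

    Mortality for the cycle from age a to a+1 is the table's entry at age
    a. Returns every intermediate distribution (T+1 of them).
    """
    if horizon < 1:
        raise ValueError("horizon must be >= 1 cycle")
    dists = [init]
    ages = [int(start_age)]
    d = init
    for t in range(horizon):
        age = start_age + t
        d = step(d, tm, mort.at_age(age))
        dists.append(d)
        ages.append(int(age) + 1)
    return Trajectory(distributions=dists, ages=ages)
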