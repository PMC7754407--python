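"""Cost accrual, incremental comparison, and cohort budget impact.

Each living severity state carries an annual cost in 2018 USD. The
least-severe state is assigned the annual cost of a child with no
behavior problems; more severe states carry the behavior-problem base
cost plus the expected cost of the four modelled conditions (PTSD,
depression, anxiety, ADHD), weighted by the state-conditional probability
of each diagnosis. Costs split into a direct (health-sector) component
and an indirect (societal: time, caregiver absenteeism, transportation)
component; the societal perspective is their sum. Per-child totals accrue
over annual cycles on start-of-cycle occupancy, optionally discounted,
and incremental costs versus the reference policy scale linearly to the
hypothetical cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .markov import Trajectory
from .severity import CONDITIONS, PrevalenceTable

__all__ = ["Perspective", "CostComponents", "CostInputs", "CohortSpec",
           "ScenarioResult", "state_annual_cost", "state_cost_vector",
           "accumulate_costs", "compare_scenarios", "scale_to_cohort"]

#: Valid accounting perspectives. "societal" = direct + indirect.
PERSPECTIVES = ("direct", "societal")
Perspective = str


@dataclass(frozen=True)
class CostComponents:
    """An annual cost split into direct and indirect components (2018 USD)."""

    direct: float
    indirect: float = 0.0

    def __post_init__(self) -> None:
        if self.direct < 0 or self.indirect < 0:
            raise ValueError("costs must be non-negative")

    def for_perspective(self, perspective: Perspective) -> float:
        if perspective == "direct":
            return self.direct
        if perspective == "societal":
            return self.direct + self.indirect

        raise ValueError(f"unknown perspective {perspective!r}; use 'direct' or 'societal'")

    def scaled(self, factor: float) -> "CostComponents":
        return CostComponents(self.direct * factor, self.indirect * factor)


@dataclass
class CostInputs:
    """Per-state base costs, per-condition costs, and diagnosis prevalence.

    ``include_q1_conditions`` controls whether children in the least-severe
    state accrue prevalence-weighted condition costs on top of the
    no-behavior-problems base (off by default: the least-severe state gets
    its base cost only, even though some of those children carry a
    diagnosis).
    """

    base_no_problems: CostComponents
    base_behavior_problems: CostComponents
    condition_costs: Mapping[str, CostComponents]
    prevalence: PrevalenceTable
    include_q1_conditions: bool = False
    currency_note: str = "2018 USD"
    conversion_factor: float = 1.0

    def __post_init__(self) -> None:
        missing = set(CONDITIONS) - set(self.condition_costs)
        extra = set(self.condition_costs) - set(CONDITIONS)
        if missing or extra:
            raise ValueError(
                f"condition_costs must cover exactly {CONDITIONS}; "
                f"missing={sorted(missing)}, unexpected={sorted(extra)}"
            )
        if self.conversion_factor != 1.0:
            self.base_no_problems = self.base_no_problems.scaled(self.conversion_factor)
            self.base_behavior_problems = self.base_behavior_problems.scaled(self.conversion_factor)
            self.condition_costs = {
                c: cc.scaled(self.conversion_factor) for c, cc in self.condition_costs.items()
            }
            self.currency_note += f" (conversion factor {self.conversion_factor} applied)"
            self.conversion_factor = 1.0


@dataclass(frozen=True)
class CohortSpec:
    """A hypothetical cohort of affected children for budget-impact scaling."""

    label: str
    size: int

    def __post_init__(self) -> None:
        if self.size < 1 or int(self.size) != self.size:
            raise ValueError("cohort size must be a positive integer")


@dataclass
class ScenarioResult:
    """Per-child totals, per-cycle breakdown and incrementals for one policy."""

    scenario: str
    perspective: Perspective
    horizon: int
    per_cycle: np.ndarray
    total: float
    incremental: float | None = None
    cohort_incrementals: dict[str, float] = field(default_factory=dict)
    ci: tuple[float, float] | None = None


def state_annual_cost(state: int, inputs: CostInputs, perspective: Perspective) -> float:
    """Annual cost of occupying one state (0..3 living, 4 = Dead).

    Least-severe state: no-behavior-problems base. States 2-4: the
    behavior-problem base plus sum over conditions of
    P(condition | state) x condition cost. Dead: 0.
    """
    if state == 4:
        return 0.0
    if state not in (0, 1, 2, 3):
        raise ValueError(f"state must be 0..4, got {state}")
    if state == 0 and not inputs.include_q1_conditions:
        return inputs.base_no_problems.for_perspective(perspective)
    base = (inputs.base_no_problems if state == 0 else inputs.base_behavior_problems)
    total = base.for_perspective(perspective)
    for cond in CONDITIONS:
        prev = inputs.prevalence.by_state(cond)[state]
        if np.isnan(prev):
            raise ValueError(
                f"prevalence of {cond} undefined in state Q{state + 1} (empty stratum)"
            )
        total += prev * inputs.condition_costs[cond].for_perspective(perspective)
    return total


def state_cost_vector(inputs: CostInputs, perspective: Perspective) -> np.ndarray:
    """Annual costs for (Q1, Q2, Q3, Q4, Dead)."""
    return np.array([state_annual_cost(s, inputs, perspective) for s in range(5)])


def accumulate_costs(traj: Trajectory, inputs: CostInputs, perspective: Perspective,
                     discount_rate: float = 0.0) -> tuple[float, np.ndarray]:
    """Per-child total cost over the trajectory, plus the per-cycle vector.

    Costs accrue on start-of-cycle occupancy: cycle t (t = 0..T-1) costs
    occupancy_t . state_costs, discounted by 1/(1+r)^t when a rate is set.
    """
    costs = state_cost_vector(inputs, perspective)
    occ = traj.occupancy_matrix()[:-1]  # start-of-cycle occupancy, t = 0..T-1
    per_cycle = occ @ costs
    if discount_rate:
        per_cycle = per_cycle / (1.0 + discount_rate) ** np.arange(len(per_cycle))
    return float(per_cycle.sum()), per_cycle


def compare_scenarios(results: Mapping[str, float],
                      reference: str = "NoDetention") -> dict[str, float]:
    """Incremental per-child cost of each scenario versus the reference."""
    if reference not in results:
        raise ValueError(f"reference scenario {reference!r} not in results")
    ref = results[reference]
    return {name: total - ref for name, total in results.items()}


def scale_to_cohort(incremental_per_child: float, cohort: CohortSpec) -> float:
    """Cohort budget impact: exact product, reported in whole dollars."""
    return round(incremental_per_child * cohort.size)
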