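"""Half-cycle-corrected Markov cohort simulation with discounted accrual.

The cohort starts from ``settings.initial_distribution`` and is pushed
through the per-cycle transition matrix for ``n_cycles`` cycles.  QALYs and
costs are accrued from state occupancy with an annual discount rate applied
per cycle; the half-cycle correction is the trapezoidal (Sonnenberg–Beck)
state-membership weighting: half weight on the initial and final occupancy
vectors, full weight in between.  With the correction disabled, accrual
counts start-of-cycle membership over the n cycles.

Cost conventions (all configurable through :class:`AccrualMap`):

* drug acquisition cost accrues per cycle while in SD or RE (on treatment,
  pre-progression);
* recurring care costs are per-year amounts converted to per-cycle by
  ``cycle_days / 365.25`` and accrue in the states they name
  (hospitalization and concomitant medications in PD, health examinations
  in SD/RE by default);
* expected adverse-event management cost and antidiarrheal prophylaxis are
  one-time costs at model entry (severe toxicity concentrates in the first
  cycles), added undiscounted at cycle 0;
* death accrues neither cost nor utility.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .parameters import (
    STATES,
    CostSchedule,
    DomainError,
    LoperamideSchedule,
    ModelSettings,
    StrategyInputs,
)
from .transitions import TransitionMatrix, build_matrix

__all__ = [
    "AccrualMap",
    "CohortTrace",
    "StrategyResult",
    "discount_factor",
    "cycle_drug_cost",
    "loperamide_prophylaxis_cost",
    "expected_ae_cost",
    "build_accrual",
    "run_cohort",
    "run_strategy",
]


def discount_factor(
    cycle_index: int, annual_rate: float, cycle_days: float = 21.0
) -> float:
    """Discount factor ``(1 + r)^(-t * cycle_days / 365.25)`` at cycle ``t``."""
    if cycle_index < 0:
        raise DomainError("cycle_index must be >= 0")
    if annual_rate < 0:
        raise DomainError("annual discount rate must be >= 0")
    return (1.0 + annual_rate) ** (-cycle_index * cycle_days / 365.25)


def cycle_drug_cost(strategy: StrategyInputs) -> float:
    """Drug acquisition cost (USD) for one 21-day cycle of the regimen.

    Units per administration are ``ceil(dose / unit_mg)`` with BSA scaling
    for per-m2 dosing; cost sums over drugs of
    units x unit price x administrations/day x on-days per cycle.
    """
    total = 0.0
    for d in strategy.costs.dosing:
        units = d.units_per_admin(strategy.costs.bsa_m2)
        total += units * d.unit_price * d.admin_per_day * d.days_per_cycle
    return total


def loperamide_prophylaxis_cost(schedule: LoperamideSchedule | None) -> float:
    """One-time cost of the first-cycle loperamide schedule (0 if none)."""
    if schedule is None:
        return 0.0
    return schedule.tablet_count * schedule.unit_price


def expected_ae_cost(costs: CostSchedule) -> float:
    """Expected one-time adverse-event management cost, sum of incidence x cost."""
    return sum(a.incidence * a.cost_per_event for a in costs.ae_profile)


@dataclass(frozen=True)
class AccrualMap:
    """Per-state accrual rules: utilities, per-cycle costs, one-time costs."""

    state_utilities: dict[str, float]
    state_cycle_costs: dict[str, float]
    one_time_cost: float = 0.0

    def __post_init__(self) -> None:
        for s in STATES:
            if s not in self.state_utilities:
                raise DomainError(f"state {s} has no utility")
        for s in self.state_cycle_costs:
            if s not in STATES:
                raise DomainError(f"cost rule references unknown state {s}")
        if self.one_time_cost < 0:
            raise DomainError("one_time_cost must be >= 0")


def build_accrual(strategy: StrategyInputs, settings: ModelSettings) -> AccrualMap:
    """Default accrual map for a strategy under the documented cost conventions."""
    drug = cycle_drug_cost(strategy)
    per_cycle = {s: 0.0 for s in STATES}
    per_cycle["SD"] += drug
    per_cycle["RE"] += drug
    frac = settings.cycle_days / 365.25
    for oc in strategy.costs.other_costs:
        for s in oc.states:
            per_cycle[s] += oc.annual_amount * frac
    one_time = expected_ae_cost(strategy.costs) + loperamide_prophylaxis_cost(
        strategy.costs.loperamide
    )
    return AccrualMap(
        state_utilities=strategy.utilities.state_utilities(),
        state_cycle_costs=per_cycle,
        one_time_cost=one_time,
    )


@dataclass(frozen=True)
class CohortTrace:
    """State occupancy and discounted accruals over the horizon.

    ``occupancy`` has shape ``(n_cycles + 1, 4)`` (row 0 is the initial
    distribution).  ``per_cycle_cost`` / ``per_cycle_qaly`` hold discounted,
    correction-weighted accrual per cycle point (one-time costs appear in
    entry 0).
    """

    occupancy: np.ndarray
    per_cycle_cost: np.ndarray
    per_cycle_qaly: np.ndarray

    @property
    def total_cost(self) -> float:
        return float(self.per_cycle_cost.sum())

    @property
    def total_qaly(self) -> float:
        return float(self.per_cycle_qaly.sum())

    @property
    def death_fraction(self) -> float:
        return float(self.occupancy[-1, STATES.index("DE")])

    def final_distribution(self) -> dict[str, float]:
        return {s: float(self.occupancy[-1, i]) for i, s in enumerate(STATES)}

    def to_frame(self) -> pd.DataFrame:
        """Tidy per-cycle trace (cycle, state, occupancy, disc_cost, disc_qaly)."""
        n = self.occupancy.shape[0]
        rows = []
        for t in range(n):
            for i, s in enumerate(STATES):
                rows.append(dict(cycle=t, state=s, occupancy=self.occupancy[t, i]))
        df = pd.DataFrame(rows)
        acc = pd.DataFrame(
            dict(
                cycle=range(n),
                disc_cost=self.per_cycle_cost,
                disc_qaly=self.per_cycle_qaly,
            )
        )
        return df.merge(acc, on="cycle")


def run_cohort(
    matrix: TransitionMatrix, accrual: AccrualMap, settings: ModelSettings
) -> CohortTrace:
    """Run the cohort simulation and accrue discounted costs and QALYs."""
    n = settings.n_cycles
    if n < 1:
        raise DomainError("n_cycles must be >= 1")
    m = matrix.matrix
    occ = np.empty((n + 1, 4))
    occ[0] = settings.initial_distribution
    for t in range(1, n + 1):
        occ[t] = occ[t - 1] @ m

    u = np.array([accrual.state_utilities[s] for s in STATES])
    c = np.array([accrual.state_cycle_costs.get(s, 0.0) for s in STATES])
    t_idx = np.arange(n + 1)
    disc = (1.0 + settings.annual_discount_rate) ** (
        -t_idx * settings.cycle_days / 365.25
    )
    if settings.half_cycle_correction:
        w = np.ones(n + 1)
        w[0] = w[-1] = 0.5
    else:
        w = np.ones(n + 1)
        w[-1] = 0.0  # start-of-cycle counting over n cycles
    qaly = (occ @ u) * settings.cycle_years * disc * w
    cost = (occ @ c) * disc * w
    cost[0] += accrual.one_time_cost  # undiscounted at entry
    return CohortTrace(occupancy=occ, per_cycle_cost=cost, per_cycle_qaly=qaly)


@dataclass(frozen=True)
class StrategyResult:
    """One arm's assembled model and its simulated trace."""

    strategy: StrategyInputs
    matrix: TransitionMatrix
    accrual: AccrualMap
    trace: CohortTrace

    @property
    def total_cost(self) -> float:
        return self.trace.total_cost

    @property
    def total_qaly(self) -> float:
        return self.trace.total_qaly


def run_strategy(
    strategy: StrategyInputs,
    settings: ModelSettings,
    matrix: TransitionMatrix | None = None,
) -> StrategyResult:
    """Build (or accept) the transition matrix, run the cohort, return results."""
    if matrix is None:
        matrix = build_matrix(strategy.clinical, settings.rounding_mode)
    accrual = build_accrual(strategy, settings)
    trace = run_cohort(matrix, accrual, settings)
    return StrategyResult(strategy=strategy, matrix=matrix, accrual=accrual, trace=trace)
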