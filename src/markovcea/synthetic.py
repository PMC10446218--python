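"""Random but structurally valid two-arm scenario generation.

The generator emulates the statistical shape of a real third-line
metastatic-oncology comparison: each arm gets median OS, PFS (a fraction
of OS, so OS > PFS holds structurally), DoR, state utilities, drug unit
prices with dosing, an adverse-event profile and recurring care costs.
Sensitivity ranges follow the +-10% (probabilities, costs) / +-20%
(utilities) conventions and distribution tags are assigned by kind, so
every generated bundle passes the parameters-module validation and fits
PSA distributions without error.

``dor_min`` defaults to 3.0 months: below ~1.81 months the
remission->relapse probability exceeds 0.25 and the x4 stable->relapse
rule would break row-stochasticity; 3.0 keeps the stable row sum below
0.92 for any response fraction.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

from .parameters import (
    AdverseEvent,
    ClinicalSummary,
    CostSchedule,
    DomainError,
    DrugDosing,
    LoperamideSchedule,
    ModelSettings,
    OtherCost,
    StrategyInputs,
    UtilitySet,
    auto_range,
    default_family,
)
from .transitions import (
    build_matrix,
    p_relapse_to_death,
    p_remission_to_relapse,
    p_stable_to_remission,
)

__all__ = ["ScenarioSpec", "generate_scenario", "generate_edge_cases", "make_strategy"]

_AE_NAMES = ("diarrhea", "ppe_syndrome", "vomiting", "fatigue", "anemia")


@dataclass(frozen=True)
class ScenarioSpec:
    """Ranges from which a random two-arm scenario is drawn."""

    seed: int = 0
    os_range: tuple[float, float] = (12.0, 40.0)
    pfs_frac_range: tuple[float, float] = (0.2, 0.8)
    dor_min: float = 3.0
    dor_max_pfs_mult: float = 2.0
    u_stable_range: tuple[float, float] = (0.55, 0.9)
    u_remission_range: tuple[float, float] = (0.7, 0.95)
    u_relapse_range: tuple[float, float] = (0.3, 0.65)
    unit_price_range: tuple[float, float] = (0.5, 20.0)
    n_ae_range: tuple[int, int] = (3, 5)
    ae_incidence_range: tuple[float, float] = (0.02, 0.35)
    ae_cost_range: tuple[float, float] = (500.0, 9000.0)
    other_cost_range: tuple[float, float] = (1000.0, 6000.0)
    identical_arms: bool = False
    cycle_days: float = 21.0
    horizon_years: float = 5.0
    annual_discount_rate: float = 0.03

    def __post_init__(self) -> None:
        if self.dor_min <= 1.81:
            raise DomainError(
                "dor_min must exceed 1.81 months to keep the stable row stochastic"
            )
        if not 0.0 < self.pfs_frac_range[0] <= self.pfs_frac_range[1] < 1.0:
            raise DomainError("pfs_frac_range must lie inside (0, 1)")


def _random_clinical(rng: np.random.Generator, spec: ScenarioSpec) -> ClinicalSummary:
    os_m = rng.uniform(*spec.os_range)
    pfs = os_m * rng.uniform(*spec.pfs_frac_range)
    dor_hi = max(spec.dor_min + 0.5, spec.dor_max_pfs_mult * pfs)
    dor = rng.uniform(spec.dor_min, dor_hi)
    return ClinicalSummary(os_months=os_m, pfs_months=pfs, dor_months=dor)


def _random_strategy(
    rng: np.random.Generator, spec: ScenarioSpec, name: str
) -> StrategyInputs:
    clinical = _random_clinical(rng, spec)
    utilities = UtilitySet(
        stable=rng.uniform(*spec.u_stable_range),
        remission=rng.uniform(*spec.u_remission_range),
        relapse=rng.uniform(*spec.u_relapse_range),
    )
    n_drugs = int(rng.integers(1, 3))
    dosing = tuple(
        DrugDosing(
            drug=f"drug_{k}",
            dose_mg=float(rng.choice([150, 240, 500, 1000, 1250])),
            unit_mg=float(rng.choice([40, 150, 250])),
            unit_price=float(rng.uniform(*spec.unit_price_range)),
            admin_per_day=int(rng.integers(1, 3)),
            days_per_cycle=int(rng.choice([14, 21])),
            per_m2=bool(rng.integers(0, 2)),
        )
        for k in range(n_drugs)
    )
    n_ae = int(rng.integers(spec.n_ae_range[0], spec.n_ae_range[1] + 1))
    ae = tuple(
        AdverseEvent(
            event=_AE_NAMES[k],
            incidence=float(rng.uniform(*spec.ae_incidence_range)),
            cost_per_event=float(rng.uniform(*spec.ae_cost_range)),
        )
        for k in range(n_ae)
    )
    other = (
        OtherCost("hospitalization", float(rng.uniform(*spec.other_cost_range)), ("PD",)),
        OtherCost(
            "health_examinations", float(rng.uniform(*spec.other_cost_range)), ("SD", "RE")
        ),
    )
    costs = CostSchedule(dosing=dosing, ae_profile=ae, other_costs=other)
    strategy = StrategyInputs(
        name=name, clinical=clinical, costs=costs, utilities=utilities
    )
    return _with_auto_ranges(strategy)


def _with_auto_ranges(strategy: StrategyInputs) -> StrategyInputs:
    """Attach +-10%/+-20% sensitivity ranges and family tags to a strategy."""
    clin = strategy.clinical
    bases = {
        "p_stable_remission": p_stable_to_remission(clin.effective_rr),
        "p_remission_relapse": p_remission_to_relapse(clin.dor_months),
        "p_relapse_death": p_relapse_to_death(clin.os_months, clin.pfs_months),
        "u_stable": strategy.utilities.stable,
        "u_remission": strategy.utilities.remission,
        "u_relapse": strategy.utilities.relapse,
    }
    for d in strategy.costs.dosing:
        bases[f"price_{d.drug}"] = d.unit_price
    for a in strategy.costs.ae_profile:
        bases[f"cost_ae_{a.event}"] = a.cost_per_event
    for c in strategy.costs.other_costs:
        bases[f"cost_{c.name}"] = c.annual_amount
    ranges = {k: auto_range(k, v) for k, v in bases.items()}
    families = {k: default_family(k) for k in bases}
    return dataclasses.replace(strategy, sa_ranges=ranges, distributions=families)


def generate_scenario(
    spec: ScenarioSpec,
) -> tuple[tuple[StrategyInputs, StrategyInputs], ModelSettings]:
    """Draw a reproducible, fully valid two-arm scenario from ``spec``.

    The generated arms always satisfy OS > PFS > 0 and DoR >= dor_min, so
    both transition matrices assemble without rejection; this is checked
    before returning.
    """
    rng = np.random.default_rng(spec.seed)
    arm_a = _random_strategy(rng, spec, "arm_a")
    if spec.identical_arms:
        arm_b = dataclasses.replace(arm_a, name="arm_b")
    else:
        arm_b = _random_strategy(rng, spec, "arm_b")
    settings = ModelSettings(
        cycle_days=spec.cycle_days,
        horizon_years=spec.horizon_years,
        annual_discount_rate=spec.annual_discount_rate,
        rounding_mode="full_precision",
    )
    for arm in (arm_a, arm_b):
        build_matrix(arm.clinical)  # raises DomainError if the spec ranges break it
    return (arm_a, arm_b), settings


def make_strategy(
    name: str,
    os_months: float,
    pfs_months: float,
    dor_months: float,
    u_stable: float = 0.74,
    u_remission: float = 0.85,
    u_relapse: float = 0.5,
    drug_price: float = 10.0,
    with_costs: bool = True,
) -> StrategyInputs:
    """Minimal hand-built strategy for tests and edge cases."""
    dosing = (
        (DrugDosing(drug="drug", dose_mg=200, unit_mg=100, unit_price=drug_price),)
        if with_costs
        else ()
    )
    other = (
        (OtherCost("hospitalization", 3000.0, ("PD",)),) if with_costs else ()
    )
    strategy = StrategyInputs(
        name=name,
        clinical=ClinicalSummary(
            os_months=os_months, pfs_months=pfs_months, dor_months=dor_months
        ),
        costs=CostSchedule(dosing=dosing, other_costs=other),
        utilities=UtilitySet(stable=u_stable, remission=u_remission, relapse=u_relapse),
    )
    return _with_auto_ranges(strategy)


def generate_edge_cases() -> list[tuple[str, tuple[StrategyInputs, StrategyInputs], ModelSettings]]:
    """Named stress-case bundles probing the model's structural boundaries."""
    default = ModelSettings(rounding_mode="full_precision")
    no_discount = ModelSettings(
        annual_discount_rate=0.0, rounding_mode="full_precision"
    )
    cases = []

    near_immortal = make_strategy("near_immortal", 2000.0, 1000.0, 60.0)
    cases.append(("near_immortal", (near_immortal, make_strategy("ref", 24, 8.8, 8.5)), default))

    quick_death = make_strategy("near_instant_death", 6.0, 5.9, 3.1)
    cases.append(("near_instant_death", (quick_death, make_strategy("ref", 24, 8.8, 8.5)), default))

    # remission->relapse near the 0.25 boundary of the x4 stable->relapse rule:
    # DoR = 1.8502 gives p_rp ~ 0.245, p_sp ~ 0.98; a tiny response fraction
    # keeps the stable row just below 1.
    boundary = make_strategy("relapse_boundary", 100.0, 94.0, 1.8502)
    cases.append(("relapse_boundary", (boundary, make_strategy("ref", 24, 8.8, 8.5)), default))

    zero_cost = make_strategy("zero_cost", 24.0, 8.8, 8.5, with_costs=False)
    cases.append(("zero_cost", (zero_cost, make_strategy("ref", 22, 6.6, 5.6)), default))

    utility_one = make_strategy(
        "utility_one", 5000.0, 2500.0, 60.0, u_stable=1.0, u_remission=1.0, u_relapse=1.0
    )
    cases.append(("utility_one", (utility_one, make_strategy("ref", 24, 8.8, 8.5)), no_discount))
    return cases
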