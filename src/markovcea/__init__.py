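"""Markov cohort cost-effectiveness analysis for two-arm oncology comparisons.

``markovcea`` implements a four-state (stable disease, remission,
progressive disease, death), half-cycle-corrected Markov cohort model with
DEALE-derived transition probabilities, discounted cost/QALY accrual,
ICER/NMB economics, tornado-style one-way sensitivity analysis and
second-order Monte-Carlo probabilistic sensitivity analysis with
acceptability curves.  It ships the published reference scenario of
third-line neratinib+capecitabine versus lapatinib+capecitabine for
HER2-positive metastatic breast cancer, and a generator of random but
structurally valid scenarios for testing.

Typical use::

    import markovcea as mc

    strategies, settings = mc.reference_scenario("whole_group")
    result = mc.run_scenario(strategies, settings)
    print(result.delta_qaly, result.icer, result.decision)
"""

from __future__ import annotations

from .economics import (
    CEResult,
    DecisionTier,
    IcerResult,
    classify_decision,
    compare,
    compute_icer,
    compute_nmb,
)
from .engine import (
    AccrualMap,
    CohortTrace,
    StrategyResult,
    build_accrual,
    cycle_drug_cost,
    discount_factor,
    expected_ae_cost,
    loperamide_prophylaxis_cost,
    run_cohort,
    run_strategy,
)
from .parameters import (
    REPORTED_RESULTS,
    STATES,
    AdverseEvent,
    ClinicalSummary,
    ConfigError,
    CostSchedule,
    DomainError,
    DrugDosing,
    LoperamideSchedule,
    ModelSettings,
    OtherCost,
    StrategyInputs,
    UtilitySet,
    load_config,
    reference_scenario,
    save_config,
)
from .sensitivity import (
    DsaRow,
    ModelBundle,
    ModelParameter,
    ParameterDistribution,
    PsaResult,
    build_parameters,
    ceac,
    evaluate,
    fit_distribution,
    one_way_dsa,
    run_psa,
)
from .synthetic import ScenarioSpec, generate_edge_cases, generate_scenario
from .transitions import (
    TransitionMatrix,
    build_matrix,
    derive_rr,
    p_relapse_to_death,
    p_remission_to_relapse,
    p_stable_to_relapse,
    p_stable_to_remission,
)

__version__ = "0.1.0"


def run_scenario(strategies, settings) -> CEResult:
    """Run both arms of a scenario and return the paired economics."""
    a = run_strategy(strategies[0], settings)
    b = run_strategy(strategies[1], settings)
    return compare(a, b, settings)
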