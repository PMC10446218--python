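"""Programmatic construction of the bundled reference scenarios.

These are the exact published inputs of the third-line HER2+ metastatic
breast cancer comparison the package reproduces: the ``whole_group``
scenario carries the full-population clinical summaries, unit costs,
grade 3/4 adverse-event profile and sensitivity ranges; ``asian_subgroup``
swaps in the Asian-subgroup OS/PFS/DoR.  The bundled YAML files under
``scenarios/`` are the serialized form of these builders and are kept in
lockstep by a snapshot test.
"""

from __future__ import annotations

from .parameters import (
    AdverseEvent,
    ClinicalSummary,
    ConfigError,
    CostSchedule,
    DrugDosing,
    LoperamideSchedule,
    ModelSettings,
    OtherCost,
    StrategyInputs,
    UtilitySet,
    auto_range,
)
from .transitions import build_matrix

__all__ = ["build_reference_bundle"]

_UTILITIES = UtilitySet(
    stable=0.74,  # no recurrence, chemotherapeutic period
    remission=0.85,
    relapse=0.5,
    extras={
        "no_recurrence_post_chemo": 0.94,  # no four-state counterpart
        "local_recurrence_year1": 0.74,
    },
)

_UTILITY_RANGES = {
    "u_stable": (0.592, 0.888),
    "u_remission": (0.680, 1.000),
    "u_relapse": (0.400, 0.600),
}

_AE_COST = {
    "diarrhea": 4083.63,
    "ppe_syndrome": 2316.0,
    "vomiting": 945.63,
    "fatigue": 1158.04,
    "anemia": 7350.98,
}

_AE_COST_RANGES = {
    "cost_ae_diarrhea": (3675.267, 4491.993),
    "cost_ae_ppe_syndrome": (2084.400, 2547.600),
    "cost_ae_vomiting": (851.067, 1040.193),
    "cost_ae_fatigue": (1042.236, 1273.844),
    "cost_ae_anemia": (6615.882, 8086.078),
}

_AE_INCIDENCE = {
    "nc": {
        "diarrhea": 0.307,
        "ppe_syndrome": 0.120,
        "vomiting": 0.050,
        "fatigue": 0.037,
        "anemia": 0.024,
    },
    "lc": {
        "diarrhea": 0.143,
        "ppe_syndrome": 0.138,
        "vomiting": 0.024,
        "fatigue": 0.040,
        "anemia": 0.044,
    },
}

_OTHER_COSTS = (
    OtherCost("hospitalization", 3200.0, ("PD",)),
    OtherCost("concomitant_medications", 2176.0, ("PD",)),
    OtherCost("health_examinations", 4552.0, ("SD", "RE")),
)

_OTHER_COST_RANGES = {
    "cost_hospitalization": (2880.0, 3520.0),
    "cost_concomitant_medications": (1958.4, 2393.6),
    "cost_health_examinations": (4096.8, 5007.2),
}

_PROB_RANGES = {
    "nc": {
        "p_stable_stable": (0.5175, 0.6325),
        "p_stable_remission": (0.1701, 0.2079),
        "p_stable_relapse": (0.2124, 0.2596),
        "p_remission_remission": (0.8469, 1.0000),
        "p_remission_relapse": (0.0531, 0.0649),
        "p_relapse_relapse": (0.8694, 1.0000),
        "p_relapse_death": (0.0306, 0.0374),
    },
    "lc": {
        "p_stable_stable": (0.3960, 0.4840),
        "p_stable_remission": (0.1872, 0.2288),
        "p_stable_relapse": (0.3168, 0.3872),
        "p_remission_remission": (0.8208, 1.0000),
        "p_remission_relapse": (0.0792, 0.0968),
        "p_relapse_relapse": (0.8703, 1.0000),
        "p_relapse_death": (0.0297, 0.0363),
    },
}

_CAPECITABINE_PRICE_RANGE = (0.540, 0.660)


def _nc_costs() -> CostSchedule:
    return CostSchedule(
        bsa_m2=1.67,
        dosing=(
            DrugDosing(
                drug="neratinib",
                dose_mg=240.0,
                unit_mg=40.0,
                unit_price=13.46,
                admin_per_day=1,
                days_per_cycle=21,
                per_m2=False,
            ),
            DrugDosing(
                drug="capecitabine",
                dose_mg=1500.0,
                unit_mg=150.0,
                unit_price=0.6,
                admin_per_day=2,
                days_per_cycle=14,
                per_m2=True,
            ),
        ),
        loperamide=LoperamideSchedule(unit_price=0.23),
        ae_profile=tuple(
            AdverseEvent(e, _AE_INCIDENCE["nc"][e], _AE_COST[e]) for e in _AE_COST
        ),
        other_costs=_OTHER_COSTS,
    )


def _lc_costs() -> CostSchedule:
    return CostSchedule(
        bsa_m2=1.67,
        dosing=(
            DrugDosing(
                drug="lapatinib",
                dose_mg=1250.0,
                unit_mg=250.0,
                unit_price=16.12,
                admin_per_day=1,
                days_per_cycle=21,
                per_m2=False,
            ),
            DrugDosing(
                drug="capecitabine",
                dose_mg=2000.0,
                unit_mg=150.0,
                unit_price=0.6,
                admin_per_day=2,
                days_per_cycle=14,
                per_m2=True,
            ),
        ),
        loperamide=None,
        ae_profile=tuple(
            AdverseEvent(e, _AE_INCIDENCE["lc"][e], _AE_COST[e]) for e in _AE_COST
        ),
        other_costs=_OTHER_COSTS,
    )


def _cost_ranges(arm: str) -> tuple[dict, dict]:
    ranges = dict(_AE_COST_RANGES)
    ranges.update(_OTHER_COST_RANGES)
    ranges["price_capecitabine"] = _CAPECITABINE_PRICE_RANGE
    if arm == "nc":
        ranges["price_neratinib"] = (12.114, 14.806)
        ranges["price_loperamide"] = (0.207, 0.253)
    else:
        ranges["price_lapatinib"] = (14.508, 17.732)
    families = {k: "gamma" for k in ranges}
    return ranges, families


def _strategy(arm: str, clinical: ClinicalSummary, prob_ranges: dict) -> StrategyInputs:
    cost_ranges, cost_fams = _cost_ranges(arm)
    sa = dict(prob_ranges)
    sa.update(_UTILITY_RANGES)
    sa.update(cost_ranges)
    fams = {k: "beta" for k in prob_ranges}
    fams.update({k: "beta" for k in _UTILITY_RANGES})
    fams.update(cost_fams)
    return StrategyInputs(
        name="neratinib+capecitabine" if arm == "nc" else "lapatinib+capecitabine",
        clinical=clinical,
        costs=_nc_costs() if arm == "nc" else _lc_costs(),
        utilities=_UTILITIES,
        sa_ranges=sa,
        distributions=fams,
    )


def _auto_prob_ranges(clinical: ClinicalSummary, rounding_mode: str) -> dict:
    """+-10% ranges around the derived per-cycle probabilities (complements
    clamped to 1), for scenarios whose source prints none."""
    prims = build_matrix(clinical, rounding_mode).primitives
    bases = {
        "p_stable_remission": prims["sr"],
        "p_stable_relapse": prims["sp"],
        "p_remission_relapse": prims["rp"],
        "p_relapse_death": prims["pd"],
        "p_stable_stable": 1.0 - prims["sr"] - prims["sp"],
        "p_remission_remission": 1.0 - prims["rp"],
        "p_relapse_relapse": 1.0 - prims["pd"],
    }
    return {k: auto_range(k, v) for k, v in bases.items()}


def build_reference_bundle(
    name: str,
) -> tuple[tuple[StrategyInputs, StrategyInputs], ModelSettings]:
    """Build a reference scenario from code (``whole_group`` / ``asian_subgroup``)."""
    settings = ModelSettings(rounding_mode="published_3dp")
    if name == "whole_group":
        nc = _strategy(
            "nc",
            ClinicalSummary(os_months=24.0, pfs_months=8.8, dor_months=8.5, rr=0.63),
            _PROB_RANGES["nc"],
        )
        lc = _strategy(
            "lc",
            ClinicalSummary(os_months=22.0, pfs_months=6.6, dor_months=5.6, rr=0.7),
            _PROB_RANGES["lc"],
        )
        return (nc, lc), settings
    if name == "asian_subgroup":
        nc_clin = ClinicalSummary(os_months=23.8, pfs_months=7.0, dor_months=11.1)
        lc_clin = ClinicalSummary(os_months=18.7, pfs_months=5.4, dor_months=4.2)
        nc = _strategy("nc", nc_clin, _auto_prob_ranges(nc_clin, settings.rounding_mode))
        lc = _strategy("lc", lc_clin, _auto_prob_ranges(lc_clin, settings.rounding_mode))
        return (nc, lc), settings
    raise ConfigError(f"unknown scenario {name!r}")
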