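"""Pairwise cost-effectiveness arithmetic: ICER, NMB, dominance, WTP tiers.

Definitions (strategy A vs comparator B):

* increments  dC = cost_A - cost_B, dE = qaly_A - qaly_B
* ICER = dC / dE (undefined when dE = 0; tagged, never thrown)
* NMB(strategy) = WTP x QALYs - cost; A is preferred iff NMB_A > NMB_B
* decision tiers follow the per-capita-GDP banding used in Chinese
  pharmacoeconomic guidelines: an ICER below 1x GDP is cost-effective,
  between 1x and 3x GDP acceptable, above 3x GDP not worthwhile;
  dominance (cheaper and more effective) short-circuits the banding.

Negative ICERs are reported as-is together with their CE-plane quadrant,
since the bare ratio is ambiguous (cost-saving/QALY-gaining and
cost-increasing/QALY-losing draws both give negative ratios).
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass

from .engine import StrategyResult
from .parameters import DomainError, ModelSettings

__all__ = [
    "DecisionTier",
    "IcerResult",
    "CEResult",
    "compute_icer",
    "compute_nmb",
    "classify_decision",
    "compare",
]


class DecisionTier(enum.Enum):
    DOMINANT = "dominant"
    COST_EFFECTIVE = "cost_effective"
    ACCEPTABLE = "acceptable"
    NOT_WORTHWHILE = "not_worthwhile"
    DOMINATED = "dominated"
    INDIFFERENT = "indifferent"


@dataclass(frozen=True)
class IcerResult:
    """Incremental comparison of strategy A against comparator B."""

    delta_cost: float
    delta_qaly: float
    icer: float | None  #: None when delta_qaly == 0
    tag: str  #: quadrant / degeneracy tag

    @property
    def quadrant(self) -> str:
        return self.tag


def _quadrant_tag(dc: float, de: float) -> str:
    if de == 0.0 and dc == 0.0:
        return "indifferent"
    if de == 0.0:
        return "cost_saving_equal_effect" if dc < 0 else "cost_increasing_equal_effect"
    if de > 0:
        return "dominant" if dc < 0 else "more_costly_more_effective"
    return "cost_saving_less_effective" if dc < 0 else "dominated"


def compute_icer(
    cost_a: float, cost_b: float, qaly_a: float, qaly_b: float
) -> IcerResult:
    """Increments and ICER of A vs B; degenerate cases are tagged, not thrown."""
    for v in (cost_a, cost_b, qaly_a, qaly_b):
        if not math.isfinite(v):
            raise DomainError("costs and QALYs must be finite")
    dc = cost_a - cost_b
    de = qaly_a - qaly_b
    icer = dc / de if de != 0.0 else None
    return IcerResult(delta_cost=dc, delta_qaly=de, icer=icer, tag=_quadrant_tag(dc, de))


def compute_nmb(cost: float, qaly: float, wtp: float) -> float:
    """Net monetary benefit ``wtp x qaly - cost``."""
    if wtp < 0:
        raise DomainError("wtp must be >= 0")
    return wtp * qaly - cost


def classify_decision(icer_result: IcerResult, gdp_per_capita: float) -> DecisionTier:
    """GDP-band decision tier for strategy A vs B.

    Total over all inputs: dominance/dominated quadrants short-circuit; in
    the NE quadrant the ICER is banded against 1x/3x GDP; in the SW
    quadrant (cost saving, QALYs lost) the banding is inverted — savings
    per QALY forgone above 3x GDP make A preferable at the threshold.
    """
    if gdp_per_capita <= 0:
        raise DomainError("gdp_per_capita must be > 0")
    dc, de = icer_result.delta_cost, icer_result.delta_qaly
    if de == 0.0:
        if dc == 0.0:
            return DecisionTier.INDIFFERENT
        return DecisionTier.DOMINANT if dc < 0 else DecisionTier.DOMINATED
    if de > 0 and dc < 0:
        return DecisionTier.DOMINANT
    if de < 0 and dc > 0:
        return DecisionTier.DOMINATED
    icer = icer_result.icer
    assert icer is not None
    if de > 0:  # paying for QALYs gained
        if icer < gdp_per_capita:
            return DecisionTier.COST_EFFECTIVE
        if icer <= 3.0 * gdp_per_capita:
            return DecisionTier.ACCEPTABLE
        return DecisionTier.NOT_WORTHWHILE
    # de < 0, dc < 0: saving money at the price of QALYs
    if icer > 3.0 * gdp_per_capita:
        return DecisionTier.COST_EFFECTIVE
    if icer >= gdp_per_capita:
        return DecisionTier.ACCEPTABLE
    return DecisionTier.NOT_WORTHWHILE


@dataclass(frozen=True)
class CEResult:
    """Full paired-strategy economics (A vs comparator B)."""

    name_a: str
    name_b: str
    cost_a: float
    cost_b: float
    qaly_a: float
    qaly_b: float
    nmb_a: float
    nmb_b: float
    delta_cost: float
    delta_qaly: float
    icer: float | None
    icer_tag: str
    decision: DecisionTier
    wtp: float
    gdp_per_capita: float

    def to_dict(self) -> dict:
        d = {k: getattr(self, k) for k in self.__dataclass_fields__}
        d["decision"] = self.decision.value
        return d


def compare(
    result_a: StrategyResult, result_b: StrategyResult, settings: ModelSettings
) -> CEResult:
    """Pairwise economics of two simulated strategies at the settings' WTP/GDP."""
    inc = compute_icer(
        result_a.total_cost, result_b.total_cost, result_a.total_qaly, result_b.total_qaly
    )
    wtp = settings.wtp_per_qaly
    return CEResult(
        name_a=result_a.strategy.name,
        name_b=result_b.strategy.name,
        cost_a=result_a.total_cost,
        cost_b=result_b.total_cost,
        qaly_a=result_a.total_qaly,
        qaly_b=result_b.total_qaly,
        nmb_a=compute_nmb(result_a.total_cost, result_a.total_qaly, wtp),
        nmb_b=compute_nmb(result_b.total_cost, result_b.total_qaly, wtp),
        delta_cost=inc.delta_cost,
        delta_qaly=inc.delta_qaly,
        icer=inc.icer,
        icer_tag=inc.tag,
        decision=classify_decision(inc, settings.gdp_per_capita),
        wtp=wtp,
        gdp_per_capita=settings.gdp_per_capita,
    )
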