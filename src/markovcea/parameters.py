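"""Typed model inputs, config I/O and bundled reference scenarios.

The model compares two treatment strategies for third-line HER2-positive
metastatic breast cancer.  Each strategy is summarised by four clinical
quantities (median overall survival OS, median progression-free survival
PFS, median duration of response DoR, and a response-like fraction
RR = (OS - PFS)/OS), a cost schedule (drug dosing and unit prices, adverse
event management, recurring care costs), a set of health-state utilities,
and per-parameter sensitivity-analysis ranges with distribution tags.

Two reference scenarios are bundled as YAML files: ``whole_group`` (the
full trial population) and ``asian_subgroup``.  Their values are the ones
reported in the published source analysis.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml

__all__ = [
    "STATES",
    "ConfigError",
    "DomainError",
    "ClinicalSummary",
    "UtilitySet",
    "DrugDosing",
    "LoperamideSchedule",
    "AdverseEvent",
    "OtherCost",
    "CostSchedule",
    "StrategyInputs",
    "ModelSettings",
    "auto_range",
    "load_config",
    "save_config",
    "config_to_json",
    "parameter_table",
    "reference_scenario",
    "REPORTED_RESULTS",
]

#: Health states, in matrix order: stable disease, remission, progressive
#: disease (relapse), death (absorbing).
STATES = ("SD", "RE", "PD", "DE")

SCHEMA_VERSION = 1

#: Summary results reported by the published analysis, used only for
#: side-by-side display in reports (never as model inputs).
REPORTED_RESULTS = {
    "whole_group": {
        "cost": (31803.33, 33664.61),
        "qaly": (2.24, 2.07),
        "icer": -13294.86,
        "nmb": (39788.07, 32876.84),
    },
    "asian_subgroup": {
        "cost": (30742.90, 31305.98),
        "qaly": (2.49, 2.26),
        "icer": -2448.17,
        "nmb": (49022.57, 41265.83),
    },
}


class ConfigError(ValueError):
    """A configuration file or mapping violates the documented schema."""


class DomainError(ValueError):
    """A value is outside the domain the model requires (e.g. OS <= PFS)."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ClinicalSummary:
    """Median-based clinical efficacy summary for one strategy.

    Parameters
    ----------
    os_months, pfs_months, dor_months
        Median overall survival, progression-free survival and duration of
        response, in months.  Requires ``os > pfs > 0`` and ``dor > 0``.
    rr
        Response-like fraction ``(OS - PFS) / OS``.  If omitted it is
        derived from the medians; a stored value lets a scenario carry the
        rounded figure reported in its source.
    """

    os_months: float
    pfs_months: float
    dor_months: float
    rr: float | None = None

    def __post_init__(self) -> None:
        if not self.pfs_months > 0:
            raise DomainError(f"pfs_months must be > 0, got {self.pfs_months}")
        if not self.os_months > self.pfs_months:
            raise DomainError(
                f"os_months ({self.os_months}) must exceed pfs_months "
                f"({self.pfs_months})"
            )
        if not self.dor_months > 0:
            raise DomainError(f"dor_months must be > 0, got {self.dor_months}")
        if self.rr is not None and not 0.0 < self.rr < 1.0:
            raise DomainError(f"rr must be in (0, 1), got {self.rr}")

    @property
    def effective_rr(self) -> float:
        """Stored ``rr`` if present, else ``(OS - PFS)/OS``."""
        if self.rr is not None:
            return self.rr
        return (self.os_months - self.pfs_months) / self.os_months


@dataclass(frozen=True)
class UtilitySet:
    """Health-state utility weights in [0, 1]; death is fixed at 0.

    ``extras`` carries published utilities with no matching state in the
    four-state model (e.g. post-chemotherapy no-recurrence); they are kept
    for provenance but never enter the QALY accrual.
    """

    stable: float
    remission: float
    relapse: float
    death: float = 0.0
    extras: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("stable", "remission", "relapse", "death"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise DomainError(f"utility {name}={v} outside [0, 1]")
        if self.death != 0.0:
            raise DomainError("death utility must be 0")

    def state_utilities(self) -> dict[str, float]:
        """Map matrix states to utilities (SD->stable, RE->remission, PD->relapse)."""
        return {
            "SD": self.stable,
            "RE": self.remission,
            "PD": self.relapse,
            "DE": self.death,
        }


@dataclass(frozen=True)
class DrugDosing:
    """One drug's dosing rule within a 21-day cycle.

    ``dose_mg`` is per administration; if ``per_m2`` it is multiplied by
    body surface area.  Dispensed units per administration are
    ``ceil(dose / unit_mg)`` (tablets cannot be split).
    """

    drug: str
    dose_mg: float
    unit_mg: float
    unit_price: float
    admin_per_day: int = 1
    days_per_cycle: int = 21
    per_m2: bool = False

    def __post_init__(self) -> None:
        if self.dose_mg < 0 or self.unit_mg <= 0:
            raise DomainError(f"invalid dosing for {self.drug}")
        if self.unit_price < 0:
            raise DomainError(f"negative unit price for {self.drug}")

    def units_per_admin(self, bsa_m2: float) -> int:
        dose = self.dose_mg * (bsa_m2 if self.per_m2 else 1.0)
        return int(math.ceil(dose / self.unit_mg)) if dose > 0 else 0


@dataclass(frozen=True)
class LoperamideSchedule:
    """Antidiarrheal prophylaxis over the first cycle (2 mg tablets).

    Default counts encode: 4 mg loading (2 tablets), then 2 mg every 4 h
    for 3 days (6/day), then 2 mg every 6 h for the remaining 18 days of
    the first cycle (4/day) — 92 tablets in total.  An every-8-h reading
    of the maintenance phase is expressed by ``maintenance_doses_per_day=3``.
    """

    unit_price: float = 0.23
    initial_doses: int = 2
    intensive_days: int = 3
    intensive_doses_per_day: int = 6
    maintenance_days: int = 18
    maintenance_doses_per_day: int = 4

    def __post_init__(self) -> None:
        if self.unit_price < 0:
            raise DomainError("negative loperamide unit price")

    @property
    def tablet_count(self) -> int:
        return (
            self.initial_doses
            + self.intensive_days * self.intensive_doses_per_day
            + self.maintenance_days * self.maintenance_doses_per_day
        )


@dataclass(frozen=True)
class AdverseEvent:
    """A grade 3/4 adverse event: incidence fraction and per-event cost."""

    event: str
    incidence: float
    cost_per_event: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.incidence <= 1.0:
            raise DomainError(f"incidence for {self.event} outside [0, 1]")
        if self.cost_per_event < 0:
            raise DomainError(f"negative cost for {self.event}")


@dataclass(frozen=True)
class OtherCost:
    """A recurring care cost accrued in given states (amount per year)."""

    name: str
    annual_amount: float
    states: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.annual_amount < 0:
            raise DomainError(f"negative amount for {self.name}")
        for s in self.states:
            if s not in STATES:
                raise ConfigError(f"unknown state {s!r} in cost {self.name}")


@dataclass(frozen=True)
class CostSchedule:
    """All monetary inputs for one strategy (USD, 2022 price year)."""

    dosing: tuple[DrugDosing, ...]
    ae_profile: tuple[AdverseEvent, ...] = ()
    other_costs: tuple[OtherCost, ...] = ()
    loperamide: LoperamideSchedule | None = None
    bsa_m2: float = 1.67

    def __post_init__(self) -> None:
        if not self.bsa_m2 > 0:
            raise DomainError(f"bsa_m2 must be > 0, got {self.bsa_m2}")


@dataclass(frozen=True)
class StrategyInputs:
    """One treatment arm: clinical summary, costs, utilities, SA metadata.

    ``sa_ranges`` maps canonical parameter ids (``p_*``, ``u_*``,
    ``price_*``, ``cost_*``) to (low, high) bounds; ``distributions`` tags
    each with its sampling family (``beta`` for probabilities/utilities,
    ``gamma`` for costs).
    """

    name: str
    clinical: ClinicalSummary
    costs: CostSchedule
    utilities: UtilitySet
    sa_ranges: Mapping[str, tuple[float, float]] = field(default_factory=dict)
    distributions: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for pid, (lo, hi) in self.sa_ranges.items():
            if not lo <= hi:
                raise ConfigError(f"sa_range for {pid} has low > high")
            fam = self.distributions.get(pid)
            if fam is None:
                raise ConfigError(f"parameter {pid} has a range but no distribution")
            if fam not in ("beta", "gamma"):
                raise ConfigError(f"unknown distribution {fam!r} for {pid}")
            expect = "gamma" if pid.startswith(("price_", "cost_")) else "beta"
            if fam != expect:
                raise ConfigError(
                    f"{pid}: distribution {fam!r} does not match parameter kind "
                    f"(expected {expect!r})"
                )


@dataclass(frozen=True)
class ModelSettings:
    """Global simulation settings.

    The horizon is truncated to whole cycles: ``n_cycles =
    floor(horizon_years * 365.25 / cycle_days)`` (86 cycles for the default
    5-year horizon with 21-day cycles), so the simulated horizon never
    exceeds the stated one.
    """

    cycle_days: float = 21.0
    horizon_years: float = 5.0
    annual_discount_rate: float = 0.03
    wtp_per_qaly: float = 36000.0
    gdp_per_capita: float = 12000.0
    initial_distribution: tuple[float, float, float, float] = (1.0, 0.0, 0.0, 0.0)
    half_cycle_correction: bool = True
    rounding_mode: str = "full_precision"

    def __post_init__(self) -> None:
        if self.annual_discount_rate < 0:
            raise DomainError("annual discount rate must be >= 0")
        if self.cycle_days <= 0 or self.horizon_years <= 0:
            raise DomainError("cycle_days and horizon_years must be > 0")
        if self.wtp_per_qaly < 0 or self.gdp_per_capita <= 0:
            raise DomainError("wtp must be >= 0 and gdp > 0")
        if abs(sum(self.initial_distribution) - 1.0) > 1e-9:
            raise DomainError("initial_distribution must sum to 1")
        if any(p < 0 for p in self.initial_distribution):
            raise DomainError("initial_distribution entries must be >= 0")
        from .transitions import ROUNDING_MODES  # local import, no cycle at module load

        if self.rounding_mode not in ROUNDING_MODES:
            raise ConfigError(f"unknown rounding_mode {self.rounding_mode!r}")

    @property
    def n_cycles(self) -> int:
        return int(math.floor(self.horizon_years * 365.25 / self.cycle_days))

    @property
    def cycle_years(self) -> float:
        return self.cycle_days / 365.25


# ---------------------------------------------------------------------------
# SA range conventions
# ---------------------------------------------------------------------------


def auto_range(pid: str, base: float) -> tuple[float, float]:
    """Default sensitivity range for a parameter without a published one.

    +-10% for probabilities and costs, +-20% for utilities; probability and
    utility ranges are clamped to [0, 1].
    """
    frac = 0.2 if pid.startswith("u_") else 0.1
    lo, hi = base * (1 - frac), base * (1 + frac)
    if pid.startswith(("p_", "u_")):
        lo, hi = max(lo, 0.0), min(hi, 1.0)
    return (lo, hi)


def default_family(pid: str) -> str:
    return "gamma" if pid.startswith(("price_", "cost_")) else "beta"


# ---------------------------------------------------------------------------
# serialisation
# ---------------------------------------------------------------------------


def _strategy_to_dict(s: StrategyInputs) -> dict:
    return {
        "name": s.name,
        "clinical": {
            "rr": s.clinical.rr,
            "os_months": s.clinical.os_months,
            "pfs_months": s.clinical.pfs_months,
            "dor_months": s.clinical.dor_months,
        },
        "utilities": {
            "stable": s.utilities.stable,
            "remission": s.utilities.remission,
            "relapse": s.utilities.relapse,
            "death": s.utilities.death,
            "extras": dict(s.utilities.extras),
        },
        "costs": {
            "bsa_m2": s.costs.bsa_m2,
            "dosing": [dataclasses.asdict(d) for d in s.costs.dosing],
            "loperamide": (
                dataclasses.asdict(s.costs.loperamide)
                if s.costs.loperamide is not None
                else None
            ),
            "ae_profile": [dataclasses.asdict(a) for a in s.costs.ae_profile],
            "other_costs": [
                {"name": c.name, "annual_amount": c.annual_amount, "states": list(c.states)}
                for c in s.costs.other_costs
            ],
        },
        "sa_ranges": {k: list(v) for k, v in s.sa_ranges.items()},
        "distributions": dict(s.distributions),
    }


def _settings_to_dict(st: ModelSettings) -> dict:
    return {
        "cycle_days": st.cycle_days,
        "horizon_years": st.horizon_years,
        "annual_discount_rate": st.annual_discount_rate,
        "wtp_per_qaly": st.wtp_per_qaly,
        "gdp_per_capita": st.gdp_per_capita,
        "initial_distribution": {s: p for s, p in zip(STATES, st.initial_distribution)},
        "half_cycle_correction": st.half_cycle_correction,
        "rounding_mode": st.rounding_mode,
    }


def _require(mapping: Mapping, key: str, ctx: str):
    if key not in mapping:
        raise ConfigError(f"missing required field {key!r} in {ctx}")
    return mapping[key]


def _strategy_from_dict(d: Mapping) -> StrategyInputs:
    name = _require(d, "name", "strategy")
    clin = _require(d, "clinical", f"strategy {name}")
    cost = _require(d, "costs", f"strategy {name}")
    util = _require(d, "utilities", f"strategy {name}")
    try:
        clinical = ClinicalSummary(
            os_months=float(_require(clin, "os_months", "clinical")),
            pfs_months=float(_require(clin, "pfs_months", "clinical")),
            dor_months=float(_require(clin, "dor_months", "clinical")),
            rr=None if clin.get("rr") is None else float(clin["rr"]),
        )
    except TypeError as exc:  # non-numeric field
        raise ConfigError(f"invalid clinical block in strategy {name}: {exc}") from exc
    utilities = UtilitySet(
        stable=float(_require(util, "stable", "utilities")),
        remission=float(_require(util, "remission", "utilities")),
        relapse=float(_require(util, "relapse", "utilities")),
        death=float(util.get("death", 0.0)),
        extras=dict(util.get("extras", {})),
    )
    lop = cost.get("loperamide")
    costs = CostSchedule(
        bsa_m2=float(cost.get("bsa_m2", 1.67)),
        dosing=tuple(DrugDosing(**dd) for dd in cost.get("dosing", [])),
        loperamide=None if lop is None else LoperamideSchedule(**lop),
        ae_profile=tuple(AdverseEvent(**a) for a in cost.get("ae_profile", [])),
        other_costs=tuple(
            OtherCost(
                name=c["name"],
                annual_amount=float(c["annual_amount"]),
                states=tuple(c["states"]),
            )
            for c in cost.get("other_costs", [])
        ),
    )
    return StrategyInputs(
        name=name,
        clinical=clinical,
        costs=costs,
        utilities=utilities,
        sa_ranges={k: (float(v[0]), float(v[1])) for k, v in d.get("sa_ranges", {}).items()},
        distributions=dict(d.get("distributions", {})),
    )


def _settings_from_dict(d: Mapping) -> ModelSettings:
    init = d.get("initial_distribution", {"SD": 1.0})
    dist = tuple(float(init.get(s, 0.0)) for s in STATES)
    return ModelSettings(
        cycle_days=float(d.get("cycle_days", 21.0)),
        horizon_years=float(d.get("horizon_years", 5.0)),
        annual_discount_rate=float(d.get("annual_discount_rate", 0.03)),
        wtp_per_qaly=float(d.get("wtp_per_qaly", 36000.0)),
        gdp_per_capita=float(d.get("gdp_per_capita", 12000.0)),
        initial_distribution=dist,
        half_cycle_correction=bool(d.get("half_cycle_correction", True)),
        rounding_mode=str(d.get("rounding_mode", "full_precision")),
    )


def config_to_dict(
    strategies: Sequence[StrategyInputs], settings: ModelSettings
) -> dict:
    return {
        "schema_version": SCHEMA_VERSION,
        "settings": _settings_to_dict(settings),
        "strategies": [_strategy_to_dict(s) for s in strategies],
    }


def save_config(
    path: str | Path, strategies: Sequence[StrategyInputs], settings: ModelSettings
) -> None:
    """Write a scenario to the documented YAML schema."""
    Path(path).write_text(
        yaml.safe_dump(config_to_dict(strategies, settings), sort_keys=False)
    )


def load_config(path: str | Path) -> tuple[tuple[StrategyInputs, ...], ModelSettings]:
    """Load and fully validate a scenario config.

    Raises
    ------
    ConfigError
        On schema violations (missing/unknown fields, bad distribution tags).
    DomainError
        On domain violations (e.g. ``os_months <= pfs_months``).
    """
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    raw = yaml.safe_load(path.read_text())
    return _config_from_mapping(raw)


def _config_from_mapping(raw) -> tuple[tuple[StrategyInputs, ...], ModelSettings]:
    if not isinstance(raw, Mapping):
        raise ConfigError("config root must be a mapping")
    version = raw.get("schema_version", SCHEMA_VERSION)
    if version != SCHEMA_VERSION:
        raise ConfigError(f"unsupported schema_version {version}")
    strategies = tuple(
        _strategy_from_dict(s) for s in _require(raw, "strategies", "config")
    )
    if len(strategies) != 2:
        raise ConfigError(f"expected exactly 2 strategies, got {len(strategies)}")
    settings = _settings_from_dict(raw.get("settings", {}))
    return strategies, settings


def config_to_json(
    strategies: Sequence[StrategyInputs], settings: ModelSettings, indent: int = 2
) -> str:
    """JSON export of a scenario (machine-readable mirror of the YAML)."""
    return json.dumps(config_to_dict(strategies, settings), indent=indent)


def parameter_table(strategies: Sequence[StrategyInputs]) -> pd.DataFrame:
    """Tidy parameter table (one row per strategy x parameter) for CSV export."""
    rows = []
    for s in strategies:
        rows.append(
            dict(strategy=s.name, parameter="rr", value=s.clinical.effective_rr)
        )
        for p in ("os_months", "pfs_months", "dor_months"):
            rows.append(dict(strategy=s.name, parameter=p, value=getattr(s.clinical, p)))
        for pid, (lo, hi) in s.sa_ranges.items():
            rows.append(
                dict(
                    strategy=s.name,
                    parameter=pid,
                    value=None,
                    sa_low=lo,
                    sa_high=hi,
                    distribution=s.distributions.get(pid),
                )
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# bundled reference scenarios
# ---------------------------------------------------------------------------

SCENARIOS = ("whole_group", "asian_subgroup")


def scenario_path(name: str) -> Path:
    """Filesystem path of a bundled scenario YAML."""
    if name not in SCENARIOS:
        raise ConfigError(f"unknown scenario {name!r}; choose from {SCENARIOS}")
    return Path(str(resources.files("markovcea").joinpath(f"scenarios/{name}.yaml")))


def reference_scenario(name: str) -> tuple[tuple[StrategyInputs, ...], ModelSettings]:
    """Load a bundled reference scenario (``whole_group`` or ``asian_subgroup``)."""
    return load_config(scenario_path(name))
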