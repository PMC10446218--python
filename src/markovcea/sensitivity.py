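"""Deterministic (tornado) and probabilistic sensitivity analysis.

One-way DSA re-evaluates the full two-arm pipeline with one parameter at
its low and at its high bound, all others at base, and records the ICER
swing.  PSA (second-order Monte Carlo) samples every uncertain parameter
independently from a beta (probabilities, utilities) or gamma (costs)
distribution fitted by the method of moments to the base value and its
sensitivity range, re-runs both arms per draw, and summarises the
(dQALY, dCost) cloud by CE-plane category and by cost-effectiveness
acceptability curves (probability of the highest NMB over a WTP grid).

Transition probabilities are varied under the complement convention: the
same-row self-transition absorbs any change (rows stay stochastic), and
varying a self-transition directly is mapped onto its constituent
outflows (remission->remission onto remission->relapse, etc.).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .economics import CEResult, compare, compute_nmb
from .engine import run_strategy
from .parameters import (
    AdverseEvent,
    DomainError,
    DrugDosing,
    ModelSettings,
    OtherCost,
    StrategyInputs,
    auto_range,
)
from .transitions import assemble_matrix, build_matrix

__all__ = [
    "FitError",
    "ParameterDistribution",
    "fit_distribution",
    "ModelParameter",
    "ModelBundle",
    "build_parameters",
    "evaluate",
    "DsaRow",
    "one_way_dsa",
    "PsaResult",
    "run_psa",
    "ceac",
]


class FitError(ValueError):
    """A distribution cannot be fitted to the requested moments."""


@dataclass(frozen=True)
class ParameterDistribution:
    """Method-of-moments parameter distribution (mean = base value).

    The sensitivity range is read as a 95% interval, so
    ``sd = (high - low) / (2 x 1.96)``.  ``family`` is ``beta``, ``gamma``
    or ``point`` (degenerate, sd = 0).  ``shape`` holds (alpha, beta) for
    beta and (shape, scale) for gamma.
    """

    family: str
    mean: float
    sd: float
    shape: tuple[float, float] = (math.nan, math.nan)

    def sample(self, rng: np.random.Generator, size: int | None = None):
        if self.family == "point":
            return (
                self.mean if size is None else np.full(size, self.mean)
            )
        if self.family == "beta":
            a, b = self.shape
            return stats.beta.rvs(a, b, size=size, random_state=rng)
        a, scale = self.shape
        return stats.gamma.rvs(a, scale=scale, size=size, random_state=rng)


def fit_distribution(
    base: float, range_low: float, range_high: float, family: str
) -> ParameterDistribution:
    """Fit a beta or gamma distribution with mean ``base`` from an SA range.

    A degenerate range (low == high == base) yields a point mass.  Raises
    :class:`FitError` when the implied variance is infeasible (for beta,
    variance must stay below ``mean (1 - mean)``).
    """
    if not range_low <= base <= range_high:
        raise FitError(
            f"base {base} outside range ({range_low}, {range_high})"
        )
    sd = (range_high - range_low) / (2.0 * 1.96)
    if sd == 0.0:
        return ParameterDistribution(family="point", mean=base, sd=0.0)
    var = sd * sd
    if family == "beta":
        if not 0.0 < base < 1.0:
            raise FitError(f"beta mean must be in (0, 1), got {base}")
        if var >= base * (1.0 - base):
            raise FitError(
                f"beta variance {var:.3g} >= mean(1-mean) = {base * (1 - base):.3g}; "
                "narrow the range or use a different family"
            )
        nu = base * (1.0 - base) / var - 1.0
        return ParameterDistribution(
            family="beta", mean=base, sd=sd, shape=(base * nu, (1.0 - base) * nu)
        )
    if family == "gamma":
        if base <= 0:
            raise FitError(f"gamma mean must be > 0, got {base}")
        return ParameterDistribution(
            family="gamma", mean=base, sd=sd, shape=(base * base / var, var / base)
        )
    raise FitError(f"unknown family {family!r}")


# ---------------------------------------------------------------------------
# parameter registry and model re-evaluation
# ---------------------------------------------------------------------------

#: probability parameter ids that vary a primitive outflow directly
_PROB_DIRECT = {
    "p_stable_remission": "sr",
    "p_stable_relapse": "sp",
    "p_remission_relapse": "rp",
    "p_relapse_death": "pd",
}
#: self-transition complements, mapped onto their constituents
_PROB_COMPLEMENT = {
    "p_remission_remission": "rp",
    "p_relapse_relapse": "pd",
    "p_stable_stable": None,  # rescales sr + sp proportionally
}


@dataclass(frozen=True)
class ModelBundle:
    """A two-arm scenario plus settings, the unit the analyses re-evaluate."""

    strategies: tuple[StrategyInputs, StrategyInputs]
    settings: ModelSettings

    def base_primitives(self) -> tuple[dict[str, float], dict[str, float]]:
        """Base outflow probabilities per arm under the settings' rounding mode."""
        return tuple(
            build_matrix(s.clinical, self.settings.rounding_mode).primitives
            for s in self.strategies
        )


@dataclass(frozen=True)
class ModelParameter:
    """One uncertain input: identity, base value, range, sampling family."""

    pid: str  #: "<arm index>:<parameter id>" or "settings:discount_rate"
    arm: int | None
    key: str
    base: float
    low: float
    high: float
    family: str
    kind: str  #: prob_direct | prob_complement | utility | cost | discount


def _strategy_base(strategy: StrategyInputs, key: str, prims: dict[str, float]) -> float:
    if key in _PROB_DIRECT:
        return prims[_PROB_DIRECT[key]]
    if key == "p_stable_stable":
        return 1.0 - prims["sr"] - prims["sp"]
    if key == "p_remission_remission":
        return 1.0 - prims["rp"]
    if key == "p_relapse_relapse":
        return 1.0 - prims["pd"]
    if key.startswith("u_"):
        return getattr(strategy.utilities, key[2:])
    if key.startswith("price_"):
        name = key[len("price_") :]
        if name == "loperamide":
            if strategy.costs.loperamide is None:
                raise DomainError("strategy has no loperamide schedule")
            return strategy.costs.loperamide.unit_price
        for d in strategy.costs.dosing:
            if d.drug == name:
                return d.unit_price
        raise DomainError(f"no dosing entry for drug {name!r}")
    if key.startswith("cost_ae_"):
        name = key[len("cost_ae_") :]
        for a in strategy.costs.ae_profile:
            if a.event == name:
                return a.cost_per_event
        raise DomainError(f"no adverse event {name!r}")
    if key.startswith("cost_"):
        name = key[len("cost_") :]
        for c in strategy.costs.other_costs:
            if c.name == name:
                return c.annual_amount
        raise DomainError(f"no recurring cost {name!r}")
    raise DomainError(f"unrecognised parameter id {key!r}")


def _param_kind(key: str) -> str:
    if key in _PROB_DIRECT:
        return "prob_direct"
    if key in _PROB_COMPLEMENT:
        return "prob_complement"
    if key.startswith("u_"):
        return "utility"
    return "cost"


def build_parameters(
    bundle: ModelBundle, include_discount: bool = True
) -> list[ModelParameter]:
    """Registry of every parameter with a sensitivity range in the bundle.

    Each strategy contributes the parameters named in its ``sa_ranges``.
    Transition probabilities are always arm-specific; a utility or cost
    parameter that appears in both arms with an identical range (the
    published tables print utilities and most unit costs once, for both
    arms) is merged into a single shared parameter (``arm=None``, pid
    ``shared:<key>``) so that varying or sampling it moves both arms
    together.  The annual discount rate is appended as a bundle-level
    parameter with a +-10% range unless ``include_discount`` is false.
    """
    prims_pair = bundle.base_primitives()
    a, b = bundle.strategies
    params: list[ModelParameter] = []

    def _checked_base(i: int, strategy: StrategyInputs, key: str) -> float:
        lo, hi = strategy.sa_ranges[key]
        base = _strategy_base(strategy, key, prims_pair[i])
        if not lo <= base <= hi:
            raise DomainError(
                f"{strategy.name}:{key} base {base:.6g} outside its "
                f"sa_range ({lo}, {hi})"
            )
        return base

    shared_keys = {
        key
        for key in a.sa_ranges
        if not key.startswith("p_")
        and key in b.sa_ranges
        and a.sa_ranges[key] == b.sa_ranges[key]
        and a.distributions[key] == b.distributions[key]
    }
    for key in sorted(shared_keys):
        base_a = _checked_base(0, a, key)
        base_b = _checked_base(1, b, key)
        if base_a != base_b:
            shared_keys.discard(key)
            continue
        lo, hi = a.sa_ranges[key]
        params.append(
            ModelParameter(
                pid=f"shared:{key}",
                arm=None,
                key=key,
                base=base_a,
                low=lo,
                high=hi,
                family=a.distributions[key],
                kind=_param_kind(key),
            )
        )
    for i, strategy in enumerate(bundle.strategies):
        for key in strategy.sa_ranges:
            if key in shared_keys:
                continue
            lo, hi = strategy.sa_ranges[key]
            params.append(
                ModelParameter(
                    pid=f"{strategy.name}:{key}",
                    arm=i,
                    key=key,
                    base=_checked_base(i, strategy, key),
                    low=lo,
                    high=hi,
                    family=strategy.distributions[key],
                    kind=_param_kind(key),
                )
            )
    if include_discount:
        r = bundle.settings.annual_discount_rate
        lo, hi = auto_range("discount", r)
        params.append(
            ModelParameter(
                pid="settings:discount_rate",
                arm=None,
                key="discount_rate",
                base=r,
                low=lo,
                high=hi,
                family="beta",
                kind="discount",
            )
        )
    return params


def _apply_strategy_override(strategy: StrategyInputs, key: str, value: float) -> StrategyInputs:
    if key.startswith("u_"):
        return replace(strategy, utilities=replace(strategy.utilities, **{key[2:]: value}))
    if key.startswith("price_"):
        name = key[len("price_") :]
        if name == "loperamide":
            return replace(
                strategy,
                costs=replace(
                    strategy.costs,
                    loperamide=replace(strategy.costs.loperamide, unit_price=value),
                ),
            )
        dosing = tuple(
            replace(d, unit_price=value) if d.drug == name else d
            for d in strategy.costs.dosing
        )
        return replace(strategy, costs=replace(strategy.costs, dosing=dosing))
    if key.startswith("cost_ae_"):
        name = key[len("cost_ae_") :]
        ae = tuple(
            replace(a, cost_per_event=value) if a.event == name else a
            for a in strategy.costs.ae_profile
        )
        return replace(strategy, costs=replace(strategy.costs, ae_profile=ae))
    if key.startswith("cost_"):
        name = key[len("cost_") :]
        oc = tuple(
            replace(c, annual_amount=value) if c.name == name else c
            for c in strategy.costs.other_costs
        )
        return replace(strategy, costs=replace(strategy.costs, other_costs=oc))
    raise DomainError(f"cannot apply override for {key!r}")


def _apply_prob_override(prims: dict[str, float], key: str, value: float) -> None:
    if key in _PROB_DIRECT:
        prims[_PROB_DIRECT[key]] = value
    elif key == "p_remission_remission":
        prims["rp"] = 1.0 - value
    elif key == "p_relapse_relapse":
        prims["pd"] = 1.0 - value
    elif key == "p_stable_stable":
        out = prims["sr"] + prims["sp"]
        if out <= 0:
            raise DomainError("cannot rescale zero stable-row outflow")
        scale = (1.0 - value) / out
        prims["sr"] *= scale
        prims["sp"] *= scale
    else:  # pragma: no cover - guarded upstream
        raise DomainError(f"not a probability parameter: {key!r}")


def evaluate(bundle: ModelBundle, overrides: dict[str, float] | None = None) -> CEResult:
    """Run the full two-arm pipeline with named parameter overrides.

    Override keys are ``"<strategy name>:<parameter id>"``,
    ``"shared:<parameter id>"`` (applied to both arms) or
    ``"settings:discount_rate"``.  Probability overrides are applied to
    the base primitives with the same-row complement absorbing the change;
    with no overrides this reproduces the base case exactly.
    """
    overrides = dict(overrides or {})
    settings = bundle.settings
    if "settings:discount_rate" in overrides:
        settings = replace(
            settings, annual_discount_rate=overrides.pop("settings:discount_rate")
        )
    results = []
    prims_pair = bundle.base_primitives()
    for i, strategy in enumerate(bundle.strategies):
        prims = dict(prims_pair[i])
        mod = strategy
        for pid, value in overrides.items():
            name, _, key = pid.partition(":")
            if name != strategy.name and name != "shared":
                continue
            if key in _PROB_DIRECT or key in _PROB_COMPLEMENT:
                if name == "shared":
                    raise DomainError("transition probabilities cannot be shared")
                _apply_prob_override(prims, key, value)
            else:
                mod = _apply_strategy_override(mod, key, value)
        matrix = assemble_matrix(prims["sr"], prims["sp"], prims["rp"], prims["pd"])
        results.append(run_strategy(mod, settings, matrix=matrix))
    return compare(results[0], results[1], settings)


# ---------------------------------------------------------------------------
# one-way DSA
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DsaRow:
    """Tornado entry: ICER at a parameter's low and high bound."""

    pid: str
    low: float
    high: float
    icer_at_low: float
    icer_at_high: float
    valid: bool = True
    note: str = ""

    @property
    def bar_width(self) -> float:
        if not self.valid:
            return 0.0
        return abs(self.icer_at_high - self.icer_at_low)


def _icer_value(res: CEResult) -> float:
    return math.nan if res.icer is None else res.icer


def one_way_dsa(
    bundle: ModelBundle, params: list[ModelParameter] | None = None
) -> list[DsaRow]:
    """One-way deterministic sensitivity analysis, sorted by ICER swing.

    Parameters whose variation breaks row-stochasticity beyond the
    complement convention's repair are flagged (``valid=False``), not
    raised.
    """
    if params is None:
        params = build_parameters(bundle)
    rows: list[DsaRow] = []
    for p in params:
        vals = {}
        note = ""
        ok = True
        for bound, v in (("low", p.low), ("high", p.high)):
            try:
                vals[bound] = _icer_value(evaluate(bundle, {p.pid: v}))
            except DomainError as exc:
                ok = False
                note = f"{bound} bound invalid: {exc}"
                vals[bound] = math.nan
        rows.append(
            DsaRow(
                pid=p.pid,
                low=p.low,
                high=p.high,
                icer_at_low=vals["low"],
                icer_at_high=vals["high"],
                valid=ok,
                note=note,
            )
        )
    return sorted(rows, key=lambda r: r.bar_width, reverse=True)


def dsa_table(rows: list[DsaRow]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            dict(
                parameter=r.pid,
                low=r.low,
                high=r.high,
                icer_at_low=r.icer_at_low,
                icer_at_high=r.icer_at_high,
                bar_width=r.bar_width,
                valid=r.valid,
                note=r.note,
            )
            for r in rows
        ]
    )


# ---------------------------------------------------------------------------
# PSA
# ---------------------------------------------------------------------------

#: CE-plane categories for strategy A vs comparator B
PSA_CATEGORIES = (
    "dominant",
    "more_effective_below_wtp",
    "more_effective_above_wtp",
    "cost_saving_favourable",
    "comparator_favoured",
    "indifferent",
)


@dataclass(frozen=True)
class PsaResult:
    """Second-order Monte-Carlo output for strategy A vs comparator B."""

    n_draws: int
    seed: int
    cost_a: np.ndarray
    cost_b: np.ndarray
    qaly_a: np.ndarray
    qaly_b: np.ndarray
    wtp: float
    n_invalid: int = 0

    @property
    def delta_cost(self) -> np.ndarray:
        return self.cost_a - self.cost_b

    @property
    def delta_qaly(self) -> np.ndarray:
        return self.qaly_a - self.qaly_b

    def nmb(self, wtp: float | None = None) -> tuple[np.ndarray, np.ndarray]:
        w = self.wtp if wtp is None else wtp
        return w * self.qaly_a - self.cost_a, w * self.qaly_b - self.cost_b

    def categories(self) -> np.ndarray:
        """Per-draw CE-plane category against the WTP line.

        * ``dominant``: dE > 0, dC < 0
        * ``more_effective_below_wtp`` / ``above_wtp``: dE > 0, dC >= 0,
          split by ICER vs WTP
        * ``cost_saving_favourable``: dE < 0, dC < 0 but NMB still favours A
        * ``comparator_favoured``: everything favouring B
        * ``indifferent``: dE = 0 and dC = 0
        """
        dc, de = self.delta_cost, self.delta_qaly
        nmb_a, nmb_b = self.nmb()
        cats = np.empty(self.n_draws, dtype=object)
        for i in range(self.n_draws):
            if de[i] == 0.0 and dc[i] == 0.0:
                cats[i] = "indifferent"
            elif de[i] > 0 and dc[i] < 0:
                cats[i] = "dominant"
            elif de[i] > 0:
                icer = dc[i] / de[i]
                cats[i] = (
                    "more_effective_below_wtp"
                    if icer <= self.wtp
                    else "more_effective_above_wtp"
                )
            elif de[i] < 0 and dc[i] < 0 and nmb_a[i] > nmb_b[i]:
                cats[i] = "cost_saving_favourable"
            else:
                cats[i] = "comparator_favoured"
        return cats

    def quadrant_fractions(self) -> dict[str, float]:
        cats = self.categories()
        return {c: float((cats == c).mean()) for c in PSA_CATEGORIES}

    def fraction_favouring_a(self) -> float:
        """Fraction of draws in which A has the (strictly) higher NMB."""
        nmb_a, nmb_b = self.nmb()
        return float((nmb_a > nmb_b).mean() + 0.5 * (nmb_a == nmb_b).mean())

    def draws_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            dict(
                draw=np.arange(self.n_draws),
                cost_a=self.cost_a,
                cost_b=self.cost_b,
                qaly_a=self.qaly_a,
                qaly_b=self.qaly_b,
                delta_cost=self.delta_cost,
                delta_qaly=self.delta_qaly,
            )
        )


def run_psa(
    bundle: ModelBundle,
    n_draws: int = 1000,
    seed: int = 0,
    params: list[ModelParameter] | None = None,
    max_invalid_fraction: float = 0.01,
) -> PsaResult:
    """Second-order Monte-Carlo PSA (fully reproducible for a given seed).

    Every parameter with a fitted distribution is sampled independently per
    draw; complement self-transitions are excluded (they are derived) and
    the discount rate is held fixed.  Draws whose transition rows exceed 1
    are resampled and counted; more than ``max_invalid_fraction`` of
    invalid draws aborts with a diagnostic.
    """
    if n_draws < 1:
        raise DomainError("n_draws must be >= 1")
    if params is None:
        params = build_parameters(bundle, include_discount=False)
    params = [p for p in params if p.kind not in ("prob_complement", "discount")]
    dists = {
        p.pid: fit_distribution(p.base, p.low, p.high, p.family) for p in params
    }
    rng = np.random.default_rng(seed)
    cost_a = np.empty(n_draws)
    cost_b = np.empty(n_draws)
    qaly_a = np.empty(n_draws)
    qaly_b = np.empty(n_draws)
    n_invalid = 0
    max_invalid = max(1, int(max_invalid_fraction * n_draws))
    for i in range(n_draws):
        while True:
            overrides = {p.pid: float(dists[p.pid].sample(rng)) for p in params}
            try:
                res = evaluate(bundle, overrides)
            except DomainError:
                n_invalid += 1
                if n_invalid > max_invalid:
                    raise DomainError(
                        f"more than {max_invalid_fraction:.0%} of PSA draws "
                        f"violate row-stochasticity ({n_invalid} invalid by "
                        f"draw {i}); check the sensitivity ranges"
                    )
                continue
            break
        cost_a[i], cost_b[i] = res.cost_a, res.cost_b
        qaly_a[i], qaly_b[i] = res.qaly_a, res.qaly_b
    return PsaResult(
        n_draws=n_draws,
        seed=seed,
        cost_a=cost_a,
        cost_b=cost_b,
        qaly_a=qaly_a,
        qaly_b=qaly_b,
        wtp=bundle.settings.wtp_per_qaly,
        n_invalid=n_invalid,
    )


def ceac(psa: PsaResult, wtp_grid: np.ndarray | None = None) -> pd.DataFrame:
    """Cost-effectiveness acceptability curves over a WTP grid.

    At each WTP the acceptability of a strategy is the fraction of draws
    in which its NMB is strictly the larger (ties split evenly); the two
    curves therefore sum to 1 pointwise.
    """
    if wtp_grid is None:
        wtp_grid = np.linspace(0.0, 64000.0, 33)
    wtp_grid = np.asarray(wtp_grid, dtype=float)
    if wtp_grid.size == 0:
        raise DomainError("wtp_grid must be non-empty")
    p_a = np.empty(wtp_grid.size)
    for k, w in enumerate(wtp_grid):
        nmb_a = w * psa.qaly_a - psa.cost_a
        nmb_b = w * psa.qaly_b - psa.cost_b
        p_a[k] = (nmb_a > nmb_b).mean() + 0.5 * (nmb_a == nmb_b).mean()
    return pd.DataFrame(dict(wtp=wtp_grid, p_strategy_a=p_a, p_strategy_b=1.0 - p_a))
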