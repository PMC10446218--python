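"""Per-cycle transition probabilities from median survival summaries.

The model converts median OS, PFS and DoR into constant-hazard per-cycle
transition probabilities (the DEALE approach: a median m under an
exponential survival law corresponds to rate ln(2)/m, and a rate r over a
cycle of length t gives probability 1 - exp(-r*t)).  With 21-day cycles
the cycle length in months is taken as 0.75, kept as the named constant
``CYCLE_MONTH_FACTOR``.

States are ordered (SD, RE, PD, DE).  Structural zeros: SD cannot reach DE
directly, RE cannot return to SD or jump to DE, PD cannot recover; DE is
absorbing.  Self-transitions are complements of the row's outflows.

Formulas (per strategy):

==================  =============================
stable -> remission   1 - exp(-RR / 3)
remission -> relapse  1 - exp(-0.75 ln2 / DoR)
relapse -> death      1 - exp(-0.75 ln2 / (OS - PFS))
stable -> relapse     4 x (remission -> relapse)
==================  =============================

Rounding modes reproduce the published source table at three decimals:
``full_precision`` (no intermediate rounding), ``round_3dp`` (round half
away from zero), ``truncate_3dp``, and ``published_3dp`` — the mixed
convention (round for the RR- and OS/PFS-based primitives, truncate for
the DoR-based one) that matches every published entry exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_DOWN, ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

from .parameters import STATES, ClinicalSummary, DomainError

__all__ = [
    "CYCLE_MONTH_FACTOR",
    "RR_SCALE",
    "STABLE_RELAPSE_MULTIPLIER",
    "ROUNDING_MODES",
    "TransitionMatrix",
    "derive_rr",
    "p_stable_to_remission",
    "p_remission_to_relapse",
    "p_relapse_to_death",
    "p_stable_to_relapse",
    "assemble_matrix",
    "build_matrix",
    "prob_to_rate",
]

#: Cycle length expressed in months for the hazard->probability conversion.
CYCLE_MONTH_FACTOR = 0.75
#: Scale constant in the stable->remission formula 1 - exp(-RR / RR_SCALE).
RR_SCALE = 3.0
#: Relapse hazard from stable is assumed this multiple of that from remission.
STABLE_RELAPSE_MULTIPLIER = 4.0

ROUNDING_MODES = ("full_precision", "round_3dp", "truncate_3dp", "published_3dp")

_ROW_TOL = 1e-12


def _round3(x: float) -> float:
    """Round half away from zero at three decimals."""
    return float(Decimal(repr(x)).quantize(Decimal("0.001"), rounding=ROUND_HALF_UP))


def _trunc3(x: float) -> float:
    """Truncate toward zero at three decimals."""
    return float(Decimal(repr(x)).quantize(Decimal("0.001"), rounding=ROUND_DOWN))


def derive_rr(os_months: float, pfs_months: float) -> float:
    """Response-like fraction ``(OS - PFS) / OS``; requires OS > PFS > 0."""
    if not pfs_months > 0 or not os_months > pfs_months:
        raise DomainError(
            f"need os > pfs > 0, got os={os_months}, pfs={pfs_months}"
        )
    return (os_months - pfs_months) / os_months


def p_stable_to_remission(rr: float, *, validate: bool = True) -> float:
    """Per-cycle stable->remission probability, ``1 - exp(-rr / 3)``."""
    if validate and not 0.0 <= rr <= 1.0:
        raise DomainError(f"rr must be in [0, 1], got {rr}")
    return 1.0 - math.exp(-rr / RR_SCALE)


def p_remission_to_relapse(dor_months: float) -> float:
    """Per-cycle remission->relapse probability, ``1 - exp(-0.75 ln2 / DoR)``."""
    if not dor_months > 0:
        raise DomainError(f"dor_months must be > 0, got {dor_months}")
    return 1.0 - math.exp(-CYCLE_MONTH_FACTOR * math.log(2.0) / dor_months)


def p_relapse_to_death(os_months: float, pfs_months: float) -> float:
    """Per-cycle relapse->death probability, ``1 - exp(-0.75 ln2 / (OS-PFS))``."""
    if not os_months > pfs_months:
        raise DomainError(
            f"need os > pfs, got os={os_months}, pfs={pfs_months}"
        )
    return 1.0 - math.exp(
        -CYCLE_MONTH_FACTOR * math.log(2.0) / (os_months - pfs_months)
    )


def p_stable_to_relapse(p_rp: float, multiplier: float = STABLE_RELAPSE_MULTIPLIER) -> float:
    """Per-cycle stable->relapse probability, ``multiplier x p_rp``."""
    if p_rp < 0:
        raise DomainError(f"p_rp must be >= 0, got {p_rp}")
    p = multiplier * p_rp
    if p > 1.0:
        raise DomainError(
            f"stable->relapse = {multiplier} x {p_rp} = {p:.4f} exceeds 1"
        )
    return p


def prob_to_rate(p: float) -> float:
    """Underlying per-cycle rate for probability ``p``: ``-ln(1 - p)``."""
    if not 0.0 <= p < 1.0:
        raise DomainError(f"p must be in [0, 1), got {p}")
    return -math.log1p(-p)


@dataclass(frozen=True)
class TransitionMatrix:
    """4x4 per-cycle transition matrix with formula provenance.

    ``matrix[i, j]`` is P(state j next cycle | state i now) with states in
    :data:`~markovcea.parameters.STATES` order.  ``primitives`` holds the
    independently derived outflow probabilities keyed ``sr`` (stable->
    remission), ``sp`` (stable->relapse), ``rp`` (remission->relapse) and
    ``pd`` (relapse->death); self-transitions are their complements.
    """

    matrix: np.ndarray
    primitives: dict[str, float]
    provenance: dict[tuple[str, str], str]

    def __post_init__(self) -> None:
        m = self.matrix
        if m.shape != (4, 4):
            raise DomainError(f"matrix must be 4x4, got {m.shape}")
        if (m < -_ROW_TOL).any() or (m > 1 + _ROW_TOL).any():
            raise DomainError("matrix entries must lie in [0, 1]")
        rows = m.sum(axis=1)
        if np.abs(rows - 1.0).max() > 1e-9:
            raise DomainError(f"rows must sum to 1, got sums {rows}")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=STATES, columns=STATES)

    def to_csv(self, path) -> None:
        """CSV export with a provenance column naming each formula."""
        rows = []
        for i, fr in enumerate(STATES):
            for j, to in enumerate(STATES):
                rows.append(
                    dict(
                        from_state=fr,
                        to_state=to,
                        probability=self.matrix[i, j],
                        formula=self.provenance.get((fr, to), ""),
                    )
                )
        pd.DataFrame(rows).to_csv(path, index=False)


def assemble_matrix(
    p_sr: float, p_sp: float, p_rp: float, p_pd: float
) -> TransitionMatrix:
    """Assemble the structural 4x4 matrix from the four outflow probabilities.

    Self-transitions are complements (``ss = 1 - sr - sp``, ``rr = 1 - rp``,
    ``pp = 1 - pd``); death is absorbing.  Raises :class:`DomainError`
    naming the offending entry if any probability leaves [0, 1].
    """
    entries = {"sr": p_sr, "sp": p_sp, "rp": p_rp, "pd": p_pd}
    for key, v in entries.items():
        if not 0.0 <= v <= 1.0:
            raise DomainError(f"probability {key}={v} outside [0, 1]")
    p_ss = 1.0 - p_sr - p_sp
    if p_ss < -_ROW_TOL:
        raise DomainError(
            f"stable row exceeds 1: sr={p_sr} + sp={p_sp} = {p_sr + p_sp:.6f}"
        )
    p_ss = max(p_ss, 0.0)
    m = np.array(
        [
            [p_ss, p_sr, p_sp, 0.0],
            [0.0, 1.0 - p_rp, p_rp, 0.0],
            [0.0, 0.0, 1.0 - p_pd, p_pd],
            [0.0, 0.0, 0.0, 1.0],
        ]
    )
    prov = {
        ("SD", "SD"): "1 - sr - sp",
        ("SD", "RE"): "1 - exp(-RR/3)",
        ("SD", "PD"): "4 x rp",
        ("RE", "RE"): "1 - rp",
        ("RE", "PD"): "1 - exp(-0.75 ln2 / DoR)",
        ("PD", "PD"): "1 - pd",
        ("PD", "DE"): "1 - exp(-0.75 ln2 / (OS - PFS))",
        ("DE", "DE"): "absorbing",
    }
    return TransitionMatrix(matrix=m, primitives=entries, provenance=prov)


def build_matrix(
    clinical: ClinicalSummary,
    rounding_mode: str = "full_precision",
    multiplier: float = STABLE_RELAPSE_MULTIPLIER,
) -> TransitionMatrix:
    """Derive the per-cycle transition matrix for one strategy.

    Parameters
    ----------
    clinical
        Median-based clinical summary (OS, PFS, DoR and optionally RR).
    rounding_mode
        One of :data:`ROUNDING_MODES`.  The three-decimal modes round each
        derived primitive before complements and multiples are formed, as
        the published source table does; ``published_3dp`` uses the mixed
        round/truncate convention that reproduces that table exactly.
    multiplier
        Stable->relapse hazard multiple of remission->relapse (default 4).
    """
    if rounding_mode not in ROUNDING_MODES:
        raise DomainError(f"unknown rounding_mode {rounding_mode!r}")
    rr = clinical.effective_rr
    sr = p_stable_to_remission(rr)
    rp = p_remission_to_relapse(clinical.dor_months)
    pd_ = p_relapse_to_death(clinical.os_months, clinical.pfs_months)
    if rounding_mode == "round_3dp":
        sr, rp, pd_ = _round3(sr), _round3(rp), _round3(pd_)
    elif rounding_mode == "truncate_3dp":
        sr, rp, pd_ = _trunc3(sr), _trunc3(rp), _trunc3(pd_)
    elif rounding_mode == "published_3dp":
        sr, rp, pd_ = _round3(sr), _trunc3(rp), _round3(pd_)
    sp = p_stable_to_relapse(rp, multiplier)
    return assemble_matrix(sr, sp, rp, pd_)
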