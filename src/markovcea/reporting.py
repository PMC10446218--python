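"""Human-readable reports, CSV/JSON artifacts, plots and run manifests."""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .economics import CEResult
from .engine import StrategyResult
from .sensitivity import DsaRow, PsaResult
from .transitions import TransitionMatrix

__all__ = [
    "RunManifest",
    "transition_table",
    "ce_summary_markdown",
    "plot_tornado",
    "plot_ce_plane",
    "plot_ceac",
]


@dataclass
class RunManifest:
    """Record of one run: inputs, seeds, version, produced files."""

    config_sha256: str
    seed: int | None
    package_version: str
    settings: dict
    outputs: list[str] = field(default_factory=list)
    timestamp: str = field(
        default_factory=lambda: datetime.now(timezone.utc).isoformat()
    )

    @staticmethod
    def hash_config(text: str) -> str:
        return hashlib.sha256(text.encode()).hexdigest()

    def add(self, path: Path) -> None:
        self.outputs.append(path.name)

    def write(self, outdir: Path) -> Path:
        path = Path(outdir) / "manifest.json"
        payload = {
            "timestamp": self.timestamp,
            "config_sha256": self.config_sha256,
            "seed": self.seed,
            "package_version": self.package_version,
            "settings": self.settings,
            "outputs": sorted(self.outputs),
        }
        path.write_text(json.dumps(payload, indent=2))
        return path


def transition_table(matrices: dict[str, TransitionMatrix]) -> pd.DataFrame:
    """Per-strategy transition probabilities with formula provenance."""
    rows = []
    for name, tm in matrices.items():
        from .parameters import STATES

        for i, fr in enumerate(STATES):
            for j, to in enumerate(STATES):
                p = tm.matrix[i, j]
                if p == 0.0 and (fr, to) not in tm.provenance:
                    continue
                rows.append(
                    dict(
                        strategy=name,
                        transition=f"{fr}->{to}",
                        probability=p,
                        formula=tm.provenance.get((fr, to), ""),
                    )
                )
    return pd.DataFrame(rows)


def _fmt(x: float | None, nd: int = 2) -> str:
    return "-" if x is None else f"{x:,.{nd}f}"


def ce_summary_markdown(result: CEResult, reported: dict | None = None) -> str:
    """Markdown summary of a paired comparison.

    When ``reported`` carries the published summary for the same scenario
    the table shows it next to the computed values, so any divergence from
    the published figures is visible rather than hidden.
    """
    lines = [
        f"## Cost-effectiveness summary: {result.name_a} vs {result.name_b}",
        "",
        "| quantity | " + result.name_a + " | " + result.name_b + " |",
        "|---|---|---|",
        f"| total cost (USD) | {_fmt(result.cost_a)} | {_fmt(result.cost_b)} |",
        f"| total QALYs | {_fmt(result.qaly_a, 3)} | {_fmt(result.qaly_b, 3)} |",
        f"| NMB at WTP {_fmt(result.wtp, 0)} | {_fmt(result.nmb_a)} | {_fmt(result.nmb_b)} |",
        "",
        f"- incremental cost: {_fmt(result.delta_cost)} USD",
        f"- incremental QALYs: {_fmt(result.delta_qaly, 3)}",
        f"- ICER: {_fmt(result.icer)} USD/QALY ({result.icer_tag})",
        f"- decision vs GDP {_fmt(result.gdp_per_capita, 0)}: {result.decision.value}",
    ]
    if reported:
        lines += [
            "",
            "### Published values for this scenario (shown for comparison)",
            f"- reported costs: {_fmt(reported['cost'][0])} / {_fmt(reported['cost'][1])}",
            f"- reported QALYs: {_fmt(reported['qaly'][0])} / {_fmt(reported['qaly'][1])}",
            f"- reported ICER: {_fmt(reported['icer'])}",
            f"- reported NMB: {_fmt(reported['nmb'][0])} / {_fmt(reported['nmb'][1])}",
        ]
    return "\n".join(lines) + "\n"


def plot_tornado(rows: Sequence[DsaRow], base_icer: float, path: Path, top: int = 15) -> None:
    rows = [r for r in rows if r.valid][:top][::-1]
    fig, ax = plt.subplots(figsize=(8, 0.4 * len(rows) + 1.5))
    for k, r in enumerate(rows):
        lo, hi = sorted((r.icer_at_low, r.icer_at_high))
        ax.barh(k, hi - lo, left=lo, height=0.6, color="steelblue")
    ax.axvline(base_icer, color="k", linestyle="--", linewidth=1)
    ax.set_yticks(range(len(rows)))
    ax.set_yticklabels([r.pid for r in rows], fontsize=7)
    ax.set_xlabel("ICER (USD/QALY)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_ce_plane(psa: PsaResult, path: Path) -> None:
    fig, ax = plt.subplots(figsize=(6, 5))
    nmb_a, nmb_b = psa.nmb()
    favour = nmb_a > nmb_b
    ax.scatter(psa.delta_qaly[favour], psa.delta_cost[favour], s=6, c="green",
               label="strategy A favoured")
    ax.scatter(psa.delta_qaly[~favour], psa.delta_cost[~favour], s=6, c="red",
               label="comparator favoured")
    xs = np.array(ax.get_xlim())
    ax.plot(xs, psa.wtp * xs, "k--", linewidth=1, label=f"WTP {psa.wtp:,.0f}/QALY")
    ax.axhline(0, color="grey", linewidth=0.5)
    ax.axvline(0, color="grey", linewidth=0.5)
    ax.set_xlabel("incremental QALYs")
    ax.set_ylabel("incremental cost (USD)")
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_ceac(curve: pd.DataFrame, names: tuple[str, str], path: Path) -> None:
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot(curve["wtp"], curve["p_strategy_a"], label=names[0])
    ax.plot(curve["wtp"], curve["p_strategy_b"], label=names[1])
    ax.set_xlabel("willingness to pay (USD/QALY)")
    ax.set_ylabel("probability cost-effective")
    ax.set_ylim(0, 1)
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
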