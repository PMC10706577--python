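"""Summary statistics and the pipeline run report.

Covers the proteomics-style spectral interpretation rate (rounded half-up to
2 d.p., matching how such tables are printed), two-set Venn partitions, and a
machine-readable report of a full pipeline run.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Any

import pandas as pd

REPORT_SCHEMA_VERSION = 1


@dataclass(frozen=True)
class SpectraSummary:
    sample_id: str
    total_spectra: int
    identified_spectra: int

    @property
    def interpretation_rate(self) -> float:
        return interpretation_rate(self.identified_spectra, self.total_spectra)


def interpretation_rate(identified: int, total: int) -> float:
    """Identified spectra as a percentage of total, half-up at 2 d.p."""
    if total <= 0:
        raise ValueError("total must be positive")
    if not 0 <= identified <= total:
        raise ValueError("identified must lie in [0, total]")
    pct = Decimal(identified) * 100 / Decimal(total)
    return float(pct.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def venn_partition(set_a: set, set_b: set) -> tuple[int, int, int, int]:
    """(only_a, only_b, shared, union) counts of a two-set partition."""
    only_a = len(set_a - set_b)
    only_b = len(set_b - set_a)
    shared = len(set_a & set_b)
    return only_a, only_b, shared, only_a + only_b + shared


def run_report(
    config: dict[str, Any],
    de_table: pd.DataFrame,
    network_summary: pd.DataFrame,
    recovery: dict[str, float] | None = None,
    extras: dict[str, Any] | None = None,
) -> dict[str, Any]:
    """Machine-readable run report (also renderable as text).

    Tallies up/down calls per RNA class, echoes the network summary and the
    thresholds/seeds used, and includes planted-recovery metrics when ground
    truth is available.
    """
    required = {"feature_id", "class", "call"}
    if not required <= set(de_table.columns):
        raise ValueError("de_table missing required columns")
    de_tally = {
        cls: {
            "up": int(((sub["call"] == "up")).sum()),
            "down": int((sub["call"] == "down").sum()),
        }
        for cls, sub in de_table.groupby("class")
    }
    report: dict[str, Any] = {
        "schema_version": REPORT_SCHEMA_VERSION,
        "config": config,
        "de_tally": de_tally,
        "network_summary": network_summary.to_dict(orient="records"),
    }
    if recovery is not None:
        report["recovery"] = recovery
    if extras:
        report.update(extras)
    return report


def render_report_text(report: dict[str, Any]) -> str:
    lines = [f"spongenet run report (schema v{report['schema_version']})", ""]
    lines.append("Differential expression (up / down):")
    for cls, tally in sorted(report["de_tally"].items()):
        lines.append(f"  {cls:8s} {tally['up']:5d} up  {tally['down']:5d} down")
    lines.append("")
    lines.append("Network summary:")
    lines.append("  Target_Type  Target_Num  miRNA_Num  Pairs_Num")
    for row in report["network_summary"]:
        lines.append(
            f"  {row['Target_Type']:11s} {row['Target_Num']:10d} "
            f"{row['miRNA_Num']:9d} {row['Pairs_Num']:9d}"
        )
    if "recovery" in report:
        lines.append("")
        lines.append("Planted-truth recovery:")
        for key, val in report["recovery"].items():
            lines.append(f"  {key}: {val}")
    return "\n".join(lines) + "\n"


def write_report(report: dict[str, Any], path: str | Path) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, default=str)
    with open(path.with_suffix(".txt"), "w") as fh:
        fh.write(render_report_text(report))
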