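"""End-to-end triage pipeline and the consolidated report.

Stages run in fixed order: enrichment (when selection counts are given) →
bound-motif call → transcriptome mapping → functional-site annotation →
RNase L scan → RIBOTAC triage → summary.  The report is a plain dict
(JSON-serialisable) carrying every count, percentage, per-candidate row
and the resolved configuration, so a rerun with the same inputs and seed
is byte-identical.

Percentages are rounded half-up at the displayed precision.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import pandas as pd

from . import mapping as mp
from . import selection as sel
from ._util import percent
from .structures import HairpinStructure
from .triage import (
    DEFAULT_MAX_DISTANCE_BP,
    candidates_table,
    scan_rnasel,
    triage as run_triage,
)

REPORT_SCHEMA_VERSION = "1"


@dataclass(frozen=True)
class RunConfig:
    """Thresholds of the triage; defaults are the screen's operating points."""

    zobs_threshold: float = sel.DEFAULT_ZOBS_THRESHOLD          # bound call: Z_obs > 8
    max_distance_bp: int = DEFAULT_MAX_DISTANCE_BP           # RNase L site within 10 bp
    top_fraction: float = sel.DEFAULT_TOP_FRACTION              # LOGO: top 0.5%
    tanimoto_threshold: float = 0.7                             # dissimilar below 0.7
    functional_window: int = mp.DEFAULT_FUNCTIONAL_WINDOW       # ±2 nt of scissile position
    rnasel_strict: bool = False
    seed: int | None = None


def run_pipeline(
    structures: list[HairpinStructure],
    bound: pd.DataFrame | None = None,
    selection_counts: pd.DataFrame | None = None,
    config: RunConfig = RunConfig(),
) -> dict:
    """Run the full triage and return the report document.

    *bound* is a compound→motif table (columns compound_id, motif).  When
    *selection_counts* is given instead (columns compound_id, motif_id /
    motif, k_sel, k_in), bound motifs are called at the Z_obs threshold
    per compound first.
    """
    report: dict = {
        "schema_version": REPORT_SCHEMA_VERSION,
        "config": asdict(config),
        "rounding": "half-up at displayed precision",
    }

    if selection_counts is not None:
        frames = []
        for compound_id, group in selection_counts.groupby("compound_id"):
            table = sel.zobs_table(group, threshold=config.zobs_threshold)
            table.insert(0, "compound_id", compound_id)
            frames.append(table)
        ztable = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()
        report["n_motifs_tested"] = int(len(ztable))
        bound_rows = ztable[ztable["bound"]][["compound_id", "motif_id"]]
        bound_from_sel = bound_rows.rename(columns={"motif_id": "motif"})
        bound = bound_from_sel if bound is None else bound
        report["n_bound_calls"] = int(len(bound_from_sel))

    if bound is None or len(bound) == 0:
        report.update(
            {
                "mapping": {"n_motifs": 0, "n_sites": 0, "n_transcripts": 0},
                "summary": mp.TriageSummary(0, 0, 0, 0, 0).as_dict(),
                "candidates": [],
            }
        )
        return report

    index, errors = mp.build_motif_index(structures)
    sites = mp.map_binders(bound, index)
    sites = mp.annotate_sites(sites, structures, window=config.functional_window)
    cleavages = {
        s.transcript_id: scan_rnasel(s, strict=config.rnasel_strict)
        for s in structures
    }
    candidates = run_triage(sites, cleavages, structures, max_distance=config.max_distance_bp)
    summary = mp.summarize_targetability(sites, candidates)

    report["structure_errors"] = errors
    report["mapping"] = mp.mapping_counts(sites)
    report["summary"] = summary.as_dict()
    report["n_rnasel_sites"] = int(sum(len(v) for v in cleavages.values()))
    report["candidates"] = candidates_table(candidates).to_dict(orient="records")
    return report


def ratio_report(
    counts: list[tuple[str, int, int, int]]
) -> pd.DataFrame:
    """Percentage table from labelled (label, numerator, denominator,
    decimals) rows; zero denominators are flagged and skipped."""
    rows = []
    for label, num, den, decimals in counts:
        if den == 0:
            rows.append(
                {"label": label, "numerator": num, "denominator": den,
                 "ratio": float("nan"), "percent": float("nan"), "valid": False}
            )
            continue
        rows.append(
            {
                "label": label,
                "numerator": num,
                "denominator": den,
                "ratio": num / den,
                "percent": percent(num, den, decimals),
                "valid": True,
            }
        )
    return pd.DataFrame(rows)


def write_report(report: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(report, indent=2, sort_keys=True, default=str) + "\n")
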