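"""Transcriptome mapping of bound motifs and functional-site annotation.

Bound motifs from the selection are matched against all non-canonical
motifs extracted from a database of hairpin structures (e.g. human pri-/
pre-miRNAs).  Matching is orientation-independent (strand-swap equivalence
classes).  Each mapped site is *functional* when its motif span lies
within a configurable window (±2 nt by default) of an annotated Drosha or
Dicer scissile position — the geometry in which a bound small molecule can
occlude processing — and *silent* otherwise.  Silent sites are what the
RIBOTAC triage downstream tries to rescue.

Percentages in summaries are reported over sites by default, with
transcript-level counts alongside, because both denominators are in common
use.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import pandas as pd

from .motifs import StructuralMotif, parse_motif
from .structures import HairpinStructure, LocatedMotif, extract_motifs
from ._util import percent

DEFAULT_FUNCTIONAL_WINDOW = 2

MotifIndex = dict[tuple[str, str], list[LocatedMotif]]


@dataclass(frozen=True)
class TargetSite:
    """One (compound, motif location) mapping hit."""

    compound_id: str
    located_motif: LocatedMotif
    functional: bool | None = None
    nearest_processing_distance: int | None = None
    annotated: bool = True

    @property
    def transcript_id(self) -> str:
        return self.located_motif.transcript_id


@dataclass(frozen=True)
class TriageSummary:
    """Counts and percentages of the end-to-end triage."""

    n_sites: int
    n_transcripts: int
    n_functional: int
    n_silent: int
    n_silent_with_rnasel: int

    @property
    def pct_functional(self) -> float:
        return percent(self.n_functional, self.n_sites, 1)

    @property
    def pct_silent(self) -> float:
        return percent(self.n_silent, self.n_sites, 1)

    @property
    def pct_rnasel_eligible(self) -> float:
        return percent(self.n_silent_with_rnasel, self.n_sites, 1)

    def as_dict(self) -> dict:
        return {
            "n_sites": self.n_sites,
            "n_transcripts": self.n_transcripts,
            "n_functional": self.n_functional,
            "n_silent": self.n_silent,
            "n_silent_with_rnasel": self.n_silent_with_rnasel,
            "pct_functional": self.pct_functional,
            "pct_silent": self.pct_silent,
            "pct_rnasel_eligible": self.pct_rnasel_eligible,
            "percent_denominator": "sites",
        }


def build_motif_index(
    structures: list[HairpinStructure],
) -> tuple[MotifIndex, list[str]]:
    """Index every extracted non-canonical motif by canonical key.

    Hairpin (apical) loops are excluded: the library displays internal
    loops and bulges.  Structures that fail to parse are reported in the
    returned error list; the rest are indexed.
    """
    index: MotifIndex = {}
    errors: list[str] = []
    for structure in structures:
        try:
            located = extract_motifs(structure)
        except Exception as exc:
            errors.append(f"{structure.transcript_id}: {exc}")
            continue
        for lm in located:
            if lm.motif.hairpin or lm.motif.motif_class == "fully paired":
                continue
            index.setdefault(lm.motif.canonical_key(), []).append(lm)
    return index, errors


def map_binders(
    bound: pd.DataFrame, index: MotifIndex
) -> list[TargetSite]:
    """One TargetSite per (compound, location) hit of a bound motif.

    *bound* has columns compound_id, motif (5′…/3′… notation).  Motifs
    absent from the index yield no hits.
    """
    sites: list[TargetSite] = []
    for row in bound.itertuples(index=False):
        motif = row.motif if isinstance(row.motif, StructuralMotif) else parse_motif(row.motif)
        for lm in index.get(motif.canonical_key(), []):
            sites.append(TargetSite(compound_id=str(row.compound_id), located_motif=lm))
    return sites


def mapping_counts(sites: list[TargetSite]) -> dict[str, int]:
    """Distinct motif / site / transcript counts of a mapping result."""
    locations = {(s.transcript_id, s.located_motif.top_span) for s in sites}
    return {
        "n_motifs": len({s.located_motif.motif.canonical_key() for s in sites}),
        "n_sites": len(locations),
        "n_transcripts": len({s.transcript_id for s in sites}),
    }


def annotate_functional(
    site: TargetSite,
    structure: HairpinStructure,
    window: int = DEFAULT_FUNCTIONAL_WINDOW,
) -> TargetSite:
    """Flag a site functional iff its motif span is within *window* nt of a
    Drosha/Dicer scissile position; the nearest distance is recorded.

    With no annotations on the transcript the site is silent and marked
    unannotated.
    """
    if not structure.processing_sites:
        return replace(site, functional=False, nearest_processing_distance=None, annotated=False)
    positions = site.located_motif.positions()
    nearest = min(
        min(abs(p - ann.position) for p in positions)
        for ann in structure.processing_sites
    )
    return replace(
        site,
        functional=nearest <= window,
        nearest_processing_distance=int(nearest),
        annotated=True,
    )


def annotate_sites(
    sites: list[TargetSite],
    structures: list[HairpinStructure],
    window: int = DEFAULT_FUNCTIONAL_WINDOW,
) -> list[TargetSite]:
    by_id = {s.transcript_id: s for s in structures}
    return [annotate_functional(s, by_id[s.transcript_id], window) for s in sites]


def summarize_targetability(
    sites: list[TargetSite], triage_results: list | None = None
) -> TriageSummary:
    """Site-level summary; distinct locations are counted once even when a
    motif is bound by several compounds."""
    if not sites:
        return TriageSummary(0, 0, 0, 0, 0)
    by_location: dict[tuple, TargetSite] = {}
    for s in sites:
        by_location.setdefault((s.transcript_id, s.located_motif.top_span), s)
    eligible_locations = set()
    if triage_results:
        for cand in triage_results:
            if cand.accepted:
                site = cand.target_site
                eligible_locations.add((site.transcript_id, site.located_motif.top_span))
    n_functional = sum(bool(s.functional) for s in by_location.values())
    return TriageSummary(
        n_sites=len(by_location),
        n_transcripts=len({t for t, _ in by_location}),
        n_functional=n_functional,
        n_silent=len(by_location) - n_functional,
        n_silent_with_rnasel=len(eligible_locations),
    )


def sites_table(sites: list[TargetSite]) -> pd.DataFrame:
    """Sites as a TSV-writable table (1-based inclusive coordinates)."""
    rows = []
    for s in sites:
        lm = s.located_motif
        rows.append(
            {
                "compound_id": s.compound_id,
                "transcript_id": s.transcript_id,
                "motif": lm.motif.notation(),
                "motif_class": lm.motif.motif_class,
                "top_start": lm.top_span[0] + 1,
                "top_end": lm.top_span[1],
                "bottom_start": lm.bottom_span[0] + 1 if lm.bottom_span else "",
                "bottom_end": lm.bottom_span[1] if lm.bottom_span else "",
                "functional": s.functional,
                "nearest_processing_distance": s.nearest_processing_distance,
                "annotated": s.annotated,
            }
        )
    return pd.DataFrame(rows)
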