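"""RNase L substrate scanning and RIBOTAC candidate triage.

RNase L preferentially cleaves RNA at UNN trinucleotides whose U is
unpaired.  The scanner reports every position *i* with an unpaired U at
*i* and two further nucleotides in bounds; in strict mode any additional U
inside the trinucleotide must be unpaired as well.

A silent binding site becomes a RIBOTAC candidate when a cleavage site
lies *within 10 bp along the stem*: the distance is the number of
base-paired columns strictly between the binding motif's nearest closing
pair and the cleavage site's loop boundary, walking the hairpin ladder
(the miR-155 proof-of-concept geometry measures 7 bp).  The threshold is
inclusive.  Functional sites are passed through flagged
"bioactive-by-binding" — they do not need a RIBOTAC.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .mapping import TargetSite
from .structures import HairpinStructure

DEFAULT_MAX_DISTANCE_BP = 10


@dataclass(frozen=True)
class RNaseLSite:
    """A UNN cleavage-site candidate (0-based start of the leading U)."""

    transcript_id: str
    start: int
    trinucleotide: str
    unpaired_flags: tuple[bool, bool, bool]
    loop_context: str


@dataclass(frozen=True)
class TriageCandidate:
    """A silent binding site paired with its nearest cleavage site."""

    target_site: TargetSite
    cleavage_site: RNaseLSite | None
    stem_distance_bp: int | None
    accepted: bool
    bioactive_by_binding: bool = False


def scan_rnasel(
    structure: HairpinStructure, *, strict: bool = False
) -> list[RNaseLSite]:
    """All UNN sites with an unpaired leading U (strict: all Us unpaired)."""
    seq, db = structure.sequence, structure.dotbracket
    sites = []
    for i in range(len(seq) - 2):
        if seq[i] != "U" or db[i] != ".":
            continue
        tri = seq[i : i + 3]
        flags = tuple(db[i + k] == "." for k in range(3))
        if strict and any(tri[k] == "U" and not flags[k] for k in range(3)):
            continue
        sites.append(
            RNaseLSite(
                transcript_id=structure.transcript_id,
                start=i,
                trinucleotide=tri,
                unpaired_flags=flags,
                loop_context=_loop_context(structure, i),
            )
        )
    return sites


def _loop_context(structure: HairpinStructure, pos: int) -> str:
    outer, inner = structure.rung_interval([pos])
    if outer is None:
        return "exterior"
    if inner is None:
        return "hairpin loop"
    return "internal loop/bulge"


def stem_distance(
    site: TargetSite, cleavage: RNaseLSite, structure: HairpinStructure
) -> int:
    """Base pairs strictly between a binding motif and a cleavage site.

    Both features occupy an interval of the hairpin's rung ladder; the
    distance is the gap between those intervals in rungs, 0 when they
    share a loop.  Symmetric in the order of the features and monotone
    along a single stem.
    """
    if site.transcript_id != cleavage.transcript_id:
        raise ValueError("binding site and cleavage site are on different transcripts")
    if site.transcript_id != structure.transcript_id:
        raise ValueError("features do not belong to the given structure")
    motif_interior = [
        p for p in site.located_motif.positions() if not structure.is_paired(p)
    ]
    if not motif_interior:  # fully paired motif: use the span itself
        motif_interior = site.located_motif.positions()
    return _rung_gap(
        structure.rung_interval(motif_interior),
        structure.rung_interval([cleavage.start]),
    )


def _rung_gap(
    a: tuple[int | None, int | None], b: tuple[int | None, int | None]
) -> int:
    (o1, i1), (o2, i2) = a, b
    if o1 == o2:  # same loop
        return 0
    # order so that feature 2 is the more apical one
    if (o1 if o1 is not None else -1) > (o2 if o2 is not None else -1):
        (o1, i1), (o2, i2) = (o2, i2), (o1, i1)
    assert i1 is not None and o2 is not None
    # rungs strictly between the loops, exclusive of each loop's own
    # bounding pair: adjacent loops (stacked closing pairs) are 0 bp apart
    return max(o2 - i1 - 1, 0)


def triage(
    sites: list[TargetSite],
    cleavages: dict[str, list[RNaseLSite]],
    structures: list[HairpinStructure],
    max_distance: int = DEFAULT_MAX_DISTANCE_BP,
) -> list[TriageCandidate]:
    """Pair every silent site with its nearest cleavage site.

    Accepted ⇔ stem distance ≤ *max_distance* (inclusive).  Nearest is by
    minimal stem distance, ties broken toward the 5′-most cleavage site.
    Sites on transcripts without cleavage sites are emitted unaccepted;
    functional sites pass through flagged bioactive-by-binding.
    """
    by_id = {s.transcript_id: s for s in structures}
    out: list[TriageCandidate] = []
    for site in sites:
        if site.functional:
            out.append(
                TriageCandidate(site, None, None, accepted=False, bioactive_by_binding=True)
            )
            continue
        options = cleavages.get(site.transcript_id, [])
        if not options:
            out.append(TriageCandidate(site, None, None, accepted=False))
            continue
        structure = by_id[site.transcript_id]
        best = min(
            options, key=lambda c: (stem_distance(site, c, structure), c.start)
        )
        d = stem_distance(site, best, structure)
        out.append(TriageCandidate(site, best, d, accepted=d <= max_distance))
    return out


def rnasel_sites_table(sites: list[RNaseLSite]) -> pd.DataFrame:
    """BED-like table (1-based inclusive) of cleavage-site candidates."""
    return pd.DataFrame(
        [
            {
                "transcript_id": s.transcript_id,
                "start": s.start + 1,
                "end": s.start + 3,
                "trinucleotide": s.trinucleotide,
                "unpaired": "".join("U" if f else "P" for f in s.unpaired_flags),
                "loop_context": s.loop_context,
            }
            for s in sites
        ]
    )


def candidates_table(candidates: list[TriageCandidate]) -> pd.DataFrame:
    rows = []
    for c in candidates:
        site = c.target_site
        rows.append(
            {
                "compound_id": site.compound_id,
                "transcript_id": site.transcript_id,
                "motif": site.located_motif.motif.notation(),
                "top_start": site.located_motif.top_span[0] + 1,
                "functional": site.functional,
                "cleavage_start": c.cleavage_site.start + 1 if c.cleavage_site else "",
                "stem_distance_bp": c.stem_distance_bp if c.stem_distance_bp is not None else "",
                "accepted": c.accepted,
                "bioactive_by_binding": c.bioactive_by_binding,
            }
        )
    return pd.DataFrame(rows)
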