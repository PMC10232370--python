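"""Hairpin structures: sequence + dot-bracket, loop extraction, stem walk.

A :class:`HairpinStructure` is one transcript's sequence with a nested
dot-bracket string describing a single hairpin (one apical loop, no
pseudoknots or multibranch junctions) and optional Drosha/Dicer processing
annotations.  Motif extraction walks the stem from the outermost base pair
to the apex, emitting one :class:`LocatedMotif` per internal loop or bulge
(each carrying its nearest closing pair on both sides) and one for the
apical hairpin loop.

The base pairs of a hairpin, sorted by 5′ position, form a ladder of
"rungs" from the base to the apex.  Loop features sit between consecutive
rungs; the rung interval of a feature is the pair of bounding rung indices,
and the stem distance between two features is the number of base-paired
columns strictly between them along this ladder.

Coordinates are 0-based half-open internally and 1-based inclusive in all
file output.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .motifs import GAP, StructuralMotif

PROCESSING_SITE_TYPES = ("Drosha", "Dicer")


class StructureError(ValueError):
    """Invalid sequence/dot-bracket input (unbalanced, pseudoknot, ...)."""


@dataclass(frozen=True)
class ProcessingSite:
    """An annotated scissile position (0-based) of a given enzyme."""

    site_type: str
    position: int

    def __post_init__(self) -> None:
        if self.site_type not in PROCESSING_SITE_TYPES:
            raise ValueError(f"site_type must be one of {PROCESSING_SITE_TYPES}")


@dataclass(frozen=True)
class LocatedMotif:
    """A structural motif located on a transcript.

    ``top_span``/``bottom_span`` are 0-based half-open intervals covering
    the motif's strands including the closing-pair columns; hairpin loops
    occupy a single contiguous interval and have ``bottom_span`` None.
    """

    motif: StructuralMotif
    transcript_id: str
    top_span: tuple[int, int]
    bottom_span: tuple[int, int] | None

    def positions(self) -> list[int]:
        pos = list(range(*self.top_span))
        if self.bottom_span is not None:
            pos += list(range(*self.bottom_span))
        return pos


def pair_table(dotbracket: str) -> list[tuple[int, int]]:
    """Base pairs (i, j), i < j, sorted by i, from a nested dot-bracket.

    Raises :class:`StructureError` on unbalanced brackets, pseudoknot
    notation (non-``()`` brackets) or a multibranch layout (a single
    hairpin must have strictly nested pairs: sorted by i, the j are
    strictly decreasing).
    """
    if any(c in "[]{}<>" for c in dotbracket):
        raise StructureError("pseudoknot bracket layers are not supported")
    bad = set(dotbracket) - set("().")
    if bad:
        raise StructureError(f"invalid dot-bracket characters: {sorted(bad)}")
    stack: list[int] = []
    pairs: list[tuple[int, int]] = []
    for i, c in enumerate(dotbracket):
        if c == "(":
            stack.append(i)
        elif c == ")":
            if not stack:
                raise StructureError(f"unbalanced ')' at position {i}")
            pairs.append((stack.pop(), i))
    if stack:
        raise StructureError(f"unbalanced '(' at position {stack[-1]}")
    pairs.sort()
    for (i1, j1), (i2, j2) in zip(pairs, pairs[1:]):
        if not j2 < j1:
            raise StructureError(
                f"multibranch junction near pair ({i2}, {j2}); single hairpin required"
            )
    return pairs


@dataclass(frozen=True)
class HairpinStructure:
    """One transcript: sequence, dot-bracket, processing annotations."""

    transcript_id: str
    sequence: str
    dotbracket: str
    processing_sites: tuple[ProcessingSite, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.dotbracket):
            raise StructureError(
                f"{self.transcript_id}: sequence length {len(self.sequence)} "
                f"!= structure length {len(self.dotbracket)}"
            )
        for site in self.processing_sites:
            if not 0 <= site.position < len(self.sequence):
                raise StructureError(
                    f"{self.transcript_id}: annotation at {site.position} out of bounds"
                )
        pair_table(self.dotbracket)  # validates nesting

    # rungs: base pairs from base to apex ---------------------------------

    @property
    def rungs(self) -> list[tuple[int, int]]:
        return pair_table(self.dotbracket)

    def is_paired(self, pos: int) -> bool:
        return self.dotbracket[pos] != "."

    def rung_interval(self, positions: list[int]) -> tuple[int | None, int | None]:
        """Bounding rung indices (outer, inner) of a loop-side feature.

        ``outer`` is the innermost rung enclosing every position (None if
        the feature lies outside all pairs); ``inner`` is ``outer + 1``
        when a more apical rung exists, else None (apical loop).  For the
        nested single-hairpin layout, the rungs enclosing a position form
        a prefix of the ladder, so the count is found by bisection.
        """
        rungs = self.rungs
        if not rungs:
            return (None, None)
        starts = [i for i, _ in rungs]
        ends = [j for _, j in rungs]  # strictly decreasing
        enclosing = len(rungs)
        for pos in positions:
            n_i = bisect.bisect_left(starts, pos)  # rungs with i < pos
            n_j = len(ends) - bisect.bisect_left(list(reversed(ends)), pos + 1)
            enclosing = min(enclosing, min(n_i, n_j))
        outer = enclosing - 1 if enclosing > 0 else None
        inner = enclosing if enclosing < len(rungs) else None
        return (outer, inner)


def extract_motifs(structure: HairpinStructure) -> list[LocatedMotif]:
    """All loop motifs of a hairpin, base to apex.

    Every internal loop / bulge between two consecutive non-stacked rungs
    yields one motif carrying both closing pairs; the apical loop yields
    one hairpin-loop motif.  Helical (stacked) regions yield nothing.
    """
    seq = structure.sequence
    rungs = structure.rungs
    out: list[LocatedMotif] = []
    for (i, j), (i2, j2) in zip(rungs, rungs[1:]):
        if i2 == i + 1 and j2 == j - 1:
            continue  # stacked pair, helix continues
        top_int = seq[i + 1 : i2]
        bottom_int = seq[j2 + 1 : j][::-1]  # read 3'->5' to align with top
        width = max(len(top_int), len(bottom_int))
        top = seq[i] + top_int + GAP * (width - len(top_int)) + seq[i2]
        bottom = seq[j] + bottom_int + GAP * (width - len(bottom_int)) + seq[j2]
        out.append(
            LocatedMotif(
                motif=StructuralMotif(top, bottom),
                transcript_id=structure.transcript_id,
                top_span=(i, i2 + 1),
                bottom_span=(j2, j + 1),
            )
        )
    if rungs:
        i, j = rungs[-1]
        out.append(
            LocatedMotif(
                motif=StructuralMotif(seq[i : j + 1], "", hairpin=True),
                transcript_id=structure.transcript_id,
                top_span=(i, j + 1),
                bottom_span=None,
            )
        )
    return out


def motif_coverage(structure: HairpinStructure) -> tuple[set[int], set[int]]:
    """Partition of positions into (loop interiors, paired helix positions).

    Unpaired tails outside the outermost pair are in neither set.
    """
    paired = {p for ij in structure.rungs for p in ij}
    loops: set[int] = set()
    for lm in extract_motifs(structure):
        loops.update(p for p in lm.positions() if not structure.is_paired(p))
    return loops, paired


# -- file formats ---------------------------------------------------------


def read_structure_files(
    fasta_path: str | Path,
    dotbracket_path: str | Path,
    annotations_path: str | Path | None = None,
) -> list[HairpinStructure]:
    """Load hairpins from paired FASTA + dot-bracket (+ annotation TSV).

    The dot-bracket file mirrors FASTA layout (``>id`` then the structure
    line).  The annotation TSV has columns transcript_id, site_type,
    position (1-based inclusive).
    """
    seqs = {r.id: str(r.seq).upper().replace("T", "U") for r in SeqIO.parse(str(fasta_path), "fasta")}
    structs: dict[str, str] = {}
    current = None
    for line in Path(dotbracket_path).read_text().splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith(">"):
            current = line[1:].split()[0]
            structs[current] = ""
        elif current is not None:
            structs[current] += line
    annotations: dict[str, list[ProcessingSite]] = {}
    if annotations_path is not None:
        table = pd.read_csv(annotations_path, sep="\t")
        for row in table.itertuples(index=False):
            annotations.setdefault(str(row.transcript_id), []).append(
                ProcessingSite(row.site_type, int(row.position) - 1)
            )
    missing = set(seqs) ^ set(structs)
    if missing:
        raise StructureError(f"FASTA/dot-bracket records do not match: {sorted(missing)}")
    return [
        HairpinStructure(tid, seqs[tid], structs[tid], tuple(annotations.get(tid, ())))
        for tid in seqs
    ]


def write_structure_files(
    structures: list[HairpinStructure],
    fasta_path: str | Path,
    dotbracket_path: str | Path,
    annotations_path: str | Path | None = None,
) -> None:
    records = [
        SeqRecord(Seq(s.sequence), id=s.transcript_id, description="") for s in structures
    ]
    SeqIO.write(records, str(fasta_path), "fasta")
    with open(dotbracket_path, "w") as fh:
        for s in structures:
            fh.write(f">{s.transcript_id}\n{s.dotbracket}\n")
    if annotations_path is not None:
        rows = [
            {
                "transcript_id": s.transcript_id,
                "site_type": site.site_type,
                "position": site.position + 1,
            }
            for s in structures
            for site in s.processing_sites
        ]
        pd.DataFrame(rows, columns=["transcript_id", "site_type", "position"]).to_csv(
            annotations_path, sep="\t", index=False
        )
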