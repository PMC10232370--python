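"""Two-strand RNA structural motifs: the unit of the binding landscape.

A motif such as ``5′GAU/3′C_A`` (the A bulge of pre-miR-155) is written as
two aligned strands: the top strand 5′→3′ and the bottom strand 3′→5′, so
that aligned columns are pairing partners.  ``_`` marks a gap.  The two
terminal columns are the closing base pairs (Watson–Crick or GU wobble);
every interior nucleotide is a loop nucleotide.  The class of a motif is a
pure function of its gap layout:

* a×b internal loop — a top and b bottom interior nucleotides (a, b ≥ 1);
* n-nt bulge        — interior nucleotides on one strand only;
* fully paired      — no interior;
* hairpin loop      — single closing pair with an apical loop (constructed
  by :func:`ribotriage.structures.extract_motifs`, not parseable notation).

Strand assignment is arbitrary in a transcript, so two motifs that differ
only by swapping top and bottom strands (with 5′/3′ re-orientation) are
*equivalent*; indexing uses the canonical (lexicographically smaller)
orientation.
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass, field

GAP = "_"
NUCLEOTIDES = "ACGU"

WATSON_CRICK = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")}
WOBBLE = {("G", "U"), ("U", "G")}
PAIRS = WATSON_CRICK | WOBBLE


class MotifParseError(ValueError):
    """Base class for motif-notation parse failures."""


class MotifGrammarError(MotifParseError):
    """Notation does not match the 5′…/3′… grammar."""


class MotifLengthError(MotifParseError):
    """Strand lengths cannot be reconciled into aligned columns."""


class ClosingPairError(MotifParseError):
    """A terminal column is not a Watson–Crick or GU pair."""


class TerminalGapError(MotifParseError):
    """A terminal column contains a gap."""


def is_pair(a: str, b: str, *, wobble: bool = True) -> bool:
    """True if nucleotides *a*, *b* form a WC (or, optionally, GU) pair."""
    return (a, b) in (PAIRS if wobble else WATSON_CRICK)


@dataclass(frozen=True)
class StructuralMotif:
    """An aligned two-strand loop motif with its closing pairs.

    Parameters
    ----------
    top : str
        Top strand 5′→3′, with ``_`` for gaps.
    bottom : str
        Bottom strand written 3′→5′ so column *i* of ``top`` and ``bottom``
        are aligned (terminal columns pair).
    hairpin : bool
        Marks an apical hairpin loop: ``top`` then holds the full loop
        including both closing bases and ``bottom`` is empty.
    """

    top: str
    bottom: str
    hairpin: bool = field(default=False, compare=True)

    def __post_init__(self) -> None:
        if self.hairpin:
            if len(self.top) < 3 or self.bottom:
                raise MotifLengthError("hairpin motif needs >= 3 nt and an empty bottom strand")
            if not is_pair(self.top[0], self.top[-1]):
                raise ClosingPairError(
                    f"hairpin closing pair {self.top[0]}·{self.top[-1]} is not WC/GU"
                )
            return
        if len(self.top) != len(self.bottom):
            raise MotifLengthError(
                f"aligned strands differ in length ({len(self.top)} vs {len(self.bottom)})"
            )
        if len(self.top) < 2:
            raise MotifLengthError("motif needs at least the two closing columns")
        for col in (0, len(self.top) - 1):
            t, b = self.top[col], self.bottom[col]
            if GAP in (t, b):
                raise TerminalGapError(f"gap in terminal column {col}")
            if not is_pair(t, b):
                raise ClosingPairError(f"column {col}: {t}·{b} is not a WC/GU closing pair")
        for col, (t, b) in enumerate(zip(self.top, self.bottom)):
            if t == b == GAP:
                raise MotifParseError(f"column {col} is gap/gap")
            if t not in NUCLEOTIDES + GAP or b not in NUCLEOTIDES + GAP:
                raise MotifGrammarError(f"column {col}: invalid character {t!r}/{b!r}")

    # -- derived views ----------------------------------------------------

    @property
    def closing_pairs(self) -> tuple[tuple[str, str], ...]:
        if self.hairpin:
            return ((self.top[0], self.top[-1]),)
        n = len(self.top)
        return ((self.top[0], self.bottom[0]), (self.top[n - 1], self.bottom[n - 1]))

    @property
    def loop_top(self) -> str:
        if self.hairpin:
            return self.top[1:-1]
        return self.top[1:-1].replace(GAP, "")

    @property
    def loop_bottom(self) -> str:
        if self.hairpin:
            return ""
        return self.bottom[1:-1].replace(GAP, "")

    @property
    def motif_class(self) -> str:
        return classify_motif(self)

    def swapped(self) -> "StructuralMotif":
        """The same physical motif written with the strands exchanged."""
        if self.hairpin:
            return self
        return StructuralMotif(self.bottom[::-1], self.top[::-1])

    def normalized(self) -> "StructuralMotif":
        """Gap placement normalised: interior gaps sit next to the 3′ closing
        column and the aligned width is the longer interior (gap positions
        carry no information inside a loop)."""
        if self.hairpin:
            return self
        a, b = self.loop_top, self.loop_bottom
        w = max(len(a), len(b))
        top = self.top[0] + a + GAP * (w - len(a)) + self.top[-1]
        bottom = self.bottom[0] + b + GAP * (w - len(b)) + self.bottom[-1]
        return StructuralMotif(top, bottom)

    def canonical_key(self) -> tuple[str, str]:
        """Orientation- and gap-placement-independent key: the
        lexicographically smaller of the two normalised strand writings."""
        if self.hairpin:
            return (self.top, "")
        m = self.normalized()
        s = m.swapped().normalized()
        return min((m.top, m.bottom), (s.top, s.bottom))

    def notation(self) -> str:
        return format_motif(self)

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.notation()


_NOTATION = re.compile(r"^5[′']?([ACGU_]+)/3[′']?([ACGU_]+)$")


def parse_motif(notation: str) -> StructuralMotif:
    """Parse ``5′…/3′…`` motif notation into a :class:`StructuralMotif`.

    Unequal strand lengths (the compact form used for asymmetric loops,
    e.g. ``5′UUU/3′GUCA``) are canonicalised by padding the shorter side's
    interior with gaps adjacent to the 3′-closing column.
    """
    m = _NOTATION.match(notation.strip())
    if m is None:
        raise MotifGrammarError(f"notation {notation!r} does not match 5′<ACGU_>/3′<ACGU_>")
    top, bottom = m.group(1), m.group(2)
    if min(len(top), len(bottom)) < 2:
        raise MotifLengthError(f"both strands need >= 2 nt, got {len(top)}/{len(bottom)}")
    if len(top) != len(bottom):
        pad = abs(len(top) - len(bottom)) * GAP
        if len(top) < len(bottom):
            top = top[:-1] + pad + top[-1]
        else:
            bottom = bottom[:-1] + pad + bottom[-1]
    return StructuralMotif(top, bottom)


def format_motif(motif: StructuralMotif) -> str:
    """Render a motif in canonical ``5′…/3′…`` notation (gaps kept)."""
    if motif.hairpin:
        raise MotifParseError("hairpin loops have no two-strand notation")
    return f"5′{motif.top}/3′{motif.bottom}"


def canonicalize(notation: str) -> str:
    """Canonical written form of a notation string (gap padding normalised)."""
    return format_motif(parse_motif(notation))


def classify_motif(motif: StructuralMotif) -> str:
    """Closed-vocabulary class label; a×b loops report a ≥ b."""
    if motif.hairpin:
        return "hairpin loop"
    a = len(motif.loop_top)
    b = len(motif.loop_bottom)
    if a == 0 and b == 0:
        return "fully paired"
    if a == 0 or b == 0:
        return f"{max(a, b)}-nt bulge"
    return f"{min(a, b)}×{max(a, b)} internal loop"


def motifs_equivalent(m1: StructuralMotif, m2: StructuralMotif) -> bool:
    """True iff the motifs are identical up to a top/bottom strand swap."""
    return m1.canonical_key() == m2.canonical_key()


def enumerate_motifs(n_interior_columns: int) -> list[StructuralMotif]:
    """All valid motifs with the given number of interior aligned columns.

    Brute-force enumeration over closing pairs and interior column contents;
    used by tests as an oracle and small enough only for n ≤ 2.
    """
    alphabet = NUCLEOTIDES + GAP
    out = []
    for left in PAIRS:
        for right in PAIRS:
            for interior in itertools.product(
                itertools.product(alphabet, repeat=2), repeat=n_interior_columns
            ):
                if any(t == b == GAP for t, b in interior):
                    continue
                top = left[0] + "".join(t for t, _ in interior) + right[0]
                bottom = left[1] + "".join(b for _, b in interior) + right[1]
                out.append(StructuralMotif(top, bottom))
    return out
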