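"""Enumeration and motif classification of the 3×3 internal-loop library.

The library is a hairpin cassette displaying an internal loop whose two
strands are fully randomized (3 + 3 nucleotides by default), giving
4^6 = 4,096 unique members; crossed with a compound collection it spans the
full set of candidate binding interactions (4,096 × 15,000 = 61,440,000 for
the default screen).

Each member *displays* a motif that depends on how its randomized region
pairs.  The default classifier is a deterministic, dependency-free ladder
rule: aligned interior columns are paired outermost-in when they are WC (or
GU) complementary, and a single register shift is tried to detect the
bulge-forming members; no thermodynamics are involved, so the class
percentages it produces are a property of this rule, not of any free-energy
model.  A folding backend with the contract ``fold(sequence) -> dot-bracket``
can be plugged in instead (e.g. ViennaRNA), in which case classes are read
off the predicted structure.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable

import pandas as pd

from .motifs import NUCLEOTIDES, StructuralMotif, is_pair
from .structures import HairpinStructure, extract_motifs

#: Synthetic default cassette arms.  ``stem5 + N*top + core5`` pairs with
#: ``core3 + N*bottom + stem3`` around a GAAA apical loop; the randomized
#: region sits between the C·G closing pair of the outer stem and the G·C
#: closing pair of the core stem.
DEFAULT_SCAFFOLD = {
    "stem5": "GGGCC",
    "core5": "GCUG",
    "apical_loop": "GAAA",
    "core3": "CAGC",
    "stem3": "GGCCC",
}


@dataclass(frozen=True)
class LibraryCassette:
    """The fixed cassette with a contiguous randomized internal region."""

    randomized_top: int = 3
    randomized_bottom: int = 3
    scaffold: dict = field(default_factory=lambda: dict(DEFAULT_SCAFFOLD))

    def __post_init__(self) -> None:
        if self.randomized_top + self.randomized_bottom < 1:
            raise ValueError("cassette needs at least one randomized position")

    @property
    def n_randomized(self) -> int:
        return self.randomized_top + self.randomized_bottom

    @property
    def size(self) -> int:
        return 4 ** self.n_randomized

    def member_sequence(self, randomized: str) -> str:
        top = randomized[: self.randomized_top]
        bottom = randomized[self.randomized_top :]
        s = self.scaffold
        return (
            s["stem5"] + top + s["core5"] + s["apical_loop"] + s["core3"] + bottom + s["stem3"]
        )


@dataclass(frozen=True)
class LibraryMember:
    """One enumerated cassette member and its displayed motif class."""

    member_id: str
    randomized_sequence: str
    motif_class: str
    displayed_motif: StructuralMotif | None = None


def enumerate_library(cassette: LibraryCassette | None = None) -> list[str]:
    """All randomized sequences of the cassette, lexicographic order."""
    cassette = cassette or LibraryCassette()
    return [
        "".join(combo)
        for combo in itertools.product(NUCLEOTIDES, repeat=cassette.n_randomized)
    ]


def interaction_space(n_members: int, n_compounds: int) -> int:
    """Number of candidate binding interactions in a library-vs-library screen."""
    return n_members * n_compounds


def _ladder_classify(
    top: str, bottom: str, *, wobble: bool = True, allow_shift: bool = True
) -> str:
    """Rule-based class of a randomized region.

    *top* is the 5′→3′ top interior; *bottom* is the bottom interior
    aligned 3′→5′ under it.  Columns are paired outermost-in when
    complementary; if a ±1 register shift pairs strictly more columns, the
    member is classed as bulge-forming.
    """
    if len(top) != len(bottom):
        return "other"
    n = len(top)
    paired = [is_pair(top[c], bottom[c], wobble=wobble) for c in range(n)]

    if allow_shift and n >= 2:
        aligned_count = sum(paired)
        shift_count = max(
            sum(is_pair(top[c + 1], bottom[c], wobble=wobble) for c in range(n - 1)),
            sum(is_pair(top[c], bottom[c + 1], wobble=wobble) for c in range(n - 1)),
        )
        if shift_count == n - 1 and shift_count > aligned_count:
            return "1-nt bulge"

    left = 0
    while left < n and paired[left]:
        left += 1
    right = 0
    while right < n - left and paired[n - 1 - right]:
        right += 1
    interior = n - left - right
    if interior == 0:
        return "fully paired"
    return f"{interior}×{interior} internal loop"


FoldBackend = Callable[[str], str]


def _backend_classify(cassette: LibraryCassette, randomized: str, fold: FoldBackend) -> str:
    """Class of the loop displayed at the randomized region per a folding backend."""
    seq = cassette.member_sequence(randomized)
    db = fold(seq)
    structure = HairpinStructure(f"member_{randomized}", seq, db)
    lo = len(cassette.scaffold["stem5"])
    hi = lo + cassette.randomized_top
    for lm in extract_motifs(structure):
        if lm.motif.hairpin:
            continue
        if lm.top_span[0] < hi and lm.top_span[1] > lo:
            return lm.motif.motif_class
    return "fully paired"


def classify_members(
    members: list[str],
    cassette: LibraryCassette | None = None,
    *,
    backend: FoldBackend | None = None,
    wobble: bool = True,
    allow_shift: bool = True,
) -> pd.DataFrame:
    """Per-member displayed-motif classes.

    Returns a DataFrame with columns member_id, randomized_sequence,
    motif_class.  With ``backend=None`` the deterministic ladder rule is
    used; otherwise classes come from the backend's predicted structures
    (failures propagate with the member id).
    """
    cassette = cassette or LibraryCassette()
    rows = []
    for rnd in members:
        if backend is None:
            top = rnd[: cassette.randomized_top]
            bottom_53 = rnd[cassette.randomized_top :]
            label = _ladder_classify(
                top, bottom_53[::-1], wobble=wobble, allow_shift=allow_shift
            )
        else:
            try:
                label = _backend_classify(cassette, rnd, backend)
            except Exception as exc:  # propagate with member id per contract
                raise RuntimeError(f"backend failed on member {rnd}") from exc
        rows.append({"member_id": f"member_{rnd}", "randomized_sequence": rnd, "motif_class": label})
    return pd.DataFrame(rows)


def library_class_report(classified: pd.DataFrame) -> pd.DataFrame:
    """Class distribution table: (motif_class, count, percent)."""
    if len(classified) == 0:
        raise ValueError("empty distribution")
    counts = classified["motif_class"].value_counts().sort_index()
    table = counts.rename("count").reset_index().rename(columns={"index": "motif_class"})
    table["percent"] = (100.0 * table["count"] / table["count"].sum()).round(1)
    return table


def write_library(
    members: pd.DataFrame,
    cassette: LibraryCassette,
    fasta_path: str | Path,
    classes_path: str | Path,
) -> None:
    """Members as FASTA with a sidecar class TSV."""
    with open(fasta_path, "w") as fh:
        for row in members.itertuples(index=False):
            fh.write(f">{row.member_id}\n{cassette.member_sequence(row.randomized_sequence)}\n")
    members.to_csv(classes_path, sep="\t", index=False)


def load_cassette(path: str | Path) -> LibraryCassette:
    """Cassette configuration from JSON."""
    cfg = json.loads(Path(path).read_text())
    return LibraryCassette(
        randomized_top=cfg.get("randomized_top", 3),
        randomized_bottom=cfg.get("randomized_bottom", 3),
        scaffold=cfg.get("scaffold", dict(DEFAULT_SCAFFOLD)),
    )


def viennarna_backend() -> FoldBackend:
    """Folding backend backed by the ViennaRNA bindings, if installed."""
    import RNA

    def fold(sequence: str) -> str:
        db, _ = RNA.fold(sequence)
        return db

    return fold
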