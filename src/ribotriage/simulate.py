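"""Synthetic inputs with planted ground truth for every pipeline stage.

Three generators emulate the data the triage consumes, so the whole
pipeline is testable without any download:

* :func:`gen_selection` — selected/input read-count pools drawn
  multinomially at fixed sequencing depth, with a configurable set of
  motifs enriched by given fold factors in the selected pool;
* :func:`gen_structure_db` — hairpin structure databases built to a
  placement plan: binding motifs, Drosha/Dicer scissile annotations and
  unpaired-U UNN loops are planted at recorded coordinates and stem
  distances, and everything else is fully paired, so a verification pass
  with the real extractors must find exactly the planted features;
* :func:`gen_compounds` — small valid compound sets decorated from ring
  templates, so scaffold grouping has a known answer.

All randomness flows through ``numpy.random.default_rng`` (PCG64); the
seed is recorded in every ground-truth object and identical seeds give
byte-identical output files.

:func:`study_plan` builds the placement plan whose mapped landscape has
the head-count structure of the miRNA analysis this package mirrors:
13 motifs placed 114 times across 111 hairpins, 33 sites inside
processing windows and 55 silent sites with a UNN loop within 10 bp.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from rdkit import Chem

from .motifs import GAP, StructuralMotif, parse_motif
from .structures import HairpinStructure, ProcessingSite, extract_motifs
from .triage import scan_rnasel

GENERATOR_ID = "numpy.random.default_rng(PCG64)"

#: Stem pairs use WC only so every stem position is unambiguously paired.
_STEM_PAIRS = [("G", "C"), ("C", "G"), ("A", "U"), ("U", "A")]

#: The planted RNase L substrate: a 2×1 loop whose single 5′-side U is
#: unpaired and starts a UNN (UCG) trinucleotide.
RNASEL_LOOP = "5′CUCG/3′GA_C"

#: Thirteen distinct binding motifs (interiors avoid U so planted binding
#: sites can never create accidental RNase L sites).  The first is the
#: pre-miR-155-style A bulge.
STUDY_MOTIFS = (
    "5′GAU/3′C_A",
    "5′CAG/3′G_C",
    "5′GAC/3′CAG",
    "5′CCG/3′GAC",
    "5′GAAC/3′CAAG",
    "5′GCAC/3′CAAG",
    "5′GAAAC/3′CAAAG",
    "5′GCACC/3′CAAAG",
    "5′GACAC/3′CAAAG",
    "5′GAAC/3′C_AG",
    "5′GCU/3′C_A",
    "5′GAAU/3′C__A",
    "5′CAAG/3′GA_C",
)


# -- selection pools ------------------------------------------------------


def gen_selection(
    n_motifs: int,
    enriched: dict[str, float] | None,
    depth_sel: int,
    depth_in: int,
    seed: int,
    *,
    motif_ids: list[str] | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Multinomial selected/input pools with planted fold-enrichments.

    The input pool is multinomial over uniform motif weights; the selected
    pool multiplies the weight of each enriched motif by its fold factor
    and renormalises.  Returns (count table, ground truth).
    """
    if depth_sel <= 0 or depth_in <= 0:
        raise ValueError("pool depths must be positive")
    if motif_ids is None:
        motif_ids = [f"motif_{i:05d}" for i in range(n_motifs)]
    if len(motif_ids) != n_motifs:
        raise ValueError("motif_ids length must equal n_motifs")
    enriched = dict(enriched or {})
    unknown = set(enriched) - set(motif_ids)
    if unknown:
        raise ValueError(f"enriched motifs not in the library: {sorted(unknown)}")
    if any(f < 0 for f in enriched.values()):
        raise ValueError("fold-enrichments must be >= 0")
    rng = np.random.default_rng(seed)
    w_in = np.full(n_motifs, 1.0 / n_motifs)
    w_sel = w_in * np.array([enriched.get(m, 1.0) for m in motif_ids])
    w_sel = w_sel / w_sel.sum()
    counts = pd.DataFrame(
        {
            "motif_id": motif_ids,
            "k_sel": rng.multinomial(depth_sel, w_sel),
            "k_in": rng.multinomial(depth_in, w_in),
        }
    )
    truth = {
        "generator": GENERATOR_ID,
        "seed": seed,
        "kind": "selection",
        "n_motifs": n_motifs,
        "depth_sel": depth_sel,
        "depth_in": depth_in,
        "enriched": enriched,
    }
    return counts, truth


# -- structure databases --------------------------------------------------


@dataclass(frozen=True)
class MotifPlacement:
    """One planted binding site, bottom-to-apex order within a hairpin."""

    motif: str
    compound_id: str
    functional: bool = False
    site_type: str = "Dicer"
    rnasel_stem_distance: int | None = None  # pairs to a planted UNN loop


@dataclass(frozen=True)
class HairpinPlan:
    transcript_id: str
    placements: tuple[MotifPlacement, ...] = field(default_factory=tuple)


class PlanError(ValueError):
    """Internally inconsistent or infeasible placement plan."""


def _build_hairpin(
    plan: HairpinPlan,
    rng: np.random.Generator,
    *,
    basal_stem: int = 4,
    spacer_stem: int = 4,
    apical_stem: int = 3,
    apical_loop: str = "GCAA",
) -> tuple[HairpinStructure, list[dict]]:
    """Assemble one hairpin: stems, planted motifs, UNN loops, apex."""
    five: list[tuple[str, str]] = []   # (nucleotide, dot-bracket) on 5' arm
    three: list[tuple[str, str]] = []  # 3' arm collected outer-first

    def add_pair(b5: str, b3: str) -> None:
        five.append((b5, "("))
        three.append((b3, ")"))

    def add_stem(n: int) -> None:
        for _ in range(n):
            b5, b3 = _STEM_PAIRS[rng.integers(len(_STEM_PAIRS))]
            add_pair(b5, b3)

    def add_motif(m: StructuralMotif) -> tuple[tuple[int, int], tuple[int, int]]:
        top_start = len(five)
        bottom_start3 = len(three)
        add_pair(m.top[0], m.bottom[0])
        for col in range(1, len(m.top) - 1):
            if m.top[col] != GAP:
                five.append((m.top[col], "."))
            if m.bottom[col] != GAP:
                three.append((m.bottom[col], "."))
        add_pair(m.top[-1], m.bottom[-1])
        return (top_start, len(five)), (bottom_start3, len(three))

    add_stem(basal_stem)
    records: list[dict] = []
    for placement in plan.placements:
        motif = parse_motif(placement.motif)
        top_span, bottom_span3 = add_motif(motif)
        rec = {
            "motif": placement.motif,
            "compound_id": placement.compound_id,
            "transcript_id": plan.transcript_id,
            "top_span": top_span,
            "bottom_span3": bottom_span3,
            "functional": placement.functional,
            "site_type": placement.site_type,
            "rnasel_stem_distance": placement.rnasel_stem_distance,
            "unn_start": None,
        }
        if placement.rnasel_stem_distance is not None:
            d = placement.rnasel_stem_distance
            if d < 0:
                raise PlanError(f"{plan.transcript_id}: negative stem distance")
            add_stem(d)
            unn_top_span, unn_bottom3 = add_motif(parse_motif(RNASEL_LOOP))
            rec["unn_start"] = unn_top_span[0] + 1  # the unpaired U
            rec["unn_spans"] = (unn_top_span, unn_bottom3)
        records.append(rec)
        add_stem(spacer_stem)
    add_stem(apical_stem)

    total = len(five) + len(apical_loop) + len(three)
    seq = "".join(b for b, _ in five) + apical_loop + "".join(
        b for b, _ in reversed(three)
    )
    db = "".join(c for _, c in five) + "." * len(apical_loop) + "".join(
        c for _, c in reversed(three)
    )

    annotations = []
    for rec in records:
        # 3'-arm collected outer-first: index k maps to final total-1-k
        b3 = rec.pop("bottom_span3")
        rec["bottom_span"] = (total - b3[1], total - b3[0])
        if "unn_spans" in rec:
            rec.pop("unn_spans")
        if rec["functional"]:
            rec["scissile_position"] = rec["top_span"][0]
            annotations.append(ProcessingSite(rec["site_type"], rec["top_span"][0]))
    structure = HairpinStructure(plan.transcript_id, seq, db, tuple(annotations))
    return structure, records


def gen_structure_db(
    plans: list[HairpinPlan],
    seed: int,
    *,
    n_plain_hairpins: int = 0,
    verify: bool = True,
) -> tuple[list[HairpinStructure], dict]:
    """Hairpin database built to a placement plan, plus ground truth.

    ``n_plain_hairpins`` appends feature-free perfect hairpins.  With
    ``verify`` the real extractors/scanners are run over the output and
    the found features checked against the plan (raises on any accidental
    or missing feature).
    """
    rng = np.random.default_rng(seed)
    structures: list[HairpinStructure] = []
    placements: list[dict] = []
    for plan in plans:
        structure, recs = _build_hairpin(plan, rng)
        structures.append(structure)
        placements.extend(recs)
    for k in range(n_plain_hairpins):
        structure, _ = _build_hairpin(
            HairpinPlan(f"plain_{k:04d}"), rng, basal_stem=6, apical_stem=4
        )
        structures.append(structure)
    truth = {
        "generator": GENERATOR_ID,
        "seed": seed,
        "kind": "structure_db",
        "n_hairpins": len(structures),
        "placements": placements,
        "rnasel_loop": RNASEL_LOOP,
    }
    if verify:
        verify_structure_db(structures, truth)
    return structures, truth


def verify_structure_db(structures: list[HairpinStructure], truth: dict) -> None:
    """Assert found features == planted features (no accidental motifs)."""
    unn_key = parse_motif(RNASEL_LOOP).canonical_key()
    planted = truth["placements"]
    by_transcript: dict[str, list[dict]] = {}
    for rec in planted:
        by_transcript.setdefault(rec["transcript_id"], []).append(rec)
    for structure in structures:
        recs = by_transcript.get(structure.transcript_id, [])
        expected_spans = {tuple(r["top_span"]): parse_motif(r["motif"]).canonical_key() for r in recs}
        expected_unn = {r["unn_start"] for r in recs if r["unn_start"] is not None}
        found_loops = {}
        for lm in extract_motifs(structure):
            if lm.motif.hairpin:
                continue
            found_loops[lm.top_span] = lm.motif.canonical_key()
        found_binding = {s: k for s, k in found_loops.items() if k != unn_key}
        found_unn_loops = sum(k == unn_key for k in found_loops.values())
        if found_binding != expected_spans:
            raise PlanError(
                f"{structure.transcript_id}: extracted motifs differ from plan "
                f"(found {sorted(found_binding)}, planted {sorted(expected_spans)})"
            )
        if found_unn_loops != len(expected_unn):
            raise PlanError(f"{structure.transcript_id}: accidental or missing UNN loop")
        scanned = {s.start for s in scan_rnasel(structure)}
        if scanned != expected_unn:
            raise PlanError(
                f"{structure.transcript_id}: UNN scan {sorted(scanned)} != planted "
                f"{sorted(expected_unn)}"
            )


def study_plan() -> tuple[list[HairpinPlan], pd.DataFrame]:
    """The head-count-replicating plan and its compound→motif table.

    13 motifs placed 114 times in 111 hairpins: 3 hairpins carry two
    functional sites, 27 single sites are functional (33 functional in
    all), 55 silent sites get a UNN loop at stem distances cycling through
    0–10 bp (five full cycles, including the 7-bp geometry), 13 get
    distances 11–13 bp and 13 get no UNN loop.  Motifs are assigned
    round-robin and each motif is bound by exactly one of six compounds.
    """
    motifs = list(STUDY_MOTIFS)
    compound_of = {m: f"C{(i % 6) + 1}" for i, m in enumerate(motifs)}
    eligible_distances = [7, 0, 3, 10, 5, 2, 8, 4, 6, 9, 1]  # 5 cycles = 55
    plans: list[HairpinPlan] = []
    placement_no = 0

    def next_motif() -> str:
        nonlocal placement_no
        m = motifs[placement_no % len(motifs)]
        placement_no += 1
        return m

    def make(motif: str, **kw) -> MotifPlacement:
        return MotifPlacement(motif=motif, compound_id=compound_of[motif], **kw)

    for h in range(3):  # double-site hairpins, both functional
        plans.append(
            HairpinPlan(
                f"hairpin_{h:03d}",
                (
                    make(next_motif(), functional=True, site_type="Drosha"),
                    make(next_motif(), functional=True, site_type="Dicer"),
                ),
            )
        )
    for h in range(3, 30):  # 27 functional singles
        site_type = "Drosha" if h % 2 else "Dicer"
        plans.append(
            HairpinPlan(
                f"hairpin_{h:03d}", (make(next_motif(), functional=True, site_type=site_type),)
            )
        )
    for k, h in enumerate(range(30, 85)):  # 55 silent, UNN within 10 bp
        d = eligible_distances[k % len(eligible_distances)]
        plans.append(
            HairpinPlan(f"hairpin_{h:03d}", (make(next_motif(), rnasel_stem_distance=d),))
        )
    for k, h in enumerate(range(85, 98)):  # 13 silent, UNN beyond 10 bp
        plans.append(
            HairpinPlan(
                f"hairpin_{h:03d}", (make(next_motif(), rnasel_stem_distance=11 + k % 3),)
            )
        )
    for h in range(98, 111):  # 13 silent, no UNN loop
        plans.append(HairpinPlan(f"hairpin_{h:03d}", (make(next_motif()),)))

    bound_table = pd.DataFrame(
        [{"compound_id": compound_of[m], "motif": m} for m in motifs]
    )
    return plans, bound_table


# -- compounds ------------------------------------------------------------

DEFAULT_TEMPLATES = {
    "benzene": "c1ccc({R})cc1",
    "pyrrolidine": "C1CCN({R})C1",
    "naphthalene": "c1ccc2cc({R})ccc2c1",
    "indole": "c1ccc2c(c1)ccn2{R}",
    "biphenyl": "c1ccc(-c2ccc({R})cc2)cc1",
}

_DECORATIONS = [
    "C", "CC", "CCC", "CCCC", "C(C)C", "CC(C)C", "CCO", "CCN",
    "O", "OC", "OCC", "N", "NC", "N(C)C", "F", "Cl", "Br", "I",
    "C(F)(F)F", "C#N", "C(=O)C", "C(=O)OC", "C(=O)N", "C=C",
]


def gen_compounds(
    n_per_template: int,
    templates: dict[str, str] | None = None,
    seed: int = 0,
) -> tuple[dict[str, str], dict]:
    """Decorated compounds from ring templates; all SMILES validated.

    Returns ({compound_id: smiles}, ground truth with the template map).
    """
    templates = dict(templates or DEFAULT_TEMPLATES)
    if n_per_template > len(_DECORATIONS):
        raise ValueError(f"at most {len(_DECORATIONS)} decorations per template")
    rng = np.random.default_rng(seed)
    compounds: dict[str, str] = {}
    template_of: dict[str, str] = {}
    for name, template in templates.items():
        if "{R}" not in template:
            raise ValueError(f"template {name!r} lacks an {{R}} attachment point")
        picks = rng.choice(len(_DECORATIONS), size=n_per_template, replace=False)
        for k, idx in enumerate(picks):
            smiles = template.replace("{R}", _DECORATIONS[int(idx)])
            if Chem.MolFromSmiles(smiles) is None:
                raise ValueError(f"template {name!r} produced invalid SMILES {smiles!r}")
            cid = f"{name}_{k:02d}"
            compounds[cid] = smiles
            template_of[cid] = name
    truth = {
        "generator": GENERATOR_ID,
        "seed": seed,
        "kind": "compounds",
        "templates": templates,
        "template_of": template_of,
    }
    return compounds, truth


# -- ground-truth serialisation ------------------------------------------


def write_ground_truth(truth: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(truth, indent=2, sort_keys=True, default=str) + "\n")


def read_ground_truth(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())
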