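"""RNase L UNN scanning, stem distances and RIBOTAC candidate triage."""

import pandas as pd
import pytest

from ribotriage.mapping import annotate_sites, build_motif_index, map_binders
from ribotriage.simulate import (
    HairpinPlan,
    MotifPlacement,
    _build_hairpin,
    gen_structure_db,
)
from ribotriage.structures import HairpinStructure
from ribotriage.triage import RNaseLSite, scan_rnasel, stem_distance, triage

import numpy as np

A_BULGE = "5′GAU/3′C_A"
MIR155_LOOP = "5′UUU/3′GUCA"


def _mapped_sites(structures, compound="C1", motif=A_BULGE):
    index, _ = build_motif_index(structures)
    bound = pd.DataFrame({"compound_id": [compound], "motif": [motif]})
    return annotate_sites(map_binders(bound, index), structures)


def test_fully_paired_duplex_has_no_sites():
    structure = HairpinStructure("d", "UUUUAAAA", "(((())))")
    assert scan_rnasel(structure) == []


def test_mir155_style_loop_is_a_substrate():
    """The 1×2 loop with unpaired Us on both strands is reported."""
    plan = HairpinPlan(
        "m155",
        (MotifPlacement(A_BULGE, "C1"), MotifPlacement(MIR155_LOOP, "C1")),
    )
    structure, _ = _build_hairpin(plan, np.random.default_rng(0))
    sites = scan_rnasel(structure)
    assert sites, "unpaired-U UNN loop not detected"
    assert all(s.trinucleotide[0] == "U" and s.unpaired_flags[0] for s in sites)
    assert any(s.loop_context == "internal loop/bulge" for s in sites)
    # strict mode drops triplets whose further Us are paired
    strict = scan_rnasel(structure, strict=True)
    assert set(s.start for s in strict) <= set(s.start for s in sites)


def test_two_planted_unn_loops_found_at_exact_positions():
    plans = [
        HairpinPlan(
            "h0",
            (
                MotifPlacement(A_BULGE, "C1", rnasel_stem_distance=3),
                MotifPlacement("5′GAC/3′CAG", "C1", rnasel_stem_distance=5),
            ),
        )
    ]
    structures, truth = gen_structure_db(plans, seed=2)
    expected = {r["unn_start"] for r in truth["placements"]}
    found = {s.start for s in scan_rnasel(structures[0])}
    assert found == expected


@pytest.mark.parametrize("planted", [0, 3, 7, 10, 11])
def test_stem_distance_matches_planted_geometry(planted):
    plans = [
        HairpinPlan("h0", (MotifPlacement(A_BULGE, "C1", rnasel_stem_distance=planted),))
    ]
    structures, _ = gen_structure_db(plans, seed=3)
    (site,) = _mapped_sites(structures)
    (cleavage,) = scan_rnasel(structures[0])
    assert stem_distance(site, cleavage, structures[0]) == planted


def test_seven_bp_mir155_geometry_with_the_real_cleavage_loop():
    """A bulge seven pairs below a 5′UUU/3′GUCA loop measures 7 bp."""
    plan = HairpinPlan(
        "m155", (MotifPlacement(A_BULGE, "C1"), MotifPlacement(MIR155_LOOP, "C1"))
    )
    structure, _ = _build_hairpin(plan, np.random.default_rng(1), spacer_stem=7)
    (site,) = _mapped_sites([structure])
    cleavages = scan_rnasel(structure)
    assert min(stem_distance(site, c, structure) for c in cleavages) == 7


def test_stem_distance_is_symmetric_between_features():
    """Distance between two loops is the same measured from either side."""
    plan = HairpinPlan(
        "sym", (MotifPlacement(A_BULGE, "C1"), MotifPlacement("5′GAC/3′CAG", "C1"))
    )
    structure, truth_recs = _build_hairpin(plan, np.random.default_rng(4), spacer_stem=6)
    index, _ = build_motif_index([structure])
    bound = pd.DataFrame(
        {"compound_id": ["C1", "C1"], "motif": [A_BULGE, "5′GAC/3′CAG"]}
    )
    site_a, site_b = annotate_sites(map_binders(bound, index), [structure])
    # synthetic cleavage markers inside each loop's unpaired region
    probe_a = RNaseLSite("sym", site_a.located_motif.top_span[0] + 1, "NNN", (True,) * 3, "x")
    probe_b = RNaseLSite("sym", site_b.located_motif.top_span[0] + 1, "NNN", (True,) * 3, "x")
    assert stem_distance(site_a, probe_b, structure) == stem_distance(
        site_b, probe_a, structure
    )


def test_stem_distance_monotone_along_one_stem():
    """A more apical loop is never closer than one in between."""
    plan = HairpinPlan(
        "mono",
        (
            MotifPlacement(A_BULGE, "C1"),
            MotifPlacement("5′GAC/3′CAG", "C1"),
            MotifPlacement("5′GAAC/3′CAAG", "C1"),
        ),
    )
    structure, _ = _build_hairpin(plan, np.random.default_rng(6), spacer_stem=4)
    sites = _mapped_sites_multi(structure)
    base = sites[0]
    probes = [
        RNaseLSite("mono", s.located_motif.top_span[0] + 1, "NNN", (True,) * 3, "x")
        for s in sites[1:]
    ]
    d_near = stem_distance(base, probes[0], structure)
    d_far = stem_distance(base, probes[1], structure)
    assert d_far >= d_near


def _mapped_sites_multi(structure):
    index, _ = build_motif_index([structure])
    bound = pd.DataFrame(
        {
            "compound_id": ["C1"] * 3,
            "motif": [A_BULGE, "5′GAC/3′CAG", "5′GAAC/3′CAAG"],
        }
    )
    sites = annotate_sites(map_binders(bound, index), [structure])
    return sorted(sites, key=lambda s: s.located_motif.top_span[0])


def test_different_transcripts_rejected():
    plans = [
        HairpinPlan("h0", (MotifPlacement(A_BULGE, "C1", rnasel_stem_distance=2),)),
        HairpinPlan("h1", (MotifPlacement(A_BULGE, "C1", rnasel_stem_distance=2),)),
    ]
    structures, _ = gen_structure_db(plans, seed=8)
    (c0,) = scan_rnasel(structures[0])
    sites = _mapped_sites(structures)
    other = next(s for s in sites if s.transcript_id == "h1")
    with pytest.raises(ValueError):
        stem_distance(other, c0, structures[1])


@pytest.mark.parametrize(
    "planted, accepted", [(3, True), (10, True), (11, False)]
)
def test_triage_distance_threshold_is_inclusive(planted, accepted):
    plans = [
        HairpinPlan("h0", (MotifPlacement(A_BULGE, "C1", rnasel_stem_distance=planted),))
    ]
    structures, _ = gen_structure_db(plans, seed=9)
    sites = _mapped_sites(structures)
    cleavages = {s.transcript_id: scan_rnasel(s) for s in structures}
    (candidate,) = triage(sites, cleavages, structures, max_distance=10)
    assert candidate.stem_distance_bp == planted
    assert candidate.accepted is accepted


def test_transcript_without_cleavage_sites_yields_unaccepted_candidate():
    plans = [HairpinPlan("h0", (MotifPlacement(A_BULGE, "C1"),))]
    structures, _ = gen_structure_db(plans, seed=10)
    sites = _mapped_sites(structures)
    (candidate,) = triage(sites, {"h0": []}, structures)
    assert candidate.cleavage_site is None
    assert candidate.accepted is False


def test_functional_sites_pass_through_as_bioactive_by_binding():
    plans = [HairpinPlan("h0", (MotifPlacement(A_BULGE, "C1", functional=True),))]
    structures, _ = gen_structure_db(plans, seed=11)
    sites = _mapped_sites(structures)
    assert sites[0].functional
    (candidate,) = triage(sites, {"h0": []}, structures)
    assert candidate.bioactive_by_binding
    assert candidate.accepted is False
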