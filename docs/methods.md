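# Methods

## Motif model

A structural motif is a pair of aligned strands: the top strand 5′→3′ and
the bottom strand written 3′→5′, so that column *i* of both strings are
pairing partners; `_` marks a gap.  The two terminal columns must be
Watson–Crick or GU-wobble pairs (the closing pairs); every interior
nucleotide is a loop nucleotide.  GU wobble counts as paired everywhere —
closing pairs and helices — which standard RNA practice requires (the
U·G closing of the miR-155 cleavage loop 5′UUU/3′GUCA would otherwise be
unparseable).  Classification is a pure function of the gap layout:
*a*×*b* internal loop (*a*, *b* ≥ 1 interior nucleotides per strand,
reported smaller-first, e.g. 1×2), *n*-nt bulge (one interior strand all
gaps), fully paired (no interior), hairpin loop (apical loops produced by
extraction only).

Two conventions make motifs comparable across writings:

* **Orientation.**  Strand assignment is arbitrary in a transcript, so a
  motif and its strand-swap (top′ = reverse(bottom), bottom′ =
  reverse(top)) are equivalent; indexing uses the lexicographically
  smaller writing as the canonical key.
* **Gap placement.**  Gap positions inside a loop carry no information;
  canonical keys right-pack interior gaps against the 3′ closing column.
  The parser also accepts the compact unequal-length notation used for
  asymmetric loops (5′UUU/3′GUCA ≡ 5′UU_U/3′GUCA).

Coordinates are 0-based half-open internally and 1-based inclusive in all
file output.

Motif extraction walks a nested dot-bracket structure (single hairpin; no
pseudoknots or multibranch junctions, which are rejected with errors)
from the outermost base pair to the apex.  Consecutive stacked pairs form
helices; each non-stacked step emits one internal loop or bulge carrying
its nearest closing pair on both sides, and the innermost pair closes the
hairpin loop.  Unpaired positions therefore partition into loop
interiors, paired positions into helices; unpaired 5′/3′ tails outside
the outermost pair are tolerated but belong to neither.

## Library classification

The 3×3 internal-loop library cassette is a hairpin with a contiguous
3+3-nt randomized region; enumeration is exhaustive and lexicographic
(4⁶ = 4,096 members).  The exact published cassette arms are not public,
so the default scaffold (`GGGCC·NNN·GCUG–GAAA–CAGC·NNN·GGCCC`) is a
documented synthetic stand-in: only the closing pairs around the
randomized window matter to the displayed motif.

What fold a member *displays* depends on a structure model.  The default
classifier is a deterministic ladder rule with no thermodynamics: aligned
interior columns are paired outermost-in while WC/GU-complementary, the
remaining block is an *n*×*n* loop (or fully paired), and a ±1 register
shift that pairs strictly more columns than the aligned reading classes
the member as bulge-forming.  Class percentages under this rule are a
property of the rule; they are not expected to reproduce percentages
derived from free-energy folding, which is why a folding backend with the
contract `fold(sequence) → dot-bracket` (e.g. the ViennaRNA bindings) can
be plugged in instead.

## Enrichment statistic

Z_obs is the pooled two-proportion z-statistic (see README for the
formula).  Choices worth stating:

* **Pooled variance**, no continuity correction, no pseudocount by
  default (a +0.5 pseudocount is available for sparse tables).  The
  statistic returns 0 when the pooled proportion is degenerate and is
  antisymmetric under pool exchange.
* **Bound call**: strictly greater than the threshold (default 8) and
  one-sided — depletion is never "bound".  No multiple-testing
  correction is applied across motifs; the fixed high threshold plays
  that role.
* **LOGO selection**: motifs ranked by Z_obs, ties broken by
  lexicographic sequence order for determinism, top ⌈0.005·n⌉ retained
  per compound; per-column nucleotide frequencies always sum to 1.
* **Class enrichment**: the replicates of the t-test are the compounds —
  each compound contributes its bound-set class fraction, tested
  two-tailed against the library background with df = n−1.  With zero
  variance the statistic degenerates to t = 0, p = 1 (all fractions equal
  to background) or p = 0 (all equal but displaced).  Fewer than two
  compounds is flagged untestable rather than guessed.

Null calibration: with equal pools at depth 10⁴ over 2,000 motifs the
per-motif statistic is approximately standard normal; the one-sided
exceedance at z > 2 sits near the nominal 0.0228 (slightly below it, the
residual being count discreteness at ~5 reads per motif) and no null
motif approaches z = 8.  At depth 10⁵, 20 motifs planted at 10-fold
enrichment among 4,096 give per-motif z ≈ 13 and are recovered in
essentially every seed.

## Mapping and functional annotation

Bound motifs are looked up in an index of every extracted internal
loop/bulge keyed by canonical motif; each (compound, location) hit is one
target site, and location-level summaries deduplicate compound
multiplicity.  A site is *functional* when any of its motif's nucleotides
lies within ±2 nt (configurable) of an annotated Drosha/Dicer scissile
position — the geometry in which a bound molecule can occlude processing;
the nearest distance is recorded, and transcripts without annotations
yield silent sites explicitly flagged unannotated.  Percentages are
reported over sites, with transcript counts alongside, because both
denominators are in common use.

## RNase L overlay and stem distance

The scanner reports every position with an unpaired U and two further
nucleotides in bounds (the UNN pattern); strict mode additionally
requires any U inside the trinucleotide to be unpaired.  The default mode
is deliberately permissive — the substrate preference is a soft motif.

The stem distance between a binding motif and a cleavage site is the
number of base-paired rungs strictly between the two loop regions on the
hairpin ladder, exclusive of each loop's own bounding pair: loops with
stacked closing pairs are 0 bp apart, and seven stacked pairs between the
A-bulge and the UNN loop of the miR-155 model hairpin measure 7 bp.  The
measure is symmetric and monotone along a stem.  "Within 10 bp" is
inclusive (≤ 10), counted in base pairs, not nucleotides.  The nearest
cleavage site is chosen by minimal distance with ties broken toward the
5′-most site.  Functional sites bypass the distance rule and are flagged
bioactive-by-binding; silent sites on transcripts without any UNN site
are emitted unaccepted rather than dropped.

## Chemical profiling

Fingerprints are 2048-bit Morgan circular fingerprints at radius 2 (the
de facto default; recorded in output metadata).  Tanimoto similarity is
|A∩B|/|A∪B|, defined as 1 for two empty fingerprints; a compound is
dissimilar to a reference set when its maximum similarity is strictly
below 0.7.  Set-level novelty reports the mean ± s.d. of per-compound
mean similarities.  Descriptors are Ertl-contribution TPSA and Lipinski
H-bond donor/acceptor counts.  Scaffolds are Bemis–Murcko ring-system
frameworks after iterative side-chain removal; scaffold *classes* merge
frameworks that coincide after making them generic (all atoms carbon,
all bonds single).  Reference binder collections are user-supplied SMILES
files, not bundled.

## Synthetic data

The generators define the conditions every statistical claim is tested
under:

* **Selection pools** are multinomial at fixed depth (matching fixed
  sequencing depth), input uniform over motifs, selected with enriched
  motifs' weights multiplied by their fold factors and renormalised.
  Default study conditions: 4,096 motifs; depth 10⁴ per pool for null
  calibration, 10⁵ for recovery studies; 20 planted motifs at 10-fold.
* **Hairpin databases** are assembled bottom-to-apex from WC stems
  (4-bp basal/spacer stems, 3-bp apical stem, GCAA apical loop) with
  placements inserted as literal motif columns.  The planted RNase L
  substrate is a 2×1 loop (5′CUCG/3′GA_C) whose single unpaired U starts
  a UCG triplet; planted binding motifs use U-free interiors, stems are
  fully paired and the apical loop is U-free, so no accidental UNN site
  or loop motif can arise — a verification pass runs the real extractor
  and scanner over every generated database and fails on any deviation
  from the plan.  Functional placements put the scissile annotation at
  the motif's first position (distance 0).
* **The study plan** mirrors the head counts of the miRNA landscape
  analysis: 111 hairpins, three carrying two functional sites and 108 one
  site (114 sites, 33 functional); of the 81 silent sites, 55 carry a UNN
  loop at stem distances cycling through 0–10 bp (five full cycles,
  including 7 bp), 13 at 11–13 bp and 13 none, so site-level summaries
  come out at 28.9 % functional and 48.2 % RIBOTAC-eligible by
  construction.
* **Compounds** are ring templates (benzene, pyrrolidine, naphthalene,
  indole, biphenyl — five distinct generic frameworks) decorated with
  acyclic substituents, so scaffold grouping has the known answer
  (5 scaffolds, 5 classes).

All randomness flows through `numpy.random.default_rng` (PCG64) with the
seed recorded in every ground-truth object; identical seeds give
byte-identical files.

What the generators do **not** emulate: sequencing error, PCR bias and
read-level data; thermodynamic structure ensembles (one fixed structure
per transcript, no alternative folds); pseudoknots and multibranch
junctions; real miRNA sequence composition (stems are random WC pairs).
Passing tests therefore demonstrate correctness of the statistics,
extraction, mapping and triage logic under known ground truth — not that
any particular biological database would yield the same percentages.

## Numerical conventions

Percentages are rounded half-up at the displayed precision (0.21752 % →
0.22 %, 22.5 % → 23 % at integer precision).  Ranking ties are broken
lexicographically throughout for determinism.  Degenerate inputs (empty
pools, zero denominators, empty bound sets, transcripts without
annotations or cleavage sites) return explicit zeros/flags rather than
raising, except where the input is malformed (unbalanced dot-bracket,
invalid SMILES, negative depths), which raises typed errors.

## Known limitations

* The ladder classifier is a rule, not a folding model; library class
  percentages are backend-dependent by design.
* The exact variant of the pooled-comparison statistic used historically
  for 2DCS is not published in full; the pooled two-proportion form
  implemented here is the standard reading, and the pooled-vs-unpooled
  choice is surfaced in the documentation for users who need to match
  other toolchains.
* Stem distances assume one nested hairpin per transcript; dynamic or
  alternative structures are out of scope (one input structure per
  transcript).
* The ±2 nt functional window and the UNN strictness mode are heuristics
  exposed as configuration, not fitted parameters.
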