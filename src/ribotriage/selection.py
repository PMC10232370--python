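"""Enrichment statistics for library-vs-library selections.

For each motif the selected-pool frequency φ₁ = k_sel/n_sel is compared to
the input-pool frequency φ₂ = k_in/n_in with the pooled two-proportion
z-statistic

    Z_obs = (φ₁ − φ₂) / sqrt( p̂ (1 − p̂) (1/n_sel + 1/n_in) ),
    p̂ = (k_sel + k_in) / (n_sel + n_in),

and a motif is called *bound* when Z_obs strictly exceeds the threshold
(8 by default) — a one-sided call: depletion is never "bound".  No
continuity correction or pseudocount is applied by default (a +0.5
pseudocount is available for sparse tables).

The LOGO matrix is the per-column nucleotide frequency matrix of the top
fraction (0.5% by default) of bound motifs ranked by Z_obs, with ties
broken lexicographically; motif-class enrichment is a two-tailed one-sample
t-test of per-compound bound-class fractions against the library background
fraction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

DEFAULT_ZOBS_THRESHOLD = 8.0
DEFAULT_TOP_FRACTION = 0.005


@dataclass(frozen=True)
class ZobsResult:
    motif_id: str
    phi_sel: float
    phi_in: float
    zobs: float
    bound: bool


def zobs(
    k_sel: int, n_sel: int, k_in: int, n_in: int, *, pseudocount: float = 0.0
) -> float:
    """Pooled two-proportion z-statistic for one motif.

    Returns 0 when the pooled proportion is degenerate (0 or 1).
    Antisymmetric under swapping the two pools.
    """
    if n_sel <= 0 or n_in <= 0:
        raise ValueError("pool depths must be positive")
    if not (0 <= k_sel <= n_sel and 0 <= k_in <= n_in):
        raise ValueError("counts must satisfy 0 <= k <= n")
    k1, k2 = k_sel + pseudocount, k_in + pseudocount
    n1, n2 = n_sel + 2 * pseudocount, n_in + 2 * pseudocount
    pooled = (k1 + k2) / (n1 + n2)
    if pooled <= 0.0 or pooled >= 1.0:
        return 0.0
    se = math.sqrt(pooled * (1.0 - pooled) * (1.0 / n1 + 1.0 / n2))
    return (k1 / n1 - k2 / n2) / se


def zobs_table(
    counts: pd.DataFrame,
    *,
    n_sel: int | None = None,
    n_in: int | None = None,
    threshold: float = DEFAULT_ZOBS_THRESHOLD,
    pseudocount: float = 0.0,
) -> pd.DataFrame:
    """Vectorised Z_obs over a count table.

    *counts* has columns motif_id, k_sel, k_in.  Pool depths default to the
    column sums (complete tables).  Returns columns motif_id, k_sel, k_in,
    phi_sel, phi_in, zobs, bound.
    """
    k1 = counts["k_sel"].to_numpy(float) + pseudocount
    k2 = counts["k_in"].to_numpy(float) + pseudocount
    d1 = (int(counts["k_sel"].sum()) if n_sel is None else n_sel) + 2 * pseudocount
    d2 = (int(counts["k_in"].sum()) if n_in is None else n_in) + 2 * pseudocount
    if d1 <= 0 or d2 <= 0:
        raise ValueError("pool depths must be positive")
    phi1, phi2 = k1 / d1, k2 / d2
    pooled = (k1 + k2) / (d1 + d2)
    se = np.sqrt(pooled * (1.0 - pooled) * (1.0 / d1 + 1.0 / d2))
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where((pooled > 0) & (pooled < 1), (phi1 - phi2) / se, 0.0)
    out = counts[["motif_id", "k_sel", "k_in"]].copy()
    out["phi_sel"] = phi1
    out["phi_in"] = phi2
    out["zobs"] = z
    out["bound"] = z > threshold
    return out


def call_bound(
    results: pd.DataFrame, threshold: float = DEFAULT_ZOBS_THRESHOLD
) -> set[str]:
    """Motifs with Z_obs strictly above the threshold (enrichment only)."""
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    if len(results) == 0:
        return set()
    return set(results.loc[results["zobs"] > threshold, "motif_id"])


def logo_matrix(
    results: pd.DataFrame,
    top_fraction: float = DEFAULT_TOP_FRACTION,
    *,
    sequence_column: str = "motif_id",
) -> dict[int, pd.DataFrame]:
    """Position frequency matrices of the top-ranked motifs.

    Motifs are ranked by Z_obs (descending), ties broken by lexicographic
    sequence order, and the top ``ceil(top_fraction * n)`` retained.  One
    A/C/G/U × position matrix is returned per sequence length; every column
    sums to 1.
    """
    if not 0 < top_fraction <= 1:
        raise ValueError("top_fraction must be in (0, 1]")
    if len(results) == 0:
        raise ValueError("empty result set")
    ranked = results.sort_values(
        ["zobs", sequence_column], ascending=[False, True], kind="mergesort"
    )
    kept = ranked.head(math.ceil(top_fraction * len(ranked)))
    matrices: dict[int, pd.DataFrame] = {}
    bad = set("".join(kept[sequence_column])) - set("ACGU")
    if bad:
        raise ValueError(
            f"sequence column contains non-nucleotide characters {sorted(bad)}"
        )
    for length, group in kept.groupby(kept[sequence_column].str.len()):
        seqs = group[sequence_column].tolist()
        mat = pd.DataFrame(
            0.0, index=list("ACGU"), columns=range(1, length + 1)
        )
        for seq in seqs:
            for col, nt in enumerate(seq, start=1):
                mat.loc[nt, col] += 1.0
        matrices[int(length)] = mat / len(seqs)
    return matrices


def class_enrichment(
    bound_fractions: pd.DataFrame, background_fractions: pd.Series
) -> pd.DataFrame:
    """Per-class enrichment of bound motifs over the library background.

    *bound_fractions* is compounds × classes (each row the class fractions
    of one compound's bound set); *background_fractions* indexes the same
    classes.  A two-tailed one-sample t-test (df = n_compounds − 1) is run
    per class; classes with fewer than two replicates are flagged with an
    undefined p-value.
    """
    rows = []
    for cls in bound_fractions.columns:
        vals = bound_fractions[cls].dropna().to_numpy(float)
        bg = float(background_fractions[cls])
        n = len(vals)
        if n >= 2:
            if np.ptp(vals) == 0.0:  # zero variance: t degenerates
                t = 0.0 if vals[0] == bg else math.copysign(math.inf, vals[0] - bg)
                p = 1.0 if vals[0] == bg else 0.0
            else:
                t, p = stats.ttest_1samp(vals, popmean=bg)
                t, p = float(t), float(p)
        else:
            t, p = float("nan"), float("nan")
        rows.append(
            {
                "motif_class": cls,
                "fraction_bound": float(vals.mean()) if n else float("nan"),
                "fraction_background": bg,
                "n_compounds": n,
                "t": t,
                "p_value": p,
                "direction": "enriched" if n and vals.mean() > bg else "depleted",
                "testable": n >= 2,
            }
        )
    return pd.DataFrame(rows)


def read_counts(path) -> pd.DataFrame:
    """Count table TSV with columns motif_id, k_sel, k_in."""
    table = pd.read_csv(path, sep="\t", dtype={"motif_id": str})
    missing = {"motif_id", "k_sel", "k_in"} - set(table.columns)
    if missing:
        raise ValueError(f"count table lacks columns {sorted(missing)}")
    return table
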