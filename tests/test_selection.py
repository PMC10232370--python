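"""Z_obs enrichment statistic, bound calls, LOGO matrices, class tests."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from ribotriage.selection import (
    call_bound,
    class_enrichment,
    logo_matrix,
    zobs,
    zobs_table,
)
from ribotriage.simulate import gen_selection


def test_equal_proportions_give_zero():
    assert zobs(50, 1000, 50, 1000) == 0.0
    assert zobs(0, 1000, 0, 1000) == 0.0  # degenerate pooled proportion
    assert zobs(1000, 1000, 1000, 1000) == 0.0


def test_zobs_matches_independent_pooled_oracle():
    """Agreement with statsmodels' pooled two-proportion z to 1e-12."""
    from statsmodels.stats.proportion import proportions_ztest

    rng = np.random.default_rng(11)
    for _ in range(50):
        n1, n2 = int(rng.integers(10, 5000)), int(rng.integers(10, 5000))
        k1, k2 = int(rng.integers(0, n1 + 1)), int(rng.integers(0, n2 + 1))
        expected, _ = proportions_ztest([k1, k2], [n1, n2])
        if math.isnan(expected):  # degenerate pooled proportion
            assert zobs(k1, n1, k2, n2) == 0.0
        else:
            assert zobs(k1, n1, k2, n2) == pytest.approx(float(expected), abs=1e-12)


@settings(max_examples=200, derandomize=True)
@given(
    st.integers(1, 2000).flatmap(
        lambda n1: st.tuples(
            st.integers(0, n1),
            st.just(n1),
            st.integers(1, 2000).flatmap(lambda n2: st.tuples(st.integers(0, n2), st.just(n2))),
        )
    )
)
def test_zobs_antisymmetry(args):
    k1, n1, (k2, n2) = args
    assert zobs(k1, n1, k2, n2) == pytest.approx(-zobs(k2, n2, k1, n1), abs=1e-12)


@pytest.mark.parametrize(
    "kwargs", [dict(k_sel=5, n_sel=0, k_in=1, n_in=10), dict(k_sel=11, n_sel=10, k_in=1, n_in=10)]
)
def test_zobs_input_validation(kwargs):
    with pytest.raises(ValueError):
        zobs(**kwargs)


def test_call_bound_is_strict_and_one_sided():
    results = pd.DataFrame(
        {"motif_id": ["a", "b", "c"], "zobs": [8.1, 7.9, -12.0]}
    )
    assert call_bound(results, 8.0) == {"a"}
    assert call_bound(results.iloc[:0], 8.0) == set()


def test_zobs_table_matches_scalar_function():
    counts = pd.DataFrame(
        {"motif_id": ["a", "b", "c"], "k_sel": [30, 10, 0], "k_in": [10, 30, 40]}
    )
    table = zobs_table(counts, n_sel=1000, n_in=1000)
    for row in table.itertuples(index=False):
        assert row.zobs == pytest.approx(
            zobs(row.k_sel, 1000, row.k_in, 1000), abs=1e-12
        )


def test_logo_single_motif_is_one_hot():
    results = pd.DataFrame({"motif_id": ["ACGU"], "zobs": [10.0]})
    (matrix,) = logo_matrix(results, top_fraction=1.0).values()
    assert matrix.loc["A", 1] == 1.0
    assert matrix.loc["C", 2] == 1.0
    assert (matrix.sum(axis=0) == 1.0).all()


def test_logo_equal_z_symmetry():
    results = pd.DataFrame({"motif_id": ["AAAA", "CCCC"], "zobs": [9.0, 9.0]})
    (matrix,) = logo_matrix(results, top_fraction=1.0).values()
    assert (matrix.loc["A"] == 0.5).all()
    assert (matrix.loc["C"] == 0.5).all()


def test_logo_top_fraction_and_rank_order():
    """ceil(0.005·1000) = 5 motifs retained, frequencies hand-computed."""
    rng = np.random.default_rng(5)
    seqs = ["".join(rng.choice(list("ACGU"), 4)) for _ in range(1000)]
    z = rng.normal(size=1000)
    results = pd.DataFrame({"motif_id": seqs, "zobs": z})
    matrices = logo_matrix(results, top_fraction=0.005)
    ranked = sorted(zip(z, seqs), key=lambda t: (-t[0], t[1]))[:5]
    top_seqs = [s for _, s in ranked]
    (matrix,) = matrices.values()
    for col in range(1, 5):
        for nt in "ACGU":
            expected = sum(s[col - 1] == nt for s in top_seqs) / 5
            assert matrix.loc[nt, col] == pytest.approx(expected)


def test_logo_rejects_empty_and_bad_fraction():
    results = pd.DataFrame({"motif_id": ["AAAA"], "zobs": [1.0]})
    with pytest.raises(ValueError):
        logo_matrix(results.iloc[:0])
    with pytest.raises(ValueError):
        logo_matrix(results, top_fraction=0.0)


def test_class_enrichment_null_and_oracle():
    bound = pd.DataFrame({"3×3": [0.48, 0.48, 0.48], "bulge": [0.7, 0.8, 0.75]})
    bg = pd.Series({"3×3": 0.48, "bulge": 0.48})
    table = class_enrichment(bound, bg).set_index("motif_class")
    # replicates equal to background: t = 0, p = 1
    assert table.loc["3×3", "t"] == 0.0
    assert table.loc["3×3", "p_value"] == 1.0
    # closed-form one-sample t for {0.7, 0.8, 0.75} vs 0.48
    vals = np.array([0.7, 0.8, 0.75])
    t_exp = (vals.mean() - 0.48) / (vals.std(ddof=1) / math.sqrt(3))
    p_exp = 2 * stats.t.sf(abs(t_exp), df=2)
    assert table.loc["bulge", "t"] == pytest.approx(t_exp, rel=1e-12)
    assert table.loc["bulge", "p_value"] == pytest.approx(p_exp, rel=1e-12)
    assert table.loc["bulge", "direction"] == "enriched"
    assert table.loc["bulge", "p_value"] < 0.05


def test_class_enrichment_single_replicate_flagged():
    bound = pd.DataFrame({"3×3": [0.7]})
    bg = pd.Series({"3×3": 0.48})
    table = class_enrichment(bound, bg)
    assert not table["testable"].iloc[0]
    assert math.isnan(table["p_value"].iloc[0])


def test_null_false_positive_rate_near_nominal():
    """One null selection at depth 1e4: exceedance at z > 2 near 2.28%."""
    counts, _ = gen_selection(2000, {}, 10**4, 10**4, seed=3)
    table = zobs_table(counts, n_sel=10**4, n_in=10**4)
    rate = float((table["zobs"] > 2).mean())
    assert 0.010 < rate < 0.040
    assert (table["zobs"] <= 8).all()


def test_planted_enrichment_recovered_in_one_run():
    ids = [f"motif_{i:05d}" for i in range(4096)]
    enriched = {m: 10.0 for m in ids[:20]}
    counts, _ = gen_selection(4096, enriched, 10**5, 10**5, seed=4)
    table = zobs_table(counts, n_sel=10**5, n_in=10**5)
    assert set(ids[:20]) <= call_bound(table, 8.0)


def test_power_monotone_in_fold_and_depth():
    """Mean planted-motif z grows with fold enrichment and with depth."""

    def mean_planted_z(fold, depth, seed):
        ids = [f"motif_{i:05d}" for i in range(1024)]
        counts, _ = gen_selection(
            1024, {m: fold for m in ids[:10]}, depth, depth, seed=seed
        )
        table = zobs_table(counts, n_sel=depth, n_in=depth)
        return float(table.head(10)["zobs"].mean())

    z2 = mean_planted_z(2, 10**5, 9)
    z5 = mean_planted_z(5, 10**5, 9)
    z10 = mean_planted_z(10, 10**5, 9)
    assert z2 < z5 < z10
    assert mean_planted_z(5, 10**4, 9) < mean_planted_z(5, 10**6, 9)
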