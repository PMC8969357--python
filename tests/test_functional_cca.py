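"""Annotation filtering, PCA/CCA, gene grouping, enrichment, network."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import hypergeom

from unimo import functional_cca as fc
from unimo.synthetic_data import gen_annotation_coupling


# ---------------------------------------------------------------------------
# annotation matrix

def test_small_terms_dropped_duplicates_collapsed():
    pairs = (
        [(f"g{i}", "tBig") for i in range(4)]
        + [(f"g{i}", "tDup") for i in range(4)]      # same gene set as tBig
        + [("g0", "tTiny"), ("g1", "tTiny")]         # only 2 genes: dropped
    )
    am = fc.build_annotation_matrix(pairs)
    assert am.matrix.shape[1] == 1
    assert "tTiny" in am.filter_log["terms_dropped_unique"]
    assert am.filter_log["terms_dropped_duplicate"] == ["tDup"]


def test_global_terms_dropped():
    pairs = [(f"g{i}", "tGlobal") for i in range(250)] + \
            [(f"g{i}", "tOk") for i in range(5)]
    am = fc.build_annotation_matrix(pairs, max_genes=199)
    assert list(am.matrix.columns) == ["tOk"]
    assert len(am.filter_log["genes_dropped_unannotated"]) == 245


def test_toy_mapping_filters_by_manual_enumeration():
    """6 genes / 5 terms, filters traced by hand:
    tA annotates g1-g4 (kept); tB duplicates tA (dropped); tC annotates
    g1-g3 (kept); tD annotates g5+g6 only (dropped, <3 genes);
    tE annotates g2-g4 (kept).  g5, g6 lose all terms and are dropped,
    leaving a 4x3 matrix."""
    pairs = (
        [(g, "tA") for g in ["g1", "g2", "g3", "g4"]]
        + [(g, "tB") for g in ["g1", "g2", "g3", "g4"]]
        + [(g, "tC") for g in ["g1", "g2", "g3"]]
        + [(g, "tD") for g in ["g5", "g6"]]
        + [(g, "tE") for g in ["g2", "g3", "g4"]]
    )
    am = fc.build_annotation_matrix(pairs)
    assert am.matrix.shape == (4, 3)
    assert set(am.matrix.columns) == {"tA", "tC", "tE"}
    assert set(am.matrix.index) == {"g1", "g2", "g3", "g4"}


def test_empty_mapping_is_an_error():
    with pytest.raises(ValueError):
        fc.build_annotation_matrix([])


# ---------------------------------------------------------------------------
# PCA with CCR

def test_dominant_variance_needs_one_component(rng):
    X = np.column_stack([rng.normal(0, math.sqrt(99), 300),
                         rng.normal(0, 1, 300)])
    assert fc.pca_reduce(X, 0.95).n_retained == 1


def test_isotropic_needs_all_components(rng):
    X = rng.normal(0, 1, (400, 4))
    assert fc.pca_reduce(X, 0.95).n_retained == 4


def test_threshold_one_retains_rank(rng):
    X = rng.normal(0, 1, (50, 3))
    X = np.column_stack([X, X[:, 0] + X[:, 1]])  # rank 3
    assert fc.pca_reduce(X, 1.0).n_retained == 3


def test_rank_zero_matrix_is_an_error():
    with pytest.raises(ValueError):
        fc.pca_reduce(np.ones((10, 3)), 0.95)


# ---------------------------------------------------------------------------
# CCA + Bartlett

def test_identical_blocks_have_unit_correlations(rng):
    X = rng.normal(0, 1, (100, 3))
    res = fc.fit_cca(X, X.copy())
    assert np.all(res.rho > 1 - 1e-6)
    assert res.rho.shape == (3,)
    assert np.all(np.diff(res.rho) <= 1e-12)


def test_cca_invariant_under_invertible_transform(rng):
    X = rng.normal(0, 1, (200, 4))
    Y = rng.normal(0, 1, (200, 3))
    Y[:, 0] += X[:, 0]
    A = rng.normal(0, 1, (4, 4)) + 4 * np.eye(4)
    res1 = fc.fit_cca(X, Y)
    res2 = fc.fit_cca(X @ A, Y)
    assert np.max(np.abs(res1.rho - res2.rho)) <= 1e-8


def test_planted_canonical_correlation_recovered(rng):
    n = 500
    u = rng.normal(0, 1, n)
    X = np.column_stack([u + rng.normal(0, 0.5, n), rng.normal(0, 1, n),
                         rng.normal(0, 1, n)])
    Y = np.column_stack([u + rng.normal(0, 0.5, n), rng.normal(0, 1, n),
                         rng.normal(0, 1, n)])
    res = fc.fit_cca(X, Y)
    assert 0.75 <= res.rho[0] <= 0.85      # true rho1 = 1/1.25 = 0.8
    assert res.n_significant >= 1
    assert res.bartlett_p[0] < 1e-10


def test_constant_column_is_named_in_error(rng):
    X = rng.normal(0, 1, (50, 2))
    X[:, 1] = 3.0
    with pytest.raises(ValueError, match="X"):
        fc.fit_cca(X, rng.normal(0, 1, (50, 2)))


# ---------------------------------------------------------------------------
# gene groups and binary distance

def test_identical_annotations_cluster_together():
    pairs = ([(g, t) for g in ("a1", "a2", "a3") for t in ("tA", "tB", "tC")]
             + [(g, t) for g in ("b1", "b2", "b3")
                for t in ("tX", "tY", "tZ")])
    am = fc.build_annotation_matrix(pairs)
    groups = fc.cluster_gene_groups(am)
    parts = sorted(sorted(g.members) for g in groups)
    assert parts == [["a1", "a2", "a3"], ["b1", "b2", "b3"]]


def test_toy_linkage_matches_hand_computation():
    """Distances computed by hand for 3 annotation patterns: x/y share 2 of
    3 terms (d = 1/3), z is disjoint (d = 1).  Complete linkage at a cut
    below 1 therefore yields {x, y} and drops singleton z."""
    pairs = [("x", "t1"), ("x", "t2"), ("x", "t3"),
             ("y", "t1"), ("y", "t2"), ("y", "t4"),
             ("z", "t5"), ("z", "t6")]
    mat = pd.crosstab(
        pd.Series([p[0] for p in pairs], name="gene"),
        pd.Series([p[1] for p in pairs], name="term")).astype(bool)
    am = fc.AnnotationMatrix(matrix=mat)
    d = fc.binary_distance(mat.to_numpy())
    # order: (x,y), (x,z), (y,z)
    assert d == pytest.approx([2.0 / 4.0, 1.0, 1.0])
    groups = fc.cluster_gene_groups(am)
    assert len(groups) == 1 and sorted(groups[0].members) == ["x", "y"]


@settings(max_examples=50, deadline=None)
@given(st.lists(st.lists(st.booleans(), min_size=6, max_size=6),
                min_size=3, max_size=3))
def test_binary_distance_is_a_metric(vectors):
    arr = np.array(vectors, dtype=bool)
    if not arr.any(axis=1).all():
        return  # all-zero rows have no defined support
    d = fc.binary_distance(arr)
    dm = np.zeros((3, 3))
    dm[np.triu_indices(3, 1)] = d
    dm += dm.T
    for i, j, k in itertools.permutations(range(3), 3):
        assert dm[i, j] <= dm[i, k] + dm[k, j] + 1e-12
    for i in range(3):
        assert dm[i, i] == 0.0
    for i, j in itertools.combinations(range(3), 2):
        if (arr[i] == arr[j]).all():
            assert dm[i, j] == 0.0


# ---------------------------------------------------------------------------
# enrichment

def test_fisher_matches_exhaustive_enumeration_perfect_split():
    """All 10 term genes inside a 10-gene group, universe 20: the two-sided
    P is 2/C(20,10) by direct enumeration of the extreme tables."""
    pairs = ([(f"in{i}", "term") for i in range(10)]
             + [(f"in{i}", "hub_all") for i in range(10)]
             + [(f"out{i}", "hub_all") for i in range(10)])
    am = fc.build_annotation_matrix(pairs)
    groups = [fc.GeneGroup(1, [f"in{i}" for i in range(10)]),
              fc.GeneGroup(2, [f"out{i}" for i in range(10)])]
    out = fc.enrich_groups(groups, am, alpha=0.05)
    term_p = dict(out[0].enriched_terms)
    expected = 2.0 / math.comb(20, 10)
    assert term_p["term"] == pytest.approx(expected, rel=1e-9)


def test_enrichment_bonferroni_cap(rng):
    _, pairs, labels = gen_annotation_coupling(60, 12, 3, 0.0, seed=2)
    am = fc.build_annotation_matrix(pairs)
    groups = fc.cluster_gene_groups(am)
    out = fc.enrich_groups(groups, am, alpha=0.05)
    for g in out:
        for term, p in g.enriched_terms:
            assert 0.0 < p <= 1.0


def test_fisher_two_sided_equals_hypergeom_enumeration():
    """scipy's two-sided Fisher P agrees with summing hypergeometric masses
    <= the observed mass (margins up to 8 exhaustively)."""
    from scipy.stats import fisher_exact
    for r1 in range(1, 9):
        for r2 in range(1, 9):
            N = r1 + r2
            for c1 in range(1, min(8, N) + 1):
                for a in range(max(0, c1 - r2), min(r1, c1) + 1):
                    table = [[a, r1 - a], [c1 - a, r2 - (c1 - a)]]
                    _, p = fisher_exact(table)
                    ks = np.arange(max(0, c1 - r2), min(r1, c1) + 1)
                    pmf = hypergeom.pmf(ks, N, r1, c1)
                    p_ref = pmf[pmf <= pmf[ks == a][0] * (1 + 1e-9)].sum()
                    assert p == pytest.approx(min(p_ref, 1.0), rel=1e-7)


# ---------------------------------------------------------------------------
# pairwise CCA and network

def test_pair_count_formula():
    assert fc.n_unordered_pairs(2) == 1
    assert fc.n_unordered_pairs(10) == 45
    assert fc.n_unordered_pairs(130) == 8385


def test_pairwise_null_rate_controlled(rng):
    scores, pairs, labels = gen_annotation_coupling(60, 12, 4, 0.0, seed=3,
                                                    n_pcv=10)
    am = fc.build_annotation_matrix(pairs)
    groups = fc.cluster_gene_groups(am)
    pdf = fc.pairwise_group_cca(groups, scores, alpha=0.0005)
    assert pdf["significant"].sum() == 0
    assert len(pdf) == fc.n_unordered_pairs(len(groups))


def test_network_zero_fills_nonsignificant_pairs(rng):
    scores, pairs, labels = gen_annotation_coupling(30, 8, 3, 0.8, seed=4,
                                                    n_pcv=6)
    am = fc.build_annotation_matrix(pairs)
    groups = fc.cluster_gene_groups(am)
    pdf = fc.pairwise_group_cca(groups, scores, alpha=0.0005)
    pdf["significant"] = False
    pdf.loc[pdf.index[:1], "significant"] = True
    net = fc.build_correlation_network(scores, groups, pdf, layout_seed=0)
    between = net.edges[net.edges["kind"] == "between"]
    assert len(between) == 1        # only the significant pair, max-|r| gene pair
    g = {gr.group_id: set(gr.members) for gr in groups}
    a, b = int(pdf.iloc[0]["group_a"]), int(pdf.iloc[0]["group_b"])
    e = between.iloc[0]
    assert (e["gene_a"] in g[a] and e["gene_b"] in g[b]) or \
           (e["gene_a"] in g[b] and e["gene_b"] in g[a])


def test_identical_and_orthogonal_pcv_vectors(rng):
    v = rng.normal(0, 1, 8)
    scores = pd.DataFrame(
        [v, v, [1, 0, 0, 0, 0, 0, 0, 0], [0, 1, 0, 0, 0, 0, 0, 0]],
        index=["a1", "a2", "b1", "b2"])
    R = np.corrcoef(scores.to_numpy())
    assert R[0, 1] == pytest.approx(1.0)


# ---------------------------------------------------------------------------
# core / dense classification

def test_core_groups_from_poisson_split():
    core, dense, info = fc.classify_core_dense(
        [0, 1, 1, 2, 2, 10, 12, 15], [0.3, 0.3, 0.4, 0.5, 0.3, 0.4, 0.5, 0.3])
    assert list(np.where(core)[0]) == [5, 6, 7]
    assert info["core_boundary"] == 10.0


def test_dense_groups_from_gamma_split():
    core, dense, info = fc.classify_core_dense(
        [0, 1, 2, 3, 9], [0.05, 0.08, 0.5, 0.6, 0.55])
    assert list(np.where(dense)[0]) == [0, 1]
    assert info["dense_boundary"] == pytest.approx(0.08)


def test_degenerate_degrees_give_no_flags():
    with pytest.warns(UserWarning, match="degrees"):
        core, dense, info = fc.classify_core_dense(
            [3, 3, 3, 3], [0.1, 0.2, 0.5, 0.6])
    assert not core.any()
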