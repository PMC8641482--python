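"""The FEM algorithm core: binarization, overlaps, tail p-values, correction,
information content, and the optimized pipeline against naive oracles."""

import math

import numpy as np
import pytest
import scipy.sparse as sp
from statsmodels.stats.multitest import multipletests

from scfem import (
    ExpressionMatrix,
    GeneSetCollection,
    adjust_pvalues,
    binarize,
    compute_fem,
    enrichment_pvalue,
    information_content,
    overlap_counts,
)
from scfem.core import _tail_pvalues

from conftest import hypergeom_tail_exact, random_instance


def naive_fem(expr, coll, correction="bonferroni", log_base=10, p_floor=1e-300):
    """Unoptimized per-(cell, set) reference: explicit set intersections and
    scalar tail p-values, no memoization, no matrix algebra."""
    bg = coll.background
    expressed = []
    dense = expr.values.toarray()
    for j in range(expr.n_cells):
        genes = {expr.gene_ids[i] for i in range(expr.n_genes) if dense[i, j] > 0}
        expressed.append(genes & bg)
    N = len(bg)
    p = np.ones((expr.n_cells, coll.n_sets))
    for j in range(expr.n_cells):
        n = len(expressed[j])
        for s in range(coll.n_sets):
            K = len(coll.members[s])
            k = len(expressed[j] & coll.members[s])
            p[j, s] = hypergeom_tail_exact(k, n, K, N)
    if correction == "bonferroni":
        adj = np.minimum(1.0, p * coll.n_sets)
    elif correction == "none":
        adj = p
    else:
        adj = np.vstack([multipletests(row, method="fdr_bh")[1] for row in p])
    gs = -np.log(np.maximum(adj, p_floor))
    if log_base != "e":
        gs = gs / math.log(log_base)
    return gs


class TestBinarize:
    def test_strict_nonzero_rule(self):
        expr = ExpressionMatrix(
            sp.csr_matrix(np.array([[0.0, 2.3], [0.0001, 0.0]])),
            np.array(["g1", "g2"]), np.array(["c1", "c2"]),
        )
        b = binarize(expr)
        assert b.A.toarray().tolist() == [[0, 1], [1, 0]]  # cells x genes
        assert b.n.tolist() == [1, 1]

    def test_all_zero_cell_has_n_zero(self):
        expr = ExpressionMatrix(
            sp.csr_matrix(np.array([[1.0, 0.0]])), np.array(["g1"]),
            np.array(["c1", "c2"]),
        )
        assert binarize(expr).n.tolist() == [1, 0]

    def test_n_restricted_to_background(self):
        expr = ExpressionMatrix(
            sp.csr_matrix(np.array([[2.0], [3.0], [1.0]])),
            np.array(["g1", "g2", "g3"]), np.array(["c1"]),
        )
        assert binarize(expr, background={"g1", "g3"}).n.tolist() == [2]

    def test_matches_per_entry_check(self):
        rng = np.random.default_rng(0)
        expr, _ = random_instance(rng)
        A = binarize(expr).A.toarray()
        dense = expr.values.toarray()
        assert np.array_equal(A, (dense.T > 0).astype(np.int8))


class TestOverlapCounts:
    def test_hand_intersection(self):
        expr = ExpressionMatrix(
            sp.csr_matrix(np.array([[1.0], [1.0], [0.0]])),
            np.array(["g1", "g2", "g3"]), np.array(["c1"]),
        )
        coll = GeneSetCollection.from_sets(["s"], [{"g1", "g3"}])
        oc = overlap_counts(binarize(expr), coll)
        assert oc.k.tolist() == [[1]]
        assert oc.N == 2  # background is {g1, g3}

    def test_zero_cell_gives_zero_row(self):
        expr = ExpressionMatrix(
            sp.csr_matrix(np.array([[1.0, 0.0]])), np.array(["g1"]),
            np.array(["c1", "c2"]),
        )
        coll = GeneSetCollection.from_sets(["s"], [{"g1"}])
        oc = overlap_counts(binarize(expr), coll)
        assert oc.k[1].tolist() == [0]

    def test_no_gene_overlap_is_an_error(self):
        expr = ExpressionMatrix(sp.csr_matrix(np.ones((1, 1))),
                                np.array(["gX"]), np.array(["c1"]))
        coll = GeneSetCollection.from_sets(["s"], [{"g1"}])
        with pytest.raises(ValueError, match="no overlap"):
            overlap_counts(binarize(expr), coll)

    def test_matches_explicit_set_intersections(self):
        rng = np.random.default_rng(1)
        expr, coll = random_instance(rng, n_cells=40, n_genes=100, n_sets=15)
        oc = overlap_counts(binarize(expr), coll)
        dense = expr.values.toarray()
        for j in range(expr.n_cells):
            expressed = {expr.gene_ids[i] for i in range(expr.n_genes)
                         if dense[i, j] > 0} & coll.background
            assert oc.n[j] == len(expressed)
            for s in range(coll.n_sets):
                assert oc.k[j, s] == len(expressed & coll.members[s])
        assert (oc.k <= np.minimum(oc.n[:, None], oc.K[None, :])).all()


class TestEnrichmentPvalue:
    def test_single_term_tail(self):
        assert enrichment_pvalue(5, 5, 5, 10) == pytest.approx(1 / 252, rel=1e-12)

    def test_k_zero_is_one(self):
        assert enrichment_pvalue(0, 3, 4, 10) == 1.0

    def test_degenerate_K_equals_N(self):
        assert enrichment_pvalue(7, 7, 10, 10) == 1.0

    @pytest.mark.parametrize("bad,msg", [
        (dict(k=3, n=2, K=5, N=10), "k"),
        (dict(k=1, n=11, K=5, N=10), "n"),
        (dict(k=1, n=2, K=11, N=10), "K"),
        (dict(k=0, n=0, K=0, N=0), "N"),
    ])
    def test_domain_errors_name_parameter(self, bad, msg):
        with pytest.raises(ValueError, match=msg):
            enrichment_pvalue(**bad)

    def test_matches_exact_summation_on_random_tuples(self):
        """200 random valid tuples with N <= 60 agree with rational-arithmetic
        tail summation to 1e-12 relative."""
        rng = np.random.default_rng(42)
        for _ in range(200):
            N = int(rng.integers(1, 61))
            K = int(rng.integers(0, N + 1))
            n = int(rng.integers(0, N + 1))
            k = int(rng.integers(0, min(n, K) + 1))
            assert enrichment_pvalue(k, n, K, N) == pytest.approx(
                hypergeom_tail_exact(k, n, K, N), rel=1e-12
            )

    def test_non_increasing_in_k(self):
        N, K, n = 50, 12, 20
        ps = [enrichment_pvalue(k, n, K, N) for k in range(min(n, K) + 1)]
        assert all(a >= b for a, b in zip(ps, ps[1:]))

    def test_vectorized_memoized_path_matches_scalar(self):
        rng = np.random.default_rng(5)
        N = 40
        n = rng.integers(0, N + 1, size=8)
        K = rng.integers(1, N + 1, size=6)
        k = np.minimum(n[:, None], K[None, :])
        k = (k * rng.random((8, 6))).astype(np.int64)
        P = _tail_pvalues(k, n, K, N)
        for j in range(8):
            for s in range(6):
                assert P[j, s] == pytest.approx(
                    enrichment_pvalue(int(k[j, s]), int(n[j]), int(K[s]), N), abs=0
                )


class TestAdjustPvalues:
    def test_bonferroni_scales_and_caps(self):
        p = np.array([[0.01, 0.5, 0.2, 0.3, 0.4]])
        adj = adjust_pvalues(p, "bonferroni")
        assert adj[0, 0] == pytest.approx(0.05)
        assert adj[0, 1] == 1.0

    def test_none_is_identity(self):
        p = np.random.default_rng(2).uniform(0.01, 1, (4, 6))
        assert np.array_equal(adjust_pvalues(p, "none"), p)

    def test_bh_matches_reference_rowwise(self):
        p = np.random.default_rng(3).uniform(1e-6, 1, (10, 50))
        adj = adjust_pvalues(p, "bh")
        for i in range(10):
            expected = multipletests(p[i], method="fdr_bh")[1]
            np.testing.assert_allclose(adj[i], expected, rtol=1e-12)

    def test_unknown_method(self):
        with pytest.raises(ValueError, match="unknown correction"):
            adjust_pvalues(np.array([[0.5]]), "holm")

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            adjust_pvalues(np.array([[0.0, 0.5]]), "bonferroni")


class TestInformationContent:
    def test_closed_forms(self):
        assert information_content(np.array([1.0]))[0] == 0.0
        assert information_content(np.array([1e-3]), log_base=10)[0] == pytest.approx(3.0)
        assert information_content(np.array([math.exp(-2.0)]), log_base="e")[0] == (
            pytest.approx(2.0)
        )

    def test_floor_caps_gs(self):
        out = information_content(np.array([1e-320]), log_base=10, p_floor=1e-300)
        assert out[0] == pytest.approx(300.0)

    def test_monotone_decreasing_above_floor(self):
        p = np.array([1e-10, 1e-5, 1e-2, 0.5, 1.0])
        gs = information_content(p)
        assert (np.diff(gs) < 0).all() or (np.diff(gs) <= 0).all()

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            information_content(np.array([1.5]))


class TestComputeFem:
    def test_single_cell_single_set_closed_form(self):
        # one cell expressing exactly one 5-gene set; 5 extra background genes
        genes = [f"g{i}" for i in range(10)]
        vals = np.zeros((10, 1))
        vals[:5] = 1.0
        expr = ExpressionMatrix(sp.csr_matrix(vals), np.array(genes, dtype=object),
                                np.array(["c1"], dtype=object))
        coll = GeneSetCollection.from_sets(
            ["hit", "pad"], [set(genes[:5]), set(genes)]
        )
        fem = compute_fem(expr, coll, correction="none", log_base=10)
        assert fem.metadata["N"] == 10
        assert fem.GS[0, 0] == pytest.approx(-math.log10(1 / 252), rel=1e-12)
        assert fem.GS[0, 1] == 0.0  # K = N is never enriched

    def test_duplicate_cells_give_identical_rows(self):
        rng = np.random.default_rng(10)
        expr, coll = random_instance(rng, n_cells=6)
        dup = ExpressionMatrix(
            sp.hstack([expr.values, expr.values[:, [0]]]).tocsr(),
            expr.gene_ids, np.append(expr.cell_ids, "c_dup"),
        )
        fem = compute_fem(dup, coll)
        np.testing.assert_array_equal(fem.GS[0], fem.GS[-1])

    @pytest.mark.parametrize("correction", ["bonferroni", "bh", "none"])
    def test_equals_naive_loop(self, correction):
        """The matrix-product + memoization optimization is purely algebraic:
        it must agree with a direct per-(cell, set) loop to 1e-12."""
        rng = np.random.default_rng(123)
        expr, coll = random_instance(rng, n_cells=30, n_genes=80, n_sets=12)
        fem = compute_fem(expr, coll, correction=correction)
        expected = naive_fem(expr, coll, correction=correction)
        np.testing.assert_allclose(fem.GS, expected, atol=1e-12, rtol=1e-9)

    def test_zero_n_cell_warns_and_yields_zero_row(self, caplog):
        expr = ExpressionMatrix(
            sp.csr_matrix(np.array([[1.0, 0.0], [0.0, 0.0]])),
            np.array(["g1", "gX"]), np.array(["c1", "c2"]),
        )
        coll = GeneSetCollection.from_sets(["s1", "s2"], [{"g1"}, {"g1", "g2"}])
        with caplog.at_level("WARNING", logger="scfem.core"):
            fem = compute_fem(expr, coll)
        assert "1 cell(s)" in caplog.text
        assert np.array_equal(fem.GS[1], [0.0, 0.0])

    def test_workers_do_not_change_result(self):
        rng = np.random.default_rng(77)
        expr, coll = random_instance(rng, n_cells=50, n_genes=100, n_sets=15)
        fems = [compute_fem(expr, coll, workers=w) for w in (1, 2, 4)]
        assert np.array_equal(fems[0].GS, fems[1].GS)
        assert np.array_equal(fems[0].GS, fems[2].GS)

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(21)
        expr, coll = random_instance(rng, n_cells=12)
        fem = compute_fem(expr, coll)
        perm = rng.permutation(expr.n_cells)
        expr_p = ExpressionMatrix(expr.values[:, perm], expr.gene_ids,
                                  expr.cell_ids[perm])
        np.testing.assert_array_equal(compute_fem(expr_p, coll).GS, fem.GS[perm])
        gperm = rng.permutation(expr.n_genes)
        expr_g = ExpressionMatrix(expr.values[gperm], expr.gene_ids[gperm],
                                  expr.cell_ids)
        np.testing.assert_array_equal(compute_fem(expr_g, coll).GS, fem.GS)


def test_dropping_one_gene_never_flips_strong_enrichment(planted_dataset):
    """Enrichment is a property of the gene set, not of any one gene: removing
    a single expressed in-set gene from a cell with k >= 10 and adj_p <= 1e-6
    must leave the set clearly significant (adj_p <= 0.05)."""
    expr, coll, labels = planted_dataset
    fem = compute_fem(expr, coll)
    b = binarize(expr, coll.background)
    oc = overlap_counts(b, coll)
    N, m = oc.N, coll.n_sets
    rng = np.random.default_rng(6)
    # strongly enriched (cell, set) pairs: bonferroni adj_p <= 1e-6, k >= 10
    strong = np.argwhere((fem.GS >= 6 + math.log10(m)) & (oc.k >= 10))
    assert len(strong) > 100
    for j, s in strong[rng.choice(len(strong), size=25, replace=False)]:
        k, n, K = int(oc.k[j, s]), int(oc.n[j]), int(oc.K[s])
        p_after = enrichment_pvalue(k - 1, n - 1, K, N)
        assert min(1.0, m * p_after) <= 0.05
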