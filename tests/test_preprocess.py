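import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst
from scipy import stats

from leukotrace.matrix import CellMatrix
from leukotrace.preprocess import (
    QCThresholds,
    bh_adjust,
    cluster,
    normalize,
    qc_filter,
    select_pcs,
    select_variable_genes,
    wilcoxon_de,
)
from tests.conftest import make_cellmatrix


def counts_matrix(counts, gene_names=None, meta_kw=None):
    counts = np.asarray(counts, dtype=int)
    n, g = counts.shape
    gene_names = gene_names or [f"g{j}" for j in range(g)]
    meta = pd.DataFrame(meta_kw or {}, index=pd.Index([f"c{i}" for i in range(n)], name="barcode"))
    return CellMatrix(counts=counts, gene_names=gene_names, cell_meta=meta)


class TestQCFilter:
    def test_low_gene_cell_removed(self):
        rng = np.random.default_rng(0)
        counts = rng.poisson(5, size=(4, 300))
        counts[0, 150:] = 0  # cell 0 expresses ~150 genes
        counts[1:, :] += 1  # others express everything
        m = counts_matrix(counts)
        out = qc_filter(m, QCThresholds(min_genes=200, min_umi=1, min_cells_per_gene=0))
        assert "c0" not in out.barcodes
        assert out.n_cells == 3

    def test_all_passing_identity(self):
        counts = np.full((5, 20), 60)
        m = counts_matrix(counts)
        out = qc_filter(m, QCThresholds(min_genes=10, min_umi=100, min_cells_per_gene=2))
        assert out.n_cells == 5 and out.n_genes == 20
        assert np.array_equal(out.counts, m.counts)

    def test_toy_enumeration(self):
        # 5 cells; one fails mito; one gene seen in a single cell is dropped
        genes = ["MT-1", "gA", "gB", "gC"]
        counts = np.array(
            [
                [1, 5, 5, 0],
                [1, 5, 5, 0],
                [1, 5, 5, 0],
                [1, 5, 5, 7],  # only cell expressing gC
                [3, 6, 6, 0],  # mito fraction 3/15 = 0.2
            ]
        )
        m = counts_matrix(counts, gene_names=genes)
        t = QCThresholds(min_genes=2, min_umi=5, max_mito=0.15, min_cells_per_gene=2)
        out = qc_filter(m, t)
        assert out.n_cells == 4
        assert "gC" not in out.gene_names
        assert "c4" not in out.barcodes

    def test_doublets_dropped(self):
        counts = np.full((4, 10), 100)
        m = counts_matrix(counts, meta_kw={"doublet_flag": [False, True, False, False]})
        out = qc_filter(m, QCThresholds(min_genes=5, min_umi=10, min_cells_per_gene=1))
        assert out.n_cells == 3

    def test_idempotent(self):
        rng = np.random.default_rng(1)
        m = counts_matrix(rng.poisson(3, size=(50, 300)))
        t = QCThresholds(min_genes=100, min_umi=300, min_cells_per_gene=5)
        once = qc_filter(m, t)
        twice = qc_filter(once, t)
        assert np.array_equal(once.counts, twice.counts)
        assert list(once.barcodes) == list(twice.barcodes)

    def test_all_filtered_raises(self):
        m = counts_matrix(np.ones((3, 5), dtype=int))
        with pytest.raises(ValueError, match="all cells filtered"):
            qc_filter(m, QCThresholds(min_genes=100, min_umi=100))


class TestNormalize:
    def test_closed_form(self):
        m = counts_matrix([[1, 1, 2]])
        out = normalize(m)
        expected = np.log1p(2 / 4 * 10_000)
        assert np.isclose(out.normalized[0, 2], expected)
        assert round(expected, 4) == 8.5174  # ln(1 + 5000)

    def test_zero_gene_stays_zero(self):
        m = counts_matrix([[1, 0], [3, 0]])
        out = normalize(m)
        assert (out.normalized[:, 1] == 0).all()

    def test_depth_invariance(self):
        m1 = counts_matrix([[1, 2, 3]])
        m2 = counts_matrix([[2, 4, 6]])
        assert np.allclose(normalize(m1).normalized, normalize(m2).normalized)

    def test_conservation_invariant(self):
        rng = np.random.default_rng(2)
        m = counts_matrix(rng.poisson(4, size=(30, 100)) + 1)
        out = normalize(m)
        totals = np.expm1(out.normalized).sum(axis=1)
        assert np.allclose(totals, 10_000, rtol=1e-6)

    def test_zero_total_cell_raises(self):
        m = counts_matrix([[0, 0], [1, 1]])
        with pytest.raises(ValueError, match="zero-total"):
            normalize(m)


class TestVariableGenes:
    def test_constant_genes_rank_last(self):
        rng = np.random.default_rng(3)
        x = rng.normal(2, 1, size=(100, 50)).clip(0)
        x[:, :10] = 1.7  # constant genes
        m = make_cellmatrix(x)
        top = select_variable_genes(m, n=30)
        assert not set(top) & {f"g{j}" for j in range(10)}

    def test_bimodal_beats_unimodal_at_same_mean(self):
        rng = np.random.default_rng(4)
        n = 400
        bimodal = np.concatenate([np.zeros(n // 2), np.full(n // 2, 4.0)])
        unimodal = rng.normal(2.0, 0.2, size=n).clip(0)
        filler = rng.normal(2.0, 0.2, size=(n, 30)).clip(0)
        x = np.column_stack([bimodal, unimodal, filler])
        m = make_cellmatrix(x)
        top = select_variable_genes(m, n=1)
        assert top == ["g0"]

    def test_n_equals_total_returns_all(self):
        m = make_cellmatrix(np.random.default_rng(5).random((20, 15)))
        assert set(select_variable_genes(m, n=15)) == {f"g{j}" for j in range(15)}

    def test_oversized_n_warns(self):
        m = make_cellmatrix(np.random.default_rng(6).random((10, 5)))
        with pytest.warns(UserWarning):
            got = select_variable_genes(m, n=50)
        assert len(got) == 5


class TestSelectPCs:
    def test_hand_evaluated_example(self):
        # co1: first cum>90 with own<5 -> PC6 (cum 95, own 4); co2: last drop>0.1 -> PC7
        assert select_pcs([30, 25, 20, 10, 6, 4, 2, 1, 1, 1]) == 6

    def test_single_component(self):
        assert select_pcs([100]) == 1

    def test_all_equal_uses_defined_branch(self):
        # own% < 5 everywhere: co1 = first cum > 90 -> ceil(90/4)+... = PC 23; co2 undefined
        assert select_pcs([4.0] * 25) == 23
        # own% >= 5 everywhere and no drops: neither defined -> all PCs
        assert select_pcs([10.0] * 10) == 10

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            select_pcs([])

    @given(
        hst.lists(hst.floats(min_value=0.01, max_value=50), min_size=1, max_size=30),
        hst.integers(min_value=0, max_value=5),
    )
    @settings(max_examples=100, deadline=None)
    def test_at_least_one_and_appending_zeros_safe(self, raw, n_zeros):
        pct = sorted(raw, reverse=True)
        total = sum(pct)
        pct = [p / total * 100 for p in pct]
        k = select_pcs(pct)
        assert k >= 1
        k2 = select_pcs(pct + [1e-9] * n_zeros)
        assert k2 >= 1


class TestCluster:
    def test_two_blobs_ari_one(self):
        rng = np.random.default_rng(7)
        a = rng.normal(0, 0.05, size=(100, 5)) + np.array([10, 0, 0, 0, 0])
        b = rng.normal(0, 0.05, size=(100, 5)) + np.array([0, 10, 0, 0, 0])
        emb = np.vstack([a, b])
        labels = cluster(emb, k_neighbors=20, seed=0)
        from sklearn.metrics import adjusted_rand_score

        truth = np.repeat([0, 1], 100)
        assert adjusted_rand_score(truth, labels) == 1.0

    def test_single_blob_single_cluster(self):
        # neighborhood commensurate with the blob: no sub-structure remains
        rng = np.random.default_rng(8)
        emb = rng.normal(5, 0.3, size=(150, 4))
        labels = cluster(emb, k_neighbors=100, resolution=0.8, seed=0)
        assert len(np.unique(labels)) == 1

    def test_permutation_consistency(self):
        rng = np.random.default_rng(9)
        a = rng.normal(0, 0.05, size=(80, 3)) + np.array([5, 0, 0])
        b = rng.normal(0, 0.05, size=(80, 3)) + np.array([0, 5, 0])
        emb = np.vstack([a, b])
        labels = cluster(emb, k_neighbors=10, seed=0)
        perm = rng.permutation(emb.shape[0])
        labels_p = cluster(emb[perm], k_neighbors=10, seed=0)
        from sklearn.metrics import adjusted_rand_score

        assert adjusted_rand_score(labels[perm], labels_p) == 1.0

    def test_too_few_cells_raises(self):
        with pytest.raises(ValueError):
            cluster(np.zeros((5, 2)), k_neighbors=10)


class TestWilcoxonDE:
    def test_identical_groups_nothing_passes(self):
        rng = np.random.default_rng(10)
        block = rng.random((5, 20)) + 0.5
        m = make_cellmatrix(np.vstack([block, block]))
        res = wilcoxon_de(m, np.arange(5), np.arange(5, 10), min_pct=0.1, lfc_min=0.25)
        assert res.empty

    def test_exact_enumeration_oracle(self):
        # gene 0 fully separated 4v4; oracle enumerates all C(8,4) assignments
        vals = np.array([5.0, 6, 7, 8, 1, 2, 3, 4])
        x = np.column_stack([vals, np.tile([1.0, 2.0], 4)])
        m = make_cellmatrix(x)
        res = wilcoxon_de(m, np.arange(4), np.arange(4, 8), min_pct=0, lfc_min=0)
        observed_u = 16  # groupA wins every pairwise comparison
        count = 0
        for combo in itertools.combinations(range(8), 4):
            ga = vals[list(combo)]
            gb = vals[[i for i in range(8) if i not in combo]]
            u = sum(1 for a in ga for b in gb if a > b)
            if abs(u - 8) >= abs(observed_u - 8):
                count += 1
        p_oracle = count / 70
        assert np.isclose(res.loc["g0", "p"], p_oracle)
        assert np.isclose(p_oracle, 2 / 70)

    def test_label_swap_symmetry(self):
        rng = np.random.default_rng(11)
        x = rng.random((12, 8)) + 0.2
        x[:6, 0] += 2.0
        m = make_cellmatrix(x)
        fwd = wilcoxon_de(m, np.arange(6), np.arange(6, 12), min_pct=0, lfc_min=0)
        rev = wilcoxon_de(m, np.arange(6, 12), np.arange(6), min_pct=0, lfc_min=0)
        assert np.allclose(fwd["lfc"], -rev["lfc"])
        assert np.allclose(fwd["p"], rev["p"])

    def test_small_group_raises(self):
        m = make_cellmatrix(np.random.default_rng(0).random((6, 4)))
        with pytest.raises(ValueError):
            wilcoxon_de(m, np.arange(2), np.arange(2, 6))

    def test_overlapping_groups_raise(self):
        m = make_cellmatrix(np.random.default_rng(0).random((8, 4)))
        with pytest.raises(ValueError, match="disjoint"):
            wilcoxon_de(m, np.arange(4), np.arange(2, 8))

    def test_q_at_least_p(self):
        rng = np.random.default_rng(12)
        x = rng.random((40, 50)) + 0.1
        m = make_cellmatrix(x)
        res = wilcoxon_de(m, np.arange(20), np.arange(20, 40), min_pct=0, lfc_min=0)
        assert (res["q"] >= res["p"] - 1e-12).all()

    def test_null_pvalues_uniform(self):
        rng = np.random.default_rng(13)
        x = rng.normal(3.0, 1.0, size=(80, 1000)).clip(0)
        m = make_cellmatrix(x)
        res = wilcoxon_de(m, np.arange(40), np.arange(40, 80), min_pct=0, lfc_min=0)
        ks = stats.kstest(res["p"], "uniform")
        assert ks.pvalue > 0.01


class TestIntegrateHook:
    def test_default_passthrough(self):
        from leukotrace.preprocess import integrate

        emb = np.random.default_rng(0).random((10, 3))
        assert np.array_equal(integrate(emb), emb)

    def test_custom_hook_applied(self):
        from leukotrace.preprocess import integrate

        emb = np.ones((4, 2))
        out = integrate(emb, batches=[0, 0, 1, 1], hook=lambda x, b: x * 2)
        assert np.array_equal(out, emb * 2)

    def test_cell_count_preserved(self):
        from leukotrace.preprocess import integrate

        with pytest.raises(ValueError):
            integrate(np.ones((4, 2)), hook=lambda x, b: x[:2])


class TestBH:
    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(14)
        p = rng.random(200)
        ours = bh_adjust(p)
        theirs = multipletests(p, method="fdr_bh")[1]
        assert np.allclose(ours, theirs)
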