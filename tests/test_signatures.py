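import numpy as np
import pandas as pd
import pytest
from scipy import stats

from leukotrace.matrix import CellMatrix
from leukotrace.preprocess import normalize
from leukotrace.signatures import (
    LSC17_COEFFICIENTS,
    call_chemoresistant,
    cd69_positive_fraction,
    gsea,
    gsea_multi,
    lsc17_score,
    lsc17_scores_cohort,
    module_score,
    resistant_vs_sensitive_degs,
    split_by_median,
)
from tests.conftest import make_cellmatrix

# the 17 printed gene weights, written out independently as the oracle
PRINTED = [
    ("DNMT3B", 0.0874), ("ZBTB46", -0.0347), ("NYNRIN", 0.00865),
    ("ARHGAP22", -0.0138), ("LAPTM4B", 0.00582), ("MMRN1", 0.0258),
    ("DPYSL3", 0.0284), ("KIAA0125", 0.0196), ("CDK6", -0.0704),
    ("CPXM1", -0.0258), ("SOCS2", 0.0271), ("SMIM24", -0.0226),
    ("EMP1", 0.0146), ("NGFRAP1", 0.0465), ("CD34", 0.0338),
    ("AKR1C3", -0.0402), ("GPR56", 0.0501),
]


class TestModuleScore:
    def test_one_bin_recompute_oracle(self):
        # n_ctrl >= pool: controls are exactly the non-member genes
        rng = np.random.default_rng(0)
        x = rng.random((20, 30)) + 0.1
        m = make_cellmatrix(x)
        members = ["g0", "g1", "g2"]
        score = module_score(m, members, n_bins=1, n_ctrl=100, seed=0)
        expected = x[:, :3].mean(axis=1) - x[:, 3:].mean(axis=1)
        assert np.allclose(score, expected)

    def test_members_at_bin_mean_score_near_zero(self):
        rng = np.random.default_rng(1)
        x = rng.normal(2.0, 0.3, size=(50, 40)).clip(0)
        x[:, 0] = x[:, 1:].mean(axis=1)  # member tracks the bin mean
        m = make_cellmatrix(x)
        score = module_score(m, ["g0"], n_bins=1, n_ctrl=100, seed=0)
        assert np.abs(score).max() < 0.05

    def test_constant_shift_linearity(self):
        rng = np.random.default_rng(2)
        x = rng.random((15, 25)) + 0.5
        m1 = make_cellmatrix(x)
        x2 = x.copy()
        x2[:, :4] += 1.5  # shift member genes only
        m2 = make_cellmatrix(x2)
        members = ["g0", "g1", "g2", "g3"]
        s1 = module_score(m1, members, n_bins=1, n_ctrl=100, seed=0)
        s2 = module_score(m2, members, n_bins=1, n_ctrl=100, seed=0)
        assert np.allclose(s2 - s1, 1.5)

    def test_seeded_sampling_reproducible(self):
        rng = np.random.default_rng(3)
        m = make_cellmatrix(rng.random((10, 200)))
        members = [f"g{i}" for i in range(5)]
        a = module_score(m, members, seed=7)
        b = module_score(m, members, seed=7)
        assert np.array_equal(a, b)

    def test_no_member_genes_raises(self):
        m = make_cellmatrix(np.ones((3, 5)))
        with pytest.raises(ValueError):
            module_score(m, ["absent"])


class TestLSC17:
    def test_all_zero(self):
        assert lsc17_score({g: 0.0 for g, _ in PRINTED}) == 0.0

    def test_single_gene_printed_coefficient(self):
        expr = {g: 0.0 for g, _ in PRINTED}
        expr["DNMT3B"] = 1.0
        assert lsc17_score(expr) == pytest.approx(0.0874)

    def test_all_ones_equals_coefficient_sum(self):
        oracle = sum(c for _, c in PRINTED)
        got = lsc17_score({g: 1.0 for g, _ in PRINTED})
        assert got == pytest.approx(oracle)
        assert oracle == pytest.approx(0.14027, abs=1e-5)

    def test_coefficients_match_printed(self):
        assert dict(PRINTED) == LSC17_COEFFICIENTS

    def test_linearity(self):
        rng = np.random.default_rng(4)
        expr = {g: rng.normal() for g, _ in PRINTED}
        scaled = {g: 3.5 * v for g, v in expr.items()}
        assert lsc17_score(scaled) == pytest.approx(3.5 * lsc17_score(expr))

    def test_missing_gene_warns_and_counts_zero(self):
        expr = {g: 1.0 for g, _ in PRINTED if g != "GPR56"}
        with pytest.warns(UserWarning, match="GPR56"):
            got = lsc17_score(expr)
        assert got == pytest.approx(sum(c for g, c in PRINTED if g != "GPR56"))

    def test_cohort_scores_zscore_scaled(self):
        rng = np.random.default_rng(5)
        expr = pd.DataFrame(rng.random((17, 8)) * 10,
                            index=[g for g, _ in PRINTED],
                            columns=[f"p{i}" for i in range(8)])
        scores = lsc17_scores_cohort(expr)
        oracle = pd.Series(0.0, index=expr.columns)
        for g, c in PRINTED:
            v = expr.loc[g]
            oracle += c * (v - v.mean()) / v.std(ddof=0)
        assert np.allclose(scores, oracle)


class TestSplitByMedian:
    def test_even_split(self):
        s = pd.Series([1.0, 2.0, 3.0, 4.0], index=list("abcd"))
        groups = split_by_median(s)
        assert set(groups[groups == "high"].index) == {"c", "d"}
        assert set(groups[groups == "low"].index) == {"a", "b"}

    def test_all_equal_all_low(self):
        s = pd.Series([2.0, 2.0, 2.0])
        assert (split_by_median(s) == "low").all()

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(6)
        s = pd.Series(rng.normal(size=11))
        assert (split_by_median(s) == split_by_median(np.exp(s))).all()

    def test_single_patient_raises(self):
        with pytest.raises(ValueError):
            split_by_median(pd.Series([1.0]))


class TestGSEA:
    def test_hand_computed_running_sum(self):
        # weight 0, N=5, set = {top gene}: curve 1, .75, .5, .25, 0 -> ES 1
        ranked = pd.Series([5.0, 4.0, 3.0, 2.0, 1.0], index=list("abcde"))
        res = gsea(ranked, ["a"], weight_exp=0.0, n_perm=50, seed=0)
        assert res.es == pytest.approx(1.0)
        assert res.leading_edge == ["a"]

    def test_all_genes_es_one(self):
        ranked = pd.Series([3.0, 2.0, 1.0], index=list("abc"))
        res = gsea(ranked, ["a", "b", "c"], n_perm=20, seed=0)
        assert res.es == pytest.approx(1.0)

    def test_reversed_ranking_negates_es(self):
        rng = np.random.default_rng(7)
        vals = rng.normal(size=60)
        ranked = pd.Series(vals, index=[f"g{i}" for i in range(60)])
        top = ranked.sort_values(ascending=False).index[:8].tolist()
        fwd = gsea(ranked, top, weight_exp=0.0, n_perm=20, seed=0)
        rev = gsea(-ranked, top, weight_exp=0.0, n_perm=20, seed=0)
        assert fwd.es > 0
        assert rev.es == pytest.approx(-fwd.es)

    def test_es_bounded(self):
        rng = np.random.default_rng(8)
        for _ in range(20):
            n = rng.integers(10, 80)
            ranked = pd.Series(rng.normal(size=n), index=[f"g{i}" for i in range(n)])
            members = rng.choice(n, size=rng.integers(2, max(3, n // 3)), replace=False)
            res = gsea(ranked, [f"g{i}" for i in members], n_perm=10, seed=0)
            assert -1.0 <= res.es <= 1.0

    def test_null_pvalues_uniform(self):
        rng = np.random.default_rng(9)
        pvals = []
        for rep in range(500):
            ranked = pd.Series(rng.normal(size=60), index=[f"g{i}" for i in range(60)])
            members = [f"g{i}" for i in rng.choice(60, size=8, replace=False)]
            pvals.append(gsea(ranked, members, n_perm=100, seed=rep).p)
        ks = stats.kstest(pvals, "uniform")
        assert ks.pvalue > 0.01

    def test_empty_overlap_raises(self):
        ranked = pd.Series([1.0, 0.5], index=["a", "b"])
        with pytest.raises(ValueError, match="overlap"):
            gsea(ranked, ["zz"])

    def test_multi_set_fdr_separates_signal_from_noise(self):
        rng = np.random.default_rng(10)
        n = 200
        vals = np.sort(rng.normal(size=n))[::-1]
        ranked = pd.Series(vals, index=[f"g{i}" for i in range(n)])
        sets = {"signal": [f"g{i}" for i in range(10)]}
        for k in range(5):
            sets[f"random{k}"] = [f"g{i}" for i in rng.choice(n, 10, replace=False)]
        res = gsea_multi(ranked, sets, n_perm=200, seed=0)
        assert res.loc["signal", "fdr"] < 0.05
        assert res.loc["signal", "nes"] > res.drop("signal")["nes"].max()


class TestChemoresistantCall:
    def _df(self, nes, fdr):
        return pd.DataFrame({"nes": [nes], "fdr": [fdr]}, index=["pop1"])

    def test_passing_call(self):
        assert call_chemoresistant(self._df(2.3, 1e-5)).iloc[0]

    def test_fdr_too_high(self):
        assert not call_chemoresistant(self._df(2.3, 0.01)).iloc[0]

    def test_boundary_strict(self):
        assert not call_chemoresistant(self._df(1.9, 1e-5)).iloc[0]
        assert not call_chemoresistant(self._df(2.3, 0.001)).iloc[0]


class TestResistantVsSensitiveDEGs:
    def _dataset(self, effects: dict[str, dict[str, float]], n_per_patient=60, n_genes=40):
        """effects: gene -> {patient: additive shift}."""
        rng = np.random.default_rng(11)
        patients = ["R1", "R2", "S1", "S2"]
        rows, pids = [], []
        for p in patients:
            x = rng.normal(2.0, 0.25, size=(n_per_patient, n_genes)).clip(0.1)
            rows.append(x)
            pids += [p] * n_per_patient
        x = np.vstack(rows)
        genes = [f"g{j}" for j in range(n_genes)]
        for g, shifts in effects.items():
            j = genes.index(g)
            for p, delta in shifts.items():
                sel = np.asarray(pids) == p
                x[sel, j] = np.clip(x[sel, j] + delta, 0.0, None)
        m = make_cellmatrix(x, gene_names=genes,
                            barcodes=[f"c{i}" for i in range(len(pids))])
        groups = {"R1": "resistant", "R2": "resistant", "S1": "sensitive", "S2": "sensitive"}
        return m, pd.Series(pids, index=m.barcodes), groups

    def test_consistent_gene_retained(self):
        m, pids, groups = self._dataset({"g0": {"R1": 2.0, "R2": 2.0}})
        degs = resistant_vs_sensitive_degs(m, pids, groups)
        assert "g0" in degs.index
        assert degs.loc["g0", "n_consistent"] == 2

    def test_discordant_gene_excluded(self):
        m, pids, groups = self._dataset({"g0": {"R1": 3.0, "R2": -1.0}})
        degs = resistant_vs_sensitive_degs(m, pids, groups)
        assert "g0" not in degs.index

    def test_identical_groups_empty(self):
        m, pids, groups = self._dataset({})
        degs = resistant_vs_sensitive_degs(m, pids, groups)
        assert degs.empty

    def test_single_patient_group_raises(self):
        m, pids, _ = self._dataset({})
        groups = {"R1": "resistant", "R2": "sensitive", "S1": "sensitive", "S2": "sensitive"}
        with pytest.raises(ValueError):
            resistant_vs_sensitive_degs(m, pids, groups)


class TestCD69Fraction:
    def test_nine_of_ten(self):
        x = np.zeros((10, 1))
        x[:9, 0] = 1.5
        m = make_cellmatrix(x, gene_names=["CD69"])
        assert cd69_positive_fraction(m, list(m.barcodes)) == pytest.approx(0.9)

    def test_none_expressing(self):
        m = make_cellmatrix(np.zeros((5, 1)), gene_names=["CD69"])
        assert cd69_positive_fraction(m, list(m.barcodes)) == 0.0

    def test_generative_recovery(self):
        from leukotrace.synthetic import CellTypeSpec, SimConfig, generate_patient_pair

        cfg = SimConfig(seed=12, n_genes=600, n_cells_per_sample=1600,
                        cd69_hsc_fraction=0.9,
                        type_catalog=[CellTypeSpec(name=n) for n in ("HSC", "LMPP", "GMP", "B")])
        pre, _, _ = generate_patient_pair(cfg)
        pre = normalize(pre)
        meta = pre.cell_meta
        hsc_like = meta.index[(meta["malignant"]) & (meta["true_type"] == "HSC")]
        assert len(hsc_like) >= 500
        frac = cd69_positive_fraction(pre, hsc_like)
        assert abs(frac - 0.9) <= 0.05

    def test_empty_population_raises(self):
        m = make_cellmatrix(np.ones((2, 1)), gene_names=["CD69"])
        with pytest.raises(ValueError):
            cd69_positive_fraction(m, [])

    def test_missing_gene_raises(self):
        m = make_cellmatrix(np.ones((2, 1)), gene_names=["other"])
        with pytest.raises(KeyError):
            cd69_positive_fraction(m, list(m.barcodes))
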