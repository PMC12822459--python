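import numpy as np
import pandas as pd
import pytest
import scipy.stats

import neotls as nt
from neotls.errors import FormatError, NeotlsError


def null_lognorm(n_genes=500, n_cells=1000, seed=0):
    """Exchangeable null data: NB counts with no planted structure."""
    cfg = nt.SimConfig(n_genes=n_genes, n_cells=n_cells,
                       subtype_table={"A": 1.0}, seed=seed)
    matrix, cells, _ = nt.simulate_cohort(cfg)
    return nt.lognormalize(matrix), cells


class TestModuleScore:
    def test_whole_transcriptome_signature_scores_zero(self):
        """A signature equal to the background must score ~0 everywhere."""
        ln, _ = null_lognorm(n_genes=500, n_cells=50, seed=1)
        sig = nt.GeneSignature("all", tuple(ln.gene_ids))
        # 25 bins of 20 genes each, n_ctrl=100 covers every bin exhaustively
        st = nt.module_score(ln, sig, n_bins=25, n_ctrl=100, seed=0)
        assert np.abs(st.values()).max() < 1e-6

    def test_random_signature_is_mean_zero_on_null_data(self):
        ln, _ = null_lognorm(n_genes=500, n_cells=1000, seed=2)
        rng = np.random.default_rng(3)
        sig = nt.GeneSignature("rand", tuple(rng.choice(ln.gene_ids, 50, replace=False)))
        st = nt.module_score(ln, sig, seed=4)
        assert abs(st.values().mean()) < 0.05

    def test_planted_subtype_scores_higher(self):
        """Cells of the subtype carrying +1 log2-fold markers score higher."""
        marker_idx = list(range(100, 150))
        cfg = nt.SimConfig(n_genes=500, n_cells=1000,
                           subtype_table={"hot": 0.3, "cold": 0.7},
                           marker_map={"hot": (marker_idx, 1.0)}, seed=5)
        matrix, cells, _ = nt.simulate_cohort(cfg)
        ln = nt.lognormalize(matrix)
        sig = nt.GeneSignature("markers", tuple(matrix.gene_ids[marker_idx]))
        st = nt.module_score(ln, sig, seed=6)
        hot = st.scores[cells["subtype"] == "hot"]
        cold = st.scores[cells["subtype"] == "cold"]
        assert hot.mean() > cold.mean()
        p = scipy.stats.mannwhitneyu(hot, cold, alternative="two-sided").pvalue
        assert p < 0.01

    def test_deterministic_under_seed_and_missing_genes_warn(self, caplog):
        ln, _ = null_lognorm(n_genes=300, n_cells=100, seed=7)
        genes = tuple(ln.gene_ids[:10]) + ("NOT_A_GENE",)
        sig = nt.GeneSignature("s", genes)
        with caplog.at_level("WARNING", logger="neotls.scoring"):
            a = nt.module_score(ln, sig, seed=42)
        assert "missing" in caplog.text
        b = nt.module_score(ln, sig, seed=42)
        pd.testing.assert_series_equal(a.scores, b.scores)

    def test_no_gene_present_errors(self):
        ln, _ = null_lognorm(n_genes=100, n_cells=30, seed=8)
        with pytest.raises(NeotlsError, match="no gene"):
            nt.module_score(ln, nt.GeneSignature("x", ("nope",)), seed=0)


class TestSummedScore:
    def test_single_gene_identity_and_additivity(self):
        ln, _ = null_lognorm(n_genes=100, n_cells=40, seed=9)
        g = str(ln.gene_ids[5])
        one = nt.summed_score(ln, nt.GeneSignature("one", (g,)))
        np.testing.assert_allclose(one.values(), ln.row(g))

        s1 = nt.GeneSignature("s1", tuple(ln.gene_ids[:10]))
        s2 = nt.GeneSignature("s2", tuple(ln.gene_ids[10:25]))
        union = nt.GeneSignature("u", s1.genes + s2.genes)
        np.testing.assert_allclose(
            nt.summed_score(ln, union).values(),
            nt.summed_score(ln, s1).values() + nt.summed_score(ln, s2).values(),
            rtol=1e-12)


class TestWilcoxonDE:
    def test_identical_groups_are_null(self):
        ln, _ = null_lognorm(n_genes=200, n_cells=50, seed=10)
        ids = list(ln.entity_ids)
        res = nt.wilcoxon_de(ln, ids, ids)
        assert all(r.log2fc == 0 for r in res)
        assert not any(r.significant for r in res)

    def test_planted_fold_changes_recovered(self):
        """Planted 2x genes: sensitivity >= 0.9, BH false positives <= 5%."""
        # planted genes kept a small share of the library so the depth
        # normalization does not induce a compositional shift in null genes
        de_idx = list(range(50))
        cfg = nt.SimConfig(n_genes=2000, n_cells=400, subtype_table={"A": 1.0},
                           groups=("R",), treatment_shift=(de_idx, 1.0),
                           seed=11)
        matrix, cells, truth = nt.simulate_cohort(cfg)
        ln = nt.lognormalize(matrix)
        pre = list(cells.index[cells["timepoint"] == "pre"])
        post = list(cells.index[cells["timepoint"] == "post"])
        assert len(pre) == len(post) == 200
        res = nt.wilcoxon_de(ln, post, pre)
        called = np.array([r.significant for r in res])
        assert called[truth.de_gene_mask].mean() >= 0.9
        assert called[~truth.de_gene_mask].mean() <= 0.05

    def test_significance_thresholds_are_strict(self):
        """log2FC > 0.5 AND padj < 0.05, both strict."""
        from neotls.scoring import DEResult
        ln, _ = null_lognorm(n_genes=10, n_cells=20, seed=12)
        res = nt.wilcoxon_de(ln, list(ln.entity_ids[:10]), list(ln.entity_ids[10:]))
        for r in res:
            assert r.significant == (r.log2fc > 0.5 and r.padj < 0.05)
        assert DEResult("g", 0.6, 0.01, 0.04, True).significant
        assert not (0.6 > 0.5 and 0.06 < 0.05)  # padj 0.06 -> not significant

    def test_relabeling_flips_sign_keeps_significance(self):
        ln, _ = null_lognorm(n_genes=100, n_cells=60, seed=13)
        a, b = list(ln.entity_ids[:30]), list(ln.entity_ids[30:])
        ab = nt.wilcoxon_de(ln, a, b)
        ba = nt.wilcoxon_de(ln, b, a)
        for r1, r2 in zip(ab, ba):
            assert r1.log2fc == pytest.approx(-r2.log2fc, abs=1e-12)
            assert r1.p == pytest.approx(r2.p, rel=1e-9)


class TestDerivedSignatures:
    def test_treatment_signature_is_intersection(self):
        from neotls.scoring import DEResult
        published = nt.GeneSignature("TLS-pub", ("g1", "g2", "g3"))
        de = [DEResult("g2", 1.0, 0.001, 0.01, True),
              DEResult("g3", -0.2, 0.002, 0.02, False),
              DEResult("g9", 2.0, 0.0001, 0.001, True)]
        out = nt.derive_treatment_signature(published, de)
        assert out.genes == ("g2", "g3")  # significance only, direction ignored
        assert out.source_tag == "neoCRT-TLS"
        assert set(out.genes) <= set(published.genes)

    def test_no_significant_gene_returns_none_with_warning(self, caplog):
        from neotls.scoring import DEResult
        published = nt.GeneSignature("TLS-pub", ("g1",))
        with caplog.at_level("WARNING", logger="neotls.scoring"):
            out = nt.derive_treatment_signature(
                published, [DEResult("g1", 0.1, 0.5, 0.9, False)])
        assert out is None
        assert "treatment-responsive" in caplog.text

    def test_planted_treatment_genes_recovered(self):
        """Only planted genes shift pre->post: Jaccard >= 0.9 with truth."""
        planted = list(range(40))
        cfg = nt.SimConfig(n_genes=2000, n_cells=400, subtype_table={"A": 1.0},
                           groups=("R",), treatment_shift=(planted, 1.0), seed=14)
        matrix, cells, truth = nt.simulate_cohort(cfg)
        ln = nt.lognormalize(matrix)
        post = list(cells.index[cells["timepoint"] == "post"])
        pre = list(cells.index[cells["timepoint"] == "pre"])
        de = nt.wilcoxon_de(ln, post, pre)
        published = nt.GeneSignature("TLS-pub", tuple(matrix.gene_ids))
        derived = nt.derive_treatment_signature(published, de)
        truth_set = set(matrix.gene_ids[truth.de_gene_mask])
        got = set(derived.genes)
        jaccard = len(got & truth_set) / len(got | truth_set)
        assert jaccard >= 0.9

    def test_top_ratio_markers_ordering_and_truncation(self, caplog):
        """Planted graded elevations: top-k are the k largest, in order."""
        elevations = {100 + i: 1.0 + 0.1 * i for i in range(30)}
        cfg = nt.SimConfig(
            n_genes=1000, n_cells=600, subtype_table={"tgt": 0.5, "oth": 0.5},
            marker_map={}, seed=15)
        matrix, cells, _ = nt.simulate_cohort(cfg)
        # plant graded shifts by scaling target-cell counts post hoc
        v = matrix.dense()
        tgt_cols = np.flatnonzero((cells["subtype"] == "tgt").to_numpy())
        rng = np.random.default_rng(16)
        for gi, fc in elevations.items():
            extra = rng.poisson(v[gi, tgt_cols] * (2 ** fc - 1))
            v[gi, tgt_cols] = v[gi, tgt_cols] + extra
        matrix = nt.ExpressionMatrix(v, matrix.gene_ids, matrix.entity_ids)
        ln = nt.lognormalize(matrix)
        tgt = list(cells.index[tgt_cols])
        oth = list(cells.index[cells["subtype"] == "oth"])
        top = nt.top_ratio_markers(ln, tgt, oth, k=20)
        assert len(top.genes) <= 20
        planted_sorted = [f"g{100 + i:04d}" for i in sorted(
            range(30), key=lambda i: -elevations[100 + i])]
        assert set(top.genes) == set(planted_sorted[:20])
        # output is ordered by the measured log2 expression ratio, descending
        de = {r.gene: r.log2fc for r in
              nt.wilcoxon_de(ln, tgt, oth)}
        measured = [de[g] for g in top.genes]
        assert measured == sorted(measured, reverse=True)
        with caplog.at_level("WARNING", logger="neotls.scoring"):
            nt.top_ratio_markers(ln, tgt, oth, k=200)
        assert "candidate" in caplog.text


class TestScoreRatioAndMSI:
    def test_ratio_identity_and_homogeneity(self):
        idx = pd.Index([f"c{i}" for i in range(5)])
        s = nt.ScoreTable(pd.Series([1.0, 2, 3, 4, 5], index=idx), "module")
        np.testing.assert_allclose(nt.score_ratio(s, s, shift=0).values(), 1.0)
        doubled = nt.ScoreTable(s.scores * 2, "module")
        np.testing.assert_allclose(nt.score_ratio(doubled, s, shift=0).values(), 2.0)

    def test_ratio_shift_handles_negative_scores(self):
        idx = pd.Index(["a", "b"])
        num = nt.ScoreTable(pd.Series([-0.5, 0.5], index=idx), "module")
        den = nt.ScoreTable(pd.Series([0.5, -0.5], index=idx), "module")
        r = nt.score_ratio(num, den)
        assert np.isfinite(r.values()).all()
        assert r.values()[1] > r.values()[0]

    def test_ratio_entity_mismatch_errors(self):
        a = nt.ScoreTable(pd.Series([1.0], index=["x"]), "module")
        b = nt.ScoreTable(pd.Series([1.0], index=["y"]), "module")
        with pytest.raises(FormatError, match="entities"):
            nt.score_ratio(a, b)

    @pytest.mark.parametrize("score,expected", [
        (0.2, "MSS"), (3.5, "MSS"), (3.5000001, "MSI"), (10.0, "MSI")])
    def test_msi_cutoff(self, score, expected):
        assert nt.classify_msi(score) == expected

    def test_msi_negative_score_errors(self):
        with pytest.raises(NeotlsError):
            nt.classify_msi(-1.0)
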