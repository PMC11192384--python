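"""Pairing, conditional histograms, sign concordance, contrasts, PCA."""

import numpy as np
import pandas as pd
import pytest

import chondroseq as cs
from chondroseq.compare import fcfc_scatter_table

from conftest import make_paired


def de_like(ids, lfc, p, alpha=0.1):
    padj = cs.bh_adjust(p)
    return pd.DataFrame({
        "gene_id": ids, "base_mean": 100.0, "lfc": lfc,
        "se": 0.1, "wald": np.asarray(lfc) / 0.1, "p": p, "padj": padj,
        "significant": padj < alpha,
    })


class TestPairResults:
    def test_identical_universe_full_join(self):
        ids = [f"g{i}" for i in range(50)]
        rng = np.random.default_rng(0)
        a = de_like(ids, rng.normal(size=50), rng.random(50))
        b = de_like(ids, rng.normal(size=50), rng.random(50))
        assert len(cs.pair_results(a, b)) == 50

    def test_partial_overlap_join_size(self):
        rng = np.random.default_rng(1)
        a = de_like([f"g{i}" for i in range(100)],
                    rng.normal(size=100), rng.random(100))
        b = de_like([f"g{i}" for i in range(40, 120)],
                    rng.normal(size=80), rng.random(80))
        assert len(cs.pair_results(a, b)) == 60

    def test_duplicate_ids_rejected(self):
        a = de_like(["g1", "g1"], [0.5, 0.5], [0.1, 0.1])
        with pytest.raises(ValueError, match="duplicate"):
            cs.pair_results(a, a)

    def test_empty_intersection_rejected(self):
        a = de_like(["g1"], [0.5], [0.1])
        b = de_like(["h1"], [0.5], [0.1])
        with pytest.raises(ValueError):
            cs.pair_results(a, b)


class TestConditionalPHist:
    def test_independent_null_is_flat(self):
        rng = np.random.default_rng(2)
        n = 2000
        df = pd.DataFrame({
            "gene_id": [f"g{i}" for i in range(n)],
            "lfc_a": rng.normal(size=n), "p_a": rng.random(n),
            "padj_a": 1.0, "sig_a": rng.random(n) < 0.5,
            "lfc_b": rng.normal(size=n), "p_b": rng.random(n),
            "padj_b": 1.0, "sig_b": rng.random(n) < 0.5,
        })
        hist = cs.conditional_p_hist(df, stratify_by="b", bins=20)
        for key in ("density_significant", "density_nonsignificant"):
            assert hist[key].max() <= 1.5 and hist[key].max() >= 0.6

    def test_shared_program_spikes_first_bin(self):
        rng = np.random.default_rng(3)
        n = 2000
        sig_b = rng.random(n) < 0.2
        p_a = np.where(sig_b & (rng.random(n) < 0.8),
                       rng.random(n) * 0.01, rng.random(n))
        df = pd.DataFrame({
            "gene_id": [f"g{i}" for i in range(n)],
            "lfc_a": 0.0, "p_a": p_a, "padj_a": 1.0, "sig_a": False,
            "lfc_b": 0.0, "p_b": 0.5, "padj_b": 1.0, "sig_b": sig_b,
        })
        hist = cs.conditional_p_hist(df, "b", bins=20)
        assert (hist["density_significant"][0]
                > 2 * max(hist["density_nonsignificant"][0], 1e-9))

    def test_histograms_integrate_to_one(self):
        rng = np.random.default_rng(4)
        df = pd.DataFrame({
            "gene_id": range(500), "lfc_a": 0.0, "p_a": rng.random(500),
            "padj_a": 1.0, "sig_a": False, "lfc_b": 0.0,
            "p_b": rng.random(500), "padj_b": 1.0,
            "sig_b": rng.random(500) < 0.3,
        })
        hist = cs.conditional_p_hist(df, "b")
        widths = np.diff(hist["bin_edges"])
        for key in ("density_significant", "density_nonsignificant"):
            assert abs((hist[key] * widths).sum() - 1.0) < 1e-9

    def test_degenerate_terminal_bin(self):
        df = pd.DataFrame({
            "gene_id": range(10), "lfc_a": 0.0, "p_a": 1.0, "padj_a": 1.0,
            "sig_a": False, "lfc_b": 0.0, "p_b": 0.5, "padj_b": 1.0,
            "sig_b": [True] * 5 + [False] * 5,
        })
        hist = cs.conditional_p_hist(df, "b", bins=20)
        for key in ("density_significant", "density_nonsignificant"):
            assert (hist[key][:-1] == 0).all() and hist[key][-1] > 0

    def test_empty_stratum_named(self):
        df = pd.DataFrame({
            "gene_id": range(4), "lfc_a": 0.0, "p_a": 0.5, "padj_a": 1.0,
            "sig_a": False, "lfc_b": 0.0, "p_b": 0.5, "padj_b": 1.0,
            "sig_b": False,
        })
        with pytest.raises(ValueError, match="significant"):
            cs.conditional_p_hist(df, "b")


class TestSignConcordance:
    def test_summary_counts_sum_and_pct(self):
        paired = make_paired(578, 139, 362)
        summary = cs.sign_concordance(paired)
        assert summary.n_both_sig == 578
        assert summary.discordant == 77
        assert summary.up_up + summary.down_down + summary.discordant == 578
        assert summary.pct_concordant == 86.7

    def test_no_both_significant_rows(self):
        paired = make_paired(10, 5, 5)
        paired["sig_a"] = False
        summary = cs.sign_concordance(paired)
        assert summary.n_both_sig == 0 and np.isnan(summary.pct_concordant)

    def test_zero_lfc_counted_discordant_with_warning(self):
        paired = make_paired(4, 2, 2)
        paired.loc[0, "lfc_a"] = 0.0
        with pytest.warns(UserWarning, match="lfc exactly 0"):
            summary = cs.sign_concordance(paired)
        assert summary.discordant == 1

    def test_pct_invariant_to_swapping_tables(self):
        paired = make_paired(200, 80, 90, seed=5)
        swapped = paired.rename(columns={
            "lfc_a": "lfc_b", "lfc_b": "lfc_a", "p_a": "p_b", "p_b": "p_a",
            "padj_a": "padj_b", "padj_b": "padj_a",
            "sig_a": "sig_b", "sig_b": "sig_a"})
        assert (cs.sign_concordance(paired).pct_concordant
                == cs.sign_concordance(swapped).pct_concordant)


class TestAssembleContrasts:
    def test_full_design_yields_six_specs(self, small_dataset):
        _, _, samples, _ = small_dataset
        specs = cs.assemble_contrasts(samples)
        assert len(specs) == 6
        names = {s.name for s in specs}
        assert "KS1_D14_genotype_KO_vs_WT" in names
        assert "KS2_KO_timepoint_D14_vs_D7" in names

    def test_missing_timepoint_halves_battery(self, small_dataset):
        _, _, samples, _ = small_dataset
        d14_only = samples[samples["timepoint"] == "D14"]
        with pytest.warns(UserWarning):
            specs = cs.assemble_contrasts(d14_only)
        assert {s.name for s in specs} == {
            "KS1_D14_genotype_KO_vs_WT", "KS2_D14_genotype_KO_vs_WT"}

    def test_single_clone_level_dropped_by_name(self, small_dataset):
        _, _, samples, _ = small_dataset
        keep = ~((samples.arm == "KS1") & (samples.genotype == "KO")
                 & (samples.timepoint == "D7")
                 & (samples.clone != "KS1_KO_1"))
        with pytest.warns(UserWarning, match="KS1_D7_genotype_KO_vs_WT"):
            specs = cs.assemble_contrasts(samples[keep])
        # the D7 KO-vs-WT spec and the KS1 trajectory spec both lose the level
        assert len(specs) == 4
        assert "KS1_D7_genotype_KO_vs_WT" not in {s.name for s in specs}


class TestPCA:
    def make_two_cluster_counts(self):
        rng = np.random.default_rng(6)
        base = rng.integers(50, 500, size=200)
        counts = np.tile(base[:, None], (1, 6)) + rng.integers(0, 5, (200, 6))
        counts[:50, 3:] += 400  # strong between-group shift on 50 genes
        return pd.DataFrame(counts, index=[f"g{i}" for i in range(200)],
                            columns=[f"s{j}" for j in range(6)])

    def test_two_cluster_fixture_separated_on_pc1(self):
        result = cs.pca_overview(self.make_two_cluster_counts(), n_top=100)
        pc1 = result.coordinates["PC1"].to_numpy()
        assert result.variance_fractions[0] > result.variance_fractions[1]
        assert (np.sign(pc1[:3]) != np.sign(pc1[3:])).all()

    def test_identical_samples_flagged_degenerate(self):
        counts = pd.DataFrame(np.full((50, 4), 100),
                              index=[f"g{i}" for i in range(50)],
                              columns=list("abcd"))
        result = cs.pca_overview(counts, n_top=50)
        assert result.degenerate

    def test_duplicating_samples_preserves_fractions(self):
        counts = self.make_two_cluster_counts()
        doubled = pd.concat(
            [counts, counts.add_suffix("_dup", axis=1)], axis=1)
        a = cs.pca_overview(counts, n_top=80)
        b = cs.pca_overview(doubled, n_top=80)
        np.testing.assert_allclose(a.variance_fractions[:3],
                                   b.variance_fractions[:3], atol=1e-8)

    def test_matches_eigendecomposition_oracle(self):
        rng = np.random.default_rng(7)
        counts = pd.DataFrame(rng.integers(10, 1000, size=(10, 6)),
                              index=[f"g{i}" for i in range(10)],
                              columns=[f"s{j}" for j in range(6)])
        result = cs.pca_overview(counts, n_top=10)
        sf = cs.size_factors(counts)
        x = np.log2(counts.to_numpy() / sf.to_numpy()[None, :] + 1)
        centered = x - x.mean(axis=1, keepdims=True)
        eigvals = np.linalg.eigvalsh(centered.T @ centered)[::-1]
        oracle = eigvals / eigvals.sum()
        np.testing.assert_allclose(
            result.variance_fractions[:len(oracle)], oracle, atol=1e-8)

    def test_n_top_clamped_with_warning(self):
        counts = self.make_two_cluster_counts()
        with pytest.warns(UserWarning, match="clamped"):
            cs.pca_overview(counts, n_top=10_000)

    def test_variance_fraction_invariants(self, small_dataset):
        _, counts, _, _ = small_dataset
        result = cs.pca_overview(cs.filter_low_expressed(counts))
        f = result.variance_fractions
        assert ((f >= 0) & (f <= 1)).all()
        assert (np.diff(f) <= 1e-12).all()
        assert f.sum() <= 1 + 1e-9


class TestCrossDatasetValidation:
    def test_identity_gives_full_concordance(self, small_de_tables):
        det = small_de_tables["KS1"]
        report = cs.cross_dataset_validation(det, det)
        assert report["concordance"].pct_concordant == 100.0
        assert report["concordance"].discordant == 0

    def test_validation_fixture_matches_expected_pct(self):
        paired = make_paired(404, 250, 153)  # 403 of 404 sign-matched
        assert cs.sign_concordance(paired).pct_concordant == 99.8

    def test_independent_tables_near_chance(self):
        rng = np.random.default_rng(8)
        ids = [f"g{i}" for i in range(3000)]
        a = de_like(ids, rng.normal(size=3000), rng.random(3000), alpha=0.5)
        b = de_like(ids, rng.normal(size=3000), rng.random(3000), alpha=0.5)
        a["significant"] = a["p"] < 0.3
        b["significant"] = b["p"] < 0.3
        summary = cs.cross_dataset_validation(a, b)["concordance"]
        from scipy.stats import binomtest
        k = summary.up_up + summary.down_down
        assert binomtest(k, summary.n_both_sig, 0.5).pvalue > 0.01


def test_fcfc_scatter_categories():
    paired = make_paired(6, 3, 3, n_extra_ns=4)
    table = fcfc_scatter_table(paired, set_members={"G00000"})
    assert set(table["category"]) <= {"both", "one", "ns", "set-member"}
    assert (table.loc[table.gene_id == "G00000", "category"]
            == "set-member").all()
    assert (table["category"] == "both").sum() == 5
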