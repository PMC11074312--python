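"""Regulatory-domain assignment, bootstrap null, and the early-TF screen."""

import numpy as np
import pandas as pd
import pytest

from switchquant import synth
from switchquant.enrichment import (
    EnrichmentConfig,
    assign_peaks_to_genes,
    bootstrap_overlap,
    screen_persistent_tfs,
)


def simple_universe():
    return pd.DataFrame(
        {
            "gene_id": ["a", "b", "c"],
            "chrom": ["chr1"] * 3,
            "tss": [100_000, 200_000, 300_000],
            "strand": ["+", "-", "+"],
        }
    )


class TestAssignment:
    def test_peak_covering_a_tss_flags_that_gene(self):
        peaks = pd.DataFrame({"chrom": ["chr1"], "start": [199_990], "end": [200_010]})
        out = assign_peaks_to_genes(peaks, simple_universe()).set_index("gene_id")
        assert out.loc["b", "has_peak"]
        assert not out.loc["a", "has_peak"] and not out.loc["c", "has_peak"]

    def test_peak_beyond_extension_flags_nothing(self):
        genes = simple_universe()
        peaks = pd.DataFrame(
            {"chrom": ["chr1"], "start": [5_000_000], "end": [5_000_100]}
        )
        out = assign_peaks_to_genes(peaks, genes, extension_bp=100_000)
        assert not out["has_peak"].any()

    def test_extension_reaches_distal_peaks_between_genes(self):
        genes = simple_universe()
        # midway between a and b, within 1 Mb of both but outside both basal domains
        peaks = pd.DataFrame({"chrom": ["chr1"], "start": [150_000], "end": [150_050]})
        out = assign_peaks_to_genes(peaks, genes).set_index("gene_id")
        assert out.loc["a", "has_peak"] or out.loc["b", "has_peak"]

    def test_strand_aware_basal_domain(self):
        genes = pd.DataFrame(
            {
                "gene_id": ["plus", "minus"],
                "chrom": ["chr1", "chr2"],
                "tss": [50_000, 50_000],
                "strand": ["+", "-"],
            }
        )
        # 3 kb downstream of the TSS: outside the 1 kb downstream basal reach
        # of a + gene, inside the 5 kb upstream-on-the-minus-strand reach
        peaks = pd.DataFrame(
            {"chrom": ["chr1", "chr2"], "start": [53_000, 53_000], "end": [53_050, 53_050]}
        )
        out = assign_peaks_to_genes(peaks, genes, extension_bp=0).set_index("gene_id")
        assert not out.loc["plus", "has_peak"]
        assert out.loc["minus", "has_peak"]

    def test_generator_universe_recovered_exactly(self):
        genes, peaks = synth.generate_gene_universe(1000, 0.137, 40_000_000, 3)
        out = assign_peaks_to_genes(peaks, genes)
        assert out["has_peak"].sum() == 137
        np.testing.assert_array_equal(out["has_peak"], genes["has_peak_true"])

    def test_duplicate_gene_ids_rejected(self):
        genes = simple_universe()
        genes.loc[2, "gene_id"] = "a"
        with pytest.raises(ValueError, match="unique"):
            assign_peaks_to_genes(
                pd.DataFrame({"chrom": ["chr1"], "start": [0], "end": [10]}), genes
            )


class TestBootstrap:
    @staticmethod
    def flagged_universe(n=1000, k=137, seed=3):
        genes, peaks = synth.generate_gene_universe(n, k / n, 40 * n * 1000, seed)
        return assign_peaks_to_genes(peaks, genes)

    def test_fully_flagged_universe_is_unenriched(self):
        uni = self.flagged_universe(n=400, k=400)
        de = list(uni["gene_id"].iloc[:100])
        res = bootstrap_overlap(de, uni, EnrichmentConfig(n_iter=200, seed=1))
        assert res.observed == 100
        assert res.fold == 1.0
        assert res.empirical_p == 1.0

    def test_null_mean_matches_hypergeometric_expectation(self):
        uni = self.flagged_universe()
        de = list(uni["gene_id"].sample(292, random_state=0))
        res = bootstrap_overlap(de, uni, EnrichmentConfig(n_draw=292, seed=42))
        expected = 292 * 137 / 1000  # = 40.0
        se = res.null_sd / np.sqrt(len(res.null_counts))
        assert abs(res.null_mean - expected) <= 3 * se

    def test_planted_excess_gives_threefold_enrichment(self):
        """114 peak-bearing genes out of a 292-gene set versus a ~40 chance
        expectation is close to a three-fold enrichment."""
        uni = self.flagged_universe()
        de = list(uni.loc[uni["has_peak"], "gene_id"].iloc[:114]) + list(
            uni.loc[~uni["has_peak"], "gene_id"].iloc[:178]
        )
        res = bootstrap_overlap(de, uni, EnrichmentConfig(seed=42))
        assert res.observed == 114
        assert res.fold == pytest.approx(114 / 40.0, rel=0.05)
        assert res.empirical_p <= 1e-3

    def test_zero_observed_has_p_one(self):
        uni = self.flagged_universe(n=300, k=150)
        de = list(uni.loc[~uni["has_peak"], "gene_id"].iloc[:50])
        res = bootstrap_overlap(de, uni, EnrichmentConfig(n_iter=99, seed=7))
        assert res.observed == 0
        assert res.empirical_p == 1.0

    def test_seed_determinism_of_null_histogram(self):
        uni = self.flagged_universe(n=200, k=50)
        de = list(uni["gene_id"].iloc[:40])
        r1 = bootstrap_overlap(de, uni, EnrichmentConfig(n_iter=500, seed=5))
        r2 = bootstrap_overlap(de, uni, EnrichmentConfig(n_iter=500, seed=5))
        np.testing.assert_array_equal(r1.null_counts, r2.null_counts)

    def test_with_replacement_matches_binomial_mean(self):
        uni = self.flagged_universe(n=500, k=100)
        de = list(uni["gene_id"].iloc[:50])
        res = bootstrap_overlap(
            de, uni, EnrichmentConfig(n_iter=4000, seed=9, with_replacement=True)
        )
        se = res.null_sd / np.sqrt(4000)
        assert abs(res.null_mean - 50 * 100 / 500) <= 3 * se

    def test_missing_de_gene_is_an_error_listing_ids(self):
        uni = self.flagged_universe(n=100, k=10)
        with pytest.raises(ValueError, match="ghost"):
            bootstrap_overlap(["ghost"], uni, EnrichmentConfig(n_iter=10, seed=1))


class TestScreen:
    @staticmethod
    def table():
        return pd.DataFrame(
            {
                "gene_id": ["tf_up", "tf_late_down", "tf_weak", "nontf_up", "tf_up2"],
                "log2fc_6h": [2.0, 1.5, 0.5, 3.0, 1.0],
                "fdr_6h": [0.01, 0.02, 0.5, 0.001, 0.05],
                "log2fc_48h": [3.0, -1.0, 0.2, 4.0, 3.5],
            }
        )

    def test_empty_tf_set_gives_empty_result(self):
        assert len(screen_persistent_tfs(self.table(), set())) == 0

    def test_persistent_tfs_selected_in_lfc_order(self):
        tfs = {"tf_up", "tf_late_down", "tf_weak", "tf_up2"}
        out = screen_persistent_tfs(self.table(), tfs)
        assert list(out["gene_id"]) == ["tf_up2", "tf_up"]

    def test_gene_down_at_48h_is_excluded(self):
        out = screen_persistent_tfs(self.table(), {"tf_late_down"})
        assert len(out) == 0

    def test_missing_columns_rejected(self):
        with pytest.raises(ValueError, match="missing"):
            screen_persistent_tfs(pd.DataFrame({"gene_id": []}), set())
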