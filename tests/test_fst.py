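import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from stagediv.fst import (
    arm_cutoffs,
    fst_table,
    gene_region_enrichment,
    read_variants,
    snp_fst,
    write_variants,
)
from stagediv.simulate import simulate_snps


def brute_force_hudson(p1, n1, p2, n2):
    """Scalar, literal transcription of the estimator (independent oracle)."""
    num = (p1 - p2) ** 2 - p1 * (1 - p1) / (n1 - 1) - p2 * (1 - p2) / (n2 - 1)
    den = p1 * (1 - p2) + p2 * (1 - p1)
    return num / den if den > 0 else float("nan")


class TestSnpFst:
    def test_hand_value(self):
        assert snp_fst(0.9, 10, 0.1, 10) == pytest.approx(0.62 / 0.82, abs=1e-12)

    def test_fixed_difference_is_one(self):
        assert snp_fst(1.0, 50, 0.0, 50) == pytest.approx(1.0)

    def test_no_differentiation_near_zero(self):
        n = 1000
        val = snp_fst(0.5, n, 0.5, n)
        assert abs(val) < 2 / (n - 1)

    def test_matches_brute_force_on_random_draws(self):
        rng = np.random.default_rng(0)
        p1 = rng.uniform(0, 1, 1000)
        p2 = rng.uniform(0, 1, 1000)
        n1 = rng.integers(2, 200, 1000)
        n2 = rng.integers(2, 200, 1000)
        vec = snp_fst(p1, n1, p2, n2)
        for i in range(1000):
            expected = brute_force_hudson(p1[i], n1[i], p2[i], n2[i])
            if np.isnan(expected):
                assert np.isnan(vec[i])
            else:
                assert vec[i] == pytest.approx(expected, abs=1e-12)

    def test_wc_estimator_agrees_at_high_divergence(self):
        # both estimators approach 1 at fixation
        assert snp_fst(1.0, 100, 0.0, 100, estimator="wc") == pytest.approx(1.0, abs=0.02)

    def test_small_sample_rejected(self):
        with pytest.raises(ValueError, match=">= 2"):
            snp_fst(0.5, 1, 0.5, 10)

    def test_monomorphic_site_nan(self):
        assert np.isnan(snp_fst(0.0, 10, 0.0, 10))


class TestArmCutoffs:
    @staticmethod
    def table_with_fst(fst_values, arm="2L"):
        n = len(fst_values)
        df = pd.DataFrame({
            "arm": arm, "pos": np.arange(1, n + 1),
            "ref_count_pop1": 10, "alt_count_pop1": 10,
            "ref_count_pop2": 10, "alt_count_pop2": 10,
        })
        df["fst"] = fst_values
        return df

    def test_uniform_distribution_quantile(self):
        rng = np.random.default_rng(1)
        snps = self.table_with_fst(rng.uniform(0, 1, 10_000))
        cuts = arm_cutoffs(snps, q=0.95)
        assert cuts.loc["2L", "cutoff"] == pytest.approx(0.95, abs=0.02)

    def test_degenerate_all_equal_no_high_calls(self):
        snps = self.table_with_fst(np.full(100, 0.3))
        cuts = arm_cutoffs(snps)
        assert cuts.loc["2L", "cutoff"] == pytest.approx(0.3)
        assert (snps["fst"] > cuts.loc["2L", "cutoff"]).sum() == 0

    def test_about_five_percent_flagged(self):
        rng = np.random.default_rng(2)
        snps = self.table_with_fst(rng.normal(0.1, 0.05, 10_000))
        cuts = arm_cutoffs(snps)
        frac = (snps["fst"] > cuts.loc["2L", "cutoff"]).mean()
        assert frac == pytest.approx(0.05, abs=0.005)

    def test_sparse_arm_flagged_without_cutoff(self):
        snps = self.table_with_fst(np.linspace(0, 1, 10))
        with pytest.warns(UserWarning, match="usable SNPs"):
            cuts = arm_cutoffs(snps, min_snps=20)
        assert np.isnan(cuts.loc["2L", "cutoff"])


class TestGeneRegionEnrichment:
    @staticmethod
    def enrichment_fixture(observed_high, n_snps=100):
        """A single gene whose span holds n SNPs, observed_high above cutoff."""
        fst = np.full(n_snps, 0.1)
        fst[:observed_high] = 0.9
        snps = pd.DataFrame({
            "arm": "2L", "pos": np.arange(1, n_snps + 1),
            "ref_count_pop1": 10, "alt_count_pop1": 10,
            "ref_count_pop2": 10, "alt_count_pop2": 10, "fst": fst,
        })
        cutoffs = pd.DataFrame({"cutoff": [0.5], "n_snps": [n_snps]},
                               index=pd.Index(["2L"], name="arm"))
        genes = pd.DataFrame({"arm": ["2L"], "start": [1], "end": [n_snps]},
                             index=pd.Index(["gene1"], name="gene"))
        return genes, snps, cutoffs

    def test_expectation_met_chi2_zero(self):
        genes, snps, cutoffs = self.enrichment_fixture(observed_high=5)
        out = gene_region_enrichment(genes, snps, cutoffs)
        assert out.loc["gene1", "chi2"] == pytest.approx(0.0)
        assert out.loc["gene1", "pvalue"] == pytest.approx(1.0)

    def test_hand_chi2_value(self):
        genes, snps, cutoffs = self.enrichment_fixture(observed_high=20)
        out = gene_region_enrichment(genes, snps, cutoffs)
        assert out.loc["gene1", "chi2"] == pytest.approx(47.368, abs=0.01)
        assert out.loc["gene1", "pvalue"] == pytest.approx(5.9e-12, rel=0.05)

    def test_monotone_in_observed_above_expectation(self):
        stats = []
        for O in (6, 10, 15, 20):
            genes, snps, cutoffs = self.enrichment_fixture(observed_high=O)
            out = gene_region_enrichment(genes, snps, cutoffs)
            stats.append(out.loc["gene1", "chi2"])
        assert all(b > a for a, b in zip(stats, stats[1:]))

    def test_sparse_gene_untested(self):
        genes, snps, cutoffs = self.enrichment_fixture(observed_high=2, n_snps=100)
        genes.loc["tiny"] = {"arm": "2L", "start": 1, "end": 5}
        out = gene_region_enrichment(genes, snps, cutoffs, min_snps=20)
        assert not out.loc["tiny", "tested"]
        assert not out.loc["tiny", "enriched"]

    def test_fourth_chromosome_excluded(self):
        genes, snps, cutoffs = self.enrichment_fixture(observed_high=20)
        genes.loc["on4"] = {"arm": "4", "start": 1, "end": 100}
        out = gene_region_enrichment(genes, snps, cutoffs)
        assert not out.loc["on4", "tested"]

    def test_planted_hot_genes_detected_end_to_end(self):
        hot = [(f"hot{i}", "2L", 1 + i * 200_000, 100_000 + i * 200_000)
               for i in range(10)]
        snps, hot_table = simulate_snps(10_000, arms=("2L",), hot_genes=hot,
                                        fst_base=0.05, fst_hot=0.4, seed=3,
                                        arm_length=25_000_000)
        ft = fst_table(snps)
        cuts = arm_cutoffs(ft)
        genes = hot_table.set_index("gene")[["arm", "start", "end"]]
        out = gene_region_enrichment(genes, ft, cuts, min_snps=20)
        assert out["enriched"].mean() >= 0.9


class TestVariantIo:
    def test_tsv_round_trip(self, tmp_path):
        snps, _ = simulate_snps(50, arms=("2L", "X"), seed=4)
        path = tmp_path / "snps.tsv"
        write_variants(snps, path, header_comment="seed=4")
        back = read_variants(path)
        cols = ["arm", "pos", "ref_count_pop1", "alt_count_pop1",
                "ref_count_pop2", "alt_count_pop2"]
        pd.testing.assert_frame_equal(snps[cols].reset_index(drop=True), back[cols])

    def test_minimal_vcf_parsed(self, tmp_path):
        vcf = tmp_path / "tiny.vcf"
        vcf.write_text(
            "##fileformat=VCFv4.2\n"
            '##FILTER=<ID=PASS,Description="ok">\n'
            "##contig=<ID=2L,length=1000>\n"
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ta\tb\tc\td\n"
            "2L\t10\t.\tA\tT\t.\tPASS\t.\tGT\t0/0\t0/1\t1/1\t0/1\n"
            "2L\t20\t.\tG\tC\t.\tPASS\t.\tGT\t0/1\t0/0\t1/1\t1/1\n"
            "2L\t30\t.\tC\tCAT\t.\tPASS\t.\tGT\t0/0\t0/1\t0/0\t0/1\n"  # indel: skipped
            "2L\t40\t.\tT\tA\t.\tPASS\t.\tGT\t./.\t0/1\t0/0\t1/1\n"
        )
        pop_map = {"a": "pop1", "b": "pop1", "c": "pop2", "d": "pop2"}
        out = read_variants(str(vcf), population_map=pop_map)
        assert len(out) == 3  # indel dropped
        assert out.attrs["n_skipped"] == 1
        first = out.iloc[0]
        assert (first["ref_count_pop1"], first["alt_count_pop1"]) == (3, 1)
        assert (first["ref_count_pop2"], first["alt_count_pop2"]) == (1, 3)
        # missing genotypes reduce n
        last = out.iloc[-1]
        assert last["ref_count_pop1"] + last["alt_count_pop1"] == 2

    def test_malformed_tsv_rejected(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("arm\tpos\n2L\t5\n")
        with pytest.raises(ValueError, match="lacks column"):
            read_variants(path)


class TestNullCalibration:
    def test_no_signal_false_flag_rate_controlled(self):
        # homogeneous divergence everywhere: no gene should stand out
        snps, _ = simulate_snps(10_000, arms=("2L",), hot_genes=(),
                                fst_base=0.05, fst_hot=0.4, seed=5,
                                arm_length=25_000_000)
        ft = fst_table(snps)
        cuts = arm_cutoffs(ft)
        genes = pd.DataFrame({
            "arm": "2L",
            "start": 1 + np.arange(200) * 120_000,
            "end": 100_000 + np.arange(200) * 120_000,
        }, index=pd.Index([f"null{i}" for i in range(200)], name="gene"))
        out = gene_region_enrichment(genes, ft, cuts, min_snps=20)
        tested = out[out["tested"]]
        assert len(tested) >= 100
        assert tested["enriched"].mean() <= 0.05
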