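"""Methylation summaries, smoothing, per-CpG testing and DMR assembly."""
import numpy as np
import pandas as pd
import pytest

from triomics.intervals import GeneModel, GenomicInterval
from triomics.methylome import (
    DMR,
    DMRParams,
    annotate_dmrs,
    call_dmrs,
    call_dmrs_two_group,
    estimate_dispersion,
    global_methylation,
    metagene_profile,
    percpg_test,
    smooth_methylation,
)


def counts_frame(rows, sample="s1"):
    df = pd.DataFrame(rows, columns=["chrom", "pos", "meth", "total"])
    df["sample"] = sample
    return df


def one_sample_sheet(sample="s1", condition="control"):
    return pd.DataFrame({"sample": [sample], "condition": [condition],
                         "timepoint": ["D0"], "replicate": [1]})


class TestGlobalMethylation:
    def test_weighted_mean(self):
        df = counts_frame([("chr1", 10, 5, 10), ("chr1", 20, 15, 20)])
        assert global_methylation(df) == pytest.approx(20 / 30)

    def test_extremes(self):
        assert global_methylation(counts_frame([("chr1", 1, 8, 8)])) == 1.0
        assert global_methylation(counts_frame([("chr1", 1, 0, 8)])) == 0.0

    def test_region_restriction_and_empty_error(self):
        df = counts_frame([("chr1", 10, 5, 10), ("chr1", 500, 20, 20)])
        region = [GenomicInterval("chr1", 0, 100)]
        assert global_methylation(df, region) == pytest.approx(0.5)
        with pytest.raises(ValueError):
            global_methylation(df, [GenomicInterval("chr2", 0, 100)])

    def test_merged_table_conserves_weighting(self, default_bundle):
        """Pooling samples then averaging equals the direct count-sum ratio."""
        df = default_bundle.meth_counts
        pooled = df.groupby(["chrom", "pos"], as_index=False)[["meth", "total"]].sum()
        pooled["sample"] = "merged"
        assert global_methylation(pooled) == pytest.approx(
            df["meth"].sum() / df["total"].sum())


class TestMetageneProfile:
    def _gene(self, start=10000, end=14000, strand="+"):
        return GeneModel("G1", GenomicInterval("chr1", start, end, strand),
                         strand)

    def test_uniform_methylome_is_flat(self):
        rows = [("chr1", p, 8, 10) for p in range(8000, 16000, 50)]
        prof = metagene_profile(counts_frame(rows), [self._gene()])
        assert np.allclose(prof[~np.isnan(prof)], 0.8)

    def test_step_profile_recovered(self):
        rows = [("chr1", p, (16 if 10000 <= p < 14000 else 4), 20)
                for p in range(8000, 16000, 40)]
        prof = metagene_profile(counts_frame(rows), [self._gene()],
                                flank_bins=10, body_bins=20)
        assert np.allclose(prof[:10], 0.2, atol=0.01)
        assert np.allclose(prof[10:30], 0.8, atol=0.01)
        assert np.allclose(prof[30:], 0.2, atol=0.01)

    def test_minus_strand_orientation(self):
        # methylated only on the 5' (right-hand) flank of a minus-strand gene
        g = self._gene(strand="-")
        rows = [("chr1", p, (20 if p >= 14000 else 0), 20)
                for p in range(8000, 16000, 40)]
        prof = metagene_profile(counts_frame(rows), [g], flank_bins=10,
                                body_bins=20)
        assert np.allclose(prof[:10], 1.0)
        assert np.allclose(prof[10:], 0.0)

    def test_no_genes_rejected(self):
        with pytest.raises(ValueError):
            metagene_profile(counts_frame([("chr1", 1, 1, 2)]), [])


class TestSmoothing:
    def test_isolated_cpg_keeps_own_proportion(self):
        df = counts_frame([("chr1", 1000, 3, 10), ("chr1", 5000, 9, 10)])
        sm = smooth_methylation(df, one_sample_sheet(), "control", span=200)
        assert np.allclose(sm["p_smooth"], [0.3, 0.9])

    def test_two_close_cpgs_average(self):
        df = counts_frame([("chr1", 100, 0, 10), ("chr1", 150, 10, 10)])
        sm = smooth_methylation(df, one_sample_sheet(), "control", span=200)
        assert np.allclose(sm["p_smooth"], [0.5, 0.5])

    def test_constant_methylome_identity(self):
        df = counts_frame([("chr1", p, 6, 10) for p in range(0, 1000, 30)])
        sm = smooth_methylation(df, one_sample_sheet(), "control", span=200)
        assert np.allclose(sm["p_smooth"], 0.6)

    def test_zero_coverage_cpg_skipped_with_warning(self):
        df = counts_frame([("chr1", 100, 0, 10), ("chr1", 5000, 0, 0)])
        with pytest.warns(UserWarning):
            sm = smooth_methylation(df, one_sample_sheet(), "control")
        assert list(sm["pos"]) == [100]


class TestPerCpGTest:
    def _smooth(self, p, n, pos=100, draw_cov=1):
        # n pooled reads arriving in draws of coverage draw_cov
        return pd.DataFrame({
            "chrom": ["chr1"], "pos": [pos], "p_smooth": [p],
            "win_meth": [p * n], "win_total": [n],
            "win_total_sq": [n * draw_cov],
            "raw_meth": [p * n], "raw_total": [n],
        })

    def test_identical_conditions_p_one(self):
        out = percpg_test(self._smooth(0.4, 100), self._smooth(0.4, 100))
        assert out["p"].iloc[0] > 0.99

    def test_stated_formula_example(self):
        # p_s=0.9, p_c=0.1, n=100 each: z = 0.8 / sqrt(0.25 * 0.02) ~ 11.31
        out = percpg_test(self._smooth(0.9, 100), self._smooth(0.1, 100))
        assert out["z"].iloc[0] == pytest.approx(11.3137, abs=1e-3)
        assert out["p"].iloc[0] < 1e-12

    def test_coverage_one_is_powerless(self):
        out = percpg_test(self._smooth(1.0, 1), self._smooth(0.0, 1))
        assert out["p"].iloc[0] > 0.1

    def test_degenerate_pooled_extremes(self):
        out = percpg_test(self._smooth(0.0, 50), self._smooth(0.0, 50))
        assert out["p"].iloc[0] == 1.0 and out["z"].iloc[0] == 0.0

    def test_overdispersion_deflates_z(self):
        # 10 draws of coverage 20 per condition; phi > 0 must widen the se
        a = self._smooth(0.6, 200, draw_cov=20)
        b = self._smooth(0.4, 200, draw_cov=20)
        plain = percpg_test(a, b, phi=0.0)
        infl = percpg_test(a, b, phi=0.1)
        assert abs(infl["z"].iloc[0]) < abs(plain["z"].iloc[0])
        # coverage-1 draws cannot be over-dispersed: phi must not matter
        c = self._smooth(0.6, 200, draw_cov=1)
        d = self._smooth(0.4, 200, draw_cov=1)
        assert percpg_test(c, d, phi=0.2)["z"].iloc[0] == pytest.approx(
            percpg_test(c, d, phi=0.0)["z"].iloc[0])


class TestDispersionEstimate:
    def test_recovers_simulated_phi(self, default_bundle):
        phi = estimate_dispersion(default_bundle.meth_counts,
                                  default_bundle.meth_samples, "D0")
        assert phi == pytest.approx(default_bundle.cfg.bb_phi, abs=0.02)

    def test_binomial_data_near_zero(self):
        rng = np.random.default_rng(0)
        rows = []
        for rep, name in ((1, "r1"), (2, "r2")):
            for p in range(0, 40000, 40):
                rows.append(("chr1", p, rng.binomial(30, 0.4), 30, name))
        counts = pd.DataFrame(rows, columns=["chrom", "pos", "meth", "total",
                                             "sample"])
        sheet = pd.DataFrame({"sample": ["r1", "r2"],
                              "condition": ["control"] * 2,
                              "timepoint": ["D0"] * 2, "replicate": [1, 2]})
        assert estimate_dispersion(counts, sheet) < 0.01


class TestCallDMRs:
    def _percpg(self, pos, p, diff=0.25, cov=40):
        n = len(pos)
        return pd.DataFrame({
            "chrom": "chr1", "pos": pos,
            "diff_smooth": diff,
            "raw_meth_s": [(0.4 + diff) * cov] * n, "raw_total_s": [cov] * n,
            "raw_meth_c": [0.4 * cov] * n, "raw_total_c": [cov] * n,
            "z": 5.0, "p": p,
        })

    def test_worked_chain_trace(self):
        per = self._percpg([100, 120, 160, 190, 260],
                           [1e-8, 1e-7, 0.5, 1e-9, 1e-6])
        dmrs = call_dmrs(per, DMRParams())
        assert len(dmrs) == 1
        d = dmrs[0]
        assert (d.interval.start, d.interval.end) == (100, 261)
        assert (d.n_cpg, d.n_sig_cpg) == (5, 4)
        assert d.direction == "hyper"

    def test_lone_candidates_fail_min_cg(self):
        per = self._percpg([100, 250], [1e-8, 1e-8])
        assert call_dmrs(per, DMRParams()) == []

    def test_all_null_gives_nothing(self):
        per = self._percpg(list(range(0, 1000, 20)), [1.0] * 50)
        assert call_dmrs(per, DMRParams()) == []

    def test_delta_filter_and_direction(self):
        pos = [100, 130, 160, 190]
        weak = self._percpg(pos, [1e-9] * 4, diff=0.05)
        assert call_dmrs(weak, DMRParams()) == []
        hypo = self._percpg(pos, [1e-9] * 4, diff=-0.3)
        out = call_dmrs(hypo, DMRParams())
        assert len(out) == 1 and out[0].direction == "hypo"

    def test_emitted_dmrs_revalidate_post_hoc(self, default_bundle):
        params = DMRParams()
        dmrs = call_dmrs_two_group(default_bundle.meth_counts,
                                   default_bundle.meth_samples, "D0", params)
        assert dmrs
        for d in dmrs:
            assert d.interval.length >= params.minlen
            assert d.n_cpg >= params.min_cg
            assert d.n_sig_cpg / d.n_cpg >= params.pct_sig
            assert abs(d.mean_diff) > params.delta
            assert d.direction == ("hyper" if d.mean_diff > 0 else "hypo")


class TestAnnotateDMRs:
    def _setup(self):
        g = GeneModel("G1", GenomicInterval("chr1", 10000, 14000, "+"), "+")
        islands = [GenomicInterval("chr1", 9800, 10300)]
        return g, islands

    def _dmr(self, start, end):
        return DMR(GenomicInterval("chr1", start, end), 5, 5, 0.3, "hyper", "D0")

    def test_promoter_dmr(self):
        g, islands = self._setup()
        ann = annotate_dmrs([self._dmr(9900, 10100)], [g], islands)[0]
        assert ann.feature == "promoter"
        assert ann.promoter_gene == "G1"
        assert ann.cpg_ctx == "island"

    def test_gene_desert_dmr(self):
        g, islands = self._setup()
        ann = annotate_dmrs([self._dmr(500000, 500100)], [g], islands)[0]
        assert ann.feature == "intergenic"
        assert ann.cpg_ctx == "open_sea"
        assert ann.promoter_gene is None

    def test_straddling_promoter_edge_counts(self):
        g, islands = self._setup()
        # promoter is [8000, 12000); one-bp overlap suffices
        ann = annotate_dmrs([self._dmr(11999, 12100)], [g], islands)[0]
        assert ann.promoter_gene == "G1"
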