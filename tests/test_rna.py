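"""RNA-target calling, biotype composition and motif presence."""
import numpy as np
import pandas as pd
import pytest

from triomics.intervals import GeneModel, GenomicInterval
from triomics.rna import (
    biotype_fractions,
    call_enriched_targets,
    call_peak_targets,
    combine_target_calls,
    motif_presence_fraction,
    overlap_external,
)


def peak_frame(rows):
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "gene_id",
                                       "adj_p", "sequence"])


class TestPeakTargets:
    def test_two_significant_peaks_and_floor(self):
        peaks = peak_frame([("chr1", 0, 100, "A", 0.01, ""),
                            ("chr1", 200, 300, "A", 0.01, "")])
        out = call_peak_targets(peaks, {"A": 25.0}).set_index("gene_id")
        assert bool(out.loc["A", "is_peak_target"])

    def test_one_peak_not_enough(self):
        peaks = peak_frame([("chr1", 0, 100, "A", 0.001, "")])
        out = call_peak_targets(peaks, {"A": 25.0}).set_index("gene_id")
        assert not bool(out.loc["A", "is_peak_target"])

    def test_low_base_mean_blocks_call(self):
        peaks = peak_frame([("chr1", i * 200, i * 200 + 100, "A", 0.001, "")
                            for i in range(3)])
        out = call_peak_targets(peaks, {"A": 10.0}).set_index("gene_id")
        assert not bool(out.loc["A", "is_peak_target"])

    def test_missing_expression_warns_and_zeroes(self):
        peaks = peak_frame([("chr1", 0, 100, "A", 0.001, ""),
                            ("chr1", 200, 300, "A", 0.001, "")])
        with pytest.warns(UserWarning):
            out = call_peak_targets(peaks, {}).set_index("gene_id")
        assert out.loc["A", "base_mean"] == 0.0
        assert not bool(out.loc["A", "is_peak_target"])

    def test_flags_recheck_from_columns(self, default_bundle):
        from triomics.rna import MIN_BASE_MEAN, MIN_PEAKS
        enr = call_enriched_targets(default_bundle.frip_counts,
                                    default_bundle.frip_samples)
        base_mean = dict(zip(enr["gene_id"], enr["base_mean"]))
        out = call_peak_targets(default_bundle.peaks, base_mean)
        recheck = (out["n_sig_peaks"] >= MIN_PEAKS) & \
            (out["base_mean"] > MIN_BASE_MEAN)
        assert (out["is_peak_target"] == recheck).all()


def sheet(samples):
    return pd.DataFrame(samples, columns=["sample", "status", "block"])


class TestEnrichedTargets:
    def _counts(self, rows, samples):
        return pd.DataFrame(rows, index=pd.Index([f"G{i}" for i in
                                                  range(len(rows))],
                                                 name="gene_id"),
                            columns=[s[0] for s in samples])

    def test_threefold_example_called(self):
        samples = [("IP_1", "IP", "b1"), ("IP_2", "IP", "b2"),
                   ("IP_3", "IP", "b3"), ("in_1", "input", "b1"),
                   ("in_2", "input", "b2"), ("in_3", "input", "b3")]
        rows = [[80, 100, 90, 10, 12, 11]]
        rows += [[50, 52, 51, 50, 49, 51] for _ in range(20)]
        out = call_enriched_targets(self._counts(rows, samples), sheet(samples))
        g0 = out.set_index("gene_id").loc["G0"]
        assert g0["enrichment_lfc"] == pytest.approx(3.0, abs=0.35)
        assert bool(g0["is_enriched_target"])

    def test_identical_groups_not_called(self):
        samples = [("IP_1", "IP", "b1"), ("IP_2", "IP", "b2"),
                   ("in_1", "input", "b1"), ("in_2", "input", "b2")]
        rows = [[60, 70, 60, 70] for _ in range(15)]
        out = call_enriched_targets(self._counts(rows, samples), sheet(samples))
        assert not out["is_enriched_target"].any()

    def test_unpairable_blocks_error(self):
        samples = [("IP_1", "IP", "b1"), ("IP_2", "IP", "b1"),
                   ("in_1", "input", "b2"), ("in_2", "input", "b2")]
        rows = [[60, 70, 60, 70] for _ in range(5)]
        with pytest.raises(ValueError):
            call_enriched_targets(self._counts(rows, samples), sheet(samples),
                                  paired=True)

    def test_recovery_on_defaults(self, default_bundle):
        """Planted LFC 2, NB dispersion 0.1, n=3/group."""
        truth = default_bundle.truth.target_genes
        out = call_enriched_targets(default_bundle.frip_counts,
                                    default_bundle.frip_samples)
        called = set(out.loc[out["is_enriched_target"], "gene_id"])
        assert len(called & truth) / len(truth) >= 0.90
        assert len(called - truth) / max(len(called), 1) <= 0.10

    def test_combination_modes(self):
        pk = pd.DataFrame({"gene_id": ["A", "B"],
                           "is_peak_target": [True, False]})
        en = pd.DataFrame({"gene_id": ["A", "B"],
                           "is_enriched_target": [False, True]})
        assert combine_target_calls(pk, en) == {"A"}
        assert combine_target_calls(pk, en, "union") == {"A", "B"}
        assert combine_target_calls(pk, en, "intersection") == set()


class TestBiotypes:
    def _genes(self, biotypes):
        return [GeneModel(f"G{i}", GenomicInterval("chr1", i * 1000,
                                                   i * 1000 + 500, "+"),
                          "+", bt) for i, bt in enumerate(biotypes)]

    def test_fraction_arithmetic(self):
        genes = self._genes(["protein_coding"] * 19 + ["lncRNA"])
        frac = biotype_fractions([g.gene_id for g in genes], genes)
        assert frac["protein_coding"] == pytest.approx(0.95)
        assert frac["lncRNA"] == pytest.approx(0.05)
        assert sum(frac.values()) == pytest.approx(1.0)

    def test_empty_target_set_rejected(self):
        with pytest.raises(ValueError):
            biotype_fractions([], self._genes(["protein_coding"]))


class TestMotifPresence:
    def test_substring_scan(self):
        peaks = peak_frame([("chr1", 0, 100, "A", 0.01, "AAUGUAUUGAA"),
                            ("chr2", 0, 100, "B", 0.01, "CCCCCCC")])
        assert motif_presence_fraction(peaks) == pytest.approx(0.5)

    def test_motif_itself_and_t_u_equivalence(self):
        peaks = peak_frame([("chr1", 0, 100, "A", 0.01, "TGTATTG")])
        assert motif_presence_fraction(peaks) == 1.0

    def test_empty_inputs_rejected(self):
        with pytest.raises(ValueError):
            motif_presence_fraction(peak_frame([]), "UGUAUUG")
        with pytest.raises(ValueError):
            motif_presence_fraction(
                peak_frame([("chr1", 0, 100, "A", 0.01, "ACGU")]), "")

    def test_planted_rate_recovered_exactly(self):
        rng = np.random.default_rng(4)
        rows = []
        for i in range(200):
            has = i % 10 < 7   # exactly 70% of regions
            seq = "".join(rng.choice(list("ACG"), 40))
            if has:
                seq = seq[:20] + "UGUAUUG" + seq[20:]
            rows.append(("chr1", i * 1000, i * 1000 + 100, f"G{i}", 0.01, seq))
        assert motif_presence_fraction(peak_frame(rows)) == pytest.approx(0.7)

    def test_adjacent_peaks_merge_before_scanning(self):
        # motif split across two abutting peaks appears only after merging
        peaks = peak_frame([("chr1", 0, 50, "A", 0.01, "AAAUGUA"),
                            ("chr1", 50, 100, "A", 0.01, "UUGAAAA")])
        assert motif_presence_fraction(peaks, merge_gap=0) == 1.0


class TestOverlapExternal:
    def test_half_overlap_matches_hypergeometric(self):
        uni = [f"g{i}" for i in range(10)]
        res = overlap_external(uni[:5], uni[2:7], uni)
        assert res.p_value == pytest.approx(0.5)

    def test_sets_outside_universe_rejected(self):
        with pytest.raises(ValueError):
            overlap_external(["x"], ["y"], ["y"])
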