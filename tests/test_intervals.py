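"""Interval algebra, promoter geometry, feature annotation and CpG context."""
import pytest
from hypothesis import given, strategies as st

from triomics.intervals import (
    FeatureLabel,
    GeneModel,
    GenomicInterval,
    annotate_feature,
    cpg_context,
    merge_intervals,
    promoter_of,
    reciprocal_overlap_consensus,
)


def gi(start, end, chrom="chr1", strand="."):
    return GenomicInterval(chrom, start, end, strand)


def gene(start, end, strand, gene_id="G1", chrom="chr1", biotype="protein_coding"):
    return GeneModel(gene_id, GenomicInterval(chrom, start, end, strand),
                     strand, biotype)


class TestGenomicInterval:
    @pytest.mark.parametrize("args", [
        ("chr1", -1, 5), ("chr1", 5, 5), ("chr1", 9, 5), ("", 0, 5),
    ])
    def test_invalid_intervals_rejected(self, args):
        with pytest.raises(ValueError):
            GenomicInterval(*args)

    def test_overlap_arithmetic(self):
        a, b = gi(0, 100), gi(50, 150)
        assert a.overlap_length(b) == 50
        assert a.gap_to(b) == 0
        assert gi(0, 10).gap_to(gi(30, 40)) == 20
        assert gi(0, 10).overlap_length(gi(0, 10, chrom="chr2")) == 0


class TestPromoterOf:
    def test_plus_strand_window(self):
        g = gene(10000, 14000, "+")
        assert promoter_of(g) == gi(8000, 12000, strand="+")

    def test_minus_strand_window_centred_on_last_base(self):
        # TSS = 8999; window [8999-2000, 8999+2000+1) in half-open coordinates
        g = gene(5000, 9000, "-")
        assert promoter_of(g) == gi(6999, 11000, strand="-")

    def test_clipped_at_zero(self):
        g = gene(500, 3000, "+")
        assert promoter_of(g, flank=2000) == gi(0, 2500, strand="+")

    def test_strandless_gene_rejected(self):
        with pytest.raises(ValueError):
            GeneModel("G1", gi(0, 10), ".")


class TestMergeIntervals:
    def test_gap_within_threshold_merges(self):
        assert merge_intervals([gi(0, 50), gi(120, 200)], gap=100) == [gi(0, 200)]

    def test_distant_intervals_untouched(self):
        out = merge_intervals([gi(0, 50), gi(500, 600)], gap=100)
        assert out == [gi(0, 50), gi(500, 600)]

    def test_empty_and_negative_gap(self):
        assert merge_intervals([], gap=10) == []
        with pytest.raises(ValueError):
            merge_intervals([gi(0, 5)], gap=-1)

    @given(st.lists(st.tuples(st.integers(0, 500), st.integers(1, 60)),
                    min_size=1, max_size=40),
           st.integers(0, 50))
    def test_idempotent_and_order_invariant(self, raw, gap):
        ivs = [gi(s, s + l) for s, l in raw]
        once = merge_intervals(ivs, gap)
        assert merge_intervals(once, gap) == once
        assert merge_intervals(list(reversed(ivs)), gap) == once


class TestReciprocalOverlap:
    def test_half_overlap_is_kept_inclusively(self):
        assert reciprocal_overlap_consensus([gi(0, 100)], [gi(50, 150)]) == [gi(0, 100)]

    def test_asymmetric_overlap_dropped(self):
        # 10 bp is 10% of A and <50% of B
        assert reciprocal_overlap_consensus([gi(0, 100)], [gi(90, 300)]) == []

    def test_identity_keeps_everything(self):
        a = [gi(0, 10), gi(50, 80), gi(200, 260, chrom="chr2")]
        assert reciprocal_overlap_consensus(a, list(a)) == sorted(
            a, key=lambda x: (x.chrom, x.start))

    def test_min_frac_validation(self):
        with pytest.raises(ValueError):
            reciprocal_overlap_consensus([], [], min_frac=0.0)
        with pytest.raises(ValueError):
            reciprocal_overlap_consensus([], [], min_frac=1.5)


class TestAnnotateFeature:
    def setup_method(self):
        ga = GeneModel(
            "GA", GenomicInterval("chr1", 10000, 16000, "+"), "+",
            "protein_coding",
            (GenomicInterval("chr1", 10000, 12000, "+"),
             GenomicInterval("chr1", 14000, 16000, "+")),
        )
        self.genes = [ga, gene(30000, 36000, "+", "GB")]

    def test_promoter_beats_intron(self):
        # inside GA's intron (between exons) and also inside GB's promoter
        genes = [gene(26000, 33000, "+", "GA"), gene(30000, 36000, "+", "GB")]
        lab = annotate_feature(gi(28500, 28600), genes)
        assert lab.label == "promoter"
        assert lab.gene_id == "GB"

    def test_downstream_within_3kb(self):
        lab = annotate_feature(gi(17000, 17100), self.genes)
        assert lab.label == "downstream" and lab.gene_id == "GA"

    def test_intergenic_fallback(self):
        lab = annotate_feature(gi(100, 200, chrom="chr9"), self.genes)
        assert lab == FeatureLabel("intergenic")

    def test_exon_beats_intron(self):
        # GA exons cover the first and last thirds
        assert annotate_feature(gi(10100, 10200), self.genes).label in {
            "promoter", "exon"}
        mid = annotate_feature(gi(13000, 13050), self.genes)
        assert mid.label == "intron"

    @given(st.integers(0, 40000))
    def test_exactly_one_label(self, pos):
        lab = annotate_feature(gi(pos, pos + 10), self.genes)
        assert lab.label in {"promoter", "exon", "intron", "downstream",
                             "intergenic"}

    @given(st.integers(5000, 20000))
    def test_promoter_monotone_in_flank(self, pos):
        narrow = annotate_feature(gi(pos, pos + 10), self.genes, flank=1000)
        wide = annotate_feature(gi(pos, pos + 10), self.genes, flank=3000)
        if narrow.label == "promoter":
            assert wide.label == "promoter"


class TestCpGContext:
    islands = [gi(10000, 10500)]

    @pytest.mark.parametrize("pos,expected", [
        (10200, "island"),
        (11000, "shore"),     # 500 bp from the edge
        (13500, "shelf"),     # 3000 bp
        (20000, "open_sea"),
        (12500, "shore"),     # exactly 2000 bp, inclusive
        (14500, "shelf"),     # exactly 4000 bp, inclusive
    ])
    def test_context_by_distance(self, pos, expected):
        assert cpg_context(gi(pos, pos + 1), self.islands) == expected

    @given(st.integers(0, 30000))
    def test_partition(self, pos):
        ctx = cpg_context(gi(pos, pos + 1), self.islands)
        assert ctx in {"island", "shore", "shelf", "open_sea"}
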