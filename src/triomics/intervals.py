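"""Genomic interval algebra and annotation primitives.

Coordinates are 0-based, half-open everywhere in the package: an interval
``[start, end)`` covers ``end - start`` bases.  BED files are read and written
natively in this convention; GTF input is converted on read.
"""
from __future__ import annotations

from bisect import bisect_left
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

VALID_STRANDS = {"+", "-", "."}

#: feature annotation priority, highest first
FEATURE_PRIORITY = ("promoter", "exon", "intron", "downstream", "intergenic")


@dataclass(frozen=True, order=True)
class GenomicInterval:
    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValueError(f"end must exceed start: [{self.start}, {self.end})")
        if self.strand not in VALID_STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def overlap_length(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def gap_to(self, other: "GenomicInterval") -> int:
        """Distance in bp between two intervals on the same chromosome (0 if
        overlapping or adjacent)."""
        if self.chrom != other.chrom:
            raise ValueError("gap_to requires intervals on the same chromosome")
        return max(0, max(self.start, other.start) - min(self.end, other.end))


@dataclass(frozen=True)
class GeneModel:
    gene_id: str
    interval: GenomicInterval
    strand: str
    biotype: str = "protein_coding"
    exons: tuple = ()

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise ValueError("gene strand must be '+' or '-'")
        if not self.exons:
            object.__setattr__(self, "exons", (self.interval,))
        prev_end = None
        for exon in self.exons:
            if exon.chrom != self.interval.chrom:
                raise ValueError("exon chromosome differs from gene")
            if exon.start < self.interval.start or exon.end > self.interval.end:
                raise ValueError("exon outside gene interval")
            if prev_end is not None and exon.start < prev_end:
                raise ValueError("exons must be sorted and non-overlapping")
            prev_end = exon.end

    @property
    def tss(self) -> int:
        """Transcription start site: first base of the gene on its own strand.

        For minus-strand genes this is the last base of the half-open interval,
        i.e. ``end - 1``.
        """
        return self.interval.start if self.strand == "+" else self.interval.end - 1

    @property
    def tes(self) -> int:
        """Transcription end site (last transcribed base)."""
        return self.interval.end - 1 if self.strand == "+" else self.interval.start


@dataclass(frozen=True)
class FeatureLabel:
    label: str
    gene_id: Optional[str] = None
    distance_to_tss: Optional[int] = None

    def __post_init__(self) -> None:
        if self.label not in FEATURE_PRIORITY:
            raise ValueError(f"unknown feature label {self.label!r}")
        if self.label != "intergenic" and self.gene_id is None:
            raise ValueError("gene_id required for non-intergenic labels")


def promoter_of(gene: GeneModel, flank: int = 2000) -> GenomicInterval:
    """Promoter window of ``flank`` bp around the TSS, clipped at position 0.

    Plus strand: ``[TSS - flank, TSS + flank)``.  Minus strand: the TSS is the
    last base of the gene, and the window is centred on that single base,
    ``[TSS - flank, TSS + flank + 1)`` in half-open coordinates.
    """
    if gene.strand not in {"+", "-"}:
        raise ValueError("promoter undefined for strand '.'")
    if flank <= 0:
        raise ValueError("flank must be positive")
    tss = gene.tss
    if gene.strand == "+":
        start, end = tss - flank, tss + flank
    else:
        start, end = tss - flank, tss + flank + 1
    return GenomicInterval(gene.interval.chrom, max(0, start), end, gene.strand)


def merge_intervals(
    intervals: Sequence[GenomicInterval], gap: int = 0
) -> list[GenomicInterval]:
    """Union same-chromosome intervals whose gap is at most ``gap`` bp.

    Output is sorted by (chrom, start) and non-overlapping; the operation is
    idempotent and invariant to input order.  Strand is not considered and is
    reported as '.'.
    """
    if gap < 0:
        raise ValueError("gap must be non-negative")
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for iv in intervals:
        by_chrom.setdefault(iv.chrom, []).append(iv)
    merged: list[GenomicInterval] = []
    for chrom in sorted(by_chrom):
        ivs = sorted(by_chrom[chrom], key=lambda x: (x.start, x.end))
        cur_start, cur_end = ivs[0].start, ivs[0].end
        for iv in ivs[1:]:
            if iv.start - cur_end <= gap:
                cur_end = max(cur_end, iv.end)
            else:
                merged.append(GenomicInterval(chrom, cur_start, cur_end))
                cur_start, cur_end = iv.start, iv.end
        merged.append(GenomicInterval(chrom, cur_start, cur_end))
    return merged


def reciprocal_overlap_consensus(
    rep_a: Sequence[GenomicInterval],
    rep_b: Sequence[GenomicInterval],
    min_frac: float = 0.5,
) -> list[GenomicInterval]:
    """Intervals of ``rep_a`` reproduced in ``rep_b`` by reciprocal overlap.

    An interval of A is kept when some interval of B overlaps at least
    ``min_frac`` (inclusive) of *both* intervals' lengths.  Coordinates of the
    reference replicate A are reported, not the intersection.
    """
    if not (0 < min_frac <= 1):
        raise ValueError("min_frac must be in (0, 1]")
    b_by_chrom: dict[str, list[GenomicInterval]] = {}
    for iv in rep_b:
        b_by_chrom.setdefault(iv.chrom, []).append(iv)
    for ivs in b_by_chrom.values():
        ivs.sort(key=lambda x: (x.start, x.end))
    kept = []
    for a in sorted(rep_a, key=lambda x: (x.chrom, x.start, x.end)):
        bs = b_by_chrom.get(a.chrom, ())
        if not bs:
            continue
        starts = [b.start for b in bs]
        # any overlapping b has b.end > a.start; scan candidates with
        # b.start < a.end and stop via the sorted starts
        hi = bisect_left(starts, a.end)
        for b in bs[:hi]:
            if b.end <= a.start:
                continue
            ov = a.overlap_length(b)
            if ov >= min_frac * a.length and ov >= min_frac * b.length:
                kept.append(a)
                break
    return kept


def _downstream_region(gene: GeneModel, limit: int = 3000) -> Optional[GenomicInterval]:
    """Region up to ``limit`` bp past the 3' end of the gene, strand-aware."""
    if gene.strand == "+":
        start, end = gene.interval.end, gene.interval.end + limit
    else:
        start, end = gene.interval.start - limit, gene.interval.start
    if end <= max(0, start):
        return None
    return GenomicInterval(gene.interval.chrom, max(0, start), end)


def _signed_tss_distance(iv: GenomicInterval, gene: GeneModel) -> int:
    """Signed bp from the gene TSS to the interval midpoint, positive when the
    interval lies downstream of the TSS in the gene's orientation."""
    mid = (iv.start + iv.end) // 2
    d = mid - gene.tss
    return d if gene.strand == "+" else -d


def annotate_feature(
    iv: GenomicInterval,
    genes: Iterable[GeneModel],
    flank: int = 2000,
    downstream_limit: int = 3000,
) -> FeatureLabel:
    """Assign exactly one feature label by priority
    promoter > exon > intron > downstream > intergenic.

    Ties within a priority class are broken by nearest TSS, then lexicographic
    gene id.  Intergenic is the fallback when the interval touches no gene.
    """
    candidates: dict[str, list[GeneModel]] = {k: [] for k in FEATURE_PRIORITY[:-1]}
    for gene in genes:
        if gene.interval.chrom != iv.chrom:
            continue
        if iv.overlaps(promoter_of(gene, flank)):
            candidates["promoter"].append(gene)
        if iv.overlaps(gene.interval):
            if any(iv.overlaps(exon) for exon in gene.exons):
                candidates["exon"].append(gene)
            else:
                candidates["intron"].append(gene)
        ds = _downstream_region(gene, downstream_limit)
        if ds is not None and iv.overlaps(ds):
            candidates["downstream"].append(gene)
    for label in FEATURE_PRIORITY[:-1]:
        if candidates[label]:
            gene = min(
                candidates[label],
                key=lambda g: (abs(_signed_tss_distance(iv, g)), g.gene_id),
            )
            return FeatureLabel(label, gene.gene_id, _signed_tss_distance(iv, gene))
    return FeatureLabel("intergenic")


def cpg_context(
    pos: GenomicInterval,
    islands: Sequence[GenomicInterval],
    shore_bp: int = 2000,
    shelf_bp: int = 4000,
) -> str:
    """CpG context of a position relative to CpG islands.

    ``island`` when overlapping one; ``shore`` within ``shore_bp`` of an island
    edge; ``shelf`` within ``(shore_bp, shelf_bp]``; otherwise ``open_sea``.
    The standard 2 kb / 2-4 kb flank distances are the defaults.
    """
    best = None
    for isl in islands:
        if isl.chrom != pos.chrom:
            continue
        if pos.overlaps(isl):
            return "island"
        d = pos.gap_to(isl)
        best = d if best is None else min(best, d)
    if best is not None and best <= shore_bp:
        return "shore"
    if best is not None and best <= shelf_bp:
        return "shelf"
    return "open_sea"
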