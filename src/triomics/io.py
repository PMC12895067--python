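"""Readers and writers for the plain-text formats used across the pipeline.

Everything is tab-separated text.  BED is consumed/emitted natively in 0-based
half-open coordinates; GTF (1-based, inclusive) is converted on read.  The
per-sample CpG count files follow the Bismark coverage dialect
(chrom, start, end, methylation%, count_methylated, count_unmethylated) with
0-based half-open positions.
"""
from __future__ import annotations

import csv
from typing import Iterable, Sequence

import pandas as pd

from .intervals import GeneModel, GenomicInterval


# ---------------------------------------------------------------- BED

def read_bed(path) -> list[GenomicInterval]:
    """Read BED3/BED6 (no header).  Columns beyond the sixth are ignored."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            strand = parts[5] if len(parts) >= 6 else "."
            out.append(GenomicInterval(parts[0], int(parts[1]), int(parts[2]), strand))
    return out


def write_bed(intervals: Sequence[GenomicInterval], path, names=None, scores=None) -> None:
    """Write BED3 (or BED6 when names/scores are provided)."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        for i, iv in enumerate(intervals):
            if names is None and scores is None:
                w.writerow([iv.chrom, iv.start, iv.end])
            else:
                name = names[i] if names is not None else f"region_{i}"
                score = scores[i] if scores is not None else 0
                w.writerow([iv.chrom, iv.start, iv.end, name, score, iv.strand])


# ---------------------------------------------------------------- gene models

GENE_TABLE_COLUMNS = ["gene_id", "chrom", "start", "end", "strand", "biotype"]


def write_gene_table(genes: Sequence[GeneModel], path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(GENE_TABLE_COLUMNS)
        for g in genes:
            w.writerow(
                [g.gene_id, g.interval.chrom, g.interval.start, g.interval.end,
                 g.strand, g.biotype]
            )


def read_gene_table(path) -> list[GeneModel]:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    genes = []
    for row in df.itertuples(index=False):
        iv = GenomicInterval(row.chrom, int(row.start), int(row.end), row.strand)
        genes.append(GeneModel(row.gene_id, iv, row.strand, row.biotype))
    return genes


def _parse_gtf_attributes(field: str) -> dict:
    attrs = {}
    for item in field.strip().split(";"):
        item = item.strip()
        if not item:
            continue
        key, _, value = item.partition(" ")
        attrs[key] = value.strip().strip('"')
    return attrs


def read_gtf_genes(path) -> list[GeneModel]:
    """Read a GTF subset: ``gene`` and ``exon`` features with ``gene_id`` and
    optional ``gene_biotype`` attributes.  1-based inclusive coordinates are
    converted to 0-based half-open."""
    gene_rows: dict[str, dict] = {}
    exon_rows: dict[str, list[GenomicInterval]] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            chrom, feature, start, end, strand = f[0], f[2], int(f[3]), int(f[4]), f[6]
            attrs = _parse_gtf_attributes(f[8])
            gid = attrs["gene_id"]
            iv = GenomicInterval(chrom, start - 1, end, strand)
            if feature == "gene":
                gene_rows[gid] = {
                    "interval": iv,
                    "strand": strand,
                    "biotype": attrs.get("gene_biotype", "other"),
                }
            elif feature == "exon":
                exon_rows.setdefault(gid, []).append(iv)
    genes = []
    for gid, info in gene_rows.items():
        exons = tuple(sorted(exon_rows.get(gid, []), key=lambda e: e.start))
        genes.append(
            GeneModel(gid, info["interval"], info["strand"], info["biotype"], exons)
        )
    return genes


# ---------------------------------------------------------------- CpG counts

def write_bismark_cov(df: pd.DataFrame, path) -> None:
    """Write one sample's CpG counts in the Bismark-coverage dialect.

    Expects columns chrom, pos, meth, total; emits
    chrom / start / end / methylation% / count_methylated / count_unmethylated.
    """
    out = pd.DataFrame(
        {
            "chrom": df["chrom"],
            "start": df["pos"],
            "end": df["pos"] + 1,
            "pct": (100.0 * df["meth"] / df["total"].where(df["total"] > 0)).round(6),
            "meth": df["meth"],
            "unmeth": df["total"] - df["meth"],
        }
    )
    out.to_csv(path, sep="\t", header=False, index=False)


def read_bismark_cov(path, sample: str | None = None) -> pd.DataFrame:
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        names=["chrom", "start", "end", "pct", "meth", "unmeth"],
        dtype={"chrom": str},
    )
    out = pd.DataFrame(
        {
            "chrom": df["chrom"],
            "pos": df["start"].astype(int),
            "meth": df["meth"].astype(int),
            "total": (df["meth"] + df["unmeth"]).astype(int),
        }
    )
    if sample is not None:
        out["sample"] = sample
    return out


# ---------------------------------------------------------------- gene lists

def read_gene_list(path) -> list[str]:
    """One identifier per line; blank lines and '#' comments ignored."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                out.append(line)
    return out


def write_gene_list(ids: Iterable[str], path) -> None:
    with open(path, "w") as fh:
        for gid in ids:
            fh.write(f"{gid}\n")
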