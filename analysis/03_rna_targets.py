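#!/usr/bin/env python
"""Call RNA targets from peak evidence and IP/input count enrichment.

Reports both target notions (>= 2 significant peaks with an expression
floor; IP-over-input log2FC > 1 at FDR < .05), the biotype composition of
the peak-based targets, and the binding-motif presence fraction among
merged peak regions.
"""
import argparse
from pathlib import Path

import pandas as pd

from triomics.io import read_gene_table
from triomics.rna import (biotype_fractions, call_enriched_targets,
                          call_peak_targets, motif_presence_fraction)


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--data", type=Path, default=Path("results/sim"))
    ap.add_argument("--outdir", type=Path, default=Path("results/rna"))
    args = ap.parse_args()
    args.outdir.mkdir(parents=True, exist_ok=True)

    peaks = pd.read_csv(args.data / "frip_peaks.tsv", sep="\t",
                        dtype={"chrom": str})
    counts = pd.read_csv(args.data / "frip_counts.tsv", sep="\t", index_col=0)
    samples = pd.read_csv(args.data / "frip_samples.tsv", sep="\t")
    genes = read_gene_table(args.data / "genes.tsv")

    enr = call_enriched_targets(counts, samples)
    base_mean = dict(zip(enr["gene_id"], enr["base_mean"]))
    pk = call_peak_targets(peaks, base_mean)
    pk.to_csv(args.outdir / "peak_targets.tsv", sep="\t", index=False)
    enr.to_csv(args.outdir / "enriched_targets.tsv", sep="\t", index=False)

    peak_targets = set(pk.loc[pk["is_peak_target"], "gene_id"])
    enriched = set(enr.loc[enr["is_enriched_target"], "gene_id"])
    print(f"{len(peak_targets)} peak-based targets "
          f"(>=2 significant peaks, baseMean > 20)")
    print(f"{len(enriched)} enrichment-based targets "
          f"(log2FC > 1, FDR < .05, baseMean > 20); "
          f"overlap {len(peak_targets & enriched)}")

    frac = biotype_fractions(peak_targets, genes)
    pd.DataFrame(sorted(frac.items()), columns=["biotype", "fraction"]).to_csv(
        args.outdir / "biotype_fractions.tsv", sep="\t", index=False)
    print("biotype fractions:",
          ", ".join(f"{k} {v:.1%}" for k, v in sorted(frac.items())))

    target_peaks = peaks[peaks["gene_id"].isin(peak_targets)]
    motif = motif_presence_fraction(target_peaks)
    print(f"UGUAUUG motif present in {motif:.1%} of merged target peak regions")
    print(f"wrote {args.outdir}/")


if __name__ == "__main__":
    main()
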