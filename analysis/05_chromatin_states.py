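#!/usr/bin/env python
"""Assign promoter chromatin states from replicate histone-mark peaks and
overlay promoter DMRs on them.

Builds reproducible consensus peaks (reciprocal >= 50% overlap between
replicates) for H3K4me3 and H3K27me3, classifies each promoter as active /
bivalent / repressed / quiescent, and reports how promoter DMRs distribute
over those states by methylation direction.
"""
import argparse
from pathlib import Path

import pandas as pd

from triomics.chromatin import (consensus_marks, promoter_state,
                                state_overlap_fractions)
from triomics.intervals import promoter_of
from triomics.io import read_bed, read_gene_table, write_bed


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--data", type=Path, default=Path("results/sim"))
    ap.add_argument("--dmrs", type=Path, default=Path("results/methylome"))
    ap.add_argument("--outdir", type=Path, default=Path("results/chromatin"))
    args = ap.parse_args()
    args.outdir.mkdir(parents=True, exist_ok=True)

    genes = read_gene_table(args.data / "genes.tsv")
    reps = {}
    for mark in ("H3K4me3", "H3K27me3"):
        reps[mark] = [read_bed(args.data / "chromatin" / f"{mark}_rep{r}.bed")
                      for r in (1, 2)]
    cons = consensus_marks(reps["H3K4me3"], reps["H3K27me3"])
    for mark, peaks in cons.items():
        write_bed(peaks, args.outdir / f"{mark}_consensus.bed")
        n_rep = len(reps[mark][0])
        print(f"{mark}: {n_rep} replicate-1 peaks -> {len(peaks)} reproducible")

    promoters = {g.gene_id: promoter_of(g) for g in genes}
    states = promoter_state(promoters, cons["H3K4me3"], cons["H3K27me3"], "D0")
    states.to_csv(args.outdir / "promoter_states.tsv", sep="\t", index=False)
    print("promoter states:", states["state"].value_counts().to_dict())

    dmr_path = args.dmrs / "dmrs_D0.tsv"
    if dmr_path.exists():
        dmrs = pd.read_csv(dmr_path, sep="\t")
        prom_dmrs = dmrs[dmrs["promoter_gene"].notna()]
        if len(prom_dmrs):
            overlay = state_overlap_fractions(prom_dmrs, states)
            overlay.to_csv(args.outdir / "dmr_state_overlay.tsv", sep="\t",
                           index=False)
            print(overlay.pivot(index="direction", columns="state",
                                values="fraction").round(3).to_string())
    print(f"wrote {args.outdir}/")


if __name__ == "__main__":
    main()
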