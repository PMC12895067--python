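#!/usr/bin/env python
"""Call and annotate differentially methylated regions per time point.

Reports global methylation per condition, calls DMRs (silenced vs control)
at D0 and D7 with the standard parameter surface, annotates them to genomic
features / CpG context / promoters, and classifies promoter methylation
dynamics between the two time points.
"""
import argparse
from pathlib import Path

import pandas as pd

from triomics.chromatin import classify_dynamics, promoter_direction_map
from triomics.io import read_bed, read_bismark_cov, read_gene_table
from triomics.methylome import (DMRParams, annotate_dmrs, call_dmrs_two_group,
                                dmrs_to_frame, global_methylation,
                                metagene_profile)


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--data", type=Path, default=Path("results/sim"))
    ap.add_argument("--outdir", type=Path, default=Path("results/methylome"))
    args = ap.parse_args()
    args.outdir.mkdir(parents=True, exist_ok=True)

    samples = pd.read_csv(args.data / "meth_samples.tsv", sep="\t")
    counts = pd.concat(
        [read_bismark_cov(args.data / "cpg" / f"{s}.cov", s)
         for s in samples["sample"]], ignore_index=True)
    genes = read_gene_table(args.data / "genes.tsv")
    islands = read_bed(args.data / "cpg_islands.bed")

    for (cond, tp), grp in samples.groupby(["condition", "timepoint"]):
        sub = counts[counts["sample"].isin(grp["sample"])]
        print(f"global CpG methylation {cond} {tp}: "
              f"{global_methylation(sub):.3f}")

    params = DMRParams()
    dirmaps = {}
    for tp in ("D0", "D7"):
        dmrs = call_dmrs_two_group(counts, samples, tp, params)
        frame = dmrs_to_frame(annotate_dmrs(dmrs, genes, islands))
        frame.to_csv(args.outdir / f"dmrs_{tp}.tsv", sep="\t", index=False)
        n_prom = frame["promoter_gene"].notna().sum()
        by_dir = frame["direction"].value_counts().to_dict()
        print(f"  {tp}: {len(frame)} DMRs ({by_dir}), "
              f"{n_prom} promoter-associated")
        dirmaps[tp] = promoter_direction_map(frame)

    dynamics = classify_dynamics(dirmaps["D0"], dirmaps["D7"])
    dynamics.to_csv(args.outdir / "promoter_dynamics.tsv", sep="\t",
                    index=False)
    print("promoter dynamics:",
          dynamics["dynamics_class"].value_counts().to_dict())

    # gene-body metagene profile per condition at D7
    rows = []
    for cond in ("control", "silenced"):
        names = samples.loc[(samples["condition"] == cond)
                            & (samples["timepoint"] == "D7"), "sample"]
        prof = metagene_profile(counts[counts["sample"].isin(names)], genes)
        rows.append(pd.Series(prof, name=cond))
    pd.concat(rows, axis=1).rename_axis("bin").to_csv(
        args.outdir / "metagene_profile_D7.tsv", sep="\t")
    print(f"wrote {args.outdir}/")


if __name__ == "__main__":
    main()
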