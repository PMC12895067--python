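"""Promoter chromatin states from replicate histone-mark peaks, DMR-state
overlay, and DMR temporal-dynamics classification.

States follow the 2x2 table of H3K4me3/H3K27me3 promoter overlap: ``active``
(H3K4me3 only), ``bivalent`` (both), ``repressed`` (H3K27me3 only),
``quiescent`` (neither).  Marks come from the reproducible-peak consensus of
two replicates (reciprocal >= 50% overlap).
"""
from __future__ import annotations

import warnings
from typing import Mapping, Optional, Sequence

import pandas as pd

from .intervals import GenomicInterval, reciprocal_overlap_consensus

DYNAMICS_TABLE = {
    ("hypo", "hypo"): "stable_hypo",
    ("hyper", "hyper"): "stable_hyper",
    ("hypo", "hyper"): "hypo_to_hyper",
    ("hyper", "hypo"): "hyper_to_hypo",
    ("hypo", "none"): "d0_only_hypo",
    ("hyper", "none"): "d0_only_hyper",
    ("none", "hypo"): "d7_only_hypo",
    ("none", "hyper"): "d7_only_hyper",
    ("none", "none"): "none",
}

STATES = ("active", "bivalent", "repressed", "quiescent")


def consensus_marks(k4_reps: Sequence[Sequence[GenomicInterval]],
                    k27_reps: Sequence[Sequence[GenomicInterval]],
                    min_frac: float = 0.5) -> dict:
    """Reproducible peaks per mark from two replicates each."""
    if len(k4_reps) < 2 or len(k27_reps) < 2:
        raise ValueError("need two replicates per mark")
    return {
        "H3K4me3": reciprocal_overlap_consensus(k4_reps[0], k4_reps[1], min_frac),
        "H3K27me3": reciprocal_overlap_consensus(k27_reps[0], k27_reps[1], min_frac),
    }


def _overlaps_any(iv: GenomicInterval, peaks: Sequence[GenomicInterval],
                  min_overlap_bp: int) -> bool:
    return any(iv.overlap_length(p) >= min_overlap_bp for p in peaks)


def promoter_state(promoters: Mapping[str, GenomicInterval],
                   k4_consensus: Sequence[GenomicInterval],
                   k27_consensus: Sequence[GenomicInterval],
                   timepoint: Optional[str] = None,
                   min_overlap_bp: int = 1) -> pd.DataFrame:
    """Assign exactly one chromatin state per promoter from the 2x2
    mark-overlap table (>= ``min_overlap_bp`` bp counts as overlap)."""
    rows = []
    for gene_id in sorted(promoters):
        prom = promoters[gene_id]
        k4 = _overlaps_any(prom, k4_consensus, min_overlap_bp)
        k27 = _overlaps_any(prom, k27_consensus, min_overlap_bp)
        state = ("bivalent" if k4 and k27 else
                 "active" if k4 else
                 "repressed" if k27 else "quiescent")
        rows.append((gene_id, state, timepoint))
    return pd.DataFrame(rows, columns=["gene_id", "state", "timepoint"])


def promoter_direction_map(annotated_dmrs: pd.DataFrame) -> dict:
    """Per-gene promoter DMR direction for one time point.

    With several DMRs on one promoter the direction of the largest
    ``|mean_diff|`` wins; an exact-magnitude conflict yields 'none' with a
    warning.
    """
    out: dict[str, str] = {}
    sub = annotated_dmrs[annotated_dmrs["promoter_gene"].notna()]
    for gene, grp in sub.groupby("promoter_gene"):
        mags = grp["mean_diff"].abs()
        best = mags.max()
        winners = set(grp.loc[mags == best, "direction"])
        if len(winners) > 1:
            warnings.warn(f"conflicting equal-magnitude DMRs at {gene}; "
                          "direction set to none")
            continue
        out[gene] = winners.pop()
    return out


def classify_dynamics(d0_directions: Mapping[str, str],
                      d7_directions: Mapping[str, str]) -> pd.DataFrame:
    """Map the per-promoter D0/D7 direction pair onto the nine dynamics
    classes (stable, switching, single-time-point)."""
    genes = sorted(set(d0_directions) | set(d7_directions))
    rows = []
    for g in genes:
        d0 = d0_directions.get(g, "none")
        d7 = d7_directions.get(g, "none")
        rows.append((g, d0, d7, DYNAMICS_TABLE[(d0, d7)]))
    return pd.DataFrame(rows, columns=["gene_id", "d0_direction",
                                       "d7_direction", "dynamics_class"])


def state_overlap_fractions(promoter_dmrs: pd.DataFrame,
                            states: pd.DataFrame) -> pd.DataFrame:
    """Fractions of promoter DMRs per chromatin state, split by methylation
    direction; fractions sum to 1 within each direction."""
    if promoter_dmrs.empty:
        raise ValueError("empty promoter DMR set")
    state_of = states.set_index("gene_id")["state"]
    rows = []
    for direction, grp in promoter_dmrs.groupby("direction"):
        assigned = grp["promoter_gene"].map(state_of)
        n = len(grp)
        for state in STATES:
            rows.append((direction, state, float((assigned == state).sum()) / n))
    return pd.DataFrame(rows, columns=["direction", "state", "fraction"])
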