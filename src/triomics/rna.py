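"""RNA-target calling from peak evidence and IP/input count enrichment,
biotype composition, and the single-motif presence statistic.

Two target notions are exposed, mirroring how RIP/fRIP experiments are read:

* peak-based: a gene with at least ``min_peaks`` significant peaks
  (adjusted P < .05) and an expression floor (baseMean > 20);
* enrichment-based: IP counts elevated over input (log2FC > 1, adjusted
  P < .05, baseMean > 20), via a simplified negative-binomial Wald test with
  a genome-wide common dispersion instead of a full GLM fit.
"""
from __future__ import annotations

import warnings
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .intervals import GeneModel
from .stats import EnrichmentResult, bh_adjust, hypergeom_enrich, median_of_ratios

PEAK_ADJ_P = 0.05
MIN_PEAKS = 2
MIN_BASE_MEAN = 20.0
ENRICH_LFC = 1.0
ENRICH_ADJ_P = 0.05

BIOTYPE_CLASSES = ("protein_coding", "lncRNA", "snoRNA", "other")


def call_peak_targets(peaks: pd.DataFrame, expression_ref: Mapping[str, float],
                      min_peaks: int = MIN_PEAKS,
                      adj_p_threshold: float = PEAK_ADJ_P,
                      min_base_mean: float = MIN_BASE_MEAN) -> pd.DataFrame:
    """Per-gene peak-evidence target calls.

    ``peaks`` needs columns gene_id and adj_p; ``expression_ref`` maps gene to
    baseMean.  Genes with peaks but no expression entry are assigned
    baseMean 0 with a warning.
    """
    sig = peaks[peaks["adj_p"] < adj_p_threshold]
    n_sig = sig.groupby("gene_id").size()
    all_genes = sorted(set(peaks["gene_id"]) | set(expression_ref))
    missing = [g for g in set(peaks["gene_id"]) if g not in expression_ref]
    if missing:
        warnings.warn(f"{len(missing)} peak genes missing from the expression "
                      "reference; baseMean set to 0")
    out = pd.DataFrame({"gene_id": all_genes})
    out["n_sig_peaks"] = out["gene_id"].map(n_sig).fillna(0).astype(int)
    out["base_mean"] = out["gene_id"].map(expression_ref).fillna(0.0)
    out["is_peak_target"] = (out["n_sig_peaks"] >= min_peaks) & \
                            (out["base_mean"] > min_base_mean)
    return out


def estimate_nb_dispersion(norm_counts: pd.DataFrame,
                           groups: Mapping[str, Sequence[str]],
                           min_mean: float = 5.0) -> float:
    """Genome-wide common negative-binomial dispersion by the method of
    moments: pooled (variance - mean) / mean^2 over genes within groups."""
    num = 0.0
    den = 0.0
    for cols in groups.values():
        sub = norm_counts[list(cols)].to_numpy(dtype=float)
        if sub.shape[1] < 2:
            continue
        m = sub.mean(axis=1)
        v = sub.var(axis=1, ddof=1)
        ok = m > min_mean
        num += float(np.sum(v[ok] - m[ok]))
        den += float(np.sum(m[ok] ** 2))
    if den <= 0:
        return 0.0
    return float(np.clip(num / den, 0.0, 5.0))


def call_enriched_targets(counts: pd.DataFrame, sample_sheet: pd.DataFrame,
                          paired: Optional[bool] = None,
                          lfc_threshold: float = ENRICH_LFC,
                          adj_p_threshold: float = ENRICH_ADJ_P,
                          min_base_mean: float = MIN_BASE_MEAN) -> pd.DataFrame:
    """IP-over-input enrichment calls from a gene x sample count matrix.

    Counts are normalized by median-of-ratios size factors; baseMean is the
    mean normalized count over all samples.  The log2 IP/input ratio is
    tested with a Wald z using a delta-method variance
    (1/mu_IP + 1/mu_input + 2 alpha) / ln(2)^2 / n, with alpha a genome-wide
    common NB dispersion estimated from within-group variability (which also
    absorbs block-to-block scatter in the unpaired mode).  When every block
    pairs one IP with one input sample the ratio is formed per block (block
    effects cancel); otherwise group means are compared.  BH across genes;
    all thresholds strict.
    """
    sheet = sample_sheet.set_index("sample")
    ip_cols = list(sheet.index[sheet["status"] == "IP"])
    in_cols = list(sheet.index[sheet["status"] == "input"])
    if len(ip_cols) < 2 or len(in_cols) < 2:
        raise ValueError("need >= 2 IP and >= 2 input samples")
    # size factors referenced to the input samples: the input fraction
    # measures the underlying transcriptome, so planted IP enrichment of a
    # sizeable gene minority cannot leak into the normalization
    ordered = ip_cols + in_cols
    ref_idx = [ordered.index(c) for c in in_cols]
    factors = median_of_ratios(counts[ordered], reference_cols=ref_idx)
    norm = counts[ordered] / factors
    base_mean = norm.mean(axis=1)
    alpha = estimate_nb_dispersion(norm, {"IP": ip_cols, "input": in_cols})

    has_blocks = "block" in sheet.columns and sheet["block"].notna().all()
    if paired is None:
        paired = has_blocks
    pseudo = 0.5
    ln2sq = np.log(2.0) ** 2
    mu_ip = np.maximum(norm[ip_cols].mean(axis=1).to_numpy(), pseudo)
    mu_in = np.maximum(norm[in_cols].mean(axis=1).to_numpy(), pseudo)
    if paired:
        if not has_blocks:
            raise ValueError("paired mode requires block labels")
        pairs = []
        for block, grp in sheet.groupby("block"):
            ips = grp.index[grp["status"] == "IP"]
            ins = grp.index[grp["status"] == "input"]
            if len(ips) != 1 or len(ins) != 1:
                raise ValueError(f"block {block!r} is not a 1 IP + 1 input pair")
            pairs.append((ips[0], ins[0]))
        ratios = np.column_stack([
            np.log2((norm[ip].to_numpy() + pseudo) / (norm[inp].to_numpy() + pseudo))
            for ip, inp in pairs
        ])
        lfc = ratios.mean(axis=1)
        var = (1.0 / mu_ip + 1.0 / mu_in + 2.0 * alpha) / ln2sq / ratios.shape[1]
    else:
        lfc = np.log2((mu_ip + pseudo) / (mu_in + pseudo))
        var = ((1.0 / mu_ip + alpha) / len(ip_cols)
               + (1.0 / mu_in + alpha) / len(in_cols)) / ln2sq
    z = lfc / np.sqrt(var)
    pvals = 2.0 * sps.norm.sf(np.abs(z))
    out = pd.DataFrame({
        "gene_id": counts.index,
        "base_mean": base_mean.to_numpy(),
        "enrichment_lfc": lfc,
        "p_value": pvals,
    })
    out["enrichment_adj_p"] = bh_adjust(out["p_value"])
    out["is_enriched_target"] = (
        (out["enrichment_lfc"] > lfc_threshold)
        & (out["enrichment_adj_p"] < adj_p_threshold)
        & (out["base_mean"] > min_base_mean)
    )
    return out.reset_index(drop=True)


def combine_target_calls(peak_calls: pd.DataFrame, enrich_calls: pd.DataFrame,
                         mode: str = "peak-only") -> set:
    """Combine the two target notions: 'peak-only' (default), 'union' or
    'intersection'."""
    peak = set(peak_calls.loc[peak_calls["is_peak_target"], "gene_id"])
    enr = set(enrich_calls.loc[enrich_calls["is_enriched_target"], "gene_id"])
    if mode == "peak-only":
        return peak
    if mode == "union":
        return peak | enr
    if mode == "intersection":
        return peak & enr
    raise ValueError(f"unknown combination mode {mode!r}")


def biotype_fractions(target_ids: Iterable[str],
                      genes: Sequence[GeneModel]) -> dict:
    """Fractions of target genes per RNA biotype; unknown biotypes count as
    'other'.  Fractions sum to 1 over a non-empty target set."""
    targets = set(target_ids)
    if not targets:
        raise ValueError("empty target set")
    by_id = {g.gene_id: g.biotype for g in genes}
    counts = dict.fromkeys(BIOTYPE_CLASSES, 0)
    for t in targets:
        bt = by_id.get(t, "other")
        counts[bt if bt in BIOTYPE_CLASSES else "other"] += 1
    total = sum(counts.values())
    return {k: v / total for k, v in counts.items()}


def motif_presence_fraction(peaks: pd.DataFrame, motif: str = "UGUAUUG",
                            merge_gap: int = 0) -> float:
    """Fraction of (gap-merged) peak regions containing >= 1 exact motif match.

    T and U are treated as equivalent; scanning is single-strand,
    presence/absence per region.  Peaks whose intervals lie within
    ``merge_gap`` bp on the same chromosome are collapsed and their sequences
    concatenated in coordinate order.
    """
    if not motif:
        raise ValueError("empty motif")
    if "sequence" not in peaks.columns or peaks.empty:
        raise ValueError("no peak sequences available")
    motif_u = motif.upper().replace("T", "U")
    df = peaks.sort_values(["chrom", "start"], kind="mergesort")
    regions = []
    cur = None
    for row in df.itertuples(index=False):
        seq = str(row.sequence).upper().replace("T", "U")
        if cur is not None and row.chrom == cur[0] and row.start - cur[2] <= merge_gap:
            cur = (cur[0], cur[1], max(cur[2], row.end), cur[3] + seq)
        else:
            if cur is not None:
                regions.append(cur[3])
            cur = (row.chrom, row.start, row.end, seq)
    if cur is not None:
        regions.append(cur[3])
    hits = sum(motif_u in seq for seq in regions)
    return hits / len(regions)


def overlap_external(target_ids: Iterable[str], external_ids: Iterable[str],
                     universe: Iterable[str]) -> EnrichmentResult:
    """Significance of the overlap between the target set and an external
    gene list, as the upper hypergeometric tail (one-sided Fisher)."""
    uni = set(universe)
    targets = set(target_ids)
    ext = set(external_ids)
    if not targets <= uni or not ext <= uni:
        raise ValueError("target and external sets must lie within the universe")
    return hypergeom_enrich(len(targets & ext), len(targets), len(ext), len(uni))
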