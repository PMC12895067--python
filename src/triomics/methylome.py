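"""Methylome analysis: global summaries, gene-body metagene profile, and a
smoothed two-group DMR caller.

The caller exposes the familiar region-assembly parameter surface
(smoothing span, minimum length, minimum CpGs, merge distance, fraction of
significant CpGs, per-CpG p threshold, minimum methylation difference) but
replaces the Bayesian beta-binomial machinery of dedicated WGBS packages with
a documented smoothed two-proportion z-test:

* replicate counts are pooled per condition (two replicates cannot support a
  per-CpG dispersion fit);
* the per-CpG proportion is smoothed with a coverage-weighted mean over a
  window of ``smoothing_span`` bp, and the test's effective sample size is the
  coverage pooled over that same window;
* the binomial variance is inflated by a beta-binomial over-dispersion factor
  ``1 + phi * (c - 1)`` per read-count draw, with ``phi`` estimated from
  replicate disagreement by the method of moments, so the null z statistic is
  approximately standard normal even for over-dispersed counts.

The minimum-difference filter is applied to the raw (unsmoothed)
coverage-weighted mean difference over the region; direction is the sign of
the silenced-minus-control difference, so "hyper" means hypermethylated upon
silencing.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .intervals import GeneModel, GenomicInterval, annotate_feature, cpg_context, promoter_of


@dataclass
class DMRParams:
    smoothing_span: int = 200
    minlen: int = 50
    min_cg: int = 3
    dis_merge: int = 100
    pct_sig: float = 0.5
    p_threshold: float = 1e-5
    delta: float = 0.1

    def validate(self) -> None:
        if min(self.smoothing_span, self.minlen, self.min_cg, self.dis_merge) <= 0:
            raise ValueError("span/minlen/min_cg/dis_merge must be positive")
        if not (0 < self.pct_sig <= 1):
            raise ValueError("pct_sig must lie in (0, 1]")
        if not (0 < self.delta < 1):
            raise ValueError("delta must lie in (0, 1)")
        if not (0 < self.p_threshold < 1):
            raise ValueError("p_threshold must lie in (0, 1)")


@dataclass(frozen=True)
class DMR:
    interval: GenomicInterval
    n_cpg: int
    n_sig_cpg: int
    mean_diff: float
    direction: str
    timepoint: Optional[str] = None


def _pool_condition(counts: pd.DataFrame, samples: pd.DataFrame,
                    condition: str, timepoint: Optional[str]) -> pd.DataFrame:
    sel = samples["condition"] == condition
    if timepoint is not None:
        sel &= samples["timepoint"] == timepoint
    names = set(samples.loc[sel, "sample"])
    if not names:
        raise ValueError(f"no samples for condition={condition!r} "
                         f"timepoint={timepoint!r}")
    sub = counts[counts["sample"].isin(names)].copy()
    sub["total_sq"] = sub["total"].astype(float) ** 2
    pooled = (
        sub.groupby(["chrom", "pos"], as_index=False)[["meth", "total", "total_sq"]]
        .sum()
        .sort_values(["chrom", "pos"], kind="mergesort")
        .reset_index(drop=True)
    )
    return pooled


def global_methylation(counts: pd.DataFrame,
                       regions: Optional[Sequence[GenomicInterval]] = None) -> float:
    """Coverage-weighted mean methylation, sum(meth) / sum(total), optionally
    restricted to CpGs inside ``regions``."""
    sub = counts
    if regions is not None:
        keep = np.zeros(len(counts), dtype=bool)
        pos = counts["pos"].to_numpy()
        chrom = counts["chrom"].to_numpy()
        for r in regions:
            keep |= (chrom == r.chrom) & (pos >= r.start) & (pos < r.end)
        sub = counts[keep]
    total = sub["total"].sum()
    if total <= 0:
        raise ValueError("no covered CpGs in the requested regions")
    return float(sub["meth"].sum() / total)


def metagene_profile(counts: pd.DataFrame, genes: Sequence[GeneModel],
                     flank: int = 2000, body_bins: int = 40,
                     flank_bins: int = 20) -> np.ndarray:
    """Strand-oriented mean methylation profile across gene bodies.

    Fixed-width flank bins cover ``flank`` bp up- and downstream; the body is
    scaled into ``body_bins`` bins.  Per bin and gene the coverage-weighted
    proportion is taken, then averaged across genes (bins without CpGs in a
    gene are skipped).  Returns an array of length
    ``flank_bins + body_bins + flank_bins``, 5' flank first.
    """
    if not genes:
        raise ValueError("no genes supplied")
    nbins = flank_bins + body_bins + flank_bins
    meth_sum = np.zeros((len(genes), nbins))
    tot_sum = np.zeros((len(genes), nbins))
    pos_all = counts["pos"].to_numpy()
    chrom_all = counts["chrom"].to_numpy()
    meth_all = counts["meth"].to_numpy(dtype=float)
    tot_all = counts["total"].to_numpy(dtype=float)
    for gi, g in enumerate(genes):
        lo = g.interval.start - flank
        hi = g.interval.end + flank
        sel = (chrom_all == g.interval.chrom) & (pos_all >= lo) & (pos_all < hi)
        if not np.any(sel):
            continue
        p = pos_all[sel]
        upstream = p < g.interval.start
        downstream = p >= g.interval.end
        body = ~(upstream | downstream)
        bin_idx = np.empty(p.shape, dtype=int)
        bin_idx[upstream] = np.minimum(
            (p[upstream] - lo) * flank_bins // flank, flank_bins - 1
        )
        glen = g.interval.length
        bin_idx[body] = flank_bins + np.minimum(
            (p[body] - g.interval.start) * body_bins // glen, body_bins - 1
        )
        bin_idx[downstream] = flank_bins + body_bins + np.minimum(
            (p[downstream] - g.interval.end) * flank_bins // flank, flank_bins - 1
        )
        np.add.at(meth_sum[gi], bin_idx, meth_all[sel])
        np.add.at(tot_sum[gi], bin_idx, tot_all[sel])
        if g.strand == "-":
            meth_sum[gi] = meth_sum[gi][::-1]
            tot_sum[gi] = tot_sum[gi][::-1]
    with np.errstate(invalid="ignore", divide="ignore"):
        per_gene = np.where(tot_sum > 0, meth_sum / tot_sum, np.nan)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return np.nanmean(per_gene, axis=0)


def smooth_methylation(counts: pd.DataFrame, samples: pd.DataFrame,
                       condition: str, timepoint: Optional[str] = None,
                       span: int = 200) -> pd.DataFrame:
    """Pool replicates of one condition and smooth per-CpG proportions with a
    coverage-weighted mean over ``[pos - span/2, pos + span/2]``.

    Returns one row per covered CpG with the smoothed proportion ``p_smooth``,
    the window-pooled coverage ``win_total`` (the test's effective sample
    size), the window sum of squared per-sample coverages ``win_total_sq``
    (used for the over-dispersion correction), and the raw pooled counts.
    CpGs with zero pooled coverage are skipped with a warning.
    """
    if span <= 0:
        raise ValueError("span must be positive")
    pooled = _pool_condition(counts, samples, condition, timepoint)
    uncovered = pooled["total"] == 0
    if uncovered.any():
        warnings.warn(f"skipping {int(uncovered.sum())} CpGs with zero coverage")
        pooled = pooled[~uncovered].reset_index(drop=True)
    half = span / 2.0
    out = []
    for chrom, grp in pooled.groupby("chrom", sort=True):
        pos = grp["pos"].to_numpy()
        meth = grp["meth"].to_numpy(dtype=float)
        tot = grp["total"].to_numpy(dtype=float)
        tot_sq = grp["total_sq"].to_numpy(dtype=float)
        cm = np.concatenate([[0.0], np.cumsum(meth)])
        ct = np.concatenate([[0.0], np.cumsum(tot)])
        cq = np.concatenate([[0.0], np.cumsum(tot_sq)])
        lo = np.searchsorted(pos, pos - half, side="left")
        hi = np.searchsorted(pos, pos + half, side="right")
        win_meth = cm[hi] - cm[lo]
        win_tot = ct[hi] - ct[lo]
        win_sq = cq[hi] - cq[lo]
        out.append(pd.DataFrame({
            "chrom": chrom,
            "pos": pos.astype(int),
            "p_smooth": win_meth / win_tot,
            "win_meth": win_meth,
            "win_total": win_tot,
            "win_total_sq": win_sq,
            "raw_meth": meth,
            "raw_total": tot,
        }))
    return pd.concat(out, ignore_index=True)


def estimate_dispersion(counts: pd.DataFrame, samples: pd.DataFrame,
                        timepoint: Optional[str] = None,
                        min_total: int = 10) -> float:
    """Method-of-moments beta-binomial over-dispersion from replicate
    disagreement, pooled over conditions and CpGs.

    For a CpG with R replicate draws of coverage c_r and pooled proportion
    p-hat, E[sum_r c_r (p_r - p_hat)^2] = p(1-p) [(R-1) + phi (C - R -
    (sum c^2 - C)/C)] with C = sum c_r.  Summing numerators and denominators
    over CpGs gives a stable single phi for the genome.
    """
    num = 0.0
    den = 0.0
    for condition in samples["condition"].unique():
        sel = samples["condition"] == condition
        if timepoint is not None:
            sel &= samples["timepoint"] == timepoint
        names = set(samples.loc[sel, "sample"])
        sub = counts[counts["sample"].isin(names)]
        piv_m = sub.pivot_table(index=["chrom", "pos"], columns="sample",
                                values="meth", aggfunc="sum")
        piv_t = sub.pivot_table(index=["chrom", "pos"], columns="sample",
                                values="total", aggfunc="sum")
        m = piv_m.to_numpy(dtype=float)
        c = piv_t.to_numpy(dtype=float)
        ok = np.all(c > 0, axis=1) & (c.sum(axis=1) >= min_total)
        m, c = m[ok], c[ok]
        if m.shape[1] < 2 or m.size == 0:
            continue
        R = m.shape[1]
        C = c.sum(axis=1)
        phat = m.sum(axis=1) / C
        pq = phat * (1 - phat)
        S = np.sum(c * (m / c - phat[:, None]) ** 2, axis=1)
        num += float(np.sum(S - pq * (R - 1)))
        den += float(np.sum(pq * (C - R - (np.sum(c ** 2, axis=1) - C) / C)))
    if den <= 0:
        return 0.0
    return float(np.clip(num / den, 0.0, 0.5))


def percpg_test(smooth_s: pd.DataFrame, smooth_c: pd.DataFrame,
                phi: float = 0.0) -> pd.DataFrame:
    """Per-CpG two-sided z-test of smoothed proportions, silenced vs control.

    z = (p_s - p_c) / sqrt(pbar (1 - pbar) (V_s + V_c)) with
    V = [n + phi (sum c^2 - n)] / n^2 for window-pooled coverage n; with
    ``phi = 0`` this is the plain two-proportion z with sample sizes equal to
    the pooled coverages.  pbar in {0, 1} yields z = 0, p = 1.  CpGs covered
    in only one condition are skipped.
    """
    merged = smooth_s.merge(smooth_c, on=["chrom", "pos"],
                            suffixes=("_s", "_c"), how="inner")
    ns = merged["win_total_s"].to_numpy()
    nc = merged["win_total_c"].to_numpy()
    pbar = (merged["win_meth_s"] + merged["win_meth_c"]).to_numpy() / (ns + nc)
    vs = (ns + phi * (merged["win_total_sq_s"].to_numpy() - ns)) / ns ** 2
    vc = (nc + phi * (merged["win_total_sq_c"].to_numpy() - nc)) / nc ** 2
    var = pbar * (1 - pbar) * (vs + vc)
    diff = (merged["p_smooth_s"] - merged["p_smooth_c"]).to_numpy()
    z = np.zeros_like(diff)
    good = var > 0
    z[good] = diff[good] / np.sqrt(var[good])
    p = np.ones_like(diff)
    p[good] = 2.0 * sps.norm.sf(np.abs(z[good]))
    return pd.DataFrame({
        "chrom": merged["chrom"],
        "pos": merged["pos"],
        "diff_smooth": diff,
        "raw_meth_s": merged["raw_meth_s"],
        "raw_total_s": merged["raw_total_s"],
        "raw_meth_c": merged["raw_meth_c"],
        "raw_total_c": merged["raw_total_c"],
        "z": z,
        "p": p,
    })


def call_dmrs(percpg: pd.DataFrame, params: DMRParams = DMRParams(),
              timepoint: Optional[str] = None) -> list[DMR]:
    """Assemble DMRs from per-CpG test results.

    Candidate CpGs (p < p_threshold) are chained while successive candidates
    lie within ``dis_merge`` bp; each chain spans first-to-last candidate
    (every CpG occupies 1 bp, so the half-open span is last - first + 1) and
    adopts every tested CpG inside.  Chains must satisfy the length, CpG
    count, significant-fraction and raw mean-difference filters; direction is
    the sign of the coverage-weighted silenced-minus-control difference.
    """
    params.validate()
    dmrs: list[DMR] = []
    for chrom, grp in percpg.groupby("chrom", sort=True):
        grp = grp.sort_values("pos", kind="mergesort")
        pos = grp["pos"].to_numpy()
        p = grp["p"].to_numpy()
        cand = np.flatnonzero(p < params.p_threshold)
        if cand.size == 0:
            continue
        breaks = np.flatnonzero(np.diff(pos[cand]) > params.dis_merge)
        chains = np.split(cand, breaks + 1)
        ms = grp["raw_meth_s"].to_numpy(dtype=float)
        ts = grp["raw_total_s"].to_numpy(dtype=float)
        mc = grp["raw_meth_c"].to_numpy(dtype=float)
        tc = grp["raw_total_c"].to_numpy(dtype=float)
        for chain in chains:
            start, stop = int(pos[chain[0]]), int(pos[chain[-1]]) + 1
            inside = slice(
                np.searchsorted(pos, start, "left"),
                np.searchsorted(pos, stop, "left"),
            )
            n_cpg = inside.stop - inside.start
            n_sig = int(np.sum(p[inside] < params.p_threshold))
            if stop - start < params.minlen or n_cpg < params.min_cg:
                continue
            if n_sig / n_cpg < params.pct_sig:
                continue
            tot_s, tot_c = ts[inside].sum(), tc[inside].sum()
            if tot_s <= 0 or tot_c <= 0:
                continue
            mean_diff = ms[inside].sum() / tot_s - mc[inside].sum() / tot_c
            if abs(mean_diff) <= params.delta:
                continue
            dmrs.append(DMR(
                GenomicInterval(chrom, start, stop),
                n_cpg, n_sig, float(mean_diff),
                "hyper" if mean_diff > 0 else "hypo",
                timepoint,
            ))
    return dmrs


def call_dmrs_two_group(counts: pd.DataFrame, samples: pd.DataFrame,
                        timepoint: Optional[str] = None,
                        params: DMRParams = DMRParams(),
                        conditions: tuple = ("silenced", "control"),
                        phi: Optional[float] = None) -> list[DMR]:
    """Convenience front-end: smooth both conditions, estimate over-dispersion
    from replicates (unless ``phi`` is given), test, and assemble DMRs."""
    test, cond_ref = conditions
    sm_s = smooth_methylation(counts, samples, test, timepoint,
                              params.smoothing_span)
    sm_c = smooth_methylation(counts, samples, cond_ref, timepoint,
                              params.smoothing_span)
    if phi is None:
        phi = estimate_dispersion(counts, samples, timepoint)
    per = percpg_test(sm_s, sm_c, phi=phi)
    return call_dmrs(per, params, timepoint)


@dataclass(frozen=True)
class AnnotatedDMR:
    dmr: DMR
    feature: str
    feature_gene: Optional[str]
    cpg_ctx: str
    promoter_gene: Optional[str]


def annotate_dmrs(dmrs: Sequence[DMR], genes: Sequence[GeneModel],
                  islands: Sequence[GenomicInterval],
                  flank: int = 2000) -> list[AnnotatedDMR]:
    """Attach feature label, CpG context and (>= 1 bp overlap) promoter gene.

    When a DMR overlaps several promoters the gene with the nearest TSS wins.
    """
    out = []
    promoters = [(g, promoter_of(g, flank)) for g in genes]
    for dmr in dmrs:
        label = annotate_feature(dmr.interval, genes, flank)
        ctx = cpg_context(dmr.interval, islands)
        hits = [g for g, prom in promoters if dmr.interval.overlaps(prom)]
        promoter_gene = None
        if hits:
            mid = (dmr.interval.start + dmr.interval.end) // 2
            promoter_gene = min(
                hits, key=lambda g: (abs(mid - g.tss), g.gene_id)
            ).gene_id
        out.append(AnnotatedDMR(dmr, label.label, label.gene_id, ctx,
                                promoter_gene))
    return out


def dmrs_to_frame(annotated: Sequence[AnnotatedDMR]) -> pd.DataFrame:
    rows = [{
        "chrom": a.dmr.interval.chrom,
        "start": a.dmr.interval.start,
        "end": a.dmr.interval.end,
        "n_cpg": a.dmr.n_cpg,
        "n_sig_cpg": a.dmr.n_sig_cpg,
        "mean_diff": a.dmr.mean_diff,
        "direction": a.dmr.direction,
        "timepoint": a.dmr.timepoint,
        "feature": a.feature,
        "cpg_context": a.cpg_ctx,
        "promoter_gene": a.promoter_gene,
    } for a in annotated]
    cols = ["chrom", "start", "end", "n_cpg", "n_sig_cpg", "mean_diff",
            "direction", "timepoint", "feature", "cpg_context", "promoter_gene"]
    return pd.DataFrame(rows, columns=cols)
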