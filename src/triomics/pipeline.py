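"""End-to-end pipeline: simulate -> interactome -> RNA targets -> DMRs ->
chromatin states -> integration, plus scoring of every stage against the
simulation's truth manifest."""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd

from . import chromatin as chrom
from . import integrate as integ
from . import kinetics as kin
from . import methylome as meth
from . import ppi as ppimod
from . import rna as rnamod
from .intervals import promoter_of
from .simulate import SimBundle, SimConfig, simulate_all, write_bundle


@dataclass
class PipelineResult:
    cfg: SimConfig
    bundle: SimBundle
    ppi_records: dict                  # timepoint -> interaction records
    ppi_timepoint_summary: pd.DataFrame
    ppi_genes: set
    peak_calls: pd.DataFrame
    enrich_calls: pd.DataFrame
    rna_target_genes: set
    dmrs: dict                         # timepoint -> annotated DMR frame
    promoter_directions: dict          # timepoint -> gene -> direction
    dmr_promoter_genes: set
    dynamics: pd.DataFrame
    promoter_states: pd.DataFrame
    state_overlay: Optional[pd.DataFrame]
    convergence_records: pd.DataFrame
    convergent_genes: set
    master_table: pd.DataFrame
    summary_table: pd.DataFrame
    half_lives: pd.DataFrame


def run_all(cfg: Optional[SimConfig] = None,
            bundle: Optional[SimBundle] = None,
            dmr_params: Optional[meth.DMRParams] = None,
            target_mode: str = "peak-only",
            outdir=None) -> PipelineResult:
    """Chain every analysis stage over one simulated data set.

    Pass ``bundle`` to analyse data already generated (or read back from
    disk); otherwise the configuration is simulated first.  With ``outdir``
    the result tables are written as TSV.
    """
    cfg = cfg or SimConfig()
    if bundle is None:
        bundle = simulate_all(cfg)
    dmr_params = dmr_params or meth.DMRParams()

    # ---- protein interactome
    filtered = ppimod.filter_detected(bundle.ipms)
    records = {}
    for tp in ("D0", "D28"):
        minus = ppimod.call_interactors(filtered, tp, "minus")
        plus = ppimod.call_interactors(filtered, tp, "plus")
        records[tp] = ppimod.classify_rnase_sensitivity(minus, plus, tp)
    tp_summary = ppimod.summarize_timepoints(records["D0"], records["D28"])
    protein_to_gene = {f"P_{g.gene_id}": g.gene_id for g in bundle.genes}
    ppi_proteins = set(records["D0"]["protein_id"]) | set(records["D28"]["protein_id"])
    ppi_genes = {protein_to_gene[p] for p in ppi_proteins if p in protein_to_gene}

    # ---- RNA targets
    enrich = rnamod.call_enriched_targets(bundle.frip_counts, bundle.frip_samples)
    base_mean = dict(zip(enrich["gene_id"], enrich["base_mean"]))
    peak_calls = rnamod.call_peak_targets(bundle.peaks, base_mean)
    rna_genes = rnamod.combine_target_calls(peak_calls, enrich, target_mode)

    # ---- methylome
    dmr_frames = {}
    dirmaps = {}
    for tp in ("D0", "D7"):
        dmrs = meth.call_dmrs_two_group(bundle.meth_counts, bundle.meth_samples,
                                        tp, dmr_params)
        ann = meth.annotate_dmrs(dmrs, bundle.genes, bundle.islands,
                                 cfg.promoter_flank)
        frame = meth.dmrs_to_frame(ann)
        dmr_frames[tp] = frame
        dirmaps[tp] = chrom.promoter_direction_map(frame)
    dynamics = chrom.classify_dynamics(dirmaps["D0"], dirmaps["D7"])
    dmr_genes = set(dirmaps["D0"]) | set(dirmaps["D7"])

    # ---- chromatin states (baseline control-cell chromatin)
    consensus = chrom.consensus_marks(
        [bundle.chromatin_peaks[("H3K4me3", 1)], bundle.chromatin_peaks[("H3K4me3", 2)]],
        [bundle.chromatin_peaks[("H3K27me3", 1)], bundle.chromatin_peaks[("H3K27me3", 2)]],
    )
    promoters = {g.gene_id: promoter_of(g, cfg.promoter_flank)
                 for g in bundle.genes}
    states = chrom.promoter_state(promoters, consensus["H3K4me3"],
                                  consensus["H3K27me3"], "D0")
    overlay = None
    d0_prom_dmrs = dmr_frames["D0"][dmr_frames["D0"]["promoter_gene"].notna()]
    if len(d0_prom_dmrs):
        overlay = chrom.state_overlap_fractions(d0_prom_dmrs, states)

    # ---- integration
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")   # background proteins have no gene map
        conv_records, convergent = integ.convergence(
            ppi_proteins, rna_genes, dmr_genes, protein_to_gene
        )
    master, summary = integ.build_report(
        conv_records,
        target_calls=peak_calls,
        dmr_dynamics=dynamics,
        promoter_states=states[["gene_id", "state"]],
    )

    # ---- kinetics
    hl_rows = []
    for gid, grp in bundle.decay.groupby("gene"):
        pr = kin.percent_remaining(grp)
        est = kin.fit_decay_halflife(pr["time_h"], pr["percent"], gid)
        hl = est.half_life
        if hl is None and (pr["percent"] > 0).all():
            # noisy quadratic can bottom out just above 50% without crossing;
            # the log-linear estimator is the robust fallback for decaying data
            hl = kin.fit_halflife_linear_log(pr["time_h"], pr["percent"],
                                             gid).half_life
        hl_rows.append((gid, hl))
    half_lives = pd.DataFrame(hl_rows, columns=["gene_id", "half_life_h"])

    result = PipelineResult(
        cfg, bundle, records, tp_summary, ppi_genes, peak_calls, enrich,
        rna_genes, dmr_frames, dirmaps, dmr_genes, dynamics, states, overlay,
        conv_records, convergent, master, summary, half_lives,
    )
    if outdir is not None:
        write_result(result, outdir)
    return result


def write_result(result: PipelineResult, outdir) -> None:
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    for tp, rec in result.ppi_records.items():
        rec.to_csv(out / f"ppi_interactions_{tp}.tsv", sep="\t", index=False)
    result.ppi_timepoint_summary.to_csv(out / "ppi_timepoint_summary.tsv",
                                        sep="\t", index=False)
    result.peak_calls.to_csv(out / "rna_peak_targets.tsv", sep="\t", index=False)
    result.enrich_calls.to_csv(out / "rna_enriched_targets.tsv", sep="\t",
                               index=False)
    for tp, frame in result.dmrs.items():
        frame.to_csv(out / f"dmrs_{tp}.tsv", sep="\t", index=False)
    result.dynamics.to_csv(out / "dmr_dynamics.tsv", sep="\t", index=False)
    result.promoter_states.to_csv(out / "promoter_states.tsv", sep="\t",
                                  index=False)
    if result.state_overlay is not None:
        result.state_overlay.to_csv(out / "dmr_state_overlay.tsv", sep="\t",
                                    index=False)
    result.master_table.to_csv(out / "master_table.tsv", sep="\t", index=False)
    result.summary_table.to_csv(out / "venn_summary.tsv", sep="\t", index=False)
    result.half_lives.to_csv(out / "half_lives.tsv", sep="\t", index=False)


# --------------------------------------------------------------- scoring

def _frac(num: int, den: int) -> float:
    return num / den if den else float("nan")


def _reciprocal_match(frame: pd.DataFrame, planted, min_frac: float = 0.5):
    """For each planted region, the matching called-DMR rows (reciprocal
    >= min_frac overlap); returns list of (planted, matched_rows)."""
    out = []
    for d in planted:
        iv = d.interval
        sub = frame[frame["chrom"] == iv.chrom]
        ov = (sub[["start", "end"]].clip(upper=iv.end, lower=iv.start)
              .eval("end - start"))
        lens = sub["end"] - sub["start"]
        ok = (ov >= min_frac * iv.length) & (ov >= min_frac * lens) & (ov > 0)
        out.append((d, sub[ok]))
    return out


def score_against_truth(result: PipelineResult) -> dict:
    """Recovery metrics of every stage against the planted ground truth."""
    truth = result.bundle.truth
    m: dict[str, float] = {}

    # protein interactome
    planted = truth.direct_proteins | truth.rna_assisted_proteins
    called = set(result.ppi_records["D0"]["protein_id"]) | \
        set(result.ppi_records["D28"]["protein_id"])
    m["ppi_sensitivity"] = _frac(len(called & planted), len(planted))
    m["ppi_precision"] = _frac(len(called & planted), len(called))
    d0 = result.ppi_records["D0"]
    truth_class = {p: "direct" for p in truth.direct_proteins}
    truth_class.update({p: "rna_assisted" for p in truth.rna_assisted_proteins})
    scored = d0[d0["protein_id"].isin(truth_class)]
    correct = sum(cls == truth_class[pid] for pid, cls in
                  zip(scored["protein_id"], scored["interaction_class"]))
    m["ppi_class_accuracy"] = _frac(correct, len(scored))

    # RNA targets
    peak_called = set(result.peak_calls.loc[result.peak_calls["is_peak_target"],
                                            "gene_id"])
    enr_called = set(result.enrich_calls.loc[
        result.enrich_calls["is_enriched_target"], "gene_id"])
    m["peak_target_recall"] = _frac(len(peak_called & truth.target_genes),
                                    len(truth.target_genes))
    m["peak_target_fdr"] = _frac(len(peak_called - truth.target_genes),
                                 len(peak_called))
    m["enriched_target_recall"] = _frac(len(enr_called & truth.target_genes),
                                        len(truth.target_genes))
    m["enriched_target_fdr"] = _frac(len(enr_called - truth.target_genes),
                                     len(enr_called))

    # DMRs per time point
    for tp in ("D0", "D7"):
        frame = result.dmrs[tp]
        planted_tp = truth.dmrs_at(tp)
        matches = _reciprocal_match(frame, planted_tp)
        recovered = [(d, rows) for d, rows in matches if len(rows)]
        m[f"dmr_recall_{tp}"] = _frac(len(recovered), len(planted_tp))
        dir_ok = sum(
            all(rows["direction"] == d.direction_at(tp)) for d, rows in recovered
        )
        m[f"dmr_direction_accuracy_{tp}"] = _frac(dir_ok, len(recovered))
        matched_idx = set()
        for _, rows in recovered:
            matched_idx |= set(rows.index)
        m[f"dmr_fdr_{tp}"] = _frac(len(frame) - len(matched_idx & set(frame.index)),
                                   len(frame))
        m[f"n_dmrs_{tp}"] = float(len(frame))

    # switching promoters
    dyn = result.dynamics.set_index("gene_id")["dynamics_class"]
    switched = sum(dyn.get(g) == "hypo_to_hyper" for g in truth.switching_promoters)
    m["switching_recovery"] = _frac(switched, len(truth.switching_promoters))

    # chromatin states
    states = result.promoter_states.set_index("gene_id")["state"]
    ok = sum(states.get(g) == s for g, s in truth.promoter_states.items())
    m["state_accuracy"] = _frac(ok, len(truth.promoter_states))

    # convergence
    m["n_convergent_called"] = float(len(result.convergent_genes))
    m["convergent_exact"] = float(result.convergent_genes ==
                                  truth.convergent_genes)

    # kinetics
    hl = result.half_lives.set_index("gene_id")["half_life_h"]
    rel_errs = []
    for gid, tau in truth.true_half_lives.items():
        est = hl.get(gid)
        if est is None or pd.isna(est):
            rel_errs.append(float("inf"))
        else:
            rel_errs.append(abs(est - tau) / tau)
    m["half_life_max_rel_error"] = max(rel_errs) if rel_errs else float("nan")
    return m
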