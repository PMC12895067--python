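"""IP-MS protein-interactome analysis.

Differential enrichment of antibody IP over IgG control intensities,
contaminant and detection filtering, RNase-sensitivity interaction typing
(direct vs RNA-assisted), novelty flagging against a reference interaction
list, and time-point bookkeeping.
"""
from __future__ import annotations

import re
import warnings
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .stats import bh_adjust, two_sample_t

#: gene-family prefixes treated as IP-MS contaminants: keratins, histones,
#: immunoglobulin variable chains
DEFAULT_CONTAMINANT_PATTERNS = (
    r"^KRT", r"^HIST", r"^H1-", r"^H2A", r"^H2B", r"^H3-", r"^H4-", r"^IG[HKL]V",
)

FC_THRESHOLD = 2.0
ADJ_P_THRESHOLD = 0.05


def filter_detected(table: pd.DataFrame,
                    contaminant_patterns: Sequence[str] = DEFAULT_CONTAMINANT_PATTERNS,
                    min_replicates: int = 2) -> pd.DataFrame:
    """Keep proteins detected (>= 1 peptide) in at least ``min_replicates``
    biological replicates of some IP run, and drop contaminant families.

    Detection is assessed within each (timepoint, rnase) IP run; a protein
    detected reliably in any run is retained table-wide.
    """
    if table.empty:
        return table.copy()
    ip = table[(table["condition"] == "IP") & (table["peptide_count"] >= 1)]
    reps = (
        ip.groupby(["protein_id", "timepoint", "rnase"])["replicate"]
        .nunique()
        .reset_index()
    )
    detected = set(reps.loc[reps["replicate"] >= min_replicates, "protein_id"])
    regexes = [re.compile(p, re.IGNORECASE) for p in contaminant_patterns]

    def is_contaminant(pid: str) -> bool:
        return any(r.search(pid) for r in regexes)

    keep = table["protein_id"].isin(detected) & ~table["protein_id"].map(is_contaminant)
    return table[keep].reset_index(drop=True)


def interactor_stats(table: pd.DataFrame, timepoint: str, rnase: str,
                     pseudo: float = 1.0,
                     var_mode: str = "common") -> pd.DataFrame:
    """Per-protein IP-vs-control statistics for one (timepoint, RNase) run.

    Fold change is taken on the linear scale, (mean IP + pseudo) /
    (mean control + pseudo).  Tests run on log2 intensities with missing
    values excluded (mass-spec dropout is not evidence of absence).  BH
    adjustment is applied across all testable proteins of the run.

    ``var_mode='common'`` (default) pools the log2 replicate variance across
    all proteins of the run and tests each protein with a z statistic:
    log-scale replicate scatter is approximately homoscedastic across
    proteins, and with 2-3 replicates a per-protein variance estimate (2-4
    degrees of freedom) would dominate the error.  It can test proteins with
    a single surviving measurement on one side.  ``var_mode='per-protein'``
    is the classical Student t (two values per side required).
    """
    run = table[(table["timepoint"] == timepoint) & (table["rnase"] == rnase)]
    if run.empty:
        return pd.DataFrame(columns=["protein_id", "fold_change", "p_value", "adj_p"])
    n_reps = run.groupby("condition")["replicate"].nunique()
    if n_reps.reindex(["IP", "control"]).fillna(0).min() < 2:
        raise ValueError("need >= 2 replicates per side")
    if var_mode not in {"common", "per-protein"}:
        raise ValueError(f"unknown var_mode {var_mode!r}")
    per_protein = []
    pooled_ss = 0.0
    pooled_df = 0
    for pid, grp in run.groupby("protein_id"):
        ip = grp.loc[grp["condition"] == "IP", "intensity"].dropna().to_numpy()
        ctrl = grp.loc[grp["condition"] == "control", "intensity"].dropna().to_numpy()
        lip, lctrl = np.log2(ip), np.log2(ctrl)
        for v in (lip, lctrl):
            if v.size >= 2:
                pooled_ss += (v.size - 1) * v.var(ddof=1)
                pooled_df += v.size - 1
        per_protein.append((pid, ip, ctrl, lip, lctrl))
    rows = []
    if var_mode == "common":
        if pooled_df == 0:
            raise ValueError("no protein has replicated measurements")
        sigma2 = pooled_ss / pooled_df
        for pid, ip, ctrl, lip, lctrl in per_protein:
            if lip.size < 1 or lctrl.size < 1:
                continue
            fc = (ip.mean() + pseudo) / (ctrl.mean() + pseudo)
            se = np.sqrt(sigma2 * (1.0 / lip.size + 1.0 / lctrl.size))
            z = (lip.mean() - lctrl.mean()) / se if se > 0 else 0.0
            p = 2.0 * sps.norm.sf(abs(z))
            rows.append((pid, float(fc), float(min(p, 1.0))))
    else:
        for pid, ip, ctrl, lip, lctrl in per_protein:
            if lip.size < 2 or lctrl.size < 2:
                continue
            fc = (ip.mean() + pseudo) / (ctrl.mean() + pseudo)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = two_sample_t(lip, lctrl)
            rows.append((pid, float(fc), res.p_value))
    out = pd.DataFrame(rows, columns=["protein_id", "fold_change", "p_value"])
    out["adj_p"] = bh_adjust(out["p_value"]) if len(out) else []
    return out


def call_interactors(table: pd.DataFrame, timepoint: str, rnase: str,
                     fc_threshold: float = FC_THRESHOLD,
                     adj_p_threshold: float = ADJ_P_THRESHOLD,
                     var_mode: str = "common") -> pd.DataFrame:
    """Significant interactors of one run: FC > 2 and BH-adjusted p < .05
    (both strict)."""
    stats = interactor_stats(table, timepoint, rnase, var_mode=var_mode)
    called = stats[(stats["fold_change"] > fc_threshold)
                   & (stats["adj_p"] < adj_p_threshold)]
    return called.reset_index(drop=True)


def classify_rnase_sensitivity(calls_minus: pd.DataFrame,
                               calls_plus: pd.DataFrame,
                               timepoint: Optional[str] = None) -> pd.DataFrame:
    """Type interactions by RNase sensitivity.

    The interactome universe is the RNase-minus call set; partners still
    called after RNase digestion are ``direct``, the rest ``rna_assisted``.
    Proteins significant only in the RNase-plus run are excluded.
    """
    plus = set(calls_plus["protein_id"])
    records = calls_minus.copy()
    records["interaction_class"] = np.where(
        records["protein_id"].isin(plus), "direct", "rna_assisted"
    )
    if timepoint is not None:
        records["timepoint"] = timepoint
    return records.reset_index(drop=True)


def flag_novel(records: pd.DataFrame, reference_ids: Iterable[str]) -> pd.DataFrame:
    """Mark partners absent from the reference (known-interaction) id set."""
    ref = set(reference_ids)
    out = records.copy()
    out["novel"] = ~out["protein_id"].isin(ref)
    return out


def summarize_timepoints(d0: pd.DataFrame, d28: pd.DataFrame) -> pd.DataFrame:
    """Counts of partners unique to each time point or shared, per interaction
    class and overall."""
    rows = []
    classes = ["direct", "rna_assisted", "all"]
    for cls in classes:
        s0 = set(d0["protein_id"] if cls == "all"
                 else d0.loc[d0["interaction_class"] == cls, "protein_id"])
        s28 = set(d28["protein_id"] if cls == "all"
                  else d28.loc[d28["interaction_class"] == cls, "protein_id"])
        rows.append((cls, len(s0 - s28), len(s28 - s0), len(s0 & s28)))
    return pd.DataFrame(rows, columns=["interaction_class", "d0_only",
                                       "d28_only", "shared"])
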