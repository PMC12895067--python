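"""Cross-layer integration: methylation-expression concordance, gene-list
enrichment, three-layer convergence, and pipeline report tables."""
from __future__ import annotations

import warnings
from typing import Iterable, Mapping, Optional

import pandas as pd

from .stats import EnrichmentResult, bh_adjust, hypergeom_enrich


def concordance(promoter_dmr_directions: Mapping[str, str],
                expression: pd.DataFrame) -> pd.DataFrame:
    """Concordance of promoter methylation with expression change.

    ``expression`` needs columns gene_id, lfc, significant; only genes with
    both a promoter DMR and a significant expression change are scored.
    Concordant means promoter hypermethylation with decreased RNA abundance,
    or hypomethylation with increased abundance.
    """
    sig = expression[expression["significant"].astype(bool)]
    rows = []
    for row in sig.itertuples(index=False):
        direction = promoter_dmr_directions.get(row.gene_id)
        if direction is None:
            continue
        concordant = (direction == "hyper" and row.lfc < 0) or \
                     (direction == "hypo" and row.lfc > 0)
        rows.append((row.gene_id, direction, float(row.lfc), concordant))
    return pd.DataFrame(rows, columns=["gene_id", "dmr_direction",
                                       "expression_lfc", "concordant"])


def convergence(ppi_genes: Iterable[str], rna_target_genes: Iterable[str],
                dmr_promoter_genes: Iterable[str],
                protein_to_gene: Optional[Mapping[str, str]] = None):
    """Three-layer membership records and the convergent (triple) gene set.

    ``ppi_genes`` may be protein identifiers when ``protein_to_gene`` is
    supplied; unmappable proteins are excluded with a warning.
    """
    if protein_to_gene is not None:
        mapped = set()
        lost = 0
        for p in ppi_genes:
            g = protein_to_gene.get(p)
            if g is None:
                lost += 1
            else:
                mapped.add(g)
        if lost:
            warnings.warn(f"{lost} protein ids had no gene mapping; excluded")
        ppi = mapped
    else:
        ppi = set(ppi_genes)
    rna = set(rna_target_genes)
    dmr = set(dmr_promoter_genes)
    union = sorted(ppi | rna | dmr)
    records = pd.DataFrame({
        "gene_id": union,
        "in_ppi": [g in ppi for g in union],
        "in_rna": [g in rna for g in union],
        "in_dmr": [g in dmr for g in union],
    })
    records["n_layers"] = records[["in_ppi", "in_rna", "in_dmr"]].sum(axis=1)
    convergent = ppi & rna & dmr
    return records, convergent


def list_enrichment(query_genes: Iterable[str], gene_lists: Mapping[str, Iterable[str]],
                    universe: Iterable[str],
                    fdr_threshold: float = 0.05) -> pd.DataFrame:
    """Hypergeometric enrichment of the query set in each named gene list,
    BH-adjusted across the lists; each list is intersected with the universe
    before testing."""
    uni = set(universe)
    query = set(query_genes)
    if not query <= uni:
        raise ValueError("query set must lie within the universe")
    rows = []
    for name in sorted(gene_lists):
        lst = set(gene_lists[name]) & uni
        res = hypergeom_enrich(len(query & lst), len(query), len(lst), len(uni))
        rows.append((name, res.k, res.n, res.K, res.N, res.p_value))
    out = pd.DataFrame(rows, columns=["list", "k", "n", "K", "N", "p_value"])
    out["fdr"] = bh_adjust(out["p_value"]) if len(out) else []
    out["significant"] = out["fdr"] < fdr_threshold
    return out


def build_report(convergence_records: pd.DataFrame,
                 ppi_records: Optional[pd.DataFrame] = None,
                 target_calls: Optional[pd.DataFrame] = None,
                 dmr_dynamics: Optional[pd.DataFrame] = None,
                 promoter_states: Optional[pd.DataFrame] = None):
    """Join all layers into one per-gene master table plus a summary of
    Venn-style counts.  Column order is deterministic; duplicate gene keys in
    any input raise an error."""
    master = convergence_records.copy()
    joins = [
        ("target_calls", target_calls, "gene_id"),
        ("dmr_dynamics", dmr_dynamics, "gene_id"),
        ("promoter_states", promoter_states, "gene_id"),
    ]
    for name, frame, key in joins:
        if frame is None:
            continue
        if frame[key].duplicated().any():
            raise ValueError(f"duplicate gene keys in {name}")
        master = master.merge(frame, on=key, how="left")
    if ppi_records is not None and "gene_id" in ppi_records.columns:
        if ppi_records["gene_id"].duplicated().any():
            raise ValueError("duplicate gene keys in ppi_records")
        master = master.merge(
            ppi_records.add_prefix("ppi_").rename(columns={"ppi_gene_id": "gene_id"}),
            on="gene_id", how="left",
        )
    n = {
        "ppi": int(master["in_ppi"].sum()),
        "rna": int(master["in_rna"].sum()),
        "dmr": int(master["in_dmr"].sum()),
        "ppi_rna": int((master["in_ppi"] & master["in_rna"]).sum()),
        "ppi_dmr": int((master["in_ppi"] & master["in_dmr"]).sum()),
        "rna_dmr": int((master["in_rna"] & master["in_dmr"]).sum()),
        "all_three": int((master["in_ppi"] & master["in_rna"]
                          & master["in_dmr"]).sum()),
        "union": len(master),
    }
    summary = pd.DataFrame(sorted(n.items()), columns=["set", "count"])
    return master, summary
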