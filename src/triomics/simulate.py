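"""Synthetic multi-omics data generator with a ground-truth manifest.

Emulates every input layer of the analysis at study scale so the whole
pipeline can be exercised and scored without any external download:

* log-normal IP-MS intensity tables (antibody IP vs IgG control, with and
  without RNase, two differentiation time points) with planted enriched
  proteins, a planted direct subset that survives RNase, and
  missing-at-random peptide dropout;
* a peak table plus negative-binomial IP/input count matrix with planted
  RNA targets carrying >= 2 significant peaks and elevated IP counts;
* beta-binomial per-CpG methylation counts (two conditions x two time points
  x replicates) with planted hypo-, hyper- and hypo-to-hyper switching
  promoter DMRs;
* replicate histone-mark peak sets realising planted promoter chromatin
  states (active / bivalent / repressed / quiescent);
* exponential-decay qPCR Ct series with known half-lives.

Every generator is a pure function of the configuration: one global seed fans
out to per-layer substreams derived by stable hashing of the layer name, so
adding or re-running one layer never perturbs another layer's draws.
"""
from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .intervals import GeneModel, GenomicInterval, promoter_of
from . import io as tio

TIMEPOINTS_METH = ("D0", "D7")
TIMEPOINTS_IPMS = ("D0", "D28")
DECAY_TIMES_H = (0.0, 2.0, 4.0, 6.0, 8.0)
CHROMATIN_STATES = ("active", "bivalent", "repressed", "quiescent")


@dataclass
class SimConfig:
    seed: int = 0
    # genome
    n_chrom: int = 2
    chrom_length: int = 1_000_000
    n_genes: int = 200
    promoter_flank: int = 2000
    # methylome
    n_cpg_per_promoter: int = 25
    cpg_coverage_mean: float = 20.0
    dmr_effect: float = 0.3
    bb_phi: float = 0.05          # beta-binomial over-dispersion (intra-class corr.)
    n_dmr_hypo: int = 40
    n_dmr_hyper: int = 40
    n_dmr_switching: int = 20
    n_meth_replicates: int = 2
    # IP-MS
    ipms_n_proteins: int = 400
    ipms_n_enriched: int = 60
    ipms_n_direct: int = 20
    ipms_fc: float = 4.0
    ipms_cv: float = 0.2
    ipms_dropout: float = 0.1
    ipms_n_replicates: int = 3
    # fRIP (peaks + counts)
    frip_n_targets: int = 60
    frip_lfc: float = 2.0
    nb_dispersion: float = 0.1
    frip_motif_rate: float = 0.9
    frip_n_blocks: int = 3
    # kinetics
    decay_half_lives: tuple = (2.0, 4.0, 6.0, 8.0)
    ct_noise_sd: float = 0.1
    # integration
    n_convergent: int = 19

    def validate(self) -> None:
        counts = [
            self.n_chrom, self.n_genes, self.n_cpg_per_promoter,
            self.n_dmr_hypo, self.n_dmr_hyper, self.n_dmr_switching,
            self.ipms_n_proteins, self.ipms_n_enriched, self.ipms_n_direct,
            self.frip_n_targets, self.n_convergent,
        ]
        if any(c < 0 for c in counts):
            raise ValueError("all counts must be >= 0")
        if not (0.0 <= self.dmr_effect < 1.0):
            raise ValueError("dmr_effect must lie in [0, 1)")
        if self.ipms_n_direct > self.ipms_n_enriched:
            raise ValueError("ipms_n_direct cannot exceed ipms_n_enriched")
        if self.frip_n_targets > self.n_genes:
            raise ValueError("frip_n_targets cannot exceed n_genes")
        if any(t <= 0 for t in self.decay_half_lives):
            raise ValueError("half-lives must be positive")
        if self.n_convergent > min(
            self.ipms_n_enriched, self.frip_n_targets, self.n_dmr_hyper
        ):
            raise ValueError(
                "n_convergent must fit inside every planted layer "
                "(it occupies hypermethylated-DMR slots)"
            )


def _rng(cfg: SimConfig, layer: str) -> np.random.Generator:
    """Deterministic per-layer substream derived from the global seed."""
    key = zlib.crc32(layer.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence([cfg.seed & 0x7FFFFFFF, key]))


# --------------------------------------------------------------- truth

@dataclass
class PlantedDMR:
    gene_id: str
    chrom: str
    start: int
    end: int
    d0_direction: Optional[str]   # hypo / hyper / None
    d7_direction: Optional[str]

    @property
    def interval(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.start, self.end)

    def direction_at(self, timepoint: str) -> Optional[str]:
        return self.d0_direction if timepoint == "D0" else self.d7_direction


@dataclass
class TruthManifest:
    direct_proteins: set
    rna_assisted_proteins: set
    target_genes: set
    dmr_regions: list                      # list[PlantedDMR]
    switching_promoters: set
    promoter_states: dict                  # gene_id -> state
    convergent_genes: set
    true_half_lives: dict                  # gene_id -> hours

    def dmrs_at(self, timepoint: str) -> list:
        return [d for d in self.dmr_regions if d.direction_at(timepoint)]

    @property
    def ppi_genes(self) -> set:
        return {p.removeprefix("P_") for p in
                self.direct_proteins | self.rna_assisted_proteins}

    @property
    def dmr_promoter_genes(self) -> set:
        return {d.gene_id for d in self.dmr_regions}

    def to_json(self, path) -> None:
        payload = {
            "direct_proteins": sorted(self.direct_proteins),
            "rna_assisted_proteins": sorted(self.rna_assisted_proteins),
            "target_genes": sorted(self.target_genes),
            "dmr_regions": [asdict(d) for d in self.dmr_regions],
            "switching_promoters": sorted(self.switching_promoters),
            "promoter_states": dict(sorted(self.promoter_states.items())),
            "convergent_genes": sorted(self.convergent_genes),
            "true_half_lives": dict(sorted(self.true_half_lives.items())),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)
            fh.write("\n")

    @classmethod
    def from_json(cls, path) -> "TruthManifest":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            direct_proteins=set(d["direct_proteins"]),
            rna_assisted_proteins=set(d["rna_assisted_proteins"]),
            target_genes=set(d["target_genes"]),
            dmr_regions=[PlantedDMR(**r) for r in d["dmr_regions"]],
            switching_promoters=set(d["switching_promoters"]),
            promoter_states=d["promoter_states"],
            convergent_genes=set(d["convergent_genes"]),
            true_half_lives={k: float(v) for k, v in d["true_half_lives"].items()},
        )

    def check_consistency(self) -> None:
        layers = (
            self.ppi_genes & self.target_genes & self.dmr_promoter_genes
        )
        if not self.convergent_genes <= layers:
            raise AssertionError("convergent genes missing from a planted layer")


# --------------------------------------------------------------- genome

def simulate_genome(cfg: SimConfig):
    """Non-overlapping gene models on a slotted genome, with promoter CpG
    islands, gene-body CpGs, and sparse intergenic background CpGs.

    Returns ``(genes, cpg_sites, islands)`` where ``cpg_sites`` is a DataFrame
    with columns chrom, pos, zone in {island, body, background}, gene_id.
    """
    cfg.validate()
    rng = _rng(cfg, "genome")
    per_chrom = -(-cfg.n_genes // cfg.n_chrom)          # ceil
    slot = cfg.chrom_length // per_chrom
    min_len, max_len = 3000, 5000
    offset = 2500
    if slot < offset + max_len + cfg.promoter_flank + 500:
        raise ValueError("genes do not fit the chromosome at this density")

    genes: list[GeneModel] = []
    lengths = rng.integers(min_len, max_len + 1, size=cfg.n_genes)
    strands = rng.choice(["+", "-"], size=cfg.n_genes)
    biotypes = rng.choice(
        ["protein_coding", "lncRNA", "snoRNA", "other"],
        size=cfg.n_genes,
        p=[0.90, 0.05, 0.02, 0.03],
    )
    for i in range(cfg.n_genes):
        chrom = f"chr{i // per_chrom + 1}"
        gstart = (i % per_chrom) * slot + offset
        gend = gstart + int(lengths[i])
        iv = GenomicInterval(chrom, gstart, gend, strands[i])
        third = (gend - gstart) // 3
        exons = (
            GenomicInterval(chrom, gstart, gstart + third, strands[i]),
            GenomicInterval(chrom, gstart + 2 * third, gend, strands[i]),
        )
        genes.append(GeneModel(f"G{i:04d}", iv, strands[i], biotypes[i], exons))

    rows = []
    islands: list[GenomicInterval] = []
    spacing = 20
    for g in genes:
        tss = g.tss
        offs = (np.arange(cfg.n_cpg_per_promoter) - cfg.n_cpg_per_promoter // 2)
        positions = tss + offs * spacing
        islands.append(
            GenomicInterval(g.interval.chrom, int(positions.min()),
                            int(positions.max()) + 2)
        )
        for p in positions:
            rows.append((g.interval.chrom, int(p), "island", g.gene_id))
        for p in range(g.interval.start + 600, g.interval.end - 600, 150):
            rows.append((g.interval.chrom, int(p), "body", g.gene_id))
    # sparse intergenic background, kept clear of genes and their promoters
    gene_spans = {}
    for g in genes:
        lo = g.interval.start - cfg.promoter_flank - 500
        hi = g.interval.end + cfg.promoter_flank + 500
        gene_spans.setdefault(g.interval.chrom, []).append((lo, hi))
    for c in range(cfg.n_chrom):
        chrom = f"chr{c + 1}"
        spans = sorted(gene_spans.get(chrom, []))
        for p in range(1000, cfg.chrom_length - 1000, 701):
            if any(lo <= p < hi for lo, hi in spans):
                continue
            rows.append((chrom, p, "background", ""))
    cpg_sites = pd.DataFrame(rows, columns=["chrom", "pos", "zone", "gene_id"])
    cpg_sites = cpg_sites.sort_values(["chrom", "pos"], kind="mergesort")
    cpg_sites = cpg_sites.reset_index(drop=True)
    return genes, cpg_sites, islands


# --------------------------------------------------------------- allocation

def allocate_truth_layers(cfg: SimConfig, genes) -> dict:
    """Deterministic assignment of genes to planted layers.

    The convergent genes sit in all three layers; the remaining slots of each
    layer are filled from disjoint index ranges except that methylome-only
    slots may reuse genes never planted in both other layers, so the exact
    three-way intersection equals the convergent set by construction.
    """
    ids = [g.gene_id for g in genes]
    need = (
        cfg.n_convergent
        + (cfg.ipms_n_enriched - cfg.n_convergent)
        + (cfg.frip_n_targets - cfg.n_convergent)
        + cfg.n_dmr_switching
        + cfg.n_dmr_hypo
        + (cfg.n_dmr_hyper - cfg.n_convergent)
    )
    if need > len(ids):
        raise ValueError(f"planted layers need {need} genes, have {len(ids)}")
    cursor = 0

    def take(n):
        nonlocal cursor
        out = ids[cursor:cursor + n]
        cursor += n
        return out

    convergent = take(cfg.n_convergent)
    ipms = convergent + take(cfg.ipms_n_enriched - cfg.n_convergent)
    frip = convergent + take(cfg.frip_n_targets - cfg.n_convergent)
    switching = take(cfg.n_dmr_switching)
    hypo = take(cfg.n_dmr_hypo)
    hyper = convergent + take(cfg.n_dmr_hyper - cfg.n_convergent)
    return {
        "convergent": convergent,
        "ipms_enriched": ipms,
        "ipms_direct": ipms[: cfg.ipms_n_direct],
        "frip_targets": frip,
        "dmr_switching": switching,
        "dmr_hypo": hypo,
        "dmr_hyper": hyper,
    }


# --------------------------------------------------------------- methylome

def simulate_methylomes(cfg: SimConfig, genes, cpg_sites: pd.DataFrame,
                        alloc: dict):
    """Beta-binomial CpG counts for {control, silenced} x {D0, D7} x replicates.

    Baseline methylation is low at promoter islands, high in gene bodies and
    intermediate elsewhere.  Planted hyper promoters shift the silenced mean up
    by ``dmr_effect`` from a low baseline; planted hypo promoters start from an
    elevated control baseline and drop by the same amount; switching promoters
    are hypo at D0 and hyper at D7.
    """
    cfg.validate()
    rng = _rng(cfg, "methylome")
    n = len(cpg_sites)
    zone = cpg_sites["zone"].to_numpy()
    gene_of = cpg_sites["gene_id"].to_numpy()

    base = np.where(zone == "island", 0.15, np.where(zone == "body", 0.75, 0.60))
    base = base + rng.normal(0.0, 0.02, size=n)

    directions = {}
    for gid in alloc["dmr_hyper"]:
        directions[gid] = {"D0": "hyper", "D7": "hyper"}
    for gid in alloc["dmr_hypo"]:
        directions[gid] = {"D0": "hypo", "D7": "hypo"}
    for gid in alloc["dmr_switching"]:
        directions[gid] = {"D0": "hypo", "D7": "hyper"}

    island_mask = zone == "island"

    def mu_for(condition: str, timepoint: str) -> np.ndarray:
        mu = base.copy()
        for gid, dirs in directions.items():
            direction = dirs[timepoint]
            sel = island_mask & (gene_of == gid)
            lo, hi = 0.15, 0.50
            if direction == "hypo":
                mu[sel] = hi if condition == "control" else hi - cfg.dmr_effect
            else:
                mu[sel] = lo if condition == "control" else lo + cfg.dmr_effect
        return np.clip(mu, 0.02, 0.98)

    counts_rows = []
    sample_rows = []
    for timepoint in TIMEPOINTS_METH:
        for condition in ("control", "silenced"):
            mu = mu_for(condition, timepoint)
            if cfg.bb_phi > 0:
                a = mu * (1 - cfg.bb_phi) / cfg.bb_phi
                b = (1 - mu) * (1 - cfg.bb_phi) / cfg.bb_phi
            for rep in range(1, cfg.n_meth_replicates + 1):
                sample = f"{condition}_{timepoint}_r{rep}"
                cov = rng.poisson(cfg.cpg_coverage_mean, size=n)
                p = rng.beta(a, b) if cfg.bb_phi > 0 else mu
                meth = rng.binomial(cov, p)
                counts_rows.append(pd.DataFrame({
                    "chrom": cpg_sites["chrom"],
                    "pos": cpg_sites["pos"],
                    "meth": meth,
                    "total": cov,
                    "sample": sample,
                }))
                sample_rows.append((sample, condition, timepoint, rep))
    counts = pd.concat(counts_rows, ignore_index=True)
    samples = pd.DataFrame(
        sample_rows, columns=["sample", "condition", "timepoint", "replicate"]
    )

    planted: list[PlantedDMR] = []
    island_bounds = {}
    isl = cpg_sites[island_mask]
    for gid, grp in isl.groupby("gene_id"):
        island_bounds[gid] = (
            grp["chrom"].iloc[0], int(grp["pos"].min()), int(grp["pos"].max()) + 1
        )
    for gid, dirs in directions.items():
        chrom, start, end = island_bounds[gid]
        planted.append(PlantedDMR(gid, chrom, start, end, dirs["D0"], dirs["D7"]))
    planted.sort(key=lambda d: d.gene_id)
    return counts, samples, planted


# --------------------------------------------------------------- IP-MS

IPMS_CONTAMINANTS = ("KRT1", "KRT5", "KRT10", "HIST1H1C", "IGHV1-2")


def simulate_ipms(cfg: SimConfig, genes, alloc: dict):
    """Long-format IP-MS intensity table over
    {IP, control} x {RNase minus, plus} x {D0, D28} x replicates."""
    cfg.validate()
    rng = _rng(cfg, "ipms")
    enriched = list(alloc["ipms_enriched"])
    direct = set(alloc["ipms_direct"])
    n_bg = cfg.ipms_n_proteins - len(enriched) - len(IPMS_CONTAMINANTS)
    if n_bg < 0:
        raise ValueError("ipms_n_proteins too small for the planted proteins")
    proteins = (
        [f"P_{gid}" for gid in enriched]
        + list(IPMS_CONTAMINANTS)
        + [f"P_BG{i:04d}" for i in range(n_bg)]
    )
    is_enriched = np.array(
        [p.startswith("P_G") for p in proteins]
    )
    is_direct = np.array(
        [p.startswith("P_") and p.removeprefix("P_") in direct for p in proteins]
    )
    is_contam = np.array([p in IPMS_CONTAMINANTS for p in proteins])

    base = rng.normal(20.0, 1.5, size=len(proteins))
    sigma_log2 = np.sqrt(np.log1p(cfg.ipms_cv ** 2)) / np.log(2.0)
    log2_fc = np.log2(cfg.ipms_fc)

    rows = []
    for timepoint in TIMEPOINTS_IPMS:
        for rnase in ("minus", "plus"):
            retained = is_direct if rnase == "plus" else is_enriched
            for condition in ("IP", "control"):
                effect = np.where(
                    (condition == "IP") & (retained | is_contam), log2_fc, 0.0
                )
                for rep in range(1, cfg.ipms_n_replicates + 1):
                    log2_int = base + effect + rng.normal(0, sigma_log2,
                                                          size=len(proteins))
                    intensity = np.power(2.0, log2_int)
                    dropped = rng.random(len(proteins)) < cfg.ipms_dropout
                    peptides = rng.poisson(4.0, size=len(proteins)) + 1
                    intensity[dropped] = np.nan
                    peptides[dropped] = 0
                    rows.append(pd.DataFrame({
                        "protein_id": proteins,
                        "condition": condition,
                        "rnase": rnase,
                        "timepoint": timepoint,
                        "replicate": rep,
                        "peptide_count": peptides,
                        "intensity": np.round(intensity, 4),
                    }))
    table = pd.concat(rows, ignore_index=True)
    truth = {
        "direct": {f"P_{g}" for g in direct},
        "rna_assisted": {f"P_{g}" for g in enriched if g not in direct},
    }
    return table, truth


# --------------------------------------------------------------- fRIP

RNA_ALPHABET = np.array(list("ACGU"))
HNRNPU_MOTIF = "UGUAUUG"


def _random_rna(rng, length: int) -> str:
    return "".join(rng.choice(RNA_ALPHABET, size=length))


def simulate_frip(cfg: SimConfig, genes, alloc: dict):
    """Peak table plus IP/input negative-binomial count matrix.

    Planted targets carry >= 2 peaks with tiny adjusted P and IP counts raised
    by ``frip_lfc``; non-targets get at most one peak or a low expression
    floor.  Counts carry a shared multiplicative block (cell-line) factor and
    samples are paired within blocks.
    """
    cfg.validate()
    rng = _rng(cfg, "frip")
    targets = list(alloc["frip_targets"])
    target_set = set(targets)
    by_id = {g.gene_id: g for g in genes}

    peak_rows = []
    for g in genes:
        gid = g.gene_id
        if gid in target_set:
            n_sig = 2 + int(rng.poisson(0.8))
            for j in range(n_sig):
                start = int(rng.integers(g.interval.start, g.interval.end - 100))
                seq = _random_rna(rng, 50)
                if rng.random() < cfg.frip_motif_rate:
                    at = int(rng.integers(0, 50 - len(HNRNPU_MOTIF)))
                    seq = seq[:at] + HNRNPU_MOTIF + seq[at + len(HNRNPU_MOTIF):]
                peak_rows.append((
                    g.interval.chrom, start, start + 100, f"{gid}_pk{j}",
                    0, g.strand, gid,
                    float(10.0 ** -rng.uniform(4.0, 8.0)), seq,
                ))
        elif rng.random() < 0.2:
            start = int(rng.integers(g.interval.start, g.interval.end - 100))
            peak_rows.append((
                g.interval.chrom, start, start + 100, f"{gid}_pk0",
                0, g.strand, gid, float(rng.uniform(0.0, 1.0)),
                _random_rna(rng, 50),
            ))
    peaks = pd.DataFrame(
        peak_rows,
        columns=["chrom", "start", "end", "peak_id", "score", "strand",
                 "gene_id", "adj_p", "sequence"],
    )

    gene_ids = [g.gene_id for g in genes]
    n = len(gene_ids)
    base_mean = np.empty(n)
    for i, gid in enumerate(gene_ids):
        if gid in target_set:
            base_mean[i] = rng.lognormal(np.log(150.0), 0.4)
        elif rng.random() < 0.7:
            base_mean[i] = rng.lognormal(np.log(80.0), 0.6)
        else:
            base_mean[i] = rng.uniform(1.0, 15.0)

    is_target = np.array([gid in target_set for gid in gene_ids])
    block_factor = np.power(2.0, rng.normal(0.0, 0.2, size=cfg.frip_n_blocks))
    sample_rows = []
    cols = {}
    for b in range(cfg.frip_n_blocks):
        for status in ("IP", "input"):
            mean = base_mean * block_factor[b]
            if status == "IP":
                mean = mean * np.where(is_target, 2.0 ** cfg.frip_lfc, 1.0)
            if cfg.nb_dispersion > 0:
                lam = rng.gamma(1.0 / cfg.nb_dispersion,
                                mean * cfg.nb_dispersion)
            else:
                lam = mean
            name = f"{status}_b{b + 1}"
            cols[name] = rng.poisson(lam)
            sample_rows.append((name, status, f"b{b + 1}"))
    counts = pd.DataFrame(cols, index=pd.Index(gene_ids, name="gene_id"))
    sample_sheet = pd.DataFrame(sample_rows, columns=["sample", "status", "block"])
    return peaks, counts, sample_sheet, set(targets)


# --------------------------------------------------------------- chromatin

def simulate_chromatin(cfg: SimConfig, genes, timepoint: str = "D0"):
    """Replicate H3K4me3/H3K27me3 peak sets realising planted promoter states.

    Peak boundaries are jittered by up to +/-100 bp per replicate, which still
    satisfies the reciprocal-50% reproducibility rule by construction; a few
    replicate-specific noise peaks and shared intergenic peaks are added to
    exercise the consensus step.
    """
    cfg.validate()
    rng = _rng(cfg, f"chromatin_{timepoint}")
    states = rng.choice(CHROMATIN_STATES, size=len(genes),
                        p=[0.45, 0.25, 0.15, 0.15])
    truth = {g.gene_id: s for g, s in zip(genes, states)}

    def jitter(lo, hi):
        return (int(lo + rng.integers(-100, 101)), int(hi + rng.integers(-100, 101)))

    peaks = {("H3K4me3", 1): [], ("H3K4me3", 2): [],
             ("H3K27me3", 1): [], ("H3K27me3", 2): []}
    for g, state in zip(genes, states):
        tss = g.tss
        chrom = g.interval.chrom
        if state in ("active", "bivalent"):
            for rep in (1, 2):
                s, e = jitter(tss - 700, tss + 800)
                peaks[("H3K4me3", rep)].append(GenomicInterval(chrom, max(0, s), e))
        if state in ("repressed", "bivalent"):
            for rep in (1, 2):
                s, e = jitter(tss - 800, tss + 900)
                peaks[("H3K27me3", rep)].append(GenomicInterval(chrom, max(0, s), e))
    # shared intergenic peaks (survive consensus, overlap no promoter) and
    # replicate-only noise peaks (removed by consensus)
    per_chrom = -(-cfg.n_genes // cfg.n_chrom)
    slot = cfg.chrom_length // per_chrom
    for mark in ("H3K4me3", "H3K27me3"):
        for c in range(cfg.n_chrom):
            chrom = f"chr{c + 1}"
            slots = rng.choice(per_chrom, size=min(10, per_chrom), replace=False)
            for s_i in slots:
                base = int(s_i) * slot
                for rep in (1, 2):
                    s, e = jitter(base + 120, base + 380)
                    peaks[(mark, rep)].append(
                        GenomicInterval(chrom, max(base + 20, s), min(base + 480, e))
                    )
            for rep in (1, 2):
                noise_slots = rng.choice(per_chrom, size=min(5, per_chrom),
                                         replace=False)
                for s_i in noise_slots:
                    base = int(s_i) * slot + 9550 + int(rng.integers(0, 200))
                    peaks[(mark, rep)].append(
                        GenomicInterval(chrom, base, base + 60 + rep)
                    )
    for key in peaks:
        peaks[key] = sorted(peaks[key], key=lambda iv: (iv.chrom, iv.start, iv.end))
    return peaks, truth


# --------------------------------------------------------------- decay

def simulate_decay(cfg: SimConfig):
    """qPCR Ct series for exponential decay at the five assay time points.

    Target Ct rises by one cycle per halving (Ct(t) = Ct0 + t / half_life);
    the reference gene stays flat; Gaussian noise of sd ``ct_noise_sd`` is
    added to every measurement.
    """
    cfg.validate()
    rng = _rng(cfg, "decay")
    rows = []
    truth = {}
    for tau in cfg.decay_half_lives:
        gid = f"DECAY_T{tau:g}"
        truth[gid] = float(tau)
        ct0_target, ct0_ref = 22.0, 18.0
        for rep in range(1, 4):
            for t in DECAY_TIMES_H:
                ct_t = ct0_target + t / tau + rng.normal(0.0, cfg.ct_noise_sd)
                ct_r = ct0_ref + rng.normal(0.0, cfg.ct_noise_sd)
                rows.append((gid, "silenced", t, rep,
                             round(float(ct_t), 5), round(float(ct_r), 5)))
    decay = pd.DataFrame(
        rows, columns=["gene", "condition", "time_h", "replicate",
                       "ct_target", "ct_reference"],
    )
    return decay, truth


# --------------------------------------------------------------- bundle

@dataclass
class SimBundle:
    cfg: SimConfig
    genes: list
    cpg_sites: pd.DataFrame
    islands: list
    meth_counts: pd.DataFrame
    meth_samples: pd.DataFrame
    ipms: pd.DataFrame
    peaks: pd.DataFrame
    frip_counts: pd.DataFrame
    frip_samples: pd.DataFrame
    chromatin_peaks: dict            # (mark, replicate) -> list[GenomicInterval]
    decay: pd.DataFrame
    truth: TruthManifest


def simulate_all(cfg: SimConfig) -> SimBundle:
    """Generate every layer plus a mutually consistent truth manifest."""
    cfg.validate()
    genes, cpg_sites, islands = simulate_genome(cfg)
    alloc = allocate_truth_layers(cfg, genes)
    meth_counts, meth_samples, planted_dmrs = simulate_methylomes(
        cfg, genes, cpg_sites, alloc
    )
    ipms, ipms_truth = simulate_ipms(cfg, genes, alloc)
    peaks, frip_counts, frip_samples, target_genes = simulate_frip(
        cfg, genes, alloc
    )
    chromatin, state_truth = simulate_chromatin(cfg, genes)
    decay, half_lives = simulate_decay(cfg)
    truth = TruthManifest(
        direct_proteins=ipms_truth["direct"],
        rna_assisted_proteins=ipms_truth["rna_assisted"],
        target_genes=target_genes,
        dmr_regions=planted_dmrs,
        switching_promoters=set(alloc["dmr_switching"]),
        promoter_states=state_truth,
        convergent_genes=set(alloc["convergent"]),
        true_half_lives=half_lives,
    )
    truth.check_consistency()
    return SimBundle(cfg, genes, cpg_sites, islands, meth_counts, meth_samples,
                     ipms, peaks, frip_counts, frip_samples, chromatin, decay,
                     truth)


def write_bundle(bundle: SimBundle, outdir) -> None:
    """Write every layer in the dialects the analysis modules read."""
    out = Path(outdir)
    (out / "cpg").mkdir(parents=True, exist_ok=True)
    (out / "chromatin").mkdir(exist_ok=True)
    tio.write_gene_table(bundle.genes, out / "genes.tsv")
    tio.write_bed(bundle.islands, out / "cpg_islands.bed")
    for sample, grp in bundle.meth_counts.groupby("sample"):
        tio.write_bismark_cov(grp, out / "cpg" / f"{sample}.cov")
    bundle.meth_samples.to_csv(out / "meth_samples.tsv", sep="\t", index=False)
    bundle.ipms.to_csv(out / "ipms_intensities.tsv", sep="\t", index=False)
    bundle.peaks.to_csv(out / "frip_peaks.tsv", sep="\t", index=False)
    bundle.frip_counts.to_csv(out / "frip_counts.tsv", sep="\t")
    bundle.frip_samples.to_csv(out / "frip_samples.tsv", sep="\t", index=False)
    for (mark, rep), ivs in sorted(bundle.chromatin_peaks.items()):
        tio.write_bed(ivs, out / "chromatin" / f"{mark}_rep{rep}.bed")
    bundle.decay.to_csv(out / "decay_ct.tsv", sep="\t", index=False)
    bundle.truth.to_json(out / "truth_manifest.json")


def read_bundle(indir, cfg: Optional[SimConfig] = None) -> SimBundle:
    """Read a bundle previously written by :func:`write_bundle`."""
    src = Path(indir)
    genes = tio.read_gene_table(src / "genes.tsv")
    islands = tio.read_bed(src / "cpg_islands.bed")
    meth_samples = pd.read_csv(src / "meth_samples.tsv", sep="\t")
    parts = []
    for sample in meth_samples["sample"]:
        parts.append(tio.read_bismark_cov(src / "cpg" / f"{sample}.cov", sample))
    meth_counts = pd.concat(parts, ignore_index=True)
    ipms = pd.read_csv(src / "ipms_intensities.tsv", sep="\t")
    peaks = pd.read_csv(src / "frip_peaks.tsv", sep="\t", dtype={"chrom": str})
    frip_counts = pd.read_csv(src / "frip_counts.tsv", sep="\t", index_col=0)
    frip_samples = pd.read_csv(src / "frip_samples.tsv", sep="\t")
    chromatin = {}
    for path in sorted((src / "chromatin").glob("*_rep*.bed")):
        mark, rep = path.stem.rsplit("_rep", 1)
        chromatin[(mark, int(rep))] = tio.read_bed(path)
    decay = pd.read_csv(src / "decay_ct.tsv", sep="\t")
    truth = TruthManifest.from_json(src / "truth_manifest.json")
    cpg_sites = meth_counts[["chrom", "pos"]].drop_duplicates().reset_index(drop=True)
    return SimBundle(cfg or SimConfig(), genes, cpg_sites, islands, meth_counts,
                     meth_samples, ipms, peaks, frip_counts, frip_samples,
                     chromatin, decay, truth)
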