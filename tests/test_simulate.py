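"""Generator contracts: counts, determinism, truth-manifest consistency and
null configurations."""
import warnings

import numpy as np
import pandas as pd
import pytest

from triomics.simulate import (
    SimConfig,
    allocate_truth_layers,
    simulate_all,
    simulate_chromatin,
    simulate_decay,
    simulate_genome,
    simulate_ipms,
    simulate_methylomes,
    read_bundle,
    write_bundle,
)


class TestConfig:
    def test_direct_subset_validation(self):
        with pytest.raises(ValueError):
            SimConfig(ipms_n_direct=50, ipms_n_enriched=20).validate()

    def test_effect_bounds(self):
        with pytest.raises(ValueError):
            SimConfig(dmr_effect=1.0).validate()
        SimConfig(dmr_effect=0.0).validate()   # null configuration is legal

    def test_targets_must_fit_genome(self):
        with pytest.raises(ValueError):
            SimConfig(frip_n_targets=500, n_genes=100).validate()

    def test_half_life_positivity(self):
        with pytest.raises(ValueError):
            SimConfig(decay_half_lives=(4.0, -1.0)).validate()


class TestGenome:
    def test_gene_count_and_chromosomes(self):
        cfg = SimConfig(seed=0)
        genes, sites, islands = simulate_genome(cfg)
        assert len(genes) == cfg.n_genes
        assert {g.interval.chrom for g in genes} <= {"chr1", "chr2"}
        assert len(islands) == cfg.n_genes

    def test_genes_non_overlapping(self):
        genes, _, _ = simulate_genome(SimConfig(seed=0))
        by_chrom = {}
        for g in genes:
            by_chrom.setdefault(g.interval.chrom, []).append(g.interval)
        for ivs in by_chrom.values():
            ivs.sort(key=lambda x: x.start)
            assert all(a.end <= b.start for a, b in zip(ivs, ivs[1:]))

    def test_density_limit_raises(self):
        with pytest.raises(ValueError):
            simulate_genome(SimConfig(n_genes=100, n_chrom=1, chrom_length=50_000))

    def test_islands_clustered_at_promoters(self):
        cfg = SimConfig(seed=0)
        genes, sites, islands = simulate_genome(cfg)
        isl = sites[sites["zone"] == "island"]
        assert (isl.groupby("gene_id").size() == cfg.n_cpg_per_promoter).all()


class TestLayers:
    def test_direct_and_rna_assisted_partition(self, default_bundle):
        t = default_bundle.truth
        assert not (t.direct_proteins & t.rna_assisted_proteins)

    def test_planted_dmr_count(self, default_bundle):
        cfg = default_bundle.cfg
        assert len(default_bundle.truth.dmr_regions) == (
            cfg.n_dmr_hypo + cfg.n_dmr_hyper + cfg.n_dmr_switching)

    def test_convergent_genes_in_every_layer(self, default_bundle):
        default_bundle.truth.check_consistency()
        assert len(default_bundle.truth.convergent_genes) == \
            default_bundle.cfg.n_convergent

    def test_null_ipms_has_no_planted_fold(self):
        cfg = SimConfig(seed=2, ipms_fc=1.0)
        genes, _, _ = simulate_genome(cfg)
        alloc = allocate_truth_layers(cfg, genes)
        table, truth = simulate_ipms(cfg, genes, alloc)
        piv = table[table["rnase"] == "minus"].pivot_table(
            index="protein_id", columns="condition", values="intensity")
        planted = sorted(truth["direct"] | truth["rna_assisted"])
        ratio = (piv.loc[planted, "IP"] / piv.loc[planted, "control"])
        assert abs(np.log2(ratio).mean()) < 0.2

    def test_decay_noise_free_construction(self):
        cfg = SimConfig(seed=0, ct_noise_sd=0.0, decay_half_lives=(4.0,))
        decay, truth = simulate_decay(cfg)
        assert truth == {"DECAY_T4": 4.0}
        g = decay[decay["time_h"] == 4.0]
        dct = g["ct_target"] - g["ct_reference"]
        g0 = decay[decay["time_h"] == 0.0]
        dct0 = (g0["ct_target"] - g0["ct_reference"]).iloc[0]
        # one extra cycle after one half-life -> exactly 50% remaining
        assert np.allclose(100 * 2.0 ** -(dct - dct0), 50.0)

    def test_chromatin_bivalent_genes_have_both_marks(self, default_bundle):
        peaks, states = simulate_chromatin(default_bundle.cfg,
                                           default_bundle.genes)
        genes = {g.gene_id: g for g in default_bundle.genes}
        for gid, st in states.items():
            tss = genes[gid].tss
            chrom = genes[gid].interval.chrom
            for mark, wanted in (("H3K4me3", st in ("active", "bivalent")),
                                 ("H3K27me3", st in ("repressed", "bivalent"))):
                for rep in (1, 2):
                    hit = any(iv.chrom == chrom and iv.start <= tss < iv.end
                              for iv in peaks[(mark, rep)])
                    assert hit == wanted


class TestDeterminism:
    def test_same_seed_byte_identical_files(self, tmp_path):
        cfg = SimConfig(seed=11, n_genes=40, chrom_length=250_000,
                        ipms_n_proteins=80, ipms_n_enriched=12,
                        ipms_n_direct=5, frip_n_targets=12, n_dmr_hypo=5,
                        n_dmr_hyper=6, n_dmr_switching=3, n_convergent=3)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            a, b = simulate_all(cfg), simulate_all(cfg)
        write_bundle(a, tmp_path / "a")
        write_bundle(b, tmp_path / "b")
        files_a = sorted(p.relative_to(tmp_path / "a")
                         for p in (tmp_path / "a").rglob("*") if p.is_file())
        files_b = sorted(p.relative_to(tmp_path / "b")
                         for p in (tmp_path / "b").rglob("*") if p.is_file())
        assert files_a == files_b
        for rel in files_a:
            assert (tmp_path / "a" / rel).read_bytes() == \
                (tmp_path / "b" / rel).read_bytes(), rel

    def test_bundle_roundtrip(self, tmp_path):
        cfg = SimConfig(seed=12, n_genes=40, chrom_length=250_000,
                        ipms_n_proteins=80, ipms_n_enriched=12,
                        ipms_n_direct=5, frip_n_targets=12, n_dmr_hypo=5,
                        n_dmr_hyper=6, n_dmr_switching=3, n_convergent=3)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            bundle = simulate_all(cfg)
        write_bundle(bundle, tmp_path)
        back = read_bundle(tmp_path)
        assert back.truth.convergent_genes == bundle.truth.convergent_genes
        assert len(back.genes) == len(bundle.genes)
        pd.testing.assert_frame_equal(
            back.frip_counts, bundle.frip_counts, check_dtype=False)
        merged = (back.meth_counts.groupby(["chrom", "pos"])["total"].sum()
                  .sort_index())
        orig = (bundle.meth_counts.groupby(["chrom", "pos"])["total"].sum()
                .sort_index())
        assert merged.equals(orig)
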