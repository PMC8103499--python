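"""The synthetic allopolyploid generator: limits, determinism, bookkeeping,
and planted statistical structure."""

import math

import numpy as np
import pandas as pd
import pytest

from dupevo import (ConfigurationError, SimulationConfig, simulate_genomes,
                    simulate_methylomes, simulate_population_variants)
from dupevo.popgen import dxy, filter_variants, nucleotide_diversity
from dupevo.synthetic import ALL_SPECIES, TETRAPLOID_SPECIES


class TestConfigValidation:
    @pytest.mark.parametrize("kwargs", [
        dict(fractionation_prob=-0.1),
        dict(fractionation_prob=1.5),
        dict(gene_length_bp=100),  # not a multiple of 3
        dict(n_scaffolds=0),
        dict(ssd_counts={"tandem": 300}, n_ancestral_genes=200),
        dict(ssd_counts={"weird_mode": 1}),
        dict(asym_offset=0.0),
    ])
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ConfigurationError):
            SimulationConfig(**kwargs).validate()

    def test_zero_accessions_rejected(self):
        cfg = SimulationConfig(seed=1, n_ancestral_genes=60, ancient_runs=0,
                               n_accessions={s: 0 for s in ALL_SPECIES})
        genomes, truth = simulate_genomes(cfg)
        with pytest.raises(ConfigurationError, match="accessions"):
            simulate_population_variants(genomes, truth, cfg)

    def test_too_many_dmgs_rejected(self):
        cfg = SimulationConfig(seed=1, n_ancestral_genes=60, n_dmg=500)
        genomes, truth = simulate_genomes(cfg)
        with pytest.raises(ConfigurationError, match="DMG"):
            simulate_methylomes(genomes, truth, cfg)


class TestNoLossLimit:
    def test_all_groups_triplet_without_loss_or_ssd(self):
        cfg = SimulationConfig(seed=2, n_ancestral_genes=80, fractionation_prob=0.0,
                               diploid_loss_prob=0.0,
                               ssd_counts={m: 0 for m in
                                           ("tandem", "proximal", "transposed",
                                            "dispersed", "segmental")},
                               ancient_runs=0, n_lineage_specific=0)
        genomes, truth = simulate_genomes(cfg)
        assert (truth.groups["category"] == "triplet").all()
        assert len(truth.groups) == 80
        assert len(genomes.genes["ginseng"]) == 160  # two copies per ancestral gene
        assert len(genomes.genes["notoginseng"]) == 80


class TestDeterminism:
    def test_identical_seed_identical_outputs(self):
        cfg = SimulationConfig(seed=5, n_ancestral_genes=60)
        a_g, a_t = simulate_genomes(cfg)
        b_g, b_t = simulate_genomes(SimulationConfig(seed=5, n_ancestral_genes=60))
        assert a_g.ref_seqs == b_g.ref_seqs
        assert a_g.species_seqs == b_g.species_seqs
        assert a_t.genes.equals(b_t.genes)
        assert [(x.gene_id_1, x.gene_id_2, x.similarity_score) for x in a_g.anchors] \
            == [(x.gene_id_1, x.gene_id_2, x.similarity_score) for x in b_g.anchors]

        pa = simulate_population_variants(a_g, a_t, cfg)
        pb = simulate_population_variants(b_g, b_t, cfg)
        for sp in ALL_SPECIES:
            for gid in pa.matrices[sp]:
                assert np.array_equal(pa.matrices[sp][gid].alleles,
                                      pb.matrices[sp][gid].alleles)

        ma = simulate_methylomes(a_g, a_t, cfg)
        mb = simulate_methylomes(b_g, b_t, cfg)
        for sp in ALL_SPECIES:
            assert np.array_equal(ma.matrices[sp].meth, mb.matrices[sp].meth)
            assert np.array_equal(ma.matrices[sp].total, mb.matrices[sp].total)


class TestBookkeeping:
    def test_gene_count_conservation(self, small_sim):
        cfg, genomes, truth = small_sim
        n_tet = len(genomes.genes["ginseng"])
        assert n_tet == 2 * cfg.n_ancestral_genes - truth.n_losses + truth.n_gains

    def test_every_tetraploid_gene_tagged_and_ranked(self, small_sim):
        _, genomes, _ = small_sim
        for scaffold, order in genomes.gene_order["ginseng"].items():
            for rank, gid in enumerate(order):
                g = genomes.genes["ginseng"][gid]
                assert g.subgenome in ("A", "B")
                assert g.rank == rank
                assert g.start >= 1

    def test_sequences_consistent_with_annotations(self, small_sim):
        cfg, genomes, _ = small_sim
        rng = np.random.default_rng(0)
        scaf = sorted(genomes.gene_order["ginseng"])[0]
        seq = genomes.scaffold_sequence("ginseng", scaf, rng)
        for gid in genomes.gene_order["ginseng"][scaf]:
            g = genomes.genes["ginseng"][gid]
            assert g.end <= len(seq)
            assert seq[g.start - 1:g.end] == genomes.ref_seqs["ginseng"][gid]


class TestLossModel:
    def test_singleton_fraction_matches_binomial_expectation(self):
        f, pd_loss, n = 0.3, 0.2, 1000
        cfg = SimulationConfig(seed=9, n_ancestral_genes=n, fractionation_prob=f,
                               diploid_loss_prob=pd_loss, ancient_runs=0,
                               n_lineage_specific=0,
                               ssd_counts={m: 0 for m in
                                           ("tandem", "proximal", "transposed",
                                            "dispersed", "segmental")})
        _, truth = simulate_genomes(cfg)
        # independent enumeration of the loss process: a family is a singleton
        # group when exactly one copy survives AND the diploid ortholog exists
        p_single = 2 * f * (1 - f) * (1 - pd_loss)
        obs = (truth.groups["category"] == "singleton").sum()
        sd = math.sqrt(n * p_single * (1 - p_single))
        assert abs(obs - n * p_single) <= 3 * sd


class TestPlantedDiversity:
    @pytest.fixture(scope="class")
    @staticmethod
    def pop():
        cfg = SimulationConfig(seed=4, n_ancestral_genes=250)
        genomes, truth = simulate_genomes(cfg)
        popdata = simulate_population_variants(genomes, truth, cfg)
        return cfg, genomes, truth, popdata

    def test_zero_pi_means_identical_haplotypes(self):
        cfg = SimulationConfig(seed=6, n_ancestral_genes=50, ancient_runs=0,
                               species_pi={s: 0.0 for s in ALL_SPECIES},
                               missing_rate=0.0)
        genomes, truth = simulate_genomes(cfg)
        popdata = simulate_population_variants(genomes, truth, cfg)
        for sp in ALL_SPECIES:
            for m in popdata.matrices[sp].values():
                assert nucleotide_diversity(filter_variants(m)) == 0.0

    def test_realized_pi_rank_order(self, pop):
        cfg, _, truth, _ = pop
        r = truth.realized_pi
        assert r["ginseng"] < r["quinquefolius"] < r["japonicus"]

    def test_unfiltered_diversity_inflated_by_noise_sites(self, pop):
        cfg, _, _, popdata = pop
        raw = np.mean([nucleotide_diversity(m)
                       for m in popdata.matrices["ginseng"].values()])
        filt = np.mean([nucleotide_diversity(filter_variants(m))
                        for m in popdata.matrices["ginseng"].values()])
        assert raw > filt  # the MQ/DP-failing planted records carry fake variation

    def test_doubling_a_branch_increases_dxy(self):
        def mean_dxy(scale):
            cfg = SimulationConfig(seed=8, n_ancestral_genes=80, ancient_runs=0,
                                   divergence_scale={"japonicus": scale})
            genomes, truth = simulate_genomes(cfg)
            popdata = simulate_population_variants(genomes, truth, cfg)
            shared = sorted(set(popdata.matrices["ginseng"])
                            & set(popdata.matrices["japonicus"]))
            return np.mean([dxy(popdata.matrices["ginseng"][g],
                                popdata.matrices["japonicus"][g]) for g in shared])
        assert mean_dxy(2.0) > mean_dxy(1.0)


class TestPlantedMethylation:
    def test_planted_asymmetry_shared_across_species(self):
        cfg = SimulationConfig(seed=10, n_ancestral_genes=120, asym_frac=0.3)
        genomes, truth = simulate_genomes(cfg)
        meth = simulate_methylomes(genomes, truth, cfg)
        assert len(truth.asym) > 0
        from dupevo.methylome import filter_sites, gene_methylation_levels
        levels = {}
        for sp in TETRAPLOID_SPECIES:
            lv = gene_methylation_levels(filter_sites(meth.matrices[sp]),
                                         contexts=("CG",))
            levels[sp] = lv.groupby("gene_id")["level"].mean()
        consistent = 0
        for r in truth.asym.itertuples():
            signs = {np.sign(levels[sp][r.gene_A] - levels[sp][r.gene_B])
                     for sp in TETRAPLOID_SPECIES}
            consistent += signs == {float(r.sign)}
        assert consistent / len(truth.asym) >= 0.95
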