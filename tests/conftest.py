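import numpy as np
import pytest

from dupevo import SimulationConfig, simulate_genomes
from dupevo.models import AnchorPair, GeneModel


@pytest.fixture(scope="session")
def small_sim():
    """A small but complete simulated complex shared across tests."""
    cfg = SimulationConfig(seed=12, n_ancestral_genes=200)
    genomes, truth = simulate_genomes(cfg)
    return cfg, genomes, truth


@pytest.fixture(scope="session")
def all_genes(small_sim):
    _, genomes, _ = small_sim
    merged = {}
    for taxon in genomes.genes:
        merged.update(genomes.genes[taxon])
    return merged


def make_genes(spec, taxon="tx", subgenome=None):
    """Build a rank-ordered gene dict from (gene_id, scaffold) pairs.

    Ranks and coordinates follow list order per scaffold; ``subgenome`` may
    be a dict gene_id -> tag.
    """
    out = {}
    counters = {}
    for gid, scaf in spec:
        rank = counters.get(scaf, 0)
        counters[scaf] = rank + 1
        sub = subgenome.get(gid) if isinstance(subgenome, dict) else subgenome
        out[gid] = GeneModel(gene_id=gid, scaffold=scaf, start=1000 * rank + 1,
                             end=1000 * rank + 500, strand="+", taxon=taxon,
                             subgenome=sub, rank=rank)
    return out


def anchors_from(pairs, score=50.0):
    return [AnchorPair(a, b, score) for a, b in pairs]


def random_genotype_matrix(rng, n_hap=6, n_sites=8, gene_length=50, missing=0.1,
                           gene_id="g", species="sp"):
    from dupevo.models import GenotypeMatrix

    bases = np.array(list("ACGT"))
    alle = bases[rng.integers(0, 4, size=(n_hap, n_sites))].astype("<U1")
    alle[rng.random((n_hap, n_sites)) < missing] = "N"
    positions = np.sort(rng.choice(np.arange(1, gene_length + 1), size=n_sites,
                                   replace=False))
    return GenotypeMatrix(
        gene_id=gene_id, species=species, alleles=alle, positions=positions,
        mq=rng.uniform(10, 60, n_sites), dp=rng.integers(0, 40, n_sites),
        gene_length_bp=gene_length,
        ref_seq="".join(bases[rng.integers(0, 4, gene_length)]))
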