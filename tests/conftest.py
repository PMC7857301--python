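import numpy as np
import pytest

from rescuesim.config_io import GenomeConfig, SimulationConfig
from rescuesim.genome import build_genome_map
from rescuesim.population import IdSource, Population, SiteTable


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def tiny_config():
    """A miniature but structurally complete parameterization."""
    return SimulationConfig(
        scenario="contraction", K_ancestral=40, K_endangered=10,
        genome=GenomeConfig(n_genes=50, n_chromosomes=5,
                            per_chromosome_gene_counts=[10] * 5,
                            gene_length_bp=100, mutation_rate_per_bp=1e-5),
        n_replicates=2, master_seed=7, max_generations=200)


@pytest.fixture
def tiny_map(tiny_config):
    return build_genome_map(tiny_config)


def build_population(genome_map, site_defs, genotypes, *, dfe=None,
                     dominance=None, K=None, seed=0, fixed_defs=()):
    """Construct a population with explicit genotypes.

    ``site_defs``: list of (gene_index, pos, s, h) tuples (position-sorted).
    ``genotypes``: per individual, a pair of iterables of site indices.
    ``fixed_defs``: optional list of (gene_index, pos, s, h) already-fixed
    mutations (folded into the fixed table and load).
    """
    from rescuesim.config_io import DominanceConfig
    from rescuesim.genome import DFEModel

    dfe = dfe if dfe is not None else DFEModel()
    dominance = dominance if dominance is not None else DominanceConfig()
    n = len(genotypes)
    pop = Population("test", genome_map, dfe, dominance,
                     K if K is not None else n,
                     np.random.default_rng(seed), IdSource())
    n_sites = len(site_defs)
    ids = np.arange(n_sites, dtype=np.int64)
    if n_sites:
        gene, pos, s, h = map(np.asarray, zip(*site_defs))
    else:
        gene = pos = s = h = np.empty(0)
    pop.sites = SiteTable(ids, gene, pos, s, h, np.zeros(n_sites, dtype=np.int64))
    n_words = max(1, (n_sites + 63) // 64)
    pop.geno = np.zeros((2 * n, n_words), dtype=np.uint64)
    for i, (hap0, hap1) in enumerate(genotypes):
        for which, hap in enumerate((hap0, hap1)):
            for site in hap:
                pop.geno[2 * i + which, site >> 6] |= np.uint64(1) << np.uint64(site & 63)
    pop.ind_ids = pop.id_source.take_individuals(n)
    pop.ages = np.zeros(n, dtype=np.int64)
    pop.w_cache = np.full(n, np.nan)
    pop.id_source.next_mutation = n_sites
    if fixed_defs:
        fgene, fpos, fs, fh = map(np.asarray, zip(*fixed_defs))
        fids = np.arange(len(fixed_defs)) + pop.id_source.next_mutation
        pop.id_source.next_mutation += len(fixed_defs)
        pop.fixed = SiteTable(fids, fgene, fpos, fs, fh,
                              np.zeros(len(fixed_defs), dtype=np.int64))
        pop.fixed_load = pop.fixed_load_from_table()
    pop._sorted_upto = n_sites
    return pop
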