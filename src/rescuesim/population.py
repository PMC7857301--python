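"""Demography core: diploid individuals, populations, and the
one-generation non-Wright-Fisher update.

Population size is emergent: every individual attempts one mating per
generation (one offspring per focal individual), and at the end of the
generation each individual survives a Bernoulli trial with probability
``min(1, w * K/N)`` — absolute fitness rescaled by density dependence.
Generations overlap: a fit individual can survive and reproduce repeatedly.

Fitness is multiplicative across sites: ``w = fixed_load * prod(1+s)`` over
homozygous and ``prod(1+h*s)`` over heterozygous mutations.  Mutations fixed
in a population are pruned from genotypes into a per-population table of
fixed sites whose product of ``(1+s)`` is the population's ``fixed_load``;
this representation change never alters any individual's fitness.  The full
fixed table (not just the scalar load) is retained so that migration between
populations with different fixation histories can re-materialize the
differing fixed sites as explicit genotypes (the masking of such sites in
migrant-native offspring is the heterosis that drives genetic rescue).

Internally genotypes are bitsets over segregating sites (see ``_engine``);
:class:`Individual` offers a per-individual object view for inspection,
sampling statistics, and small-scale operations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from . import _engine
from .genome import (DFEModel, GenomeMap, Mutation, assign_dominance,
                     draw_fitness_effects)

__all__ = [
    "IdSource", "SiteTable", "Individual", "Population", "EcologyDraws",
    "individual_fitness", "reproduce", "viability_selection", "prune_fixed",
    "catastrophe_mortality", "step_generation",
]


class IdSource:
    """Issues globally unique mutation and individual ids within a replicate."""

    def __init__(self, first_mutation: int = 0, first_individual: int = 0):
        self.next_mutation = int(first_mutation)
        self.next_individual = int(first_individual)

    def take_mutations(self, n: int) -> np.ndarray:
        out = np.arange(self.next_mutation, self.next_mutation + n, dtype=np.int64)
        self.next_mutation += n
        return out

    def take_individuals(self, n: int) -> np.ndarray:
        out = np.arange(self.next_individual, self.next_individual + n, dtype=np.int64)
        self.next_individual += n
        return out


class SiteTable:
    """Parallel per-site attribute arrays (one entry per tracked mutation)."""

    _FIELDS = ("ids", "gene", "pos", "s", "h", "origin", "log_hom", "log_het")
    __slots__ = _FIELDS

    def __init__(self, ids, gene, pos, s, h, origin,
                 log_hom=None, log_het=None):
        self.ids = np.asarray(ids, dtype=np.int64)
        self.gene = np.asarray(gene, dtype=np.int64)
        self.pos = np.asarray(pos, dtype=np.int64)
        self.s = np.asarray(s, dtype=np.float64)
        self.h = np.asarray(h, dtype=np.float64)
        self.origin = np.asarray(origin, dtype=np.int64)
        if log_hom is None:
            with np.errstate(divide="ignore"):
                log_hom = np.log1p(self.s)
                log_het = np.log1p(self.h * self.s)
        self.log_hom = log_hom
        self.log_het = log_het

    @classmethod
    def empty(cls) -> "SiteTable":
        z = np.empty(0, dtype=np.int64)
        return cls(z, z, z, z.astype(float), z.astype(float), z)

    def __len__(self) -> int:
        return len(self.ids)

    def subset(self, index) -> "SiteTable":
        return SiteTable(*(getattr(self, f)[index] for f in self._FIELDS))

    @staticmethod
    def concat(tables: Sequence["SiteTable"]) -> "SiteTable":
        return SiteTable(*(np.concatenate([getattr(t, f) for t in tables])
                           for f in SiteTable._FIELDS))

    def position_order(self) -> np.ndarray:
        return np.lexsort((self.ids, self.pos))

    def mutation(self, i: int) -> Mutation:
        return Mutation(id=int(self.ids[i]), gene_index=int(self.gene[i]),
                        bp_position=int(self.pos[i]), s=float(self.s[i]),
                        h=float(self.h[i]), origin_generation=int(self.origin[i]))


def _n_words(n_sites: int) -> int:
    return max(1, (n_sites + 63) >> 6)


@dataclass
class EcologyDraws:
    """One generation's ecological inputs for the endangered population."""
    K_next: Optional[int] = None
    catastrophe_p: float = 0.0


class Individual:
    """Object view of one diploid individual (indexes into the population)."""

    def __init__(self, pop: "Population", index: int):
        self._pop = pop
        self._index = int(index)

    @property
    def id(self) -> int:
        return int(self._pop.ind_ids[self._index])

    @property
    def age(self) -> int:
        return int(self._pop.ages[self._index])

    def haplotype_site_indices(self, which: int) -> np.ndarray:
        """Indices (into the population's site table) carried on haplotype 0/1."""
        pop = self._pop
        row = pop.geno[2 * self._index + which]
        bits = np.unpackbits(row.view(np.uint8), bitorder="little")[: len(pop.sites)]
        return np.flatnonzero(bits)

    @property
    def haplotype_pair(self):
        pop = self._pop
        return tuple(
            [pop.sites.mutation(i) for i in self.haplotype_site_indices(which)]
            for which in (0, 1))

    @property
    def hom_site_indices(self) -> np.ndarray:
        a, b = (self.haplotype_site_indices(w) for w in (0, 1))
        return np.intersect1d(a, b, assume_unique=True)

    @property
    def het_site_indices(self) -> np.ndarray:
        a, b = (self.haplotype_site_indices(w) for w in (0, 1))
        return np.setxor1d(a, b, assume_unique=True)

    @property
    def cached_fitness(self) -> Optional[float]:
        w = self._pop.w_cache[self._index]
        return None if np.isnan(w) else float(w)


class Population:
    """A diploid population plus its carrying capacity and fixed-load state."""

    def __init__(self, label: str, genome_map: GenomeMap, dfe: DFEModel,
                 dominance, K_base: int, rng: np.random.Generator,
                 id_source: Optional[IdSource] = None):
        self.label = label
        self.genome_map = genome_map
        self.dfe = dfe
        self.dominance = dominance
        self.K_base = int(K_base)
        self.K_current = int(K_base)
        self.generation = 0
        self.rng = rng
        self.id_source = id_source if id_source is not None else IdSource()
        self.sites = SiteTable.empty()
        self.fixed = SiteTable.empty()
        self.fixed_load = 1.0
        self.geno = np.zeros((0, 1), dtype=np.uint64)
        self.ind_ids = np.empty(0, dtype=np.int64)
        self.ages = np.empty(0, dtype=np.int64)
        self.w_cache = np.empty(0, dtype=np.float64)
        self._sorted_upto = 0  # columns beyond this index are an unsorted tail

    # ------------------------------------------------------------------ basics

    @property
    def n(self) -> int:
        return len(self.ind_ids)

    @property
    def extinct(self) -> bool:
        return self.n < 1

    @classmethod
    def founders(cls, n: int, label: str, genome_map: GenomeMap, dfe: DFEModel,
                 dominance, K_base: int, rng: np.random.Generator,
                 id_source: Optional[IdSource] = None) -> "Population":
        pop = cls(label, genome_map, dfe, dominance, K_base, rng, id_source)
        pop.geno = np.zeros((2 * n, 1), dtype=np.uint64)
        pop.ind_ids = pop.id_source.take_individuals(n)
        pop.ages = np.zeros(n, dtype=np.int64)
        pop.w_cache = np.full(n, np.nan)
        return pop

    def individual(self, index: int) -> Individual:
        return Individual(self, index)

    def individuals(self):
        return [Individual(self, i) for i in range(self.n)]

    def _keep_individuals(self, keep: np.ndarray) -> None:
        idx = np.flatnonzero(keep) if keep.dtype == bool else np.asarray(keep)
        rows = np.empty(2 * len(idx), dtype=np.int64)
        rows[0::2] = 2 * idx
        rows[1::2] = 2 * idx + 1
        self.geno = self.geno[rows]
        self.ind_ids = self.ind_ids[idx]
        self.ages = self.ages[idx]
        self.w_cache = self.w_cache[idx]

    def subsample(self, k: int, label: str, K_base: int,
                  rng: np.random.Generator) -> "Population":
        """Copy-split: a new population founded by ``k`` individuals sampled
        uniformly without replacement.  Sites fixed or lost within the sample
        are pruned immediately."""
        if k > self.n:
            raise ValueError(f"cannot sample {k} individuals from N={self.n}")
        idx = np.sort(rng.choice(self.n, size=k, replace=False))
        new = Population(label, self.genome_map, self.dfe, self.dominance,
                         K_base, rng, self.id_source)
        new.generation = self.generation
        rows = np.empty(2 * k, dtype=np.int64)
        rows[0::2] = 2 * idx
        rows[1::2] = 2 * idx + 1
        new.geno = self.geno[rows].copy()
        new.ind_ids = self.ind_ids[idx].copy()
        new.ages = self.ages[idx].copy()
        new.w_cache = self.w_cache[idx].copy()
        new.sites = self.sites.subset(slice(None))
        new.fixed = self.fixed.subset(slice(None))
        new.fixed_load = self.fixed_load
        new._sorted_upto = self._sorted_upto
        prune_fixed(new)
        return new

    def _ensure_sorted(self) -> None:
        if self._sorted_upto < len(self.sites):
            prune_fixed(self)

    def fixed_load_from_table(self) -> float:
        with np.errstate(divide="ignore"):
            return float(np.exp(np.sum(np.log1p(self.fixed.s))))

    # ------------------------------------------------------- migrant transfer

    def absorb_migrants(self, source: "Population", migrant_index: np.ndarray) -> int:
        """Copy the listed source individuals into this population.

        The two populations may have diverged in which mutations they carry
        as fixed.  Sites fixed here but not in the source (and vice versa)
        are re-materialized as explicit genotypes on the union site table, so
        heterosis in admixed offspring is represented exactly.  The source
        population is left unchanged.  Returns the number of migrants added.
        """
        migrant_index = np.asarray(migrant_index, dtype=np.int64)
        self._ensure_sorted()
        source._ensure_sorted()
        here_fixed_ids = self.fixed.ids
        src_fixed_ids = source.fixed.ids
        shared_mask = np.isin(here_fixed_ids, src_fixed_ids)
        here_only = self.fixed.subset(~shared_mask)
        src_only = source.fixed.subset(~np.isin(src_fixed_ids, here_fixed_ids))

        parts = [self.sites, here_only, source.sites, src_only]
        merged = SiteTable.concat(parts)
        uniq_ids, first = np.unique(merged.ids, return_index=True)
        union = merged.subset(first)          # unique by id, sorted by id
        order = union.position_order()
        union = union.subset(order)
        # column index of a given mutation id in the union table
        id_order = np.argsort(union.ids, kind="stable")
        sorted_ids = union.ids[id_order]

        def col_of(ids):
            return id_order[np.searchsorted(sorted_ids, ids)]

        W_new = _n_words(len(union))
        # natives: remap + re-materialize sites fixed here but not in source
        old2new = col_of(self.sites.ids) if len(self.sites) else np.empty(0, np.int64)
        native = _engine.repack(self.geno, old2new, W_new, _engine.DB_TABLE)
        for c in col_of(here_only.ids):
            native[:, c >> 6] |= np.uint64(1) << np.uint64(c & 63)
        # migrants: remap their source genotypes + source-only fixed sites
        rows = np.empty(2 * len(migrant_index), dtype=np.int64)
        rows[0::2] = 2 * migrant_index
        rows[1::2] = 2 * migrant_index + 1
        src_old2new = (col_of(source.sites.ids) if len(source.sites)
                       else np.empty(0, np.int64))
        migrant = _engine.repack(np.ascontiguousarray(source.geno[rows]),
                                 src_old2new, W_new, _engine.DB_TABLE)
        for c in col_of(src_only.ids):
            migrant[:, c >> 6] |= np.uint64(1) << np.uint64(c & 63)

        self.sites = union
        self.fixed = self.fixed.subset(shared_mask)
        self.fixed_load = self.fixed_load_from_table()
        self.geno = np.vstack([native, migrant])
        self.ind_ids = np.concatenate([self.ind_ids, source.ind_ids[migrant_index]])
        self.ages = np.concatenate([self.ages, source.ages[migrant_index]])
        # a migrant's total fitness is representation-invariant, so its source
        # cache (if any) remains valid here
        self.w_cache = np.concatenate([self.w_cache, source.w_cache[migrant_index]])
        self._sorted_upto = len(union)
        return len(migrant_index)


# ---------------------------------------------------------------- operations

def individual_fitness(ind: Individual, fixed_load: Optional[float] = None) -> float:
    """Multiplicative absolute fitness of one individual.

    ``w = fixed_load * prod(1+s)`` over homozygous sites ``* prod(1+h*s)``
    over heterozygous sites, clamped to [0, 1].  Computed by direct products
    over the individual's site lists (independent of the engine's summed-log
    kernel).
    """
    pop = ind._pop
    if fixed_load is None:
        fixed_load = pop.fixed_load
    st = pop.sites
    hom = ind.hom_site_indices
    het = ind.het_site_indices
    w = fixed_load * np.prod(1.0 + st.s[hom]) * np.prod(1.0 + st.h[het] * st.s[het])
    return float(min(max(w, 0.0), 1.0))


def reproduce(pop: Population, rng: Optional[np.random.Generator] = None):
    """One round of random mating: every individual draws a mate uniformly
    from the population (self included, as in the standard non-Wright-Fisher
    recipe — a hermaphrodite can self, so a single survivor can refound the
    population) and leaves one offspring whose gametes undergo recombination
    and new mutation.  Offspring join the population with age 0.  Returns
    the list of offspring views (empty when N = 0)."""
    n_children = _reproduce(pop, rng)
    n = pop.n
    return [Individual(pop, i) for i in range(n - n_children, n)]


def _reproduce(pop: Population, rng: Optional[np.random.Generator] = None) -> int:
    if pop.n < 1:
        return 0
    rng = pop.rng if rng is None else rng
    pop._ensure_sorted()
    gm = pop.genome_map
    n = pop.n
    S_old = len(pop.sites)
    W_old = pop.geno.shape[1]

    mates = rng.integers(0, n, size=n)
    parent_idx = np.empty(2 * n, dtype=np.int64)
    parent_idx[0::2] = np.arange(n)
    parent_idx[1::2] = mates

    start_bits = rng.integers(0, 1 << gm.n_chromosomes, size=2 * n, dtype=np.uint64)
    if gm.n_adjacencies > 0 and gm.inter_gene_recomb_rate > 0:
        k_cross = rng.binomial(gm.n_adjacencies, gm.inter_gene_recomb_rate,
                               size=2 * n).astype(np.int64)
    else:
        k_cross = np.zeros(2 * n, dtype=np.int64)
    cross_off = np.zeros(2 * n + 1, dtype=np.int64)
    np.cumsum(k_cross, out=cross_off[1:])
    cross_u = rng.random(int(cross_off[-1]))
    # first site index per gene (sites are gene-sorted): O(S + n_genes)
    gene_first_site = np.zeros(gm.n_genes + 1, dtype=np.int64)
    np.cumsum(np.bincount(pop.sites.gene, minlength=gm.n_genes),
              out=gene_first_site[1:])
    span_ptr, span_chrom, span_mask = _engine.build_span_table(
        gene_first_site[gm.chrom_first_gene], W_old)
    gametes = np.empty((2 * n, W_old), dtype=np.uint64)
    _engine.make_gametes(pop.geno, parent_idx, start_bits, k_cross, cross_u,
                         cross_off, gm.adj_to_gene, gm.chrom_first_gene,
                         gene_first_site, span_ptr, span_chrom, span_mask,
                         gametes)

    # de novo mutation on each gamete
    mu = gm.mutation_rate_per_bp * gm.total_coding_bp
    n_new = (rng.poisson(mu, size=2 * n) if mu > 0
             else np.zeros(2 * n, dtype=np.int64))
    M = int(n_new.sum())
    if M:
        mpos = rng.integers(1, gm.total_coding_bp + 1, size=M)
        ms = draw_fitness_effects(rng, pop.dfe, M)
        mh = np.atleast_1d(assign_dominance(ms, pop.dominance))
        new_sites = SiteTable(pop.id_source.take_mutations(M),
                              gm.gene_of_position(mpos), mpos, ms, mh,
                              np.full(M, pop.generation, dtype=np.int64))
        pop.sites = SiteTable.concat([pop.sites, new_sites])

    W_new = _n_words(len(pop.sites))
    geno = np.zeros((4 * n, W_new), dtype=np.uint64)
    geno[: 2 * n, :W_old] = pop.geno
    geno[2 * n:, :W_old] = gametes
    if M:
        gamete_of_mut = np.repeat(np.arange(2 * n), n_new)
        _engine.set_bits(geno, 2 * n + gamete_of_mut,
                         S_old + np.arange(M, dtype=np.int64))
    pop.geno = geno
    pop.ind_ids = np.concatenate([pop.ind_ids, pop.id_source.take_individuals(n)])
    pop.ages = np.concatenate([pop.ages, np.zeros(n, dtype=np.int64)])
    pop.w_cache = np.concatenate([pop.w_cache, np.full(n, np.nan)])
    # appended mutation columns form an unsorted tail until the next prune
    return n


def catastrophe_mortality(pop: Population, p: float,
                          rng: Optional[np.random.Generator] = None) -> None:
    """Each individual dies independently with probability ``p``."""
    if p <= 0 or pop.n == 0:
        return
    rng = pop.rng if rng is None else rng
    pop._keep_individuals(rng.random(pop.n) >= p)


def prune_fixed(pop: Population) -> Population:
    """Remove mutations carried on every haplotype from all genotypes and
    fold their ``(1+s)`` into the population's fixed load; drop lost sites;
    restore the sorted-column invariant.  Idempotent; never changes any
    individual's total fitness."""
    S = len(pop.sites)
    if pop.n == 0:
        return pop
    counts = (_engine.count_alleles(pop.geno, S, _engine.DB_TABLE)
              if S else np.empty(0, dtype=np.int64))
    fixed = counts == 2 * pop.n
    keep = ~fixed & (counts > 0)
    if fixed.any():
        pop.fixed = SiteTable.concat([pop.fixed, pop.sites.subset(fixed)])
        pop.fixed_load = pop.fixed_load_from_table()
    idx_keep = np.flatnonzero(keep)
    kept = pop.sites.subset(idx_keep)
    order = kept.position_order()
    old2new = np.full(S, -1, dtype=np.int64)
    old2new[idx_keep[order]] = np.arange(len(idx_keep))
    pop.sites = kept.subset(order)
    pop.geno = _engine.repack(pop.geno, old2new, _n_words(len(pop.sites)),
                              _engine.DB_TABLE)
    pop._sorted_upto = len(pop.sites)
    return pop


def viability_selection(pop: Population,
                        rng: Optional[np.random.Generator] = None,
                        n_density: Optional[int] = None) -> None:
    """Density-dependent viability: each individual survives with probability
    ``min(1, w * K_current/N)``; survivors' ages increment.

    ``N`` is the post-reproduction cohort size (parents plus offspring).
    When catastrophe mortality strikes between reproduction and viability,
    the caller passes that pre-catastrophe count as ``n_density``:
    catastrophe deaths do not relax the density term within the same
    generation.
    """
    if pop.n == 0:
        return
    rng = pop.rng if rng is None else rng
    if n_density is None:
        n_density = pop.n
    need = np.flatnonzero(np.isnan(pop.w_cache))
    if len(need):
        raw = np.empty(pop.n)
        _engine.pair_log_fitness(pop.geno, need, pop.sites.log_hom,
                                 pop.sites.log_het, _engine.DB_TABLE, raw)
        pop.w_cache[need] = np.clip(raw[need] * pop.fixed_load, 0.0, 1.0)
    p = np.minimum(1.0, pop.w_cache * (pop.K_current / n_density))
    survive = rng.random(pop.n) < p
    pop.ages += 1
    pop._keep_individuals(survive)


def step_generation(pop: Population, ecology_draws: Optional[EcologyDraws] = None,
                    rng: Optional[np.random.Generator] = None) -> Population:
    """Advance one generation.

    Phases, in order: (1) set this generation's realized carrying capacity
    (ecology draws apply to the endangered population only; otherwise the
    configured K); (2) reproduction with mutation; (3) catastrophe mortality
    on parents and offspring alike; (4) fixed-mutation pruning; (5)
    density-dependent viability selection.  An empty output is the terminal
    (extinct) state; a lone survivor can still self and recover.
    """
    draws = ecology_draws if ecology_draws is not None else EcologyDraws()
    pop.K_current = int(draws.K_next) if draws.K_next is not None else pop.K_base
    _reproduce(pop, rng)
    n_cohort = pop.n  # density term sees the full post-reproduction cohort
    catastrophe_mortality(pop, draws.catastrophe_p, rng)
    prune_fixed(pop)
    viability_selection(pop, rng, n_density=n_cohort)
    pop.generation += 1
    return pop
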