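"""Genome model: coordinate map, fitness-effect (DFE) sampling, dominance,
and gamete formation.

The simulated genome is coding sequence only: ``n_genes`` genes of fixed
length laid end to end on each autosome, mirroring the exome of a wolf-like
organism.  There is no recombination within a gene, a small recombination
fraction between adjacent genes on the same chromosome, and free
recombination between chromosomes.  All physical coordinates used by the
package (mutation positions, runs of homozygosity) live on this
coding-contiguous coordinate system; under the defaults 1 Mb of sequence
corresponds to ~667 consecutive genes.

New mutations are neutral or deleterious.  Deleterious selection
coefficients are drawn from a gamma distribution of fitness effects
(defaults estimated from a large human sample: shape 0.186, mean |s|
0.0131), and dominance follows one of three schemes:

* ``hs_relationship`` — h(s) = 1 / (2 (1 + C |s|)) with C = 7071.07, so the
  most deleterious mutations are the most recessive;
* ``hmix`` — a two-class approximation of the above: h = 0.25 for
  s >= -0.01, h = 0 for s < -0.01;
* ``fixed`` — one dominance coefficient for every deleterious mutation.

Neutral mutations carry h = 0.5 by convention (h never enters fitness for
s = 0).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "DOG_AUTOSOME_MB",
    "Mutation",
    "DFEModel",
    "GenomeMap",
    "default_chromosome_gene_counts",
    "build_genome_map",
    "draw_fitness_effect",
    "draw_fitness_effects",
    "assign_dominance",
    "make_gamete",
    "mutate_gamete",
]

#: Approximate physical lengths (Mb) of the 38 dog autosomes (CanFam3.1),
#: used to apportion genes among chromosomes in the default genome map.
DOG_AUTOSOME_MB = np.array([
    122.7, 85.4, 91.9, 88.3, 88.9, 77.6, 80.9, 74.3, 61.0, 69.3,
    74.4, 72.5, 63.4, 60.9, 64.2, 59.6, 64.3, 55.9, 53.5, 58.2,
    50.8, 61.4, 52.3, 47.7, 51.6, 39.0, 45.9, 41.2, 41.8, 40.2,
    39.9, 38.8, 31.4, 42.1, 26.5, 30.8, 30.9, 23.9,
])


@dataclass(frozen=True)
class Mutation:
    """A single mutation.

    ``s`` is the selection coefficient acting on homozygote fitness (factor
    ``1 + s``); heterozygotes experience ``1 + h*s``.  ``bp_position`` is the
    1-based position on the genome-wide coding-contiguous coordinate.
    """

    id: int
    gene_index: int
    bp_position: int
    s: float
    h: float
    origin_generation: int = 0

    def __post_init__(self):
        if not (-1.0 <= self.s <= 0.0):
            raise ValueError(f"selection coefficient out of range: {self.s}")


@dataclass(frozen=True)
class DFEModel:
    """Mixture DFE: neutral with probability ``1 - p_deleterious``, otherwise
    s = -min(1, X) with X gamma-distributed.

    ``truncation`` converts one deleterious class into neutral mutations
    (the overall mutation rate is unchanged):

    * ``"strong_only"``   — deleterious draws with s >= -0.01 become neutral;
    * ``"weak_moderate_only"`` — deleterious draws with s < -0.01 become
      neutral.
    """

    p_deleterious: float = 2.31 / 3.31
    gamma_shape: float = 0.186
    gamma_mean_abs_s: float = 0.01314833
    truncation: str = "none"
    strong_threshold: float = -0.01

    def __post_init__(self):
        if not (0.0 <= self.p_deleterious <= 1.0):
            raise ValueError("p_deleterious must lie in [0, 1]")
        if self.truncation not in ("none", "strong_only", "weak_moderate_only"):
            raise ValueError(f"unknown truncation mode: {self.truncation!r}")

    @classmethod
    def from_ratio(cls, deleterious_to_neutral_ratio: float, **kwargs) -> "DFEModel":
        r = deleterious_to_neutral_ratio
        if r < 0:
            raise ValueError("deleterious_to_neutral_ratio must be >= 0")
        return cls(p_deleterious=r / (1.0 + r), **kwargs)


def draw_fitness_effects(rng: np.random.Generator, dfe: DFEModel, n: int) -> np.ndarray:
    """Vector of ``n`` selection coefficients (0 for neutral mutations)."""
    s = np.zeros(n)
    deleterious = rng.random(n) < dfe.p_deleterious
    k = int(deleterious.sum())
    if k:
        scale = dfe.gamma_mean_abs_s / dfe.gamma_shape
        x = np.minimum(rng.gamma(dfe.gamma_shape, scale, size=k), 1.0)
        s[deleterious] = -x
    if dfe.truncation == "strong_only":
        s[s >= dfe.strong_threshold] = 0.0
    elif dfe.truncation == "weak_moderate_only":
        s[s < dfe.strong_threshold] = 0.0
    return s


def draw_fitness_effect(rng: np.random.Generator, dfe: DFEModel) -> float:
    """Single draw from the DFE (see :func:`draw_fitness_effects`)."""
    return float(draw_fitness_effects(rng, dfe, 1)[0])


def assign_dominance(s, model) -> np.ndarray | float:
    """Dominance coefficient(s) for selection coefficient(s) ``s``.

    ``model`` is any object with the fields of the dominance config block
    (``model``, ``fixed_h``, ``hs_scale_constant``, ``hmix_strong_threshold``,
    ``hmix_weak_h``, ``hmix_strong_h``).  Neutral mutations (s = 0) always
    receive h = 0.5.
    """
    arr = np.asarray(s, dtype=float)
    if np.any(arr > 0) or np.any(arr < -1):
        raise ValueError("selection coefficients must lie in [-1, 0]")
    if model.model == "hs_relationship":
        h = 0.5 / (1.0 + model.hs_scale_constant * np.abs(arr))
    elif model.model == "hmix":
        h = np.where(arr >= model.hmix_strong_threshold,
                     model.hmix_weak_h, model.hmix_strong_h)
    elif model.model == "fixed":
        h = np.full_like(arr, model.fixed_h)
    else:
        raise ValueError(f"unknown dominance model: {model.model!r}")
    h = np.where(arr == 0.0, 0.5, h)
    if np.ndim(s) == 0:
        return float(h)
    return h


def default_chromosome_gene_counts(n_genes: int, weights=None) -> np.ndarray:
    """Apportion ``n_genes`` among chromosomes proportionally to ``weights``
    (default: dog autosome lengths), using the largest-remainder method so
    the counts sum exactly to ``n_genes``."""
    w = DOG_AUTOSOME_MB if weights is None else np.asarray(weights, dtype=float)
    if np.any(w < 0) or w.sum() <= 0:
        raise ValueError("weights must be non-negative with positive sum")
    quota = n_genes * w / w.sum()
    counts = np.floor(quota).astype(np.int64)
    remainder = n_genes - int(counts.sum())
    if remainder:
        # stable: ties broken by lower chromosome index
        order = np.argsort(-(quota - counts), kind="stable")
        counts[order[:remainder]] += 1
    return counts


@dataclass(frozen=True)
class GenomeMap:
    """Physical layout of the simulated coding genome.

    Gene ``k`` (0-based, genome-wide) occupies base pairs
    ``[k*L + 1, (k+1)*L]`` on the 1-based genome-wide coordinate, where
    ``L = gene_length_bp``.  Chromosome boundaries fall between gene blocks.
    """

    gene_length_bp: int
    chrom_gene_counts: np.ndarray
    inter_gene_recomb_rate: float = 1e-3
    mutation_rate_per_bp: float = 1e-8
    chrom_first_gene: np.ndarray = field(init=False, repr=False)
    adj_to_gene: np.ndarray = field(init=False, repr=False)

    def __post_init__(self):
        counts = np.asarray(self.chrom_gene_counts, dtype=np.int64)
        if np.any(counts < 0):
            raise ValueError("per-chromosome gene counts must be >= 0")
        object.__setattr__(self, "chrom_gene_counts", counts)
        first = np.concatenate([[0], np.cumsum(counts)])
        object.__setattr__(self, "chrom_first_gene", first)
        # crossover "adjacencies": every gene that has a same-chromosome
        # predecessor; a crossover at adjacency a occurs *before* gene
        # adj_to_gene[a].
        all_genes = np.arange(1, self.n_genes, dtype=np.int64)
        boundary = np.isin(all_genes, first[1:-1])
        object.__setattr__(self, "adj_to_gene", all_genes[~boundary])

    @property
    def n_genes(self) -> int:
        return int(self.chrom_gene_counts.sum())

    @property
    def n_chromosomes(self) -> int:
        return len(self.chrom_gene_counts)

    @property
    def total_coding_bp(self) -> int:
        return self.n_genes * self.gene_length_bp

    @property
    def n_adjacencies(self) -> int:
        return len(self.adj_to_gene)

    @property
    def chrom_bp_offsets(self) -> np.ndarray:
        """Genome-wide bp offset of each chromosome start (length nc+1)."""
        return self.chrom_first_gene * self.gene_length_bp

    def chrom_labels(self):
        return [f"chr{i + 1}" for i in range(self.n_chromosomes)]

    def gene_of_position(self, pos) -> np.ndarray:
        """0-based genome-wide gene index of 1-based bp position(s)."""
        return (np.asarray(pos, dtype=np.int64) - 1) // self.gene_length_bp

    def chrom_of_gene(self, gene) -> np.ndarray:
        return np.searchsorted(self.chrom_first_gene, np.asarray(gene), side="right") - 1

    def to_chrom_coords(self, pos):
        """Map genome-wide 1-based positions to (chrom index, local 1-based pos)."""
        pos = np.asarray(pos, dtype=np.int64)
        chrom = self.chrom_of_gene(self.gene_of_position(pos))
        local = pos - self.chrom_bp_offsets[chrom]
        return chrom, local

    def expected_crossovers_per_gamete(self) -> float:
        return self.n_adjacencies * self.inter_gene_recomb_rate


def build_genome_map(config) -> GenomeMap:
    """Build the genome map from a configuration object (its ``genome`` block).

    Deterministic given the configuration.  Raises if the per-chromosome gene
    counts do not sum to ``n_genes``.
    """
    g = config.genome
    if g.per_chromosome_gene_counts is not None:
        counts = np.asarray(g.per_chromosome_gene_counts, dtype=np.int64)
        if len(counts) != g.n_chromosomes:
            raise ValueError("per_chromosome_gene_counts length != n_chromosomes")
        if int(counts.sum()) != g.n_genes:
            raise ValueError(
                f"per_chromosome_gene_counts sums to {int(counts.sum())}, "
                f"expected n_genes={g.n_genes}")
    else:
        counts = default_chromosome_gene_counts(
            g.n_genes, DOG_AUTOSOME_MB[: g.n_chromosomes])
    return GenomeMap(
        gene_length_bp=g.gene_length_bp,
        chrom_gene_counts=counts,
        inter_gene_recomb_rate=g.inter_gene_recomb_rate,
        mutation_rate_per_bp=g.mutation_rate_per_bp,
    )


def _gene_chooser(genome_map: GenomeMap, rng: np.random.Generator) -> np.ndarray:
    """Per-gene parental-haplotype chooser (0/1) for one gamete.

    Each chromosome starts from a uniformly chosen haplotype; between each
    pair of adjacent genes the chooser switches with probability
    ``inter_gene_recomb_rate``; chromosomes assort independently.
    """
    gm = genome_map
    toggles = np.zeros(gm.n_genes, dtype=np.int64)
    # chromosome starts: fresh uniform state (implemented as a toggle stream)
    starts = rng.integers(0, 2, size=gm.n_chromosomes)
    switch = rng.random(gm.n_adjacencies) < gm.inter_gene_recomb_rate
    toggles[gm.chrom_first_gene[:-1]] = starts
    np.add.at(toggles, gm.adj_to_gene[switch], 1)
    state = np.zeros(gm.n_genes, dtype=np.int64)
    # cumulative parity, reset at chromosome boundaries by absolute starts
    for c in range(gm.n_chromosomes):
        lo, hi = gm.chrom_first_gene[c], gm.chrom_first_gene[c + 1]
        if hi > lo:
            t = toggles[lo:hi].copy()
            t[0] = starts[c]
            state[lo:hi] = np.cumsum(t) % 2
    return state


def make_gamete(parent, genome_map: GenomeMap, rng: np.random.Generator):
    """Form one gamete from ``parent`` (anything exposing ``haplotype_pair``
    as two sequences of :class:`Mutation`).

    Returns the gamete's mutations sorted by position.
    """
    hap0, hap1 = parent.haplotype_pair
    chooser = _gene_chooser(genome_map, rng)
    out = [m for m in hap0 if chooser[m.gene_index] == 0]
    out += [m for m in hap1 if chooser[m.gene_index] == 1]
    out.sort(key=lambda m: (m.bp_position, m.id))
    return out


def mutate_gamete(haplotype, genome_map: GenomeMap, dfe: DFEModel, dominance,
                  rng: np.random.Generator, generation: int = 0,
                  next_id: int = 0):
    """Add new mutations to a gamete.

    The number of new mutations is Poisson with mean
    ``mutation_rate_per_bp * total_coding_bp``; positions are uniform over
    the coding genome (multiple hits at one bp are allowed as distinct
    mutations); effects come from the DFE and the dominance model.  Returns
    ``(new_haplotype, next_id)``.
    """
    n_new = rng.poisson(genome_map.mutation_rate_per_bp * genome_map.total_coding_bp)
    if n_new == 0:
        return list(haplotype), next_id
    pos = rng.integers(1, genome_map.total_coding_bp + 1, size=n_new)
    s = draw_fitness_effects(rng, dfe, n_new)
    h = np.atleast_1d(assign_dominance(s, dominance))
    genes = genome_map.gene_of_position(pos)
    new = [Mutation(id=next_id + i, gene_index=int(genes[i]),
                    bp_position=int(pos[i]), s=float(s[i]), h=float(h[i]),
                    origin_generation=generation)
           for i in range(n_new)]
    out = sorted(list(haplotype) + new, key=lambda m: (m.bp_position, m.id))
    return out, next_id + n_new
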