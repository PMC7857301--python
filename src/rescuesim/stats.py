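"""Per-generation population summaries and cross-replicate comparison.

Summaries mirror what a conservation-genomics study tracks: observed
per-bp heterozygosity, the genomic inbreeding coefficient F_ROH (fraction of
the genome in runs of homozygosity longer than 1 Mb, on the coding-contiguous
coordinate), mean absolute fitness, and per-individual deleterious allele
counts binned by selection coefficient:

    weak        -0.001 < s <= -0.00001
    moderate    -0.01  < s <= -0.001
    strong      s < -0.01
    very strong s < -0.05   (a subset of strong)

Counts are allele copies (heterozygote 1, homozygote 2) over segregating
sites, averaged over a sample of individuals (default 30).
"""

from __future__ import annotations

from dataclasses import dataclass, fields
from typing import Optional, Sequence

import numpy as np
from scipy import stats as sp_stats

from .genome import GenomeMap
from .population import Individual, Population

__all__ = [
    "GenStats", "sample_for_stats", "mean_heterozygosity", "f_roh",
    "deleterious_counts", "collect_gen_stats", "summarize_extinctions",
]

WEAK_BOUNDS = (-0.001, -0.00001)
MODERATE_BOUNDS = (-0.01, -0.001)
STRONG_THRESHOLD = -0.01
VERY_STRONG_THRESHOLD = -0.05
ROH_MIN_LENGTH_BP = 1_000_000


@dataclass
class GenStats:
    """One generation's summary for one replicate."""

    replicate: int
    generation: int
    phase: str  # "burn_in" | "post_contraction"
    N: int
    K: int
    mean_het: float
    mean_Froh: float
    mean_fitness: float
    n_weak: float
    n_moderate: float
    n_strong: float
    n_very_strong: float

    @classmethod
    def columns(cls):
        return [f.name for f in fields(cls)]


def sample_for_stats(pop: Population, n: int,
                     rng: np.random.Generator) -> list[Individual]:
    """Uniform sample without replacement of min(n, N) individuals."""
    if pop.n == 0:
        raise ValueError("cannot sample from an empty population")
    k = min(n, pop.n)
    idx = np.sort(rng.choice(pop.n, size=k, replace=False))
    return [pop.individual(i) for i in idx]


def mean_heterozygosity(sample: Sequence[Individual], total_coding_bp: int) -> float:
    """Mean per-bp observed heterozygosity: heterozygous sites / coding bp,
    averaged over individuals.  Invariant to fixed-site pruning (fixed sites
    are homozygous in everyone)."""
    if not sample:
        raise ValueError("empty sample")
    counts = [len(ind.het_site_indices) for ind in sample]
    return float(np.mean(counts) / total_coding_bp)


def f_roh(ind: Individual, genome_map: GenomeMap,
          min_length_bp: int = ROH_MIN_LENGTH_BP) -> float:
    """Fraction of the coding genome in runs of homozygosity strictly longer
    than ``min_length_bp``.

    On each chromosome the heterozygous sites partition the coding
    coordinate into maximal homozygous segments (chromosome ends bound the
    outer segments); F_ROH sums the qualifying segment lengths over the
    whole genome.  1 with no heterozygous site; 0 when every segment is
    short.
    """
    pop = ind._pop
    het_pos = pop.sites.pos[ind.het_site_indices]
    # every chromosome edge is a breakpoint, so no segment spans two
    # chromosomes; heterozygous sites add the interior breakpoints
    marks = np.sort(np.concatenate([genome_map.chrom_bp_offsets, het_pos]))
    seg = np.diff(marks)
    total = int(seg[seg > min_length_bp].sum())
    return total / genome_map.total_coding_bp


def _allele_bin_counts(ind: Individual) -> np.ndarray:
    st = ind._pop.sites
    out = np.zeros(4)
    for idx, copies in ((ind.het_site_indices, 1), (ind.hom_site_indices, 2)):
        s = st.s[idx]
        out[0] += copies * np.count_nonzero((s > WEAK_BOUNDS[0]) & (s <= WEAK_BOUNDS[1]))
        out[1] += copies * np.count_nonzero((s > MODERATE_BOUNDS[0]) & (s <= MODERATE_BOUNDS[1]))
        out[2] += copies * np.count_nonzero(s < STRONG_THRESHOLD)
        out[3] += copies * np.count_nonzero(s < VERY_STRONG_THRESHOLD)
    return out


def deleterious_counts(sample: Sequence[Individual]):
    """Mean allele copies per individual in the weak / moderate / strong /
    very-strong bins (strong and very-strong overlap by design)."""
    if not sample:
        raise ValueError("empty sample")
    acc = np.zeros(4)
    for ind in sample:
        acc += _allele_bin_counts(ind)
    return tuple(acc / len(sample))


def _sample_mean_fitness(sample: Sequence[Individual]) -> float:
    from .population import individual_fitness
    vals = []
    for ind in sample:
        w = ind.cached_fitness
        vals.append(individual_fitness(ind) if w is None else w)
    return float(np.mean(vals))


def collect_gen_stats(pop: Population, replicate: int, phase: str,
                      sample_size: int, rng: np.random.Generator) -> GenStats:
    """Summaries from a fresh uniform sample of the population."""
    sample = sample_for_stats(pop, sample_size, rng)
    gm = pop.genome_map
    nw, nm, ns, nvs = deleterious_counts(sample)
    return GenStats(
        replicate=replicate,
        generation=pop.generation,
        phase=phase,
        N=pop.n,
        K=pop.K_current,
        mean_het=mean_heterozygosity(sample, gm.total_coding_bp),
        mean_Froh=float(np.mean([f_roh(ind, gm) for ind in sample])),
        mean_fitness=_sample_mean_fitness(sample),
        n_weak=nw, n_moderate=nm, n_strong=ns, n_very_strong=nvs,
    )


def _uncensored_times(records) -> np.ndarray:
    return np.array([r.extinction_generation for r in records if not r.censored],
                    dtype=float)


def summarize_extinctions(records, baseline_records) -> dict:
    """Compare extinction times of a treatment group against a baseline.

    Censored replicates (still extant at the generation cap) are excluded
    from the moments but reported.  Returns mean/median/SD per group, the
    percent change in mean time to extinction, and a one-tailed Welch t-test
    p-value for the treatment increasing time to extinction.
    """
    treat = _uncensored_times(records)
    base = _uncensored_times(baseline_records)
    if len(treat) < 2 or len(base) < 2:
        raise ValueError("need at least 2 uncensored replicates per group")
    res = sp_stats.ttest_ind(treat, base, equal_var=False, alternative="greater")
    return {
        "n": len(treat),
        "n_censored": len(records) - len(treat),
        "mean": float(treat.mean()),
        "median": float(np.median(treat)),
        "sd": float(treat.std(ddof=1)),
        "baseline_n": len(base),
        "baseline_n_censored": len(baseline_records) - len(base),
        "baseline_mean": float(base.mean()),
        "baseline_median": float(np.median(base)),
        "baseline_sd": float(base.std(ddof=1)),
        "pct_change": float(100.0 * (treat.mean() - base.mean()) / base.mean()),
        "p_value": float(res.pvalue),
    }
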