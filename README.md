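# rescuesim

Individual-based, non-Wright-Fisher simulation of extinction risk driven by
recessive strongly deleterious variation — population contraction,
inbreeding depression, purging, and genetic rescue.

## The problem

Small, isolated populations face extinction from inbreeding depression:
recessive deleterious mutations, hidden as heterozygotes in large
populations, become homozygous under inbreeding. This creates a
counterintuitive risk structure. A *historically large* population carries
many strongly deleterious recessive alleles precisely because selection
never saw them; when it contracts, inbreeding exposes them and fitness
collapses. A historically small population has purged them and persists
longer at the same size. The same logic applies to choosing source
populations for genetic rescue: migrants from a large, genetically diverse
source can import hidden load into the very population they are meant to
save.

`rescuesim` is for population geneticists and conservation modellers who
want to quantify these dynamics: time to extinction after contraction as a
function of ancestral size, dominance model, and mutational target size;
and the effectiveness of rescue strategies (source demography, migrant
screening, numbers and repetition of translocations).

## The model

Population size is emergent, not imposed. Each generation every
hermaphroditic individual mates with a uniformly drawn partner (selfing
possible) and leaves one offspring; at the end of the generation each
individual survives a Bernoulli trial with probability

    min(1, w · K/N)

where `w` is absolute fitness, `K` the carrying capacity and `N` the
post-reproduction cohort size. Fitness is multiplicative over genotypes,

    w = Π (1 + s) over homozygous · Π (1 + h·s) over heterozygous sites,

with mutations fixed in a population folded into a persistent fixed load.
The simulated genome is a canine-like exome: 20,000 genes × 1500 bp on 38
autosomes, mutation rate 1e-8/bp, deleterious:neutral mutations 2.31:1,
deleterious effects from a gamma DFE (shape 0.186, mean |s| 0.0131), and an
`hs` dominance relationship h(s) = 1/(2(1+7071.07|s|)) or its two-class
`hmix` approximation (h = 0.25 for s ≥ −0.01, h = 0 for s < −0.01). The
endangered population's capacity follows a mean-reverting log10 random walk
(φ = 0.9, σ = log10 1.3) with per-generation catastrophe mortality drawn
from Beta(0.5, 8). See `docs/methods.md` for the full model.

## Worked example

A scaled-down contraction study — an ancestral population of `K = 300`
versus one of `K = 100`, both collapsing to an endangered population of 25
(1000 genes, `hmix` dominance, full `10·K` burn-ins):

```yaml
# contraction_large.yaml
scenario: contraction
K_ancestral: 300
K_endangered: 25
genome:
  n_genes: 1000
n_replicates: 5
master_seed: 42
max_generations: 20000
```

```
$ rescuesim simulate --config contraction_large.yaml --out run_large
INFO replicate 1/5: extinct at generation 7800
INFO replicate 2/5: extinct at generation 327
INFO replicate 3/5: extinct at generation 5418
INFO replicate 4/5: extinct at generation 1317
INFO replicate 5/5: extinct at generation 14610
5 replicate(s) complete; 5 extinct, 0 censored. Tables in run_large/

$ rescuesim simulate --config contraction_small.yaml --out run_small   # K_ancestral: 100
INFO replicate 1/5: extinct at generation 13733
...
$ rescuesim summarize --in run_small --baseline run_large --out cmp.tsv
mean time to extinction: 11438.8 vs 5894.4 baseline (+94.1%, p=0.067)
```

Each replicate burns in its own ancestral population, samples 25 founders,
and runs the endangered population under capacity fluctuation and
catastrophes until extinction. `extinctions.tsv` holds one row per
replicate (extinction generation, censoring flag, any rescue events);
`gen_stats.tsv` holds per-generation summaries (N, realized K, mean
heterozygosity, mean F_ROH, mean fitness, and deleterious allele counts per
individual in weak/moderate/strong/very-strong bins) from samples of 30
individuals. The comparison above shows the signature contrast at this
scale: the population with the *smaller* ancestral size persists roughly
twice as long after contraction, because it carried fewer hidden strongly
deleterious alleles (+94% mean persistence; with five replicates and
strong ecological stochasticity the one-tailed Welch test is only
suggestive, and at this reduced mutational target the standing-variation
contrast is far more robust than the persistence contrast — see
`docs/methods.md`).

Genetic rescue works the same way (`scenario: genetic_rescue` plus a
`rescue:` block choosing the source population kind, migrant count,
translocation count, and screening strategy: `random`, `min_strong_load`,
or `max_heterozygosity`).

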