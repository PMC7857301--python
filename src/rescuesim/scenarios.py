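"""Scenario orchestration: burn-in, population contraction, genetic rescue.

Scenarios:

* ``contraction`` — an ancestral population at K_ancestral is burned in for
  10*K_ancestral generations (or a fixed 30,000), then K_endangered
  individuals are sampled to found the endangered population, which evolves
  under environmental stochasticity and catastrophes until extinction or a
  generation cap.
* ``gradual_contraction`` — inserts an intermediate phase (K_intermediate
  for generations_intermediate generations, constant K) before the final
  contraction.
* ``genetic_rescue`` — as contraction, plus a source population split off
  before the contraction; whenever the endangered population's
  post-mortality size falls to the trigger threshold and translocations
  remain, migrants chosen by the configured strategy are copied in at the
  start of the next generation.
* ``neutral_ecology`` — the endangered population with every mutation
  neutral: the ecological null model for extinction risk.  Because fitness
  is identically 1, extinction dynamics are independent of genetics and the
  population starts directly at K_endangered with no burn-in.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field as dc_field

import numpy as np

from .config_io import SimulationConfig, replicate_streams
from .ecology import (EcologyState, draw_catastrophe_probability,
                      update_carrying_capacity)
from .genome import build_genome_map
from .population import (EcologyDraws, IdSource, Individual, Population,
                         step_generation)
from .stats import STRONG_THRESHOLD, collect_gen_stats

logger = logging.getLogger("rescuesim")

__all__ = [
    "ExtinctionRecord", "SourcePopulationSpec", "SOURCE_SPECS",
    "run_burn_in", "run_contraction", "prepare_source_population",
    "select_migrants", "run_genetic_rescue", "run_replicates",
]


@dataclass
class ExtinctionRecord:
    """Outcome of one replicate.  ``extinction_generation`` counts
    generations since the (final) contraction; when the replicate is still
    extant at the cap it equals the cap and ``censored`` is set."""

    replicate: int
    scenario: str
    extinction_generation: int
    censored: bool = False
    rescue_events: list = dc_field(default_factory=list)


@dataclass(frozen=True)
class SourcePopulationSpec:
    """A genetic-rescue source: carrying capacity and how many generations
    before the contraction it was split from the ancestral population."""

    kind: str
    K_source: int
    isolation_generations_at_split: int


SOURCE_SPECS = {
    "K10000": SourcePopulationSpec("K10000", 10000, 0),
    "K1000_1000gen": SourcePopulationSpec("K1000_1000gen", 1000, 1000),
    "K100_100gen": SourcePopulationSpec("K100_100gen", 100, 100),
    "K25_10gen": SourcePopulationSpec("K25_10gen", 25, 10),
}


class _StatsCollector:
    def __init__(self, config: SimulationConfig, replicate: int,
                 rng: np.random.Generator):
        self.config = config
        self.replicate = replicate
        self.rng = rng
        self.records: list = []

    def record(self, pop: Population, phase: str) -> None:
        if pop.n >= 1:
            self.records.append(collect_gen_stats(
                pop, self.replicate, phase, self.config.stats_sample_size,
                self.rng))


def run_burn_in(config: SimulationConfig, rng: np.random.Generator,
                stats: _StatsCollector | None = None) -> Population:
    """Evolve the ancestral population to its pre-contraction state.

    Constant K = K_ancestral, no environmental stochasticity, no
    catastrophes; fixed mutations are retained in the population's fixed
    load (there is no reverse mutation, so absolute fitness declines slowly
    as weak mutations fix).  Duration is 10*K_ancestral generations, or
    30,000 under the fixed mode.  Summaries are recorded every 1000
    generations.
    """
    gm = build_genome_map(config)
    pop = Population.founders(config.K_ancestral, "ancestral", gm,
                              config.dfe_model(), config.dominance,
                              K_base=config.K_ancestral, rng=rng,
                              id_source=IdSource())
    for _ in range(config.burn_in_generations):
        step_generation(pop)
        if pop.extinct:
            raise RuntimeError(
                f"ancestral population went extinct during burn-in at "
                f"generation {pop.generation} (K={config.K_ancestral})")
        if stats is not None and pop.generation % 1000 == 0:
            stats.record(pop, "burn_in")
    return pop


def _run_endangered_phase(config: SimulationConfig, endangered: Population,
                          eco: EcologyState, eco_rng: np.random.Generator,
                          stats: _StatsCollector | None,
                          record: ExtinctionRecord,
                          sources: dict | None = None) -> None:
    """Shared post-contraction loop: ecology draws, optional rescue events,
    per-generation statistics, extinction bookkeeping (in place)."""
    rescue_cfg = config.rescue
    remaining = rescue_cfg.n_translocations if sources else 0
    pending = False
    threshold = config.effective_trigger_threshold if sources else 0
    source = sources[rescue_cfg.source_kind] if sources else None
    for t in range(1, config.max_generations + 1):
        if pending and remaining > 0:
            pending = False
            if source.n < rescue_cfg.n_migrants:
                logger.warning(
                    "replicate %d: source %s exhausted (N=%d < %d); "
                    "skipping translocation", record.replicate, source.label,
                    source.n, rescue_cfg.n_migrants)
                remaining -= 1
            else:
                idx = _select_migrant_indices(
                    source, rescue_cfg.n_migrants, rescue_cfg.migrant_strategy,
                    endangered.rng)
                endangered.absorb_migrants(source, idx)
                remaining -= 1
                record.rescue_events.append({
                    "generation": t, "n_migrants": rescue_cfg.n_migrants,
                    "source_label": source.label,
                    "strategy": rescue_cfg.migrant_strategy})
        if source is not None:
            step_generation(source)
        draws = EcologyDraws(
            K_next=update_carrying_capacity(eco, config.K_endangered, eco_rng),
            catastrophe_p=draw_catastrophe_probability(eco, eco_rng))
        step_generation(endangered, draws)
        if stats is not None:
            stats.record(endangered, "post_contraction")
        if endangered.extinct:
            record.extinction_generation = t
            record.censored = False
            return
        if remaining > 0 and endangered.n <= threshold:
            pending = True
    record.extinction_generation = config.max_generations
    record.censored = True


def run_contraction(config: SimulationConfig, replicate: int = 0,
                    streams=None, ancestral: Population | None = None,
                    collect_stats: bool = True):
    """One contraction replicate: burn-in (unless an ancestral population is
    supplied), sampling of K_endangered founders, then the endangered phase
    under full ecology.  The gradual variant first contracts to
    K_intermediate (constant K, no endangered-style ecology) for
    generations_intermediate generations.  Returns
    ``(ExtinctionRecord, [GenStats, ...])``."""
    if streams is None:
        streams = replicate_streams(config.master_seed, replicate)
    gen_rng, eco_rng, samp_rng = streams
    stats = _StatsCollector(config, replicate, samp_rng) if collect_stats else None
    record = ExtinctionRecord(replicate, config.scenario, -1)

    if config.scenario == "neutral_ecology":
        gm = build_genome_map(config)
        endangered = Population.founders(
            config.K_endangered, "endangered", gm, config.dfe_model(),
            config.dominance, K_base=config.K_endangered, rng=gen_rng)
    else:
        if ancestral is None:
            ancestral = run_burn_in(config, gen_rng, stats)
        source = ancestral
        if config.scenario == "gradual_contraction":
            intermediate = ancestral.subsample(
                min(config.K_intermediate, ancestral.n), "intermediate",
                K_base=config.K_intermediate, rng=gen_rng)
            for _ in range(config.generations_intermediate):
                step_generation(intermediate)
                if intermediate.extinct:
                    raise RuntimeError("intermediate population went extinct")
            source = intermediate
        if config.K_endangered > source.n:
            raise ValueError(
                f"K_endangered={config.K_endangered} exceeds N={source.n}")
        endangered = source.subsample(config.K_endangered, "endangered",
                                      K_base=config.K_endangered, rng=gen_rng)
    eco = config.ecology_state()
    _run_endangered_phase(config, endangered, eco, eco_rng, stats, record)
    return record, (stats.records if stats else [])


def prepare_source_population(spec: SourcePopulationSpec,
                              ancestral: Population,
                              rng: np.random.Generator) -> Population:
    """Split a rescue source population off the burned-in ancestral
    population: downsample to K_source and evolve at constant K (no
    endangered-style ecology) for the configured pre-contraction isolation
    period.  A spec with zero isolation at the ancestral size is the
    ancestral population itself, continuing unchanged."""
    if spec.isolation_generations_at_split == 0 and spec.K_source >= ancestral.n:
        return ancestral
    if spec.K_source > ancestral.n:
        raise ValueError(
            f"K_source={spec.K_source} exceeds ancestral N={ancestral.n}")
    source = ancestral.subsample(spec.K_source, spec.kind,
                                 K_base=spec.K_source, rng=rng)
    for _ in range(spec.isolation_generations_at_split):
        step_generation(source)
        if source.extinct:
            raise RuntimeError(f"source population {spec.kind} went extinct "
                               "during pre-contraction isolation")
    return source


def _strong_allele_counts(pop: Population) -> np.ndarray:
    """Per-individual copies of strongly deleterious alleles (s < -0.01)."""
    S = len(pop.sites)
    bits = np.unpackbits(pop.geno.view(np.uint8), axis=1,
                         bitorder="little")[:, :S].astype(np.int64)
    strong = pop.sites.s < STRONG_THRESHOLD
    per_hap = bits[:, strong].sum(axis=1)
    return per_hap[0::2] + per_hap[1::2]


def _het_site_counts(pop: Population) -> np.ndarray:
    S = len(pop.sites)
    x = pop.geno[0::2] ^ pop.geno[1::2]
    bits = np.unpackbits(x.view(np.uint8), axis=1, bitorder="little")[:, :S]
    return bits.sum(axis=1).astype(np.int64)


def _select_migrant_indices(source: Population, n: int, strategy: str,
                            rng: np.random.Generator) -> np.ndarray:
    if n > source.n:
        raise ValueError(f"cannot select {n} migrants from N={source.n}")
    if strategy == "random":
        return np.sort(rng.choice(source.n, size=n, replace=False))
    if strategy == "min_strong_load":
        key = _strong_allele_counts(source)
    elif strategy == "max_heterozygosity":
        key = -_het_site_counts(source)
    else:
        raise ValueError(f"unknown migrant strategy: {strategy!r}")
    order = np.lexsort((source.ind_ids, key))  # ties: lower individual id
    return np.sort(order[:n])


def select_migrants(source: Population, n: int, strategy: str,
                    rng: np.random.Generator) -> list[Individual]:
    """The individuals chosen for translocation (source left unchanged)."""
    return [source.individual(i)
            for i in _select_migrant_indices(source, n, strategy, rng)]


def run_genetic_rescue(config: SimulationConfig, replicate: int = 0,
                       streams=None, ancestral: Population | None = None,
                       collect_stats: bool = True):
    """One genetic-rescue replicate.

    As :func:`run_contraction`, plus a source population prepared before the
    contraction; when the endangered population's post-mortality size falls
    to the trigger threshold (5 when K_endangered=25, 15 when 50) and
    translocations remain, migrants arrive before reproduction in the next
    generation.  With zero translocations this reduces exactly to the
    contraction scenario.  Returns ``(ExtinctionRecord, [GenStats, ...])``.
    """
    if streams is None:
        streams = replicate_streams(config.master_seed, replicate)
    gen_rng, eco_rng, samp_rng = streams
    stats = _StatsCollector(config, replicate, samp_rng) if collect_stats else None
    record = ExtinctionRecord(replicate, config.scenario, -1)
    if ancestral is None:
        ancestral = run_burn_in(config, gen_rng, stats)
    sources = None
    if config.rescue.n_translocations > 0:
        spec = SOURCE_SPECS[config.rescue.source_kind]
        source = prepare_source_population(spec, ancestral, gen_rng)
        sources = {config.rescue.source_kind: source}
    if config.K_endangered > ancestral.n:
        raise ValueError(
            f"K_endangered={config.K_endangered} exceeds N={ancestral.n}")
    endangered = ancestral.subsample(config.K_endangered, "endangered",
                                     K_base=config.K_endangered, rng=gen_rng)
    eco = config.ecology_state()
    _run_endangered_phase(config, endangered, eco, eco_rng, stats, record,
                          sources=sources)
    return record, (stats.records if stats else [])


_RUNNERS = {
    "contraction": run_contraction,
    "gradual_contraction": run_contraction,
    "neutral_ecology": run_contraction,
    "genetic_rescue": run_genetic_rescue,
}


def run_replicates(config: SimulationConfig, out_dir=None,
                   collect_stats: bool = True):
    """Run all configured replicates with derived seeds; returns
    ``(extinction_records, gen_stats_records)`` and, when ``out_dir`` is
    given, writes ``extinctions.tsv`` and ``gen_stats.tsv`` there.
    Per-replicate failures are logged and do not abort the other
    replicates."""
    from . import config_io

    runner = _RUNNERS[config.scenario]
    extinctions, gen_records = [], []
    for rep in range(config.n_replicates):
        streams = replicate_streams(config.master_seed, rep)
        try:
            record, series = runner(config, replicate=rep, streams=streams,
                                    collect_stats=collect_stats)
        except Exception:
            logger.exception("replicate %d failed", rep)
            continue
        extinctions.append(record)
        gen_records.extend(series)
        logger.info("replicate %d/%d: %s at generation %s%s", rep + 1,
                    config.n_replicates, "censored" if record.censored
                    else "extinct", record.extinction_generation,
                    f" ({len(record.rescue_events)} rescue event(s))"
                    if record.rescue_events else "")
    if out_dir is not None:
        from pathlib import Path
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        if extinctions:
            config_io.write_extinctions(extinctions, out / "extinctions.tsv")
        if gen_records:
            config_io.write_gen_stats(gen_records, out / "gen_stats.tsv")
    return extinctions, gen_records
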