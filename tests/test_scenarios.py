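"""Scenario orchestration: burn-in, contraction, sources, migrants, rescue."""

import numpy as np
import pytest

from rescuesim.config_io import (GenomeConfig, RescueConfig, SimulationConfig,
                                 replicate_streams)
from rescuesim.genome import build_genome_map
from rescuesim.population import individual_fitness, reproduce
from rescuesim.scenarios import (SOURCE_SPECS, SourcePopulationSpec,
                                 prepare_source_population, run_burn_in,
                                 run_contraction, run_genetic_rescue,
                                 run_replicates, select_migrants,
                                 _StatsCollector)

from conftest import build_population


def _scaled_config(**kw):
    base = dict(
        scenario="contraction", K_ancestral=40, K_endangered=8,
        genome=GenomeConfig(n_genes=200, n_chromosomes=4,
                            per_chromosome_gene_counts=[50] * 4,
                            gene_length_bp=500, mutation_rate_per_bp=2e-7),
        n_replicates=2, master_seed=13, max_generations=120)
    base.update(kw)
    return SimulationConfig(**base)


class TestBurnIn:
    def test_proportional_duration(self):
        cfg = _scaled_config(K_ancestral=30)
        rng, _, _ = replicate_streams(1, 0)
        pop = run_burn_in(cfg, rng)
        assert pop.generation == 300
        assert pop.n > 0

    def test_fixed_mode_ignores_capacity(self):
        cfg = _scaled_config(burn_in_mode="fixed_30000")
        assert cfg.burn_in_generations == 30_000
        cfg2 = _scaled_config(K_ancestral=1500)
        assert cfg2.burn_in_generations == 15_000

    def test_without_mutation_population_stays_pristine(self):
        cfg = _scaled_config(K_ancestral=25, genome=GenomeConfig(
            n_genes=200, n_chromosomes=4, per_chromosome_gene_counts=[50] * 4,
            gene_length_bp=500, mutation_rate_per_bp=0.0))
        rng, _, _ = replicate_streams(2, 0)
        pop = run_burn_in(cfg, rng)
        assert len(pop.sites) == 0
        assert pop.fixed_load == 1.0

    def test_burn_in_stats_cadence(self):
        cfg = _scaled_config(K_ancestral=120)
        streams = replicate_streams(3, 0)
        stats = _StatsCollector(cfg, 0, streams[2])
        run_burn_in(cfg, streams[0], stats)
        assert [r.generation for r in stats.records] == [1000]
        assert stats.records[0].phase == "burn_in"


class TestContraction:
    def test_record_bookkeeping(self):
        cfg = _scaled_config(max_generations=40)
        record, series = run_contraction(cfg, replicate=0)
        assert record.scenario == "contraction"
        assert record.rescue_events == []
        if record.censored:
            assert record.extinction_generation == 40
        else:
            assert 1 <= record.extinction_generation <= 40
        post = [g for g in series if g.phase == "post_contraction"]
        # one record per post-contraction generation survived
        assert len(post) >= 1
        assert post[0].K >= 1

    def test_gradual_defaults_match_standard_design(self):
        cfg = SimulationConfig(scenario="gradual_contraction")
        assert (cfg.K_ancestral, cfg.K_intermediate, cfg.K_endangered) == \
            (10000, 1000, 25)
        assert cfg.generations_intermediate == 200

    def test_gradual_intermediate_phase_runs(self):
        cfg = _scaled_config(scenario="gradual_contraction", K_intermediate=20,
                             generations_intermediate=15, max_generations=30)
        record, series = run_contraction(cfg, replicate=1)
        assert record.scenario == "gradual_contraction"

    def test_seeding_requires_enough_individuals(self):
        cfg = _scaled_config(K_endangered=4000)
        with pytest.raises(ValueError, match="K_endangered"):
            run_contraction(cfg, replicate=0)


class TestSourcePopulations:
    def test_spec_catalogue(self):
        assert {(s.K_source, s.isolation_generations_at_split)
                for s in SOURCE_SPECS.values()} == \
            {(10000, 0), (1000, 1000), (100, 100), (25, 10)}

    def test_large_source_is_ancestral_itself(self):
        cfg = _scaled_config()
        rng, _, _ = replicate_streams(4, 0)
        ancestral = run_burn_in(cfg, rng)
        source = prepare_source_population(SOURCE_SPECS["K10000"], ancestral, rng)
        assert source is ancestral

    def test_split_downsamples_and_isolates(self):
        cfg = _scaled_config()
        rng, _, _ = replicate_streams(5, 0)
        ancestral = run_burn_in(cfg, rng)
        n_anc = ancestral.n
        spec = SourcePopulationSpec("toy", 12, 5)
        source = prepare_source_population(spec, ancestral, rng)
        assert source.label == "toy"
        assert source.generation == ancestral.generation + 5
        assert ancestral.n == n_anc  # copy-split leaves the ancestral intact
        assert source.K_base == 12


class TestSelectMigrants:
    def _pop_with_loads(self, tiny_map):
        # ind0: no strong alleles; ind1: 4 copies (two homozygous s=-0.02);
        # ind2: 1 copy het; ind3: none but 3 het neutral sites
        sites = [(0, 1, -0.02, 0.0), (10, 1001, -0.02, 0.0),
                 (20, 2001, 0.0, 0.5), (30, 3001, 0.0, 0.5), (40, 4001, 0.0, 0.5)]
        genotypes = [([], []), ([0, 1], [0, 1]), ([0], []), ([2, 3, 4], [])]
        return build_population(tiny_map, sites, genotypes)

    def test_whole_population(self, tiny_map, rng):
        pop = self._pop_with_loads(tiny_map)
        for strategy in ("random", "min_strong_load", "max_heterozygosity"):
            assert len(select_migrants(pop, 4, strategy, rng)) == 4

    def test_min_strong_load_prefers_clean_individuals(self, tiny_map, rng):
        pop = self._pop_with_loads(tiny_map)
        chosen = select_migrants(pop, 2, "min_strong_load", rng)
        assert {c.id for c in chosen} == {0, 3}  # zero-count, tie by lower id

    def test_tie_broken_by_lower_id(self, tiny_map, rng):
        pop = self._pop_with_loads(tiny_map)
        chosen = select_migrants(pop, 1, "min_strong_load", rng)
        assert chosen[0].id == 0

    def test_max_heterozygosity(self, tiny_map, rng):
        pop = self._pop_with_loads(tiny_map)
        chosen = select_migrants(pop, 1, "max_heterozygosity", rng)
        assert chosen[0].id == 3

    def test_source_too_small(self, tiny_map, rng):
        pop = self._pop_with_loads(tiny_map)
        with pytest.raises(ValueError):
            select_migrants(pop, 5, "random", rng)


class TestGeneticRescue:
    def test_zero_translocations_reduces_to_contraction(self, tmp_path):
        shared = dict(K_ancestral=40, K_endangered=8,
                      genome=GenomeConfig(n_genes=200, n_chromosomes=4,
                                          per_chromosome_gene_counts=[50] * 4,
                                          gene_length_bp=500,
                                          mutation_rate_per_bp=2e-7),
                      n_replicates=2, master_seed=31, max_generations=60)
        cfg_resc = SimulationConfig(
            scenario="genetic_rescue",
            rescue=RescueConfig(n_translocations=0, trigger_threshold=3),
            **shared)
        cfg_base = SimulationConfig(scenario="contraction", **shared)
        ra, sa = run_replicates(cfg_resc, out_dir=tmp_path / "a")
        rb, sb = run_replicates(cfg_base, out_dir=tmp_path / "b")
        assert [r.extinction_generation for r in ra] == \
            [r.extinction_generation for r in rb]
        assert (tmp_path / "a" / "gen_stats.tsv").read_bytes() == \
            (tmp_path / "b" / "gen_stats.tsv").read_bytes()

    def test_translocations_fire_and_are_recorded(self):
        cfg = _scaled_config(
            scenario="genetic_rescue", max_generations=30,
            rescue=RescueConfig(source_kind="K10000", n_migrants=3,
                                n_translocations=2, trigger_threshold=1000))
        record, _ = run_genetic_rescue(cfg, replicate=0)
        # threshold always satisfied: one event per generation, starting at
        # the generation after the first trigger observation
        gens = [e["generation"] for e in record.rescue_events]
        assert len(gens) == 2 and gens == [2, 3]
        for e in record.rescue_events:
            assert e["n_migrants"] == 3
            assert e["source_label"] == "ancestral"
            assert e["strategy"] == "random"

    def test_migrant_genes_enter_endangered_pool(self):
        cfg = _scaled_config(
            scenario="genetic_rescue", K_endangered=6, max_generations=10,
            rescue=RescueConfig(source_kind="K10000", n_migrants=4,
                                n_translocations=1, trigger_threshold=1000))
        record, series = run_genetic_rescue(cfg, replicate=3)
        assert len(record.rescue_events) == 1
        post = [g for g in series if g.phase == "post_contraction"]
        sizes = [g.N for g in post]
        # population jumps by the migrant count at the rescue generation
        assert max(sizes) > 6

    def test_heterosis_on_disjoint_fixed_loads(self, tiny_map):
        """Masking of population-specific fixed recessive mutations raises
        offspring fitness above the parental mean after admixture."""
        recessive = [(0, 1, -0.3, 0.0), (10, 1001, -0.3, 0.0)]
        other = [(20, 2001, -0.3, 0.0), (30, 3001, -0.3, 0.0)]
        home = build_population(tiny_map, [], [([], [])] * 6,
                                fixed_defs=recessive, seed=11)
        away = build_population(tiny_map, [], [([], [])] * 6,
                                fixed_defs=other, seed=12)
        away.fixed.ids += 1000  # distinct mutation identities
        away.id_source.next_mutation += 1000
        w_native = individual_fitness(home.individual(0))
        assert w_native == pytest.approx(0.49)
        home.absorb_migrants(away, np.arange(6))
        parents_mean = np.mean([individual_fitness(home.individual(i))
                                for i in range(home.n)])
        children = reproduce(home)
        child_w = [individual_fitness(c) for c in children]
        assert np.mean(child_w) > parents_mean
        # native x migrant offspring mask everything: fitness exactly 1
        assert max(child_w) == pytest.approx(1.0)


class TestReplicates:
    def test_replicate_count_and_determinism(self, tmp_path):
        cfg = _scaled_config(n_replicates=3, max_generations=40)
        recs1, _ = run_replicates(cfg, out_dir=tmp_path / "r1")
        recs2, _ = run_replicates(cfg, out_dir=tmp_path / "r2")
        assert len(recs1) == 3
        for name in ("extinctions.tsv", "gen_stats.tsv"):
            assert (tmp_path / "r1" / name).read_bytes() == \
                (tmp_path / "r2" / name).read_bytes()

    def test_replicate_seeds_distinct(self):
        from rescuesim.config_io import derive_replicate_seed
        seeds = [derive_replicate_seed(13, i) for i in range(25)]
        assert len(set(seeds)) == 25
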