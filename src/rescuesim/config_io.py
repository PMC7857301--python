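"""Configuration schema, deterministic seeding, and file output.

A run is fully specified by one YAML file plus a master seed.  The schema is
nested key-value blocks mirroring :class:`SimulationConfig`; unknown keys are
rejected, omitted keys take the defaults below (which reproduce the standard
parameterization: a 20,000-gene / 1500-bp wolf-like exome on 38 autosomes,
mutation rate 1e-8/bp, deleterious:neutral ratio 2.31:1, the gamma DFE, the
hmix dominance model, and the OU + catastrophe ecology).

Seeding: one master seed; per-replicate seeds and per-subsystem streams
(genetics / ecology / statistics sampling) are derived deterministically via
``numpy.random.SeedSequence`` spawn keys, so any replicate can be reproduced
in isolation.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import yaml

from .ecology import EcologyState
from .genome import DFEModel

__all__ = [
    "GenomeConfig", "DFEConfig", "DominanceConfig", "EcologyConfig",
    "RescueConfig", "SimulationConfig", "load_config", "dump_config",
    "config_to_dict", "config_from_dict", "derive_replicate_seed",
    "replicate_streams", "write_gen_stats", "read_gen_stats",
    "write_extinctions", "export_vcf",
]

SCENARIOS = ("contraction", "gradual_contraction", "genetic_rescue",
             "neutral_ecology")
BURN_IN_MODES = ("proportional", "fixed_30000")
SOURCE_KINDS = ("K10000", "K1000_1000gen", "K100_100gen", "K25_10gen")
MIGRANT_STRATEGIES = ("random", "min_strong_load", "max_heterozygosity")


@dataclass
class GenomeConfig:
    n_genes: int = 20000
    gene_length_bp: int = 1500
    n_chromosomes: int = 38
    per_chromosome_gene_counts: Optional[list] = None
    inter_gene_recomb_rate: float = 1e-3
    mutation_rate_per_bp: float = 1e-8


@dataclass
class DFEConfig:
    deleterious_to_neutral_ratio: float = 2.31
    gamma_shape: float = 0.186
    gamma_mean_abs_s: float = 0.01314833
    truncation: str = "none"


@dataclass
class DominanceConfig:
    model: str = "hmix"
    fixed_h: float = 0.0
    hs_scale_constant: float = 7071.07
    hmix_strong_threshold: float = -0.01
    hmix_weak_h: float = 0.25
    hmix_strong_h: float = 0.0


@dataclass
class EcologyConfig:
    ou_phi: float = 0.9
    ou_sigma: float = float(np.log10(1.3))
    catastrophe_alpha: float = 0.5
    catastrophe_beta: float = 8.0
    apply_to: str = "endangered_only"


@dataclass
class RescueConfig:
    source_kind: str = "K10000"
    n_migrants: int = 5
    n_translocations: int = 1
    trigger_threshold: Optional[int] = None
    migrant_strategy: str = "random"


@dataclass
class SimulationConfig:
    scenario: str
    K_ancestral: int = 10000
    K_endangered: int = 25
    K_intermediate: int = 1000
    generations_intermediate: int = 200
    burn_in_mode: str = "proportional"
    genome: GenomeConfig = field(default_factory=GenomeConfig)
    dfe: DFEConfig = field(default_factory=DFEConfig)
    dominance: DominanceConfig = field(default_factory=DominanceConfig)
    ecology: EcologyConfig = field(default_factory=EcologyConfig)
    rescue: RescueConfig = field(default_factory=RescueConfig)
    n_replicates: int = 25
    master_seed: int = 1
    stats_sample_size: int = 30
    max_generations: int = 10000

    def __post_init__(self):
        if self.genome.per_chromosome_gene_counts is not None:
            self.genome.per_chromosome_gene_counts = [
                int(x) for x in self.genome.per_chromosome_gene_counts]
        _validate(self)

    # -------------------------------------------------------------- derived

    @property
    def burn_in_generations(self) -> int:
        if self.burn_in_mode == "fixed_30000":
            return 30000
        return 10 * self.K_ancestral

    @property
    def effective_trigger_threshold(self) -> int:
        if self.rescue.trigger_threshold is not None:
            return self.rescue.trigger_threshold
        if self.K_endangered == 25:
            return 5
        if self.K_endangered == 50:
            return 15
        raise ValueError(
            "rescue.trigger_threshold must be set explicitly when "
            f"K_endangered={self.K_endangered} (defaults exist only for 25/50)")

    def dfe_model(self) -> DFEModel:
        if self.scenario == "neutral_ecology":
            # all mutations neutral: extinction dynamics are purely ecological
            return DFEModel(p_deleterious=0.0,
                            gamma_shape=self.dfe.gamma_shape,
                            gamma_mean_abs_s=self.dfe.gamma_mean_abs_s)
        return DFEModel.from_ratio(self.dfe.deleterious_to_neutral_ratio,
                                   gamma_shape=self.dfe.gamma_shape,
                                   gamma_mean_abs_s=self.dfe.gamma_mean_abs_s,
                                   truncation=self.dfe.truncation)

    def ecology_state(self) -> EcologyState:
        return EcologyState.at_equilibrium(
            self.K_endangered, phi=self.ecology.ou_phi,
            sigma=self.ecology.ou_sigma,
            catastrophe_alpha=self.ecology.catastrophe_alpha,
            catastrophe_beta=self.ecology.catastrophe_beta)


def _require(cond: bool, message: str) -> None:
    if not cond:
        raise ValueError(message)


def _validate(cfg: SimulationConfig) -> None:
    _require(bool(cfg.scenario), "scenario: missing or empty")
    _require(cfg.scenario in SCENARIOS,
             f"scenario: {cfg.scenario!r} not one of {SCENARIOS}")
    _require(cfg.burn_in_mode in BURN_IN_MODES,
             f"burn_in_mode: {cfg.burn_in_mode!r} not one of {BURN_IN_MODES}")
    for name in ("K_ancestral", "K_endangered", "K_intermediate"):
        _require(int(getattr(cfg, name)) >= 1, f"{name}: must be a positive integer")
    _require(cfg.generations_intermediate >= 0,
             "generations_intermediate: must be >= 0")
    g = cfg.genome
    _require(g.n_genes >= 1, "genome.n_genes: must be >= 1")
    _require(g.gene_length_bp >= 1, "genome.gene_length_bp: must be >= 1")
    _require(1 <= g.n_chromosomes <= 63,
             "genome.n_chromosomes: must be in [1, 63]")
    _require(g.mutation_rate_per_bp >= 0,
             "genome.mutation_rate_per_bp: must be >= 0")
    _require(0 <= g.inter_gene_recomb_rate <= 0.5,
             "genome.inter_gene_recomb_rate: must be in [0, 0.5]")
    if g.per_chromosome_gene_counts is not None:
        counts = list(g.per_chromosome_gene_counts)
        _require(len(counts) == g.n_chromosomes,
                 "genome.per_chromosome_gene_counts: length != n_chromosomes")
        _require(sum(counts) == g.n_genes,
                 "genome.per_chromosome_gene_counts: must sum to n_genes")
    d = cfg.dfe
    _require(d.deleterious_to_neutral_ratio >= 0,
             "dfe.deleterious_to_neutral_ratio: must be >= 0")
    _require(d.gamma_shape > 0 and d.gamma_mean_abs_s > 0,
             "dfe: gamma parameters must be positive")
    _require(d.truncation in ("none", "strong_only", "weak_moderate_only"),
             f"dfe.truncation: {d.truncation!r} invalid")
    dom = cfg.dominance
    _require(dom.model in ("hs_relationship", "hmix", "fixed"),
             f"dominance.model: {dom.model!r} invalid")
    _require(0.0 <= dom.fixed_h <= 0.5, "dominance.fixed_h: must be in [0, 0.5]")
    e = cfg.ecology
    _require(0.0 <= e.ou_phi < 1.0, "ecology.ou_phi: must be in [0, 1)")
    _require(e.ou_sigma >= 0.0, "ecology.ou_sigma: must be >= 0")
    _require(e.catastrophe_alpha > 0 and e.catastrophe_beta > 0,
             "ecology: beta-distribution parameters must be positive")
    _require(e.apply_to == "endangered_only",
             "ecology.apply_to: only 'endangered_only' is supported")
    r = cfg.rescue
    _require(r.source_kind in SOURCE_KINDS,
             f"rescue.source_kind: {r.source_kind!r} not one of {SOURCE_KINDS}")
    _require(r.migrant_strategy in MIGRANT_STRATEGIES,
             f"rescue.migrant_strategy: {r.migrant_strategy!r} invalid")
    _require(r.n_migrants >= 1, "rescue.n_migrants: must be >= 1")
    _require(r.n_translocations >= 0, "rescue.n_translocations: must be >= 0")
    if r.trigger_threshold is not None:
        _require(r.trigger_threshold >= 1,
                 "rescue.trigger_threshold: must be >= 1")
    _require(cfg.n_replicates >= 1, "n_replicates: must be >= 1")
    _require(cfg.stats_sample_size >= 1, "stats_sample_size: must be >= 1")
    _require(cfg.max_generations >= 1, "max_generations: must be >= 1")


_BLOCKS = {"genome": GenomeConfig, "dfe": DFEConfig, "dominance": DominanceConfig,
           "ecology": EcologyConfig, "rescue": RescueConfig}


def _build_block(cls, data: dict, block: str):
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"{block}: unknown key(s) {sorted(unknown)}")
    return cls(**data)


def config_from_dict(data: dict) -> SimulationConfig:
    """Build and validate a configuration from a nested dict (e.g. parsed
    YAML).  Unknown keys at any level are rejected."""
    if not isinstance(data, dict):
        raise ValueError("configuration must be a mapping")
    data = dict(data)
    if not data.get("scenario"):
        raise ValueError("scenario: missing or empty")
    kwargs = {}
    for block, cls in _BLOCKS.items():
        if block in data:
            sub = data.pop(block)
            if sub is None:
                sub = {}
            if not isinstance(sub, dict):
                raise ValueError(f"{block}: must be a mapping")
            kwargs[block] = _build_block(cls, sub, block)
    known = {f.name for f in dataclasses.fields(SimulationConfig)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown key(s) {sorted(unknown)}")
    return SimulationConfig(**data, **kwargs)


def config_to_dict(cfg: SimulationConfig) -> dict:
    return dataclasses.asdict(cfg)


def load_config(path) -> SimulationConfig:
    """Load, default-fill, and validate a YAML configuration file."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"config file not found: {path}")
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if data is None:
        raise ValueError("scenario: missing or empty (empty config file)")
    return config_from_dict(data)


def dump_config(cfg: SimulationConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config_to_dict(cfg), fh, sort_keys=False)


# ------------------------------------------------------------------ seeding

def derive_replicate_seed(master_seed: int, replicate_index: int) -> int:
    """Deterministic, collision-free (within a run) per-replicate seed."""
    if replicate_index < 0:
        raise ValueError("replicate_index must be >= 0")
    ss = np.random.SeedSequence(master_seed, spawn_key=(replicate_index,))
    return int(ss.generate_state(1)[0]) & 0x7FFFFFFF


def replicate_streams(master_seed: int, replicate_index: int):
    """Independent per-replicate streams: (genetics, ecology, sampling)."""
    root = np.random.SeedSequence(master_seed, spawn_key=(replicate_index,))
    return tuple(np.random.Generator(np.random.PCG64(s)) for s in root.spawn(3))


# ------------------------------------------------------------- file output

_FLOAT_FIELDS = ("mean_het", "mean_Froh", "mean_fitness",
                 "n_weak", "n_moderate", "n_strong", "n_very_strong")
_GEN_STATS_HEADER = ("replicate", "generation", "phase", "N", "K") + _FLOAT_FIELDS


def _fmt(value) -> str:
    if isinstance(value, float):
        return f"{value:.6g}"
    return str(value)


def write_gen_stats(records, path) -> None:
    """Tab-separated per-generation summary table (6 significant digits)."""
    records = list(records)
    if not records:
        raise ValueError("no records to write")
    with open(path, "w") as fh:
        fh.write("\t".join(_GEN_STATS_HEADER) + "\n")
        for r in records:
            fh.write("\t".join(_fmt(getattr(r, name if name != "K" else "K"))
                               for name in _GEN_STATS_HEADER) + "\n")


def read_gen_stats(path):
    import pandas as pd
    return pd.read_csv(path, sep="\t")


def write_extinctions(records, path) -> None:
    """Tab-separated per-replicate extinction summary."""
    records = list(records)
    if not records:
        raise ValueError("no records to write")
    header = ["replicate", "scenario", "extinction_generation", "censored",
              "n_rescue_events", "rescue_events"]
    with open(path, "w") as fh:
        fh.write("\t".join(header) + "\n")
        for r in records:
            events = ";".join(
                f"gen={e['generation']},n={e['n_migrants']},"
                f"source={e['source_label']},strategy={e['strategy']}"
                for e in r.rescue_events) or "."
            fh.write("\t".join(map(str, [
                r.replicate, r.scenario, r.extinction_generation,
                int(r.censored), len(r.rescue_events), events])) + "\n")


def export_vcf(sample, genome_map, path) -> None:
    """Write the sampled individuals' segregating genotypes as VCF 4.2.

    One record per site segregating in the sample; INFO carries the
    selection (S=) and dominance (H=) coefficients; GT fields are unphased
    diploid.  REF/ALT are placeholder alleles (the simulation tracks
    mutations, not nucleotides).
    """
    sample = list(sample)
    if not sample:
        raise ValueError("empty sample")
    pop = sample[0]._pop
    st = pop.sites
    n_sites = len(st)
    # genotype codes per sampled individual: 0 absent, 1 het, 2 hom
    codes = np.zeros((len(sample), n_sites), dtype=np.int8)
    for k, ind in enumerate(sample):
        codes[k, ind.het_site_indices] = 1
        codes[k, ind.hom_site_indices] = 2
    seg = np.flatnonzero(codes.sum(axis=0) > 0)
    chrom, local = genome_map.to_chrom_coords(st.pos[seg]) if len(seg) else \
        (np.empty(0, int), np.empty(0, int))
    order = np.lexsort((st.ids[seg], local, chrom)) if len(seg) else []
    labels = genome_map.chrom_labels()
    gt = {0: "0/0", 1: "0/1", 2: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=rescuesim\n")
        for c, lab in enumerate(labels):
            length = int(genome_map.chrom_gene_counts[c]) * genome_map.gene_length_bp
            fh.write(f"##contig=<ID={lab},length={length}>\n")
        fh.write('##INFO=<ID=S,Number=1,Type=Float,'
                 'Description="Selection coefficient">\n')
        fh.write('##INFO=<ID=H,Number=1,Type=Float,'
                 'Description="Dominance coefficient">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        names = [f"ind{ind.id}" for ind in sample]
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(names) + "\n")
        for j in order:
            i = seg[j]
            info = f"S={st.s[i]:.6g};H={st.h[i]:.6g}"
            row = [labels[int(chrom[j])], str(int(local[j])), str(int(st.ids[i])),
                   "A", "T", ".", "PASS", info, "GT"]
            row += [gt[int(codes[k, i])] for k in range(len(sample))]
            fh.write("\t".join(row) + "\n")
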