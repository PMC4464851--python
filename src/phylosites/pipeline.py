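"""End-to-end orchestration: simulation, the core pipeline, evaluation.

Every random stage takes an explicit seed derived from one master seed by
stage name (stable hashing), so a run is reproducible from its config alone
and the worker count never changes an output byte.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from . import consensus as consensus_mod
from . import sites as sites_mod
from .assemble import (DEFAULT_K, DEFAULT_MIN_CONTIG_LENGTH,
                       DEFAULT_MIN_KMER_COUNT, CompositeGenome,
                       assemble_composite)
from .errors import ConfigurationError
from .evaluate import EvaluationReport, anchor_composite, score_run
from .evolve import GenomeSet, census_variable_sites, evolve_genomes
from .mapper import CompositeIndex, Pileup, map_reads
from .reads import (DEFAULT_ERROR_RATE, DEFAULT_INSERT_MEAN,
                    DEFAULT_INSERT_SD, DEFAULT_READ_LENGTH, ReadBatch,
                    simulate_reads)
from .subsample import plan_subsample, subsample_batch
from .trees import SimTree, make_tree

logger = logging.getLogger("phylosites")


def stage_seed(master_seed: int, stage: str) -> int:
    """Stable per-stage seed below 2**31 derived from the master seed."""
    h = hashlib.blake2b(f"{master_seed}:{stage}".encode(), digest_size=4)
    return int.from_bytes(h.digest(), "big") % (2 ** 31)


@dataclass
class RunConfig:
    """Full configuration of one pipeline run (simulated or file-based)."""

    species: list[str] = field(default_factory=list)
    fastq: dict[str, list[str]] = field(default_factory=dict)
    # simulation parameters (used when fastq is empty)
    topology: str = "balanced"
    variant: str = "equal"
    scaler: int = 1
    genome_length: int = 50_000
    coverage: float = 10.0
    read_length: int = DEFAULT_READ_LENGTH
    insert_mean: float = DEFAULT_INSERT_MEAN
    insert_sd: float = DEFAULT_INSERT_SD
    error_rate: float = DEFAULT_ERROR_RATE
    # core pipeline parameters
    genome_size: int = 50_000
    target_depth: float = 10.0
    k: int = DEFAULT_K
    min_kmer_count: int = DEFAULT_MIN_KMER_COUNT
    min_contig_length: int = DEFAULT_MIN_CONTIG_LENGTH
    seed_length: int = 25
    max_mismatch_frac: float = 0.1
    min_depth: int = 2
    min_callable_sites: int = 3
    max_unknown: list[int] = field(default_factory=lambda: [3])
    seed: int = 0
    workers: int = 1

    def save(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    @classmethod
    def load(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


@dataclass
class SimulatedDataset:
    tree: SimTree
    genomes: GenomeSet
    batches: dict[str, ReadBatch]


def simulate_dataset(config: RunConfig) -> SimulatedDataset:
    """Tree -> genomes -> reads for every taxon, seeds derived per stage."""
    tree = make_tree(config.topology, config.variant, config.scaler)
    genomes = evolve_genomes(tree, config.genome_length,
                             stage_seed(config.seed, "evolve"))
    batches = {}
    for taxon in genomes.taxa:
        batches[taxon] = simulate_reads(
            genomes.sequences[taxon], config.coverage,
            read_length=config.read_length, insert_mean=config.insert_mean,
            insert_sd=config.insert_sd, error_rate=config.error_rate,
            seed=stage_seed(config.seed, f"reads:{taxon}"), species=taxon)
    return SimulatedDataset(tree=tree, genomes=genomes, batches=batches)


@dataclass
class CoreResult:
    plan_quotas: dict[str, int]
    subsampled: dict[str, ReadBatch]
    composite: CompositeGenome
    pileup: Pileup
    matrix: "consensus_mod.SpeciesCallMatrix"
    alignments: dict[int, "sites_mod.VariableSiteAlignment"]


def run_core(batches: dict[str, ReadBatch], config: RunConfig) -> CoreResult:
    """Subsample -> assemble -> map -> call -> sites on in-memory batches."""
    species = sorted(batches)
    read_length = min(b.read_length for b in batches.values())
    plan = plan_subsample(config.genome_size, config.target_depth, species,
                          read_length)
    subsampled = {
        sp: subsample_batch(batches[sp], plan.quotas[sp],
                            stage_seed(config.seed, f"subsample:{sp}"))
        for sp in species}
    logger.info("subsampled reads: %s",
                {sp: 2 * b.n_pairs for sp, b in subsampled.items()})
    composite = assemble_composite(
        subsampled.values(), k=config.k,
        min_kmer_count=config.min_kmer_count,
        min_contig_length=config.min_contig_length)
    logger.info("composite: %d contigs, %d bp",
                composite.n_contigs, composite.total_length)
    index = CompositeIndex(composite, config.seed_length)
    pileup = None
    for sp in species:
        pileup, _ = map_reads(batches[sp], index,
                              seed_length=config.seed_length,
                              max_mismatch_frac=config.max_mismatch_frac,
                              workers=config.workers, pileup=pileup)
    if pileup is None:
        pileup = Pileup(layout=index.layout)
    logger.info("mapping: %s", {sp: pileup.stats[sp]._asdict()
                                for sp in species if sp in pileup.stats})
    matrix = consensus_mod.call_strict_consensus(
        pileup, min_depth=config.min_depth, species=species)
    matrix = sites_mod.filter_loci(matrix, config.min_callable_sites)
    alignments = {m: sites_mod.extract_variable_sites(matrix, m)
                  for m in config.max_unknown}
    logger.info("variable sites per max_unknown: %s",
                {m: a.n_sites for m, a in alignments.items()})
    return CoreResult(plan_quotas=plan.quotas, subsampled=subsampled,
                      composite=composite, pileup=pileup, matrix=matrix,
                      alignments=alignments)


@dataclass
class BenchmarkRun:
    dataset: SimulatedDataset
    core: CoreResult
    report: EvaluationReport


def run_benchmark(config: RunConfig, max_unknown_eval: int | None = None,
                  ) -> BenchmarkRun:
    """Simulate a dataset, run the core pipeline, and score it against truth."""
    dataset = simulate_dataset(config)
    core = run_core(dataset.batches, config)
    census = census_variable_sites(dataset.genomes)
    placements = anchor_composite(core.composite, dataset.genomes,
                                  k_anchor=config.k)
    m = max_unknown_eval if max_unknown_eval is not None \
        else max(config.max_unknown)
    report = score_run(core.alignments[m], census, placements, core.pileup,
                       core.composite, dataset.batches,
                       min_depth=config.min_depth,
                       genome_length=dataset.genomes.length,
                       tree=dataset.tree)
    return BenchmarkRun(dataset=dataset, core=core, report=report)


def run_pipeline(config: RunConfig, out_dir) -> Path:
    """Run end to end and write all artifacts into ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.save(out / "config.yaml")
    handler = logging.FileHandler(out / "log.txt", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    try:
        simulated = not config.fastq
        if simulated:
            dataset = simulate_dataset(config)
            batches = dataset.batches
            dataset.genomes.write_fasta(out / "true_genomes.fasta",
                                        include_root=True)
        else:
            from .io import batch_from_fastq
            batches = {sp: batch_from_fastq(sp, paths)
                       for sp, paths in config.fastq.items()}
        logger.info("input reads: %s",
                    {sp: 2 * b.n_pairs for sp, b in batches.items()})
        core = run_core(batches, config)
        core.composite.write_fasta(out / "composite.fasta")
        core.pileup.write_tsv(out / "pileup.tsv")
        core.matrix.write_tsv(out / "call_matrix.tsv")
        for m, aln in core.alignments.items():
            sites_mod.export_alignment(aln, out / f"alignment_m{m}.fasta",
                                       "fasta",
                                       sidecar_path=out / f"sites_m{m}.tsv")
        if simulated:
            census = census_variable_sites(dataset.genomes)
            census.write_tsv(out / "true_variable_sites.tsv")
            placements = anchor_composite(core.composite, dataset.genomes,
                                          k_anchor=config.k)
            m = max(config.max_unknown)
            report = score_run(core.alignments[m], census, placements,
                               core.pileup, core.composite, batches,
                               min_depth=config.min_depth,
                               genome_length=dataset.genomes.length,
                               tree=dataset.tree)
            report.to_json(out / "evaluation.json")
            logger.info("evaluation: sites simulated=%d output=%d "
                        "recovered=%d false_positive=%d",
                        report.n_true_variable, report.n_output,
                        report.n_true_recovered, report.n_false_positive)
    finally:
        logger.removeHandler(handler)
        handler.close()
    return out
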