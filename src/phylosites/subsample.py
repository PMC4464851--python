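"""Uniform read subsampling by single-pass reservoir sampling.

Composite-genome assembly only needs roughly 10x pooled coverage of a
user-specified approximate genome size, split equally across species.
Each species' FASTQ stream is therefore reduced to a fixed quota with
Algorithm R: the first ``quota`` records fill the reservoir, and the i-th
record thereafter replaces a uniformly chosen slot with probability
``quota / (i+1)``. The pass is single and memory stays proportional to the
quota, never the stream length. Paired reads are sampled as units so mates
are never split.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass
from typing import Iterable, Iterator, Sequence

import numpy as np
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .errors import ConfigurationError, FastqParseError
from .reads import ReadBatch

_CHUNK = 8192


@dataclass
class SubsamplePlan:
    """Per-species read quotas realizing the pooled target depth."""

    genome_size: int
    target_depth: float
    read_length: int
    quotas: dict[str, int]

    @property
    def total_reads(self) -> int:
        return sum(self.quotas.values())


def plan_subsample(genome_size: int, target_depth: float,
                   species: Sequence[str],
                   read_length: int) -> SubsamplePlan:
    """Split a ``target_depth x genome_size`` base budget equally by species.

    quota = round(target_depth * genome_size / (read_length * n_species))
    reads per species, reported before any sampling happens.
    """
    if genome_size <= 0:
        raise ConfigurationError("genome_size must be positive")
    if read_length <= 0:
        raise ConfigurationError("read_length must be positive")
    if len(species) < 2:
        raise ConfigurationError("need at least two species")
    if target_depth < 0:
        raise ConfigurationError("target_depth must be >= 0")
    quota = int(round(target_depth * genome_size
                      / (read_length * len(species))))
    return SubsamplePlan(genome_size=genome_size, target_depth=target_depth,
                         read_length=read_length,
                         quotas={s: quota for s in species})


def reservoir_sample(records: Iterable, quota: int, seed: int) -> list:
    """Uniform sample of exactly ``min(quota, N)`` records in one pass.

    Works on any iterable of records without knowing ``N`` in advance.
    Returns records in reservoir order (an arbitrary but seed-deterministic
    order).
    """
    if quota < 0:
        raise ConfigurationError("quota must be >= 0")
    if quota == 0:
        # drain the stream so parse errors are still surfaced
        for _ in records:
            pass
        return []
    rng = np.random.default_rng(seed)
    reservoir: list = []
    n_seen = 0
    it = iter(records)
    while True:
        chunk = []
        for rec in it:
            chunk.append(rec)
            if len(chunk) >= _CHUNK:
                break
        if not chunk:
            break
        if n_seen < quota:
            head = chunk[:max(0, quota - n_seen)]
            reservoir.extend(head)
            chunk = chunk[len(head):]
            n_seen += len(head)
        if chunk:
            # vectorized slot draws; replacements applied in stream order
            idx = np.arange(n_seen, n_seen + len(chunk))
            slots = np.floor(rng.random(len(chunk)) * (idx + 1)).astype(np.int64)
            for item, j in zip(chunk, slots):
                if j < quota:
                    reservoir[j] = item
            n_seen += len(chunk)
    return reservoir


def subsample_batch(batch: ReadBatch, quota_reads: int, seed: int) -> ReadBatch:
    """Reservoir-sample an in-memory batch, pairs as units.

    ``quota_reads`` counts reads (mates individually), as in the plan; the
    pair quota is ``quota_reads // 2``.
    """
    n_pairs_quota = quota_reads // 2
    idx = reservoir_sample(range(batch.n_pairs), n_pairs_quota, seed)
    idx = np.array(sorted(idx), dtype=np.int64)
    return batch.subset(idx)


def _fastq_records(handle, label: str) -> Iterator[tuple[str, str, str]]:
    i = -1
    try:
        for i, rec in enumerate(FastqGeneralIterator(handle)):
            yield rec
    except ValueError as exc:
        raise FastqParseError(
            f"{label}: malformed FASTQ at record {i + 1}: {exc}") from exc


def _open_text(path):
    if str(path).endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path)


def iter_fastq(path) -> Iterator[tuple[str, str, str]]:
    """Stream (title, sequence, quality) tuples from plain or gzipped FASTQ."""
    with _open_text(path) as fh:
        yield from _fastq_records(fh, str(path))


def iter_fastq_pairs(path1, path2) -> Iterator[tuple]:
    """Stream mate-paired records ((t1, s1, q1), (t2, s2, q2))."""
    with _open_text(path1) as f1, _open_text(path2) as f2:
        it1 = _fastq_records(f1, str(path1))
        it2 = _fastq_records(f2, str(path2))
        for rec1, rec2 in zip(it1, it2):
            yield rec1, rec2


def write_fastq(records: Iterable[tuple[str, str, str]], path) -> None:
    op = gzip.open if str(path).endswith(".gz") else open
    with op(path, "wt") as fh:
        for title, seq, qual in records:
            fh.write(f"@{title}\n{seq}\n+\n{qual}\n")


def subsample_fastq(in_paths, out_paths, quota_reads: int, seed: int) -> int:
    """Subsample single (1 path) or paired (2 paths) FASTQ files.

    Pairs count as one sampled record (both mates kept), so the read quota is
    halved for paired input. Returns the number of records written.
    """
    if len(in_paths) == 1:
        sample = reservoir_sample(iter_fastq(in_paths[0]), quota_reads, seed)
        write_fastq(sample, out_paths[0])
        return len(sample)
    if len(in_paths) == 2:
        sample = reservoir_sample(iter_fastq_pairs(*in_paths),
                                  quota_reads // 2, seed)
        write_fastq((r[0] for r in sample), out_paths[0])
        write_fastq((r[1] for r in sample), out_paths[1])
        return len(sample)
    raise ConfigurationError("expected 1 (single-end) or 2 (paired) FASTQ paths")
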