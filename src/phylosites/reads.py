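"""Paired-end shotgun read simulation with a parametric error model.

Fragments are drawn uniformly along a linear genome with normally distributed
lengths (truncated to ``[read_length, genome_length]``); mate 1 reads the
fragment 5' end, mate 2 the reverse complement of its 3' end, with the
fragment's strand chosen uniformly. Sequencing error is a uniform per-base
substitution (default 0.1%) to a random different base; quality strings are a
constant Phred+33 character encoding the error rate used. True fragment
origins are recorded so the evaluator can match reads back to the genome.
"""

from __future__ import annotations

import gzip
import math
from dataclasses import dataclass, field

import numpy as np

from . import _seq

DEFAULT_READ_LENGTH = 100
DEFAULT_INSERT_MEAN = 300
DEFAULT_INSERT_SD = 30
DEFAULT_ERROR_RATE = 0.001


def _phred_char(error_rate: float) -> str:
    q = 40 if error_rate <= 0 else min(40, round(-10.0 * math.log10(error_rate)))
    return chr(33 + q)


@dataclass
class ReadBatch:
    """One species' simulated read pairs as dense arrays.

    ``r1``/``r2`` are uint8 code matrices of shape ``(n_pairs, read_length)``;
    ``starts``/``lengths`` give each fragment's genome interval and
    ``strands`` (+1/-1) which strand the fragment was read from.
    """

    species: str
    read_length: int
    coverage: float
    seed: int
    error_rate: float
    r1: np.ndarray
    r2: np.ndarray
    starts: np.ndarray
    lengths: np.ndarray
    strands: np.ndarray
    quality_char: str = field(default="I")

    @property
    def n_pairs(self) -> int:
        return len(self.starts)

    def read_id(self, i: int) -> str:
        return f"{self.species}_{i}"

    def mate_intervals(self) -> np.ndarray:
        """(n_pairs, 2, 2) genome [start, end) intervals of both mates."""
        ends = self.starts + self.lengths
        m1 = np.stack([self.starts, self.starts + self.read_length], axis=1)
        m2 = np.stack([ends - self.read_length, ends], axis=1)
        return np.stack([m1, m2], axis=1)

    def iter_records(self):
        """Yield (read_id, seq1, qual1, seq2, qual2) as strings."""
        q = self.quality_char * self.read_length
        for i in range(self.n_pairs):
            yield (self.read_id(i), _seq.decode(self.r1[i]), q,
                   _seq.decode(self.r2[i]), q)

    def write_fastq(self, path1, path2) -> None:
        """Write the pair as (optionally gzipped) _R1/_R2 FASTQ files."""
        op = gzip.open if str(path1).endswith(".gz") else open
        with op(path1, "wt") as f1, op(path2, "wt") as f2:
            for rid, s1, q1, s2, q2 in self.iter_records():
                f1.write(f"@{rid}/1\n{s1}\n+\n{q1}\n")
                f2.write(f"@{rid}/2\n{s2}\n+\n{q2}\n")

    def write_origins(self, path) -> None:
        """Sidecar table of true fragment origins for the evaluator."""
        with open(path, "w") as fh:
            fh.write("read_id\tstart\tfragment_length\tstrand\n")
            for i in range(self.n_pairs):
                strand = "+" if self.strands[i] > 0 else "-"
                fh.write(f"{self.read_id(i)}\t{self.starts[i]}\t"
                         f"{self.lengths[i]}\t{strand}\n")

    def subset(self, idx: np.ndarray) -> "ReadBatch":
        return ReadBatch(
            species=self.species, read_length=self.read_length,
            coverage=self.coverage, seed=self.seed, error_rate=self.error_rate,
            r1=self.r1[idx], r2=self.r2[idx], starts=self.starts[idx],
            lengths=self.lengths[idx], strands=self.strands[idx],
            quality_char=self.quality_char)


def _apply_errors(reads: np.ndarray, error_rate: float,
                  rng: np.random.Generator) -> None:
    if error_rate <= 0:
        return
    hit = rng.random(reads.shape) < error_rate
    n = int(hit.sum())
    if n:
        reads[hit] = (reads[hit] + rng.integers(1, 4, size=n, dtype=np.uint8)) % 4


def simulate_reads(genome: np.ndarray, coverage: float, *,
                   read_length: int = DEFAULT_READ_LENGTH,
                   insert_mean: float = DEFAULT_INSERT_MEAN,
                   insert_sd: float = DEFAULT_INSERT_SD,
                   error_rate: float = DEFAULT_ERROR_RATE,
                   seed: int = 0, species: str = "sample") -> ReadBatch:
    """Simulate paired-end reads at the requested fold coverage.

    The pair count is ``round(coverage * L / (2 * read_length))`` so total
    sequenced bases match ``coverage * L`` to within one read pair.
    """
    L = len(genome)
    if L < read_length:
        raise ValueError(
            f"genome length {L} shorter than read length {read_length}")
    if coverage <= 0:
        raise ValueError("coverage must be positive")
    rng = np.random.default_rng(seed)
    n_pairs = int(round(coverage * L / (2 * read_length)))
    lengths = np.rint(rng.normal(insert_mean, insert_sd, size=n_pairs))
    lengths = np.clip(lengths, read_length, L).astype(np.int64)
    # uniform start over valid positions for each fragment length
    starts = np.floor(rng.random(n_pairs) * (L - lengths + 1)).astype(np.int64)
    strands = np.where(rng.random(n_pairs) < 0.5, 1, -1).astype(np.int8)

    offs = np.arange(read_length)
    five = genome[starts[:, None] + offs]                      # fragment 5' end
    three_start = starts + lengths - read_length
    three = genome[three_start[:, None] + offs]                # fragment 3' end
    three_rc = _seq.COMP_CODE[three][:, ::-1]

    # plus-strand fragment: r1 = 5' end (forward), r2 = revcomp of 3' end;
    # minus-strand: r1 reads the reverse strand from the 3' end, r2 the
    # forward strand at the 5' end
    plus = strands > 0
    r1 = np.where(plus[:, None], five, three_rc).astype(np.uint8)
    r2 = np.where(plus[:, None], three_rc, five).astype(np.uint8)

    _apply_errors(r1, error_rate, rng)
    _apply_errors(r2, error_rate, rng)
    return ReadBatch(
        species=species, read_length=read_length, coverage=coverage,
        seed=seed, error_rate=error_rate, r1=r1, r2=r2, starts=starts,
        lengths=lengths, strands=strands,
        quality_char=_phred_char(error_rate))
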