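"""Composite-genome assembly with a built-in de Bruijn assembler.

Reads subsampled from *all* species are pooled and assembled jointly, so
regions conserved across taxa reach assemblable k-mer coverage while
species-unique or fast-evolving regions are pruned away with the error
k-mers. The resulting "composite genome" is a mosaic of conserved-region
contigs that serves as the pipeline's mapping reference; at columns where
species disagree it carries the most common base, because bubbles between
haplotype paths are popped in favor of the higher-coverage branch.

Graph model: nodes are canonical (strand-merged) k-mers; an edge exists
between two oriented k-mers overlapping by k-1. Assembly steps:

1. count canonical k-mers over all pooled reads; drop count < min_kmer_count;
2. repeatedly compact the graph into unitigs, clipping dead-end tips shorter
   than 2k and popping parallel paths (bubbles) between the same pair of
   junctions, keeping the higher-coverage path;
3. emit maximal unbranched paths of length >= min_contig_length as contigs.

An adapter contract allows an external assembler executable to stand in.
"""

from __future__ import annotations

import subprocess
import tempfile
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO

from . import _seq
from ._seq import canonical, revcomp_bytes
from .errors import AdapterError
from .reads import ReadBatch

DEFAULT_K = 31
DEFAULT_MIN_KMER_COUNT = 2
DEFAULT_MIN_CONTIG_LENGTH = 100
_MAX_SIMPLIFY_ROUNDS = 24

_EXT = [bytes([b]) for b in b"ACGT"]


@dataclass
class CompositeGenome:
    """Assembled contigs; the pipeline's coordinate system."""

    contigs: list[tuple[str, bytes]]
    k: int
    provenance: dict = field(default_factory=dict)

    @property
    def n_contigs(self) -> int:
        return len(self.contigs)

    @property
    def total_length(self) -> int:
        return sum(len(s) for _, s in self.contigs)

    def contig_dict(self) -> dict[str, bytes]:
        return dict(self.contigs)

    def write_fasta(self, path) -> None:
        with open(path, "w") as fh:
            for cid, seq in self.contigs:
                fh.write(f">{cid}\n{seq.decode()}\n")

    @classmethod
    def from_fasta(cls, path, k: int = DEFAULT_K,
                   provenance: dict | None = None) -> "CompositeGenome":
        contigs = [(rec.id, str(rec.seq).upper().encode())
                   for rec in SeqIO.parse(str(path), "fasta")]
        return cls(contigs=contigs, k=k, provenance=provenance or {})


def count_kmers(batches: Iterable[ReadBatch], k: int) -> Counter:
    """Canonical k-mer counts over all reads (both mates) of all batches."""
    counts: Counter = Counter()
    for batch in batches:
        for mat in (batch.r1, batch.r2):
            # rows are fixed-width; slice k-mers out of each row
            data = _seq.DECODE[mat].tobytes()
            L = mat.shape[1]
            for r in range(mat.shape[0]):
                row = data[r * L:(r + 1) * L]
                counts.update(canonical(row[i:i + k])
                              for i in range(L - k + 1))
    return counts


def _successors(seq_kmer: bytes, counts) -> list[bytes]:
    core = seq_kmer[1:]
    return [core + e for e in _EXT if canonical(core + e) in counts]


def _predecessors(seq_kmer: bytes, counts) -> list[bytes]:
    core = seq_kmer[:-1]
    return [e + core for e in _EXT if canonical(e + core) in counts]


@dataclass
class Unitig:
    seq: bytes          # canonical spelling (min of seq, revcomp)
    n_kmers: int
    mean_coverage: float


def _walk_forward(start: bytes, counts, in_path: set) -> list[bytes]:
    """Extend right from an oriented k-mer while the path stays simple."""
    path = []
    cur = start
    while True:
        succs = _successors(cur, counts)
        if len(succs) != 1:
            break
        nxt = succs[0]
        if len(_predecessors(nxt, counts)) != 1:
            break
        cn = canonical(nxt)
        if cn in in_path:
            break  # cycle
        path.append(nxt)
        in_path.add(cn)
        cur = nxt
    return path


def build_unitigs(counts, k: int) -> list[Unitig]:
    """Compact the k-mer graph into maximal simple paths (each k-mer once)."""
    visited: set[bytes] = set()
    unitigs = []
    for km in sorted(counts):
        if km in visited:
            continue
        in_path = {km}
        fwd = _walk_forward(km, counts, in_path)
        bwd = _walk_forward(revcomp_bytes(km), counts, in_path)
        # backward path, reoriented
        left = [revcomp_bytes(x) for x in reversed(bwd)]
        chain = left + [km] + fwd
        seq = chain[0] + b"".join(x[-1:] for x in chain[1:])
        seq = min(seq, revcomp_bytes(seq))
        cov = float(np.mean([counts[canonical(x)] for x in chain]))
        unitigs.append(Unitig(seq=seq, n_kmers=len(chain), mean_coverage=cov))
        visited.update(canonical(x) for x in chain)
    return unitigs


def _unitig_kmers(seq: bytes, k: int):
    return (canonical(seq[i:i + k]) for i in range(len(seq) - k + 1))


def _remove_unitig(u: Unitig, counts, k: int) -> None:
    for km in _unitig_kmers(u.seq, k):
        counts.pop(km, None)


def _clip_tips(unitigs: Sequence[Unitig], counts, k: int) -> int:
    """Remove dead-end unitigs shorter than 2k that hang off a junction."""
    removed = 0
    for u in unitigs:
        if len(u.seq) >= 2 * k:
            continue
        n_pred = len(_predecessors(u.seq[:k], counts))
        n_succ = len(_successors(u.seq[-k:], counts))
        if (n_pred == 0) != (n_succ == 0):  # exactly one free end
            _remove_unitig(u, counts, k)
            removed += 1
    return removed


def _bubble_key(u: Unitig, counts, k: int):
    """Junction pair flanking a candidate bubble path, orientation-normalized."""
    preds = _predecessors(u.seq[:k], counts)
    succs = _successors(u.seq[-k:], counts)
    if len(preds) != 1 or len(succs) != 1:
        return None
    a, b = preds[0], succs[0]
    return min((a, b), (revcomp_bytes(b), revcomp_bytes(a)))


def _pop_bubbles(unitigs: Sequence[Unitig], counts, k: int) -> int:
    """Keep the highest-coverage path among parallel same-junction paths.

    Coverage plurality realizes most-common-base composites; ties break to
    the lexicographically smallest sequence for determinism.
    """
    groups: dict = {}
    for u in unitigs:
        key = _bubble_key(u, counts, k)
        if key is not None:
            groups.setdefault(key, []).append(u)
    removed = 0
    for group in groups.values():
        if len(group) < 2:
            continue
        group.sort(key=lambda u: (-u.mean_coverage, u.seq))
        for loser in group[1:]:
            _remove_unitig(loser, counts, k)
            removed += 1
    return removed


def assemble_composite(pooled_reads: Iterable[ReadBatch], *,
                       k: int = DEFAULT_K,
                       min_kmer_count: int = DEFAULT_MIN_KMER_COUNT,
                       min_contig_length: int = DEFAULT_MIN_CONTIG_LENGTH,
                       ) -> CompositeGenome:
    """Assemble the pooled multi-species subsample into a composite genome."""
    batches = list(pooled_reads)
    if batches:
        read_length = min(b.read_length for b in batches)
        if not (k % 2 == 1 and 15 <= k < read_length):
            raise ValueError(f"k must be odd and in [15, read_length), got {k}")
    if min_kmer_count < 1:
        raise ValueError("min_kmer_count must be >= 1")
    counts = count_kmers(batches, k)
    counts = {km: c for km, c in counts.items() if c >= min_kmer_count}
    for _ in range(_MAX_SIMPLIFY_ROUNDS):
        unitigs = build_unitigs(counts, k)
        removed = _clip_tips(unitigs, counts, k)
        if removed == 0:
            removed = _pop_bubbles(unitigs, counts, k)
        if removed == 0:
            break
    unitigs = build_unitigs(counts, k)
    final = sorted((u for u in unitigs if len(u.seq) >= min_contig_length),
                   key=lambda u: (-len(u.seq), u.seq))
    width = max(5, len(str(len(final))))
    contigs = [(f"contig_{i:0{width}d}", u.seq) for i, u in enumerate(final, 1)]
    return CompositeGenome(
        contigs=contigs, k=k,
        provenance={"assembler": "phylosites-dbg", "k": k,
                    "min_kmer_count": min_kmer_count,
                    "min_contig_length": min_contig_length})


def contig_is_graph_walk(seq: bytes, counts, k: int) -> bool:
    """True if every k-mer of the contig exists in the (pruned) graph."""
    return all(canonical(seq[i:i + k]) in counts
               for i in range(len(seq) - k + 1))


def external_assembler_adapter(command_template: str,
                               pooled_reads: Iterable[ReadBatch],
                               k: int = DEFAULT_K) -> CompositeGenome:
    """Run an external assembler producing contig FASTA.

    ``command_template`` is shell-formatted with ``{reads}`` (interleaved
    FASTQ of the pooled subsample) and ``{out}`` (expected contig FASTA
    path). Nonzero exit or unparsable output raises :class:`AdapterError`
    carrying the captured log.
    """
    with tempfile.TemporaryDirectory() as tmp:
        reads_path = Path(tmp) / "pooled.fastq"
        out_path = Path(tmp) / "contigs.fasta"
        with open(reads_path, "w") as fh:
            for batch in pooled_reads:
                for rid, s1, q1, s2, q2 in batch.iter_records():
                    fh.write(f"@{rid}/1\n{s1}\n+\n{q1}\n")
                    fh.write(f"@{rid}/2\n{s2}\n+\n{q2}\n")
        cmd = command_template.format(reads=reads_path, out=out_path)
        proc = subprocess.run(cmd, shell=True, capture_output=True, text=True)
        log = proc.stdout + proc.stderr
        if proc.returncode != 0:
            raise AdapterError(
                f"external assembler exited with {proc.returncode}", log=log)
        if not out_path.exists():
            raise AdapterError("external assembler produced no output", log=log)
        try:
            composite = CompositeGenome.from_fasta(
                out_path, k=k, provenance={"assembler": cmd})
        except Exception as exc:  # noqa: BLE001 - adapter contract
            raise AdapterError(f"unparsable assembler output: {exc}",
                               log=log) from exc
        if any(set(seq) - set(b"ACGTN") for _, seq in composite.contigs):
            raise AdapterError("assembler output contains non-nucleotide "
                               "characters", log=log)
        return composite
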