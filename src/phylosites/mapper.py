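"""K-mer seed-and-extend read mapping against the composite genome.

Each read is tried in both orientations: exact seed hits of ``seed_length``
bases are collected from an index of all composite k-mer positions, every
candidate placement is extended end-to-end without gaps, and the placement
with the fewest mismatches wins if its mismatch count is at most
``max_mismatch_frac * read_length``. Reads whose best score is tied across
two or more placements are discarded as ambiguous — only uniquely mapped
reads contribute to the per-site, per-species base pileups downstream
consensus calling consumes.

Mates are mapped independently; the pileup is a pure sum over accepted reads,
so it is invariant to read order and to how work is chunked across workers.
"""

from __future__ import annotations

from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple

import numpy as np

from . import _seq
from .assemble import CompositeGenome
from .reads import ReadBatch

DEFAULT_SEED_LENGTH = 25
DEFAULT_MAX_MISMATCH_FRAC = 0.1


@dataclass
class CompositeLayout:
    """Concatenated coordinate layout of composite contigs."""

    contig_ids: list[str]
    lengths: np.ndarray      # int64 per contig
    starts: np.ndarray       # int64 global start of each contig
    total: int

    @classmethod
    def from_composite(cls, composite: CompositeGenome) -> "CompositeLayout":
        ids = [cid for cid, _ in composite.contigs]
        lengths = np.array([len(s) for _, s in composite.contigs], dtype=np.int64)
        starts = np.concatenate([[0], np.cumsum(lengths)[:-1]]).astype(np.int64)
        return cls(contig_ids=ids, lengths=lengths, starts=starts,
                   total=int(lengths.sum()))

    def locate(self, gpos: int) -> tuple[str, int]:
        i = int(np.searchsorted(self.starts, gpos, side="right")) - 1
        return self.contig_ids[i], int(gpos - self.starts[i])

    def contig_index(self, gpos: int) -> int:
        return int(np.searchsorted(self.starts, gpos, side="right")) - 1

    def global_pos(self, contig_id: str, offset: int) -> int:
        return int(self.starts[self.contig_ids.index(contig_id)] + offset)


class CompositeIndex:
    """Every-position seed index over the concatenated composite."""

    def __init__(self, composite: CompositeGenome,
                 seed_length: int = DEFAULT_SEED_LENGTH):
        self.composite = composite
        self.seed_length = seed_length
        self.layout = CompositeLayout.from_composite(composite)
        seqs = [s for _, s in composite.contigs]
        cat = b"".join(seqs)
        self.genome_codes = _seq.encode(cat) if cat else np.empty(0, np.uint8)
        index: dict[bytes, list[int]] = {}
        s = seed_length
        for cstart, seq in zip(self.layout.starts, seqs):
            for i in range(len(seq) - s + 1):
                index.setdefault(seq[i:i + s], []).append(int(cstart) + i)
        self.index = index
        self.contig_ends = self.layout.starts + self.layout.lengths


class MapStats(NamedTuple):
    n_reads: int
    n_mapped: int
    n_ambiguous: int
    n_unmapped: int
    aligned_bases: int


class AlignmentRecord(NamedTuple):
    read_id: str
    mate: int
    contig: str
    offset: int
    strand: str
    mismatches: int


@dataclass
class Pileup:
    """Per (site, species) A/C/G/T counts from uniquely mapped reads."""

    layout: CompositeLayout
    counts: dict[str, np.ndarray] = field(default_factory=dict)  # (4, total)
    stats: dict[str, MapStats] = field(default_factory=dict)

    def species_counts(self, species: str) -> np.ndarray:
        if species not in self.counts:
            self.counts[species] = np.zeros((4, self.layout.total),
                                            dtype=np.uint32)
        return self.counts[species]

    def depth(self, species: str) -> np.ndarray:
        return self.species_counts(species).sum(axis=0)

    @property
    def species(self) -> list[str]:
        return sorted(self.counts)

    def site_counts(self, contig_id: str, offset: int,
                    species: str) -> dict[str, int]:
        g = self.layout.global_pos(contig_id, offset)
        col = self.species_counts(species)[:, g]
        return {b: int(c) for b, c in zip("ACGT", col) if c}

    @classmethod
    def from_tsv(cls, path, layout: "CompositeLayout") -> "Pileup":
        """Read back a pileup written by :meth:`write_tsv`."""
        pileup = cls(layout=layout)
        cid_to_start = dict(zip(layout.contig_ids, layout.starts))
        with open(path) as fh:
            header = fh.readline()
            assert header.startswith("contig\t")
            for line in fh:
                cid, pos, sp, a, c, g, t = line.rstrip("\n").split("\t")
                counts = pileup.species_counts(sp)
                gpos = int(cid_to_start[cid]) + int(pos)
                counts[:, gpos] = (int(a), int(c), int(g), int(t))
        return pileup

    def write_tsv(self, path) -> None:
        """Nonzero sites as (contig, pos, species, A, C, G, T) rows."""
        with open(path, "w") as fh:
            fh.write("contig\tpos\tspecies\tA\tC\tG\tT\n")
            for sp in self.species:
                counts = self.counts[sp]
                nz = np.flatnonzero(counts.sum(axis=0))
                for g in nz:
                    cid, off = self.layout.locate(int(g))
                    a, c, gg, t = (int(x) for x in counts[:, g])
                    fh.write(f"{cid}\t{off}\t{sp}\t{a}\t{c}\t{gg}\t{t}\n")


def _map_chunk(idx: CompositeIndex, rows_f, bytes_f, rows_r, bytes_r,
               row_ids, seed_offs, max_mm):
    """Map one chunk of reads; returns accepted placements and tallies."""
    genome = idx.genome_codes
    index = idx.index
    starts_arr = idx.layout.starts
    ends_arr = idx.contig_ends
    L = rows_f.shape[1]
    acc_starts = [[], []]   # per orientation (0 fwd, 1 rc)
    acc_rows = [[], []]
    acc_mm = [[], []]
    n_mapped = n_ambig = n_unmap = 0
    for r in range(rows_f.shape[0]):
        cands = set()
        for orient, bl in ((0, bytes_f), (1, bytes_r)):
            b = bl[r]
            for off in seed_offs:
                hits = index.get(b[off:off + idx.seed_length])
                if hits:
                    for p in hits:
                        cands.add((p - off, orient))
        best = None
        best_mm = max_mm + 1
        tied = False
        for g, orient in cands:
            if g < 0:
                continue
            ci = np.searchsorted(starts_arr, g, side="right") - 1
            if g + L > ends_arr[ci]:
                continue
            row = rows_f[r] if orient == 0 else rows_r[r]
            mm = int(np.count_nonzero(genome[g:g + L] != row))
            if mm < best_mm:
                best, best_mm, tied = (g, orient), mm, False
            elif mm == best_mm and best is not None and (g, orient) != best:
                tied = True
        if best is None or best_mm > max_mm:
            n_unmap += 1
        elif tied:
            n_ambig += 1
        else:
            g, orient = best
            acc_starts[orient].append(g)
            acc_rows[orient].append(row_ids[r])
            acc_mm[orient].append(best_mm)
            n_mapped += 1
    return acc_starts, acc_rows, acc_mm, n_mapped, n_ambig, n_unmap


def _seed_offsets(read_length: int, seed_length: int) -> list[int]:
    offs = list(range(0, read_length - seed_length + 1, seed_length))
    tail = read_length - seed_length
    if tail not in offs:
        offs.append(tail)
    return offs


def map_reads(batch: ReadBatch, composite: CompositeGenome | CompositeIndex, *,
              seed_length: int = DEFAULT_SEED_LENGTH,
              max_mismatch_frac: float = DEFAULT_MAX_MISMATCH_FRAC,
              workers: int = 1, pileup: Pileup | None = None,
              keep_alignments: bool = False,
              ) -> tuple[Pileup, list[AlignmentRecord] | None]:
    """Map both mates of every pair and accumulate the species' pileup.

    Results are byte-identical for any ``workers`` value: chunks are merged
    in fixed order and the pileup is an order-free sum.
    """
    idx = (composite if isinstance(composite, CompositeIndex)
           else CompositeIndex(composite, seed_length))
    if seed_length > batch.read_length:
        raise ValueError("seed_length must be <= read_length")
    layout = idx.layout
    if pileup is None:
        pileup = Pileup(layout=layout)
    counts = pileup.species_counts(batch.species)
    L = batch.read_length
    max_mm = int(max_mismatch_frac * L)
    seed_offs = _seed_offsets(L, idx.seed_length)

    # mates concatenated: rows 0..n-1 are mate 1, n..2n-1 are mate 2
    rows_f = np.vstack([batch.r1, batch.r2])
    rows_r = _seq.COMP_CODE[rows_f][:, ::-1].copy()
    data_f = _seq.DECODE[rows_f].tobytes()
    data_r = _seq.DECODE[rows_r].tobytes()
    bytes_f = [data_f[i * L:(i + 1) * L] for i in range(rows_f.shape[0])]
    bytes_r = [data_r[i * L:(i + 1) * L] for i in range(rows_r.shape[0])]
    row_ids = np.arange(rows_f.shape[0])

    n = rows_f.shape[0]
    n_chunks = max(1, min(n, workers * 4 if workers > 1 else 1))
    bounds = np.linspace(0, n, n_chunks + 1).astype(int)
    jobs = []
    for lo, hi in zip(bounds[:-1], bounds[1:]):
        jobs.append((rows_f[lo:hi], bytes_f[lo:hi], rows_r[lo:hi],
                     bytes_r[lo:hi], row_ids[lo:hi]))

    def run(job):
        rf, bf, rr, br, ri = job
        return _map_chunk(idx, rf, bf, rr, br, ri, seed_offs, max_mm)

    if workers > 1 and len(jobs) > 1:
        with ThreadPoolExecutor(max_workers=workers) as pool:
            results = list(pool.map(run, jobs))
    else:
        results = [run(job) for job in jobs]

    total = layout.total
    flat = counts.reshape(-1)
    n_mapped = n_ambig = n_unmap = 0
    alignments: list[AlignmentRecord] | None = [] if keep_alignments else None
    offs = np.arange(L)
    for acc_starts, acc_rows, acc_mm, m, a, u in results:
        n_mapped += m
        n_ambig += a
        n_unmap += u
        for orient in (0, 1):
            if not acc_starts[orient]:
                continue
            starts = np.asarray(acc_starts[orient], dtype=np.int64)
            rows_sel = np.asarray(acc_rows[orient], dtype=np.int64)
            codes = (rows_f if orient == 0 else rows_r)[rows_sel]
            pos = starts[:, None] + offs
            lin = codes.astype(np.int64) * total + pos
            np.add.at(flat, lin[codes < 4], 1)  # N read bases contribute nothing
            if alignments is not None:
                for s0, ri, mm in zip(starts, rows_sel,
                                      acc_mm[orient]):
                    cid, off = layout.locate(int(s0))
                    mate = 1 if ri < batch.n_pairs else 2
                    rid = batch.read_id(int(ri % batch.n_pairs))
                    alignments.append(AlignmentRecord(
                        read_id=rid, mate=mate, contig=cid, offset=off,
                        strand="+" if orient == 0 else "-",
                        mismatches=int(mm)))
    prev = pileup.stats.get(batch.species)
    stats = MapStats(
        n_reads=n + (prev.n_reads if prev else 0),
        n_mapped=n_mapped + (prev.n_mapped if prev else 0),
        n_ambiguous=n_ambig + (prev.n_ambiguous if prev else 0),
        n_unmapped=n_unmap + (prev.n_unmapped if prev else 0),
        aligned_bases=n_mapped * L + (prev.aligned_bases if prev else 0))
    pileup.stats[batch.species] = stats
    if alignments is not None:
        alignments.sort()
    return pileup, alignments


def pileup_from_origins(batch: ReadBatch, genome_length: int,
                        contig_id: str = "root",
                        pileup: Pileup | None = None) -> Pileup:
    """Truthful pileup: place every read at its recorded origin.

    Used by the evaluation oracle: the 'composite' is the true root genome as
    a single contig and mapping is bypassed entirely.
    """
    layout = CompositeLayout(contig_ids=[contig_id],
                             lengths=np.array([genome_length], dtype=np.int64),
                             starts=np.array([0], dtype=np.int64),
                             total=genome_length)
    if pileup is None:
        pileup = Pileup(layout=layout)
    counts = pileup.species_counts(batch.species)
    flat = counts.reshape(-1)
    L = batch.read_length
    offs = np.arange(L)
    plus = batch.strands > 0
    ends = batch.starts + batch.lengths
    # forward-strand codes at the 5' interval and at the 3' interval
    five_codes = np.where(plus[:, None], batch.r1, batch.r2)
    three_rc = np.where(plus[:, None], batch.r2, batch.r1)
    three_codes = _seq.COMP_CODE[three_rc][:, ::-1]
    for starts, codes in (
            (batch.starts, five_codes),
            (ends - L, three_codes)):
        pos = starts[:, None] + offs
        lin = codes.astype(np.int64) * genome_length + pos
        np.add.at(flat, lin.ravel(), 1)
    n = 2 * batch.n_pairs
    pileup.stats[batch.species] = MapStats(
        n_reads=n, n_mapped=n, n_ambiguous=0, n_unmapped=0,
        aligned_bases=n * L)
    return pileup


def external_mapper_adapter(command_template: str, batch: ReadBatch,
                            composite: CompositeGenome, *,
                            max_mismatch_frac: float = DEFAULT_MAX_MISMATCH_FRAC,
                            min_mapq: int = 1,
                            pileup: Pileup | None = None) -> Pileup:
    """Run an external mapper producing SAM/BAM against the composite.

    ``command_template`` is shell-formatted with ``{ref}`` (composite FASTA),
    ``{r1}``/``{r2}`` (mate FASTQs) and ``{out}`` (expected SAM/BAM path).
    The package's uniqueness and mismatch filters are applied in the form
    expressible from standard fields: records that are unmapped, secondary,
    supplementary, below ``min_mapq`` (multi-mapping), or with edit distance
    NM above ``max_mismatch_frac * read_length`` are dropped. Deleted
    reference bases receive nothing and inserted read bases are ignored.
    """
    import subprocess
    import tempfile

    import pysam

    from .errors import AdapterError

    if pileup is None:
        pileup = Pileup(layout=CompositeLayout.from_composite(composite))
    counts = pileup.species_counts(batch.species)
    layout = pileup.layout
    max_mm = int(max_mismatch_frac * batch.read_length)
    with tempfile.TemporaryDirectory() as tmp:
        tmp = Path(tmp)
        ref = tmp / "composite.fasta"
        r1, r2 = tmp / "r1.fastq", tmp / "r2.fastq"
        out = tmp / "aln.sam"
        composite.write_fasta(ref)
        batch.write_fastq(r1, r2)
        cmd = command_template.format(ref=ref, r1=r1, r2=r2, out=out)
        proc = subprocess.run(cmd, shell=True, capture_output=True, text=True)
        if proc.returncode != 0:
            raise AdapterError(f"external mapper exited with {proc.returncode}",
                               log=proc.stdout + proc.stderr)
        cindex = {cid: i for i, cid in enumerate(layout.contig_ids)}
        n_mapped = aligned = 0
        try:
            with pysam.AlignmentFile(str(out), check_sq=False) as sam:
                for rec in sam:
                    if (rec.is_unmapped or rec.is_secondary
                            or rec.is_supplementary):
                        continue
                    if rec.mapping_quality < min_mapq:
                        continue
                    nm = rec.get_tag("NM") if rec.has_tag("NM") else 0
                    if nm > max_mm:
                        continue
                    gstart = layout.starts[cindex[rec.reference_name]]
                    seq = _seq.encode(rec.query_sequence.upper())
                    pairs = rec.get_aligned_pairs(matches_only=True)
                    qpos = np.array([p[0] for p in pairs], dtype=np.int64)
                    rpos = np.array([p[1] for p in pairs], dtype=np.int64)
                    valid = seq[qpos] < 4
                    np.add.at(counts, (seq[qpos[valid]],
                                       gstart + rpos[valid]), 1)
                    n_mapped += 1
                    aligned += int(valid.sum())
        except (ValueError, KeyError, OSError) as exc:
            raise AdapterError(f"unparsable mapper output: {exc}",
                               log=proc.stdout + proc.stderr) from exc
    prev = pileup.stats.get(batch.species)
    pileup.stats[batch.species] = MapStats(
        n_reads=2 * batch.n_pairs + (prev.n_reads if prev else 0),
        n_mapped=n_mapped + (prev.n_mapped if prev else 0),
        n_ambiguous=0, n_unmapped=2 * batch.n_pairs - n_mapped,
        aligned_bases=aligned + (prev.aligned_bases if prev else 0))
    return pileup


def write_sam(alignments: list[AlignmentRecord], batch: ReadBatch,
              composite: CompositeGenome, path) -> None:
    """Emit accepted alignments as a minimal valid SAM file."""
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unsorted\n")
        for cid, seq in composite.contigs:
            fh.write(f"@SQ\tSN:{cid}\tLN:{len(seq)}\n")
        q = batch.quality_char * batch.read_length
        for rec in alignments:
            i = int(rec.read_id.rsplit("_", 1)[1])
            mat = batch.r1 if rec.mate == 1 else batch.r2
            codes = mat[i]
            flag = 16 if rec.strand == "-" else 0
            seq = _seq.decode(_seq.COMP_CODE[codes][::-1] if flag else codes)
            fh.write(f"{rec.read_id}/{rec.mate}\t{flag}\t{rec.contig}\t"
                     f"{rec.offset + 1}\t60\t{batch.read_length}M\t*\t0\t0\t"
                     f"{seq}\t{q}\tNM:i:{rec.mismatches}\n")
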