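import numpy as np
import pysam
import pytest

from conftest import make_tiled_batch
from phylosites import _seq
from phylosites.assemble import CompositeGenome
from phylosites.mapper import (CompositeIndex, CompositeLayout, Pileup,
                               external_mapper_adapter, map_reads,
                               pileup_from_origins, write_sam)
from phylosites.reads import ReadBatch, simulate_reads


def _batch_from_rows(rows, species="s", starts=None):
    rows = np.asarray(rows, dtype=np.uint8)
    n, L = rows.shape
    return ReadBatch(species=species, read_length=L, coverage=0.0, seed=0,
                     error_rate=0.0, r1=rows, r2=rows,
                     starts=np.zeros(n, np.int64) if starts is None
                     else np.asarray(starts, np.int64),
                     lengths=np.full(n, 2 * L, np.int64),
                     strands=np.ones(n, np.int8))


def _composite_of(*seq_codes):
    return CompositeGenome(
        contigs=[(f"c{i}", _seq.to_bytes(s)) for i, s in enumerate(seq_codes)],
        k=31)


def test_exact_substring_maps_at_correct_offset():
    rng = np.random.default_rng(0)
    contig = _seq.random_sequence(500, rng)
    composite = _composite_of(contig)
    read = contig[123:123 + 100]
    batch = _batch_from_rows([read])
    pileup, alns = map_reads(batch, composite, keep_alignments=True)
    placements = {(a.contig, a.offset, a.strand, a.mismatches) for a in alns}
    assert placements == {("c0", 123, "+", 0)}
    counts = pileup.species_counts("s")
    # both identical mates piled the same 100 positions
    assert counts.sum() == 200


def test_reverse_complement_read_maps_minus_strand():
    rng = np.random.default_rng(1)
    contig = _seq.random_sequence(400, rng)
    composite = _composite_of(contig)
    read = _seq.revcomp_codes(contig[50:150]).copy()
    _, alns = map_reads(_batch_from_rows([read]), composite,
                        keep_alignments=True)
    assert {(a.offset, a.strand) for a in alns} == {(50, "-")}


def test_repeated_read_discarded_as_ambiguous():
    rng = np.random.default_rng(2)
    shared = _seq.random_sequence(150, rng)
    c1 = np.concatenate([shared, _seq.random_sequence(200, rng)])
    c2 = np.concatenate([_seq.random_sequence(200, rng), shared])
    composite = _composite_of(c1, c2)
    batch = _batch_from_rows([shared[10:110]])
    pileup, alns = map_reads(batch, composite, keep_alignments=True)
    assert alns == []
    assert pileup.stats["s"].n_ambiguous == 2  # both identical mates
    assert pileup.species_counts("s").sum() == 0


def test_mismatch_ceiling_rejects_diverged_reads():
    rng = np.random.default_rng(3)
    contig = _seq.random_sequence(300, rng)
    composite = _composite_of(contig)
    read = contig[100:200].copy()
    read[::7] = (read[::7] + 1) % 4  # 15 mismatches > 10% of 100
    pileup, alns = map_reads(_batch_from_rows([read]), composite,
                             keep_alignments=True)
    assert alns == []
    assert pileup.stats["s"].n_unmapped == 2


def test_error_free_reads_map_to_their_origins():
    rng = np.random.default_rng(4)
    genome = _seq.random_sequence(5000, rng)
    composite = _composite_of(genome)
    batch = simulate_reads(genome, 20, error_rate=0.0, seed=9)
    assert 2 * batch.n_pairs >= 1000
    _, alns = map_reads(batch, composite, keep_alignments=True)
    five_start = batch.starts
    three_start = batch.starts + batch.lengths - batch.read_length
    correct = 0
    by_read = {(a.read_id, a.mate): a for a in alns}
    for i in range(batch.n_pairs):
        plus = batch.strands[i] > 0
        # mate 1 reads the 5' end on plus-strand fragments, the 3' end on
        # minus-strand ones (and vice versa for mate 2)
        expected = {1: five_start[i] if plus else three_start[i],
                    2: three_start[i] if plus else five_start[i]}
        for mate in (1, 2):
            a = by_read.get((batch.read_id(i), mate))
            if a is not None and a.offset == expected[mate]:
                correct += 1
    assert correct >= 0.99 * 2 * batch.n_pairs


def test_pileup_counts_conserve_aligned_bases():
    rng = np.random.default_rng(5)
    genome = _seq.random_sequence(3000, rng)
    composite = _composite_of(genome)
    batch = simulate_reads(genome, 8, error_rate=0.001, seed=3)
    pileup, _ = map_reads(batch, composite)
    stats = pileup.stats["sample"]
    assert pileup.species_counts("sample").sum() == stats.aligned_bases
    assert stats.n_mapped + stats.n_ambiguous + stats.n_unmapped \
        == stats.n_reads == 2 * batch.n_pairs


def test_pileup_invariant_to_read_order_and_workers():
    rng = np.random.default_rng(6)
    genome = _seq.random_sequence(4000, rng)
    composite = _composite_of(genome)
    batch = simulate_reads(genome, 10, error_rate=0.001, seed=4)
    perm = rng.permutation(batch.n_pairs)
    shuffled = batch.subset(perm)
    base, _ = map_reads(batch, composite)
    reordered, _ = map_reads(shuffled, composite)
    parallel, _ = map_reads(batch, composite, workers=4)
    assert np.array_equal(base.species_counts("sample"),
                          reordered.species_counts("sample"))
    assert np.array_equal(base.species_counts("sample"),
                          parallel.species_counts("sample"))


def test_pileup_from_origins_matches_truthful_mapping():
    rng = np.random.default_rng(7)
    genome = _seq.random_sequence(2000, rng)
    batch = simulate_reads(genome, 6, error_rate=0.0, seed=8)
    pileup = pileup_from_origins(batch, len(genome))
    counts = pileup.species_counts("sample")
    # every piled base agrees with the genome (error-free, truthful placement)
    for b in range(4):
        sites = np.flatnonzero(counts[b])
        assert np.all(genome[sites] == b)


def test_pileup_tsv_roundtrip(tmp_path):
    rng = np.random.default_rng(8)
    genome = _seq.random_sequence(500, rng)
    composite = _composite_of(genome)
    batch = simulate_reads(genome, 4, error_rate=0.0, seed=2)
    pileup, _ = map_reads(batch, composite)
    path = tmp_path / "pileup.tsv"
    pileup.write_tsv(path)
    layout = CompositeLayout.from_composite(composite)
    back = Pileup.from_tsv(path, layout)
    assert np.array_equal(back.species_counts("sample"),
                          pileup.species_counts("sample"))


def test_sam_output_parses_and_places_reads(tmp_path):
    rng = np.random.default_rng(9)
    genome = _seq.random_sequence(800, rng)
    composite = _composite_of(genome)
    batch = simulate_reads(genome, 3, error_rate=0.0, seed=5)
    _, alns = map_reads(batch, composite, keep_alignments=True)
    path = tmp_path / "out.sam"
    write_sam(alns, batch, composite, path)
    with pysam.AlignmentFile(str(path), check_sq=True) as sam:
        recs = list(sam)
    assert len(recs) == len(alns)
    by_key = {(a.read_id + f"/{a.mate}"): a for a in alns}
    for rec in recs:
        a = by_key[rec.query_name]
        assert rec.reference_start == a.offset
        assert rec.get_tag("NM") == a.mismatches
        # SEQ is reference-forward: it matches the contig up to mismatches
        contig = composite.contig_dict()[a.contig]
        ref = contig[a.offset:a.offset + batch.read_length].decode()
        diff = sum(1 for x, y in zip(ref, rec.query_sequence) if x != y)
        assert diff == a.mismatches


def test_external_mapper_adapter_with_bwa(tmp_path):
    rng = np.random.default_rng(10)
    genome = _seq.random_sequence(2000, rng)
    composite = _composite_of(genome)
    batch = simulate_reads(genome, 6, error_rate=0.0, seed=6)
    cmd = ("bwa index {ref} 2>/dev/null && "
           "bwa mem -v 0 {ref} {r1} {r2} > {out} 2>/dev/null")
    pileup = external_mapper_adapter(cmd, batch, composite)
    counts = pileup.species_counts("sample")
    assert pileup.stats["sample"].n_mapped >= 0.9 * 2 * batch.n_pairs
    # piled bases agree with the reference genome at every site (error-free)
    for b in range(4):
        sites = np.flatnonzero(counts[b])
        assert np.all(genome[sites] == b)
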