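import edlib
import numpy as np
import pytest

from conftest import make_tiled_batch
from phylosites import _seq
from phylosites.assemble import CompositeGenome
from phylosites.consensus import call_strict_consensus
from phylosites.errors import IntegrityError
from phylosites.evaluate import (EvaluationReport, anchor_composite,
                                 clade_support, score_run, simulated_depth)
from phylosites.evolve import GenomeSet, census_variable_sites
from phylosites.mapper import map_reads
from phylosites.sites import extract_variable_sites
from phylosites.trees import make_tree


def _genome_set(sequences: dict[str, np.ndarray], root: np.ndarray,
                tree=None) -> GenomeSet:
    return GenomeSet(tree=tree or make_tree("balanced", "equal", 1), seed=0,
                     root_sequence=root, sequences=sequences)


class TestAnchor:
    def _genomes(self, L=600, seed=0):
        rng = np.random.default_rng(seed)
        root = _seq.random_sequence(L, rng)
        return _genome_set({t: root.copy() for t in "ABCDEFGH"}, root)

    def test_exact_substring_contig_placed(self):
        gs = self._genomes()
        contig = _seq.to_bytes(gs.sequences["A"][100:300])
        comp = CompositeGenome(contigs=[("c0", contig)], k=31)
        place = anchor_composite(comp, gs)["c0"]
        assert place is not None
        assert (place.start, place.strand) == (100, "+")
        assert place.root_coord(0) == 100
        assert place.root_coord(199) == 299

    def test_reverse_complement_contig_placed_minus(self):
        gs = self._genomes()
        fwd = gs.sequences["A"][100:300]
        comp = CompositeGenome(
            contigs=[("c0", _seq.to_bytes(_seq.revcomp_codes(fwd)))], k=31)
        place = anchor_composite(comp, gs)["c0"]
        assert place is not None and place.strand == "-"
        assert place.start == 100
        # contig offset 0 is the genome's last base of the interval
        assert place.root_coord(0) == 299

    def test_random_contig_unplaced(self):
        gs = self._genomes()
        rng = np.random.default_rng(99)
        junk = _seq.to_bytes(_seq.random_sequence(200, rng))
        comp = CompositeGenome(contigs=[("c0", junk)], k=31)
        assert anchor_composite(comp, gs)["c0"] is None

    def test_placements_agree_with_edit_distance_oracle(self, small_benchmark):
        gs = small_benchmark.dataset.genomes
        comp = small_benchmark.core.composite
        placements = anchor_composite(comp, gs, k_anchor=31)
        root = _seq.to_bytes(gs.root_sequence).decode()
        checked = 0
        for cid, seq in comp.contigs[:20]:
            place = placements[cid]
            if place is None:
                continue
            fwd = edlib.align(seq.decode(), root, mode="HW", task="locations")
            rev = edlib.align(_seq.revcomp_bytes(seq).decode(), root,
                              mode="HW", task="locations")
            best = fwd if fwd["editDistance"] <= rev["editDistance"] else rev
            strand = "+" if best is fwd else "-"
            starts = {loc[0] for loc in best["locations"]}
            assert place.strand == strand
            assert any(abs(place.start - s) <= 2 for s in starts)
            checked += 1
        assert checked >= 10


class TestScoreRun:
    def _toy_run(self):
        """600 bp, 3 planted variable sites, taxon C starved around one."""
        rng = np.random.default_rng(12)
        root = _seq.random_sequence(600, rng)
        sequences = {}
        for t in "ABCDEFGH":
            sequences[t] = root.copy()
        for pos in (150, 300, 450):
            alt = (root[pos] + 1) % 4
            for t in "EFGH":  # clean 4/4 split at each planted site
                sequences[t][pos] = alt
        gs = _genome_set(sequences, root)
        batches = {}
        for t in "ABCDEFGH":
            exclude = (250, 350) if t == "C" else None
            batches[t] = make_tiled_batch(sequences[t], t, read_length=50,
                                          step=20, fragment_length=100,
                                          exclude=exclude)
        composite = CompositeGenome(contigs=[("c0", _seq.to_bytes(root))],
                                    k=31)
        pileup = None
        for t in "ABCDEFGH":
            pileup, _ = map_reads(batches[t], composite, pileup=pileup)
        matrix = call_strict_consensus(pileup, min_depth=2)
        aln = extract_variable_sites(matrix, max_unknown=0)
        census = census_variable_sites(gs)
        placements = anchor_composite(composite, gs)
        return gs, batches, composite, pileup, aln, census, placements

    def test_planted_sites_partitioned_correctly(self):
        gs, batches, composite, pileup, aln, census, placements = \
            self._toy_run()
        assert census.n_variable == 3
        report = score_run(aln, census, placements, pileup, composite,
                           batches, min_depth=2, genome_length=600)
        assert report.n_output == 2
        assert report.n_true_recovered == 2
        assert report.n_false_positive == 0
        assert report.misses == {"insufficient_simulated_coverage": 1,
                                 "not_in_composite": 0,
                                 "insufficient_mapped_coverage": 0,
                                 "other": 0}

    def test_starved_taxon_depth_is_low_where_expected(self):
        gs, batches, *_ = self._toy_run()
        depth = simulated_depth(batches, 600)
        assert depth["C"][300] < 2
        assert depth["C"][150] >= 2 and depth["C"][450] >= 2
        assert depth["A"][300] >= 2

    def test_empty_alignment_categorizes_everything(self):
        gs, batches, composite, pileup, aln, census, placements = \
            self._toy_run()
        empty = extract_variable_sites(
            call_strict_consensus(pileup, min_depth=2), max_unknown=0)
        empty.calls = empty.calls[:, :0]
        empty.sites = []
        report = score_run(empty, census, placements, pileup, composite,
                           batches, min_depth=2, genome_length=600)
        assert report.n_output == 0
        assert report.false_positive_rate == 0.0
        assert sum(report.misses.values()) == census.n_variable

    def test_report_invariants_enforced(self):
        with pytest.raises(IntegrityError):
            EvaluationReport(n_true_variable=5, n_output=3,
                             n_true_recovered=1, n_false_positive=1,
                             misses={"other": 4}, n_recovered_positions=1)
        with pytest.raises(IntegrityError):
            EvaluationReport(n_true_variable=5, n_output=2,
                             n_true_recovered=1, n_false_positive=1,
                             misses={"other": 3}, n_recovered_positions=1)


class TestCladeSupport:
    def _aln(self, columns):
        """columns: list of 8-char strings (A..H order)."""
        calls = np.array([["ACGTN".index(col[i]) for col in columns]
                          for i in range(8)], dtype=np.uint8)
        from phylosites.sites import VariableSiteAlignment
        return VariableSiteAlignment(species=list("ABCDEFGH"),
                                     sites=[("c0", j) for j in
                                            range(len(columns))],
                                     calls=calls, max_unknown=3)

    def test_clean_synapomorphy_supports_single_clade(self):
        tree = make_tree("pectinate", "equal", 1)
        support = clade_support(self._aln(["AACCCCCC"]), tree)
        assert support[frozenset("AB")] == 1
        assert all(n == 0 for c, n in support.items() if c != frozenset("AB"))

    def test_alternating_pattern_supports_nothing(self):
        for topology in ("pectinate", "balanced"):
            tree = make_tree(topology, "equal", 1)
            support = clade_support(self._aln(["ACACACAC"]), tree)
            assert all(n == 0 for n in support.values())

    def test_unknowns_respect_ceiling(self):
        tree = make_tree("pectinate", "equal", 1)
        aln = self._aln(["AACCCCNN"])
        assert clade_support(aln, tree,
                             max_unknown=2)[frozenset("AB")] == 1
        assert clade_support(aln, tree,
                             max_unknown=1)[frozenset("AB")] == 0

    def test_partial_unknown_inside_clade_blocks_support(self):
        tree = make_tree("pectinate", "equal", 1)
        support = clade_support(self._aln(["ANCCCCCC"]), tree)
        assert support[frozenset("AB")] == 0

    def test_matches_bruteforce_on_simulated_alignment(self, small_benchmark):
        aln = small_benchmark.core.alignments[3]
        tree = small_benchmark.dataset.tree
        support = clade_support(aln, tree)
        n_check = min(aln.n_sites, 500)
        expected = {clade: 0 for clade in tree.clades()}
        for j in range(n_check):
            col = aln.column(j)
            n_unknown = sum(1 for v in col.values() if v == "N")
            if n_unknown > aln.max_unknown:
                continue
            for clade in expected:
                members = {col[t] for t in clade}
                others = {col[t] for t in col if t not in clade} - {"N"}
                if ("N" not in members and len(members) == 1
                        and len(others) == 1 and members != others):
                    expected[clade] += 1
        if n_check == aln.n_sites:
            assert support == expected
        else:
            partial = clade_support(
                type(aln)(species=aln.species, sites=aln.sites[:n_check],
                          calls=aln.calls[:, :n_check],
                          max_unknown=aln.max_unknown), tree)
            assert partial == expected
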