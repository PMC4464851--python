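"""Truth-matched evaluation of a simulated pipeline run.

Because the simulation is substitution-only, every taxon genome shares the
root genome's coordinate system, so composite contigs can be anchored back
onto it by exact k-mer matches against the true genomes. Output sites then
map to true positions and can be scored against the simulated variable-site
census: a site is a TRUE RECOVERY when its mapped coordinate is a true
variable position *and* every non-N call matches the true base pattern
there; anything else the pipeline output is a FALSE POSITIVE (including
sites on contigs that cannot be placed, and true positions reported with a
wrong pattern — pattern errors mislead phylogenetics exactly like positional
ones).

Missed true sites are attributed to the first matching failure category:
too little simulated read depth in some taxon, absence of the region from
the composite genome, or too little per-species depth after mapping; the
remainder (e.g. strict-consensus N from read errors, locus filtering) is
``other``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from ._seq import COMP_CODE, N_CODE, revcomp_bytes
from .assemble import CompositeGenome
from .errors import IntegrityError
from .evolve import GenomeSet, TrueSiteCensus
from .mapper import Pileup
from .reads import ReadBatch
from .sites import VariableSiteAlignment
from .trees import SimTree

DEFAULT_K_ANCHOR = 31
ANCHOR_AGREEMENT = 0.8

MISS_CATEGORIES = ("insufficient_simulated_coverage", "not_in_composite",
                   "insufficient_mapped_coverage", "other")


@dataclass
class ContigPlacement:
    contig_id: str
    start: int          # root-genome coordinate of contig position 0 (+) /
    strand: str         # last position (-)
    length: int

    def root_coord(self, offset: int) -> int:
        if self.strand == "+":
            return self.start + offset
        return self.start + self.length - 1 - offset


def anchor_composite(composite: CompositeGenome, genomes: GenomeSet,
                     k_anchor: int = DEFAULT_K_ANCHOR,
                     stride: int | None = None,
                     ) -> dict[str, ContigPlacement | None]:
    """Place each contig on the shared root coordinate system.

    Anchor k-mers taken every ``stride`` bases along the contig are looked up
    (both strands) in an index of all taxa's true genomes; a placement wins
    when at least 80% of the anchors that hit anywhere agree on one
    (offset, strand). Contigs with no consistent placement map to ``None``.
    """
    if stride is None:
        stride = max(1, k_anchor // 4)
    L = genomes.length
    index: dict[bytes, set[int]] = {}
    from . import _seq as _s
    for seq_codes in genomes.sequences.values():
        data = _s.to_bytes(seq_codes)
        for i in range(L - k_anchor + 1):
            index.setdefault(data[i:i + k_anchor], set()).add(i)
    placements: dict[str, ContigPlacement | None] = {}
    for cid, seq in composite.contigs:
        n_anchor = max(1, (len(seq) - k_anchor) // stride + 1)
        votes: dict[tuple[int, str], set[int]] = {}
        n_hit = 0
        rc = revcomp_bytes(seq)
        for j in range(0, len(seq) - k_anchor + 1, stride):
            hit_any = False
            for spelled, strand in ((seq, "+"), (rc, "-")):
                jj = j if strand == "+" else len(seq) - k_anchor - j
                hits = index.get(spelled[jj:jj + k_anchor])
                if hits:
                    hit_any = True
                    for p in hits:
                        # the (possibly revcomped) contig spelling starts at
                        # genome coordinate p - jj
                        start = p - jj
                        votes.setdefault((start, strand), set()).add(j)
            if hit_any:
                n_hit += 1
        placements[cid] = None
        if n_hit == 0:
            continue
        (start, strand), sup = max(
            votes.items(), key=lambda kv: (len(kv[1]), -kv[0][0]))
        if len(sup) >= ANCHOR_AGREEMENT * n_hit and \
                0 <= start and start + len(seq) <= L:
            placements[cid] = ContigPlacement(contig_id=cid, start=start,
                                              strand=strand, length=len(seq))
    return placements


def simulated_depth(batches: dict[str, ReadBatch], genome_length: int,
                    ) -> dict[str, np.ndarray]:
    """Per-taxon simulated read depth along the true genome, from origins."""
    out = {}
    for sp, batch in batches.items():
        diff = np.zeros(genome_length + 1, dtype=np.int64)
        iv = batch.mate_intervals().reshape(-1, 2)
        np.add.at(diff, iv[:, 0], 1)
        np.add.at(diff, iv[:, 1], -1)
        out[sp] = np.cumsum(diff[:-1])
    return out


@dataclass
class EvaluationReport:
    """Counts behind site-recovery, failure-category and clade-support plots."""

    n_true_variable: int
    n_output: int
    n_true_recovered: int
    n_false_positive: int
    misses: dict[str, int]
    clade_support: dict[frozenset, int] = field(default_factory=dict)
    # distinct true positions recovered (an output site count can exceed it
    # when overlapping contigs report the same truth position twice)
    n_recovered_positions: int = 0

    @property
    def false_positive_rate(self) -> float:
        return (self.n_false_positive / self.n_output) if self.n_output else 0.0

    def __post_init__(self):
        if self.n_true_recovered + self.n_false_positive != self.n_output:
            raise IntegrityError("recovered + false positives != output sites")
        if sum(self.misses.values()) + self.n_recovered_positions \
                != self.n_true_variable:
            raise IntegrityError("miss categories do not partition the misses")

    def to_dict(self) -> dict:
        return {
            "n_true_variable": self.n_true_variable,
            "n_output": self.n_output,
            "n_true_recovered": self.n_true_recovered,
            "n_false_positive": self.n_false_positive,
            "false_positive_rate": self.false_positive_rate,
            "misses": dict(self.misses),
            "clade_support": {"+".join(sorted(c)): n
                              for c, n in self.clade_support.items()},
        }

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), indent=2, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text

    def table(self) -> str:
        d = self.to_dict()
        lines = [f"{'true variable sites':<32s}{d['n_true_variable']:>10d}",
                 f"{'sites output':<32s}{d['n_output']:>10d}",
                 f"{'true recoveries':<32s}{d['n_true_recovered']:>10d}",
                 f"{'false positives':<32s}{d['n_false_positive']:>10d}",
                 f"{'false positive rate':<32s}{d['false_positive_rate']:>10.4f}"]
        for cat in MISS_CATEGORIES:
            lines.append(f"{'miss: ' + cat:<32s}{self.misses[cat]:>10d}")
        for clade, n in sorted(d["clade_support"].items()):
            lines.append(f"{'support ' + clade:<32s}{n:>10d}")
        return "\n".join(lines)


def score_run(aln: VariableSiteAlignment, census: TrueSiteCensus,
              placements: dict[str, ContigPlacement | None],
              pileup: Pileup, composite: CompositeGenome,
              batches: dict[str, ReadBatch], *,
              min_depth: int = 2,
              genome_length: int | None = None,
              tree: SimTree | None = None) -> EvaluationReport:
    """Score one pipeline run against the simulation truth."""
    if set(aln.species) - set(batches):
        raise IntegrityError("alignment species missing from read batches")
    if set(placements) != {cid for cid, _ in composite.contigs}:
        raise IntegrityError("placements do not match composite contigs")
    taxa = list(census.taxa)
    if genome_length is None:
        genome_length = _genome_length(batches)
        if len(census.positions):
            genome_length = max(genome_length, int(census.positions[-1]) + 1)
        for place in placements.values():
            if place is not None:
                genome_length = max(genome_length, place.start + place.length)
    census_col = {int(p): j for j, p in enumerate(census.positions)}
    sp_index = {sp: taxa.index(sp) for sp in aln.species}

    n_recovered = 0
    n_fp = 0
    recovered_positions: set[int] = set()
    for j, (cid, off) in enumerate(aln.sites):
        place = placements.get(cid)
        ok = False
        if place is not None:
            r = place.root_coord(off)
            col = census_col.get(r)
            if col is not None:
                ok = True
                for sp in aln.species:
                    call = aln.calls[aln.species.index(sp), j]
                    if call == N_CODE:
                        continue
                    true_base = census.patterns[sp_index[sp], col]
                    if place.strand == "-":
                        call = COMP_CODE[call]
                    if call != true_base:
                        ok = False
                        break
                if ok:
                    recovered_positions.add(r)
        if ok:
            n_recovered += 1
        else:
            n_fp += 1

    depth = simulated_depth(batches, genome_length)
    covered = np.zeros(genome_length, dtype=bool)
    pile_ok = np.zeros(genome_length, dtype=bool)
    layout = pileup.layout
    cid_to_i = {cid: i for i, cid in enumerate(layout.contig_ids)}
    species = sorted(batches)
    depth_ok_global = np.ones(layout.total, dtype=bool)
    for sp in species:
        depth_ok_global &= pileup.depth(sp) >= min_depth
    for cid, place in placements.items():
        if place is None:
            continue
        i = cid_to_i[cid]
        lo = int(layout.starts[i])
        g = np.arange(place.length)
        roots = place.start + (g if place.strand == "+"
                               else place.length - 1 - g)
        covered[roots] = True
        pile_ok[roots] |= depth_ok_global[lo + g]

    misses = {cat: 0 for cat in MISS_CATEGORIES}
    sim_ok = np.ones(genome_length, dtype=bool)
    for sp in species:
        sim_ok &= depth[sp] >= min_depth
    for p in (int(x) for x in census.positions):
        if p in recovered_positions:
            continue
        if not sim_ok[p]:
            misses["insufficient_simulated_coverage"] += 1
        elif not covered[p]:
            misses["not_in_composite"] += 1
        elif not pile_ok[p]:
            misses["insufficient_mapped_coverage"] += 1
        else:
            misses["other"] += 1

    support = clade_support(aln, tree) if tree is not None else {}
    return EvaluationReport(
        n_true_variable=census.n_variable, n_output=aln.n_sites,
        n_true_recovered=n_recovered, n_false_positive=n_fp,
        misses=misses, clade_support=support,
        n_recovered_positions=len(recovered_positions))


def _genome_length(batches: dict[str, ReadBatch]) -> int:
    return int(max((b.starts + b.lengths).max() for b in batches.values()))


def clade_support(aln: VariableSiteAlignment, tree: SimTree,
                  max_unknown: int | None = None) -> dict[frozenset, int]:
    """Sites cleanly supporting each non-trivial clade of the tree.

    A site supports clade C when all members of C share one called base, all
    called non-members share a single different base, and no more than
    ``max_unknown`` taxa overall are N (defaults to the alignment's own
    ceiling).
    """
    if not set(aln.species) <= set(tree.taxa):
        raise IntegrityError("alignment taxa not a subset of tree taxa")
    if max_unknown is None:
        max_unknown = aln.max_unknown
    out: dict[frozenset, int] = {}
    calls = aln.calls
    known = calls != N_CODE
    n_unknown = (~known).sum(axis=0)
    sp_pos = {sp: i for i, sp in enumerate(aln.species)}
    for clade in sorted(tree.clades(), key=lambda c: (len(c), sorted(c))):
        members = [sp_pos[sp] for sp in sorted(clade) if sp in sp_pos]
        others = [i for sp, i in sorted(sp_pos.items()) if sp not in clade]
        if not members or not others:
            out[clade] = 0
            continue
        mc = calls[members]
        oc = calls[others]
        m_known = known[members].all(axis=0)
        m_same = (mc == mc[0]).all(axis=0)
        o_known = known[others]
        # single shared base among *called* non-members
        o_call = np.where(o_known, oc, np.uint8(255))
        o_first = np.full(calls.shape[1], 255, dtype=np.uint8)
        for row in o_call:
            o_first = np.where((o_first == 255) & (row != 255), row, o_first)
        o_same = ((o_call == o_first[None, :]) | ~o_known).all(axis=0)
        o_any = o_known.any(axis=0)
        good = (m_known & m_same & o_any & o_same
                & (mc[0] != o_first) & (n_unknown <= max_unknown))
        out[clade] = int(good.sum())
    return out
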