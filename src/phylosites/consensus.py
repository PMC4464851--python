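"""Strict-consensus genotype calling.

A species' base at a composite position is called only when every one of its
mapped reads agrees: if exactly one base has nonzero count and total depth is
at least ``min_depth``, that base is the call; any within-species
disagreement — sequencing error, paralogy, pooled-individual polymorphism —
or insufficient depth yields the unknown state ``N``. No plurality or
frequency thresholding is applied; strictness is absolute, which is what
suppresses non-phylogenetic signal at the cost of discarding genuinely
polymorphic sites.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._seq import N_CODE
from .mapper import CompositeLayout, Pileup

DEFAULT_MIN_DEPTH = 2

_CALL_CHARS = "ACGTN"


@dataclass
class SpeciesCallMatrix:
    """Per-site strict-consensus calls, species x composite position.

    ``calls`` holds uint8 codes (A=0..T=3, N=4) with one row per species and
    one column per position of every contig in the layout.
    """

    layout: CompositeLayout
    species: list[str]
    calls: np.ndarray
    min_depth: int

    @property
    def n_sites(self) -> int:
        return self.calls.shape[1]

    def call(self, contig_id: str, offset: int, species: str) -> str:
        g = self.layout.global_pos(contig_id, offset)
        return _CALL_CHARS[self.calls[self.species.index(species), g]]

    def contig_slice(self, contig_index: int) -> np.ndarray:
        lo = self.layout.starts[contig_index]
        return self.calls[:, lo:lo + self.layout.lengths[contig_index]]

    @classmethod
    def from_tsv(cls, path, layout: CompositeLayout,
                 min_depth: int = DEFAULT_MIN_DEPTH) -> "SpeciesCallMatrix":
        """Read back a matrix written by :meth:`write_tsv`."""
        cid_to_start = dict(zip(layout.contig_ids, layout.starts))
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split("\t")
            species = header[2:]
            calls = np.full((len(species), layout.total), N_CODE,
                            dtype=np.uint8)
            for line in fh:
                parts = line.rstrip("\n").split("\t")
                g = int(cid_to_start[parts[0]]) + int(parts[1])
                for i, ch in enumerate(parts[2:]):
                    calls[i, g] = _CALL_CHARS.index(ch)
        return cls(layout=layout, species=species, calls=calls,
                   min_depth=min_depth)

    def write_tsv(self, path, skip_all_unknown: bool = True) -> None:
        with open(path, "w") as fh:
            fh.write("contig\tpos\t" + "\t".join(self.species) + "\n")
            known = (self.calls != N_CODE).any(axis=0)
            cols = np.flatnonzero(known) if skip_all_unknown \
                else np.arange(self.calls.shape[1])
            for g in cols:
                cid, off = self.layout.locate(int(g))
                row = "\t".join(_CALL_CHARS[c] for c in self.calls[:, g])
                fh.write(f"{cid}\t{off}\t{row}\n")


def call_strict_consensus(pileup: Pileup,
                          min_depth: int = DEFAULT_MIN_DEPTH,
                          species: list[str] | None = None,
                          ) -> SpeciesCallMatrix:
    """Call every composite position for every species in the pileup."""
    if min_depth < 1:
        raise ValueError("min_depth must be >= 1")
    if species is None:
        species = sorted(pileup.counts)
    calls = np.full((len(species), pileup.layout.total), N_CODE,
                    dtype=np.uint8)
    for i, sp in enumerate(species):
        counts = pileup.species_counts(sp)
        total = counts.sum(axis=0)
        n_bases = (counts > 0).sum(axis=0)
        ok = (n_bases == 1) & (total >= min_depth)
        calls[i, ok] = counts[:, ok].argmax(axis=0).astype(np.uint8)
    return SpeciesCallMatrix(layout=pileup.layout, species=list(species),
                             calls=calls, min_depth=min_depth)
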