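"""Variable-site filtering and alignment export.

Three refinements turn the raw call matrix into the pipeline's phylogenetic
output: (1) whole loci (contigs) with too few callable sites are dropped;
(2) a missing-data ceiling removes sites where more than ``max_unknown``
species are N; (3) only sites with at least two distinct called bases among
species are kept ("variable"; sites that vary only through N are excluded).
Sweeping the ceiling from strict to permissive yields a nested family of
alignments of growing size.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from ._seq import N_CODE
from .consensus import SpeciesCallMatrix, _CALL_CHARS
from .mapper import CompositeLayout

DEFAULT_MIN_CALLABLE_SITES = 3

FORMATS = ("fasta", "phylip", "nexus")


def filter_loci(matrix: SpeciesCallMatrix,
                min_callable_sites: int = DEFAULT_MIN_CALLABLE_SITES,
                ) -> SpeciesCallMatrix:
    """Drop contigs with fewer than ``min_callable_sites`` callable sites.

    A site is callable when at least one species has a non-N call; the
    removed contig disappears from the matrix (and its layout) entirely.
    """
    if min_callable_sites < 0:
        raise ValueError("min_callable_sites must be >= 0")
    if min_callable_sites == 0:
        return matrix
    layout = matrix.layout
    keep_ids, keep_lengths, keep_cols = [], [], []
    callable_ = (matrix.calls != N_CODE).any(axis=0)
    for i, cid in enumerate(layout.contig_ids):
        lo = int(layout.starts[i])
        hi = lo + int(layout.lengths[i])
        if int(callable_[lo:hi].sum()) >= min_callable_sites:
            keep_ids.append(cid)
            keep_lengths.append(int(layout.lengths[i]))
            keep_cols.append(np.arange(lo, hi))
    if keep_ids:
        cols = np.concatenate(keep_cols)
        calls = matrix.calls[:, cols]
    else:
        calls = matrix.calls[:, :0]
    lengths = np.array(keep_lengths, dtype=np.int64)
    starts = (np.concatenate([[0], np.cumsum(lengths)[:-1]]).astype(np.int64)
              if keep_ids else np.empty(0, dtype=np.int64))
    new_layout = CompositeLayout(contig_ids=keep_ids, lengths=lengths,
                                 starts=starts, total=int(lengths.sum()))
    return SpeciesCallMatrix(layout=new_layout, species=matrix.species,
                             calls=calls, min_depth=matrix.min_depth)


@dataclass
class VariableSiteAlignment:
    """Final alignment of variable sites with per-column provenance."""

    species: list[str]
    sites: list[tuple[str, int]]      # (contig id, offset), deterministic order
    calls: np.ndarray                 # uint8, (n_species, n_sites)
    max_unknown: int
    provenance: dict = field(default_factory=dict)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def sequence(self, species: str) -> str:
        row = self.calls[self.species.index(species)]
        return "".join(_CALL_CHARS[c] for c in row)

    def column(self, j: int) -> dict[str, str]:
        return {sp: _CALL_CHARS[c]
                for sp, c in zip(self.species, self.calls[:, j])}


def extract_variable_sites(matrix: SpeciesCallMatrix, max_unknown: int,
                           ) -> VariableSiteAlignment:
    """Sites with <= max_unknown N calls and >= 2 distinct called bases.

    Column order is deterministic: contig id lexicographic, then offset
    ascending.
    """
    n_species = len(matrix.species)
    if not 0 <= max_unknown < n_species:
        raise ValueError("max_unknown must be in [0, n_species)")
    calls = matrix.calls
    n_unknown = (calls == N_CODE).sum(axis=0)
    present = np.stack([(calls == b).any(axis=0) for b in range(4)])
    distinct = present.sum(axis=0)
    keep = (n_unknown <= max_unknown) & (distinct >= 2)
    order = sorted(range(len(matrix.layout.contig_ids)),
                   key=lambda i: matrix.layout.contig_ids[i])
    cols, sites = [], []
    for i in order:
        lo = int(matrix.layout.starts[i])
        hi = lo + int(matrix.layout.lengths[i])
        sel = np.flatnonzero(keep[lo:hi])
        cols.append(sel + lo)
        sites.extend((matrix.layout.contig_ids[i], int(o)) for o in sel)
    col_idx = (np.concatenate(cols) if cols
               else np.empty(0, dtype=np.int64))
    return VariableSiteAlignment(
        species=list(matrix.species), sites=sites,
        calls=calls[:, col_idx].copy(), max_unknown=max_unknown,
        provenance={"min_depth": matrix.min_depth,
                    "max_unknown": max_unknown})


def sweep_alignments(matrix: SpeciesCallMatrix,
                     max_unknown_values=None) -> dict[int, VariableSiteAlignment]:
    """One alignment per missing-data ceiling (default 0..n_species-1)."""
    if max_unknown_values is None:
        max_unknown_values = range(len(matrix.species))
    return {m: extract_variable_sites(matrix, m) for m in max_unknown_values}


def export_alignment(aln: VariableSiteAlignment, path, format: str,
                     sidecar_path=None) -> None:
    """Write the alignment as FASTA, sequential PHYLIP or NEXUS.

    ``N`` is written as each format's missing symbol (declared as such in
    NEXUS). A sidecar table maps alignment columns back to (contig, offset).
    """
    if format not in FORMATS:
        raise ValueError(f"unknown format {format!r}; expected one of {FORMATS}")
    if aln.n_sites == 0:
        warnings.warn("alignment is empty; writing no sequence data")
    with open(path, "w") as fh:
        if format == "fasta":
            for sp in aln.species:
                fh.write(f">{sp}\n{aln.sequence(sp)}\n")
        elif format == "phylip":
            fh.write(f"{len(aln.species)} {aln.n_sites}\n")
            for sp in aln.species:
                fh.write(f"{sp:<10s}{aln.sequence(sp)}\n")
        else:  # nexus
            fh.write("#NEXUS\nBEGIN DATA;\n")
            fh.write(f"  DIMENSIONS NTAX={len(aln.species)} "
                     f"NCHAR={aln.n_sites};\n")
            fh.write("  FORMAT DATATYPE=DNA MISSING=N GAP=-;\n  MATRIX\n")
            for sp in aln.species:
                fh.write(f"    {sp} {aln.sequence(sp)}\n")
            fh.write("  ;\nEND;\n")
    if sidecar_path is not None:
        write_site_table(aln, sidecar_path)


def write_site_table(aln: VariableSiteAlignment, path) -> None:
    """Column-provenance TSV: alignment column -> (contig, offset)."""
    with open(path, "w") as fh:
        fh.write("column\tcontig\toffset\n")
        for j, (cid, off) in enumerate(aln.sites):
            fh.write(f"{j}\t{cid}\t{off}\n")
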