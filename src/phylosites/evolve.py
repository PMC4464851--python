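"""Genome evolution along a tree under the Jukes–Cantor (JC69) model.

A root genome of i.i.d. uniform ACGT bases is evolved down every branch of a
:class:`~phylosites.trees.SimTree`. A branch of length ``d`` (expected
substitutions per site) flips each site independently with probability

    p(d) = 3/4 * (1 - exp(-4 d / 3)),

replacing the base uniformly among the three alternatives. Substitutions
compound along root-to-tip paths, so multiple hits and reversals occur as in
the continuous-time JC69 process. There are no indels: all sequences share
one coordinate system, which the truth-matching evaluator relies on.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _seq
from .trees import SimTree


def jc69_p(d: float) -> float:
    """Probability that a site differs after a branch of length d."""
    return 0.75 * (1.0 - np.exp(-4.0 * d / 3.0))


@dataclass
class GenomeSet:
    """Per-taxon genomes (uint8 code arrays) sharing one coordinate system."""

    tree: SimTree
    seed: int
    root_sequence: np.ndarray
    sequences: dict[str, np.ndarray]

    @property
    def length(self) -> int:
        return len(self.root_sequence)

    @property
    def taxa(self) -> tuple[str, ...]:
        return tuple(self.sequences)

    def sequence_str(self, taxon: str) -> str:
        return _seq.decode(self.sequences[taxon])

    def write_fasta(self, path, include_root: bool = False) -> None:
        """Write per-taxon genomes (and optionally the root) as multi-FASTA."""
        with open(path, "w") as fh:
            if include_root:
                fh.write(">root\n" + _seq.decode(self.root_sequence) + "\n")
            for taxon, codes in self.sequences.items():
                fh.write(f">{taxon}\n" + _seq.decode(codes) + "\n")


def _mutate(parent: np.ndarray, d: float, rng: np.random.Generator) -> np.ndarray:
    child = parent.copy()
    if d <= 0:
        return child
    hit = rng.random(len(parent)) < jc69_p(d)
    n = int(hit.sum())
    if n:
        # uniform among the 3 non-parent bases
        child[hit] = (parent[hit] + rng.integers(1, 4, size=n, dtype=np.uint8)) % 4
    return child


def evolve_genomes(tree: SimTree, length: int, seed: int) -> GenomeSet:
    """Simulate a GenomeSet of the given length on the tree.

    Fully reproducible from ``seed``: branches are visited in preorder and
    each consumes random draws in a fixed order.
    """
    if length < 1:
        raise ValueError("genome length must be >= 1")
    rng = np.random.default_rng(seed)
    root = _seq.random_sequence(length, rng)
    state = {}
    sequences = {}
    for node in tree.tree.preorder_node_iter():
        if node.parent_node is None:
            state[node] = root
        else:
            state[node] = _mutate(state[node.parent_node], node.edge.length, rng)
        if node.is_leaf():
            sequences[node.taxon.label] = state[node]
    sequences = {t: sequences[t] for t in sorted(sequences)}
    return GenomeSet(tree=tree, seed=seed, root_sequence=root, sequences=sequences)


@dataclass
class TrueSiteCensus:
    """Positions (0-based) that vary among taxa, with the true base pattern."""

    taxa: tuple[str, ...]
    positions: np.ndarray           # sorted int64, shape (n_var,)
    patterns: np.ndarray            # uint8 codes, shape (n_taxa, n_var)

    @property
    def n_variable(self) -> int:
        return len(self.positions)

    def pattern_at(self, position: int) -> dict[str, str]:
        col = int(np.searchsorted(self.positions, position))
        if col >= len(self.positions) or self.positions[col] != position:
            raise KeyError(position)
        return {t: "ACGT"[c] for t, c in zip(self.taxa, self.patterns[:, col])}

    def write_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("position\t" + "\t".join(self.taxa) + "\n")
            for j, pos in enumerate(self.positions):
                bases = "\t".join("ACGT"[c] for c in self.patterns[:, j])
                fh.write(f"{pos}\t{bases}\n")


def census_variable_sites(genomes: GenomeSet) -> TrueSiteCensus:
    """Exact census of positions with >=2 distinct bases among the taxa."""
    taxa = tuple(genomes.sequences)
    mat = np.vstack([genomes.sequences[t] for t in taxa])
    variable = (mat != mat[0]).any(axis=0)
    positions = np.flatnonzero(variable).astype(np.int64)
    return TrueSiteCensus(taxa=taxa, positions=positions,
                          patterns=mat[:, positions].copy())
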