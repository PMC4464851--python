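"""Benchmark simulation phylogenies.

The benchmark uses eight-taxon rooted binary trees (tips ``A``..``H``) in two
shapes — pectinate (ladder) and balanced — each in three branch-length
variants:

* ``equal``: every branch (terminal and internal) is 0.01 substitutions/site,
  multiplied by an integer scaler 1..6;
* ``long-deep``: node heights of the equal tree are normalized so the root is
  at height 1, raised elementwise to the power 2, and rescaled to the
  original tree height — this stretches deep branches and shrinks shallow
  ones;
* ``short-deep``: the same transform with exponent 1/2, which shortens deep
  branches.

The factory therefore yields 2 shapes x 3 variants x 6 scalers = 36 trees.
Trees are backed by :mod:`dendropy` for structure, Newick I/O and patristic
distances.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy

from .errors import ConfigurationError

TAXA: tuple[str, ...] = tuple("ABCDEFGH")
BASE_BRANCH_LENGTH = 0.01
TOPOLOGIES = ("pectinate", "balanced")
VARIANTS = ("equal", "long-deep", "short-deep")
SCALERS = tuple(range(1, 7))

_VARIANT_EXPONENT = {"equal": 1.0, "long-deep": 2.0, "short-deep": 0.5}

_SHAPE_NEWICK = {
    "pectinate": "(((((((A,B),C),D),E),F),G),H);",
    "balanced": "(((A,B),(C,D)),((E,F),(G,H)));",
}


@dataclass
class SimTree:
    """A rooted eight-taxon benchmark tree with branch lengths in subs/site."""

    topology: str
    variant: str
    scaler: int
    tree: dendropy.Tree = field(repr=False)

    @property
    def name(self) -> str:
        return f"{self.topology}_{self.variant}_s{self.scaler}"

    @property
    def taxa(self) -> tuple[str, ...]:
        return TAXA

    def branch_lengths(self) -> dict[frozenset[str], float]:
        """Map each edge (keyed by its subtended tip set) to its length."""
        out = {}
        for node in self.tree.preorder_node_iter():
            if node.parent_node is None:
                continue
            tips = frozenset(lf.taxon.label for lf in node.leaf_iter())
            out[tips] = node.edge.length
        return out

    def patristic_distance(self, a: str, b: str) -> float:
        pdm = self.tree.phylogenetic_distance_matrix()
        tns = self.tree.taxon_namespace
        return pdm.patristic_distance(
            tns.get_taxon(a), tns.get_taxon(b)
        )

    def clades(self) -> set[frozenset[str]]:
        """Non-trivial clades: internal-node tip sets minus root set/singletons."""
        out = set()
        n_tips = len(self.tree.leaf_nodes())
        for node in self.tree.preorder_internal_node_iter():
            tips = frozenset(lf.taxon.label for lf in node.leaf_iter())
            if 1 < len(tips) < n_tips:
                out.add(tips)
        return out

    def newick(self) -> str:
        return self.tree.as_string(schema="newick", suppress_rooting=True).strip()

    def write_newick(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.newick() + "\n")

    def validate(self) -> None:
        leaves = self.tree.leaf_nodes()
        if sorted(lf.taxon.label for lf in leaves) != list(TAXA):
            raise AssertionError("tree must have tips A..H")
        internal = [n for n in self.tree.preorder_internal_node_iter()]
        if len(internal) != len(leaves) - 1:
            raise AssertionError("tree must be rooted binary")
        for node in self.tree.preorder_node_iter():
            if node.parent_node is None:
                continue
            if not (node.edge.length and node.edge.length > 0):
                raise AssertionError("branch lengths must be positive")


def _shape_tree(topology: str) -> dendropy.Tree:
    try:
        newick = _SHAPE_NEWICK[topology]
    except KeyError:
        raise ConfigurationError(
            f"unknown topology {topology!r}; expected one of {TOPOLOGIES}"
        ) from None
    tree = dendropy.Tree.get(data=newick, schema="newick")
    tree.is_rooted = True
    return tree


def make_tree(topology: str, variant: str, scaler: int) -> SimTree:
    """Build one benchmark tree.

    The equal-variant tree has every branch at ``0.01 * scaler``; the
    long-deep / short-deep variants apply :func:`transform_heights` (exponent
    2 or 1/2) to the equal tree *before* scaling.
    """
    if variant not in VARIANTS:
        raise ConfigurationError(
            f"unknown variant {variant!r}; expected one of {VARIANTS}"
        )
    if scaler not in SCALERS:
        raise ConfigurationError(f"scaler must be in 1..6, got {scaler}")
    tree = _shape_tree(topology)
    for edge in tree.preorder_edge_iter():
        if edge.head_node.parent_node is not None:
            edge.length = BASE_BRANCH_LENGTH
    sim = SimTree(topology=topology, variant=variant, scaler=1, tree=tree)
    exponent = _VARIANT_EXPONENT[variant]
    if exponent != 1.0:
        sim = transform_heights(sim, exponent)
    for edge in sim.tree.preorder_edge_iter():
        if edge.head_node.parent_node is not None:
            edge.length *= scaler
    sim.variant = variant
    sim.scaler = scaler
    return sim


def transform_heights(sim: SimTree, exponent: float) -> SimTree:
    """Power-transform node heights, preserving topology and total height.

    Node depths (root-to-node path lengths) are converted to heights
    ``h = (H - depth) / H`` where ``H`` is the maximum tip depth, so the root
    sits at height 1. Heights are raised elementwise to ``exponent`` and
    depths are rebuilt as ``H * (1 - h**exponent)``; branch lengths are the
    resulting parent/child depth differences. Exponent 2 lengthens deep
    branches (long-deep); 1/2 shortens them (short-deep); 1 is the identity.
    """
    if not exponent > 0:
        raise ConfigurationError(f"exponent must be positive, got {exponent}")
    tree = sim.tree.clone(depth=1)
    depth = {}
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            depth[node] = 0.0
        else:
            depth[node] = depth[node.parent_node] + node.edge.length
    height_total = max(depth[lf] for lf in tree.leaf_node_iter())
    new_depth = {
        node: height_total * (1.0 - ((height_total - d) / height_total) ** exponent)
        for node, d in depth.items()
    }
    for node in tree.preorder_node_iter():
        if node.parent_node is not None:
            node.edge.length = new_depth[node] - new_depth[node.parent_node]
    return SimTree(topology=sim.topology, variant=sim.variant,
                   scaler=sim.scaler, tree=tree)


def enumerate_benchmark_trees() -> list[SimTree]:
    """All 36 benchmark trees, in a fixed deterministic order."""
    return [
        make_tree(topology, variant, scaler)
        for topology in TOPOLOGIES
        for variant in VARIANTS
        for scaler in SCALERS
    ]


def clades(sim: SimTree) -> set[frozenset[str]]:
    return sim.clades()


def read_newick(path, topology: str = "custom", variant: str = "custom",
                scaler: int = 1) -> SimTree:
    """Load a user tree from Newick for simulation."""
    tree = dendropy.Tree.get(path=str(path), schema="newick")
    tree.is_rooted = True
    return SimTree(topology=topology, variant=variant, scaler=scaler, tree=tree)
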