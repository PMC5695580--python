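"""Distance-based relationship tree (neighbor-joining) and newick output.

The tree is a visual summary of between-group genetic distances, not a
topology-inference result: neighbor-joining is exact on additive matrices
and deterministic here (ties on the Q criterion resolve to the lowest pair
of active-node indices; negative branch-length estimates are clamped to 0
with the total deficit recorded).  The stored tree is unrooted; midpoint
rooting is offered for display only.
"""
from __future__ import annotations

from dataclasses import dataclass

import dendropy
import numpy as np

from .diversity import DistanceMatrix

__all__ = ["RelationshipTree", "nj_tree", "to_newick", "from_newick"]


@dataclass(frozen=True)
class RelationshipTree:
    """An unrooted tree over the distance-matrix labels.

    ``tree`` is a dendropy tree with a trifurcating (or, for 3 taxa, single
    internal) root used purely as an anchor; ``clamped_deficit`` is the sum
    of negative branch-length estimates that were clamped to zero.
    """

    tree: dendropy.Tree
    labels: tuple[str, ...]
    clamped_deficit: float = 0.0

    def midpoint_rooted(self) -> dendropy.Tree:
        """A midpoint-rooted copy, for display."""
        clone = self.tree.clone(depth=1)
        clone.is_rooted = True
        clone.reroot_at_midpoint(update_bipartitions=True)
        return clone

    def leaf_edge_length(self, label: str) -> float:
        for leaf in self.tree.leaf_node_iter():
            if leaf.taxon.label == label:
                return float(leaf.edge.length or 0.0)
        raise KeyError(f"no leaf {label!r}")

    def patristic_distance(self, a: str, b: str) -> float:
        """Sum of branch lengths on the path between two leaves."""
        pdm = self.tree.phylogenetic_distance_matrix()
        taxa = {t.label: t for t in self.tree.taxon_namespace}
        for label in (a, b):
            if label not in taxa:
                raise KeyError(f"no leaf {label!r}")
        return float(pdm.patristic_distance(taxa[a], taxa[b]))

    def has_cluster(self, labels: set[str]) -> bool:
        """True if ``labels`` form a clade on some rooting (a split of the
        unrooted tree)."""
        taxa = frozenset(labels)
        all_taxa = frozenset(self.labels)
        if not taxa <= all_taxa:
            raise KeyError(f"labels not in tree: {sorted(taxa - all_taxa)}")
        self.tree.encode_bipartitions()
        target = {taxa, all_taxa - taxa}
        for bipartition in self.tree.bipartition_encoding:
            split = frozenset(
                t.label
                for t in self.tree.taxon_namespace
                if bipartition.split_bitmask
                & self.tree.taxon_namespace.taxon_bitmask(t)
            )
            if split in target:
                return True
        return False


def _clamp(value: float, deficit: list[float]) -> float:
    if value < 0:
        deficit[0] += -value
        return 0.0
    return value


def nj_tree(matrix: DistanceMatrix) -> RelationshipTree:
    """Neighbor-joining agglomeration of a distance matrix.

    Standard Saitou–Nei algorithm: repeatedly join the active pair (i, j)
    minimising Q(i, j) = (n - 2) d(i, j) - r_i - r_j, until three nodes
    remain and are joined at a single internal node by the three-point
    formulas.  Exact on additive matrices.
    """
    n = len(matrix.labels)
    if n < 3:
        raise ValueError("neighbor-joining needs >= 3 labels")
    values = np.asarray(matrix.values, dtype=float)  # validated symmetric

    taxon_namespace = dendropy.TaxonNamespace()
    nodes: list[dendropy.Node] = []
    for label in matrix.labels:
        taxon = dendropy.Taxon(label=label)
        taxon_namespace.add_taxon(taxon)
        nodes.append(dendropy.Node(taxon=taxon))

    deficit = [0.0]
    D = values.copy()
    active = list(range(n))  # indices into `nodes` via position parallelism

    while len(active) > 3:
        m = len(active)
        sub = D[np.ix_(active, active)]
        r = sub.sum(axis=1)
        Q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        # deterministic tie-break: smallest (i, j) in active-order
        best = np.unravel_index(np.argmin(Q), Q.shape)
        i, j = sorted((int(best[0]), int(best[1])))
        dij = sub[i, j]
        li = 0.5 * dij + (r[i] - r[j]) / (2 * (m - 2))
        lj = dij - li
        li, lj = _clamp(li, deficit), _clamp(lj, deficit)

        parent = dendropy.Node()
        child_i, child_j = nodes[active[i]], nodes[active[j]]
        parent.add_child(child_i)
        parent.add_child(child_j)
        child_i.edge.length = li
        child_j.edge.length = lj

        gi, gj = active[i], active[j]
        new_row = 0.5 * (D[gi, :] + D[gj, :] - D[gi, gj])
        D = np.pad(D, ((0, 1), (0, 1)))
        D[-1, :-1] = new_row
        D[:-1, -1] = new_row
        D[-1, -1] = 0.0
        nodes.append(parent)
        active = [g for g in active if g not in (gi, gj)] + [len(nodes) - 1]

    # join the last three at an internal node (three-point formulas)
    a, b, c = active
    root = dendropy.Node()
    dab, dac, dbc = D[a, b], D[a, c], D[b, c]
    lengths = {
        a: 0.5 * (dab + dac - dbc),
        b: 0.5 * (dab + dbc - dac),
        c: 0.5 * (dac + dbc - dab),
    }
    for g in (a, b, c):
        root.add_child(nodes[g])
        nodes[g].edge.length = _clamp(float(lengths[g]), deficit)

    tree = dendropy.Tree(taxon_namespace=taxon_namespace, seed_node=root)
    tree.is_rooted = False
    return RelationshipTree(
        tree=tree, labels=tuple(matrix.labels), clamped_deficit=deficit[0]
    )


def to_newick(tree: RelationshipTree) -> str:
    """Newick serialization (labels quoted when needed, 6-decimal branch
    lengths)."""
    return tree.tree.as_string(
        schema="newick",
        suppress_rooting=True,
        real_value_format_specifier=".6f",
    ).strip()


def from_newick(newick: str) -> RelationshipTree:
    tree = dendropy.Tree.get(data=newick, schema="newick")
    tree.is_rooted = False
    labels = tuple(leaf.taxon.label for leaf in tree.leaf_node_iter())
    return RelationshipTree(tree=tree, labels=labels)
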