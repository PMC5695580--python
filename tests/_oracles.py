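"""Independent brute-force oracles used by the test suite.

These re-derive expected results by literal enumeration, deliberately
sharing no code with the implementation they check.
"""
from __future__ import annotations

from itertools import combinations

import numpy as np

BASES = "ACGT"


def brute_force_call(counts, min_coverage=20, min_variant_frequency=0.125,
                     require_both_strands=True, reference=None):
    """Literal application of the three calling rules to a (L, 4, 2) tally.

    Returns (consensus_string, {position: [(minor_base, freq), ...]}).
    """
    counts = np.asarray(counts)
    consensus = []
    variants = {}
    for pos in range(counts.shape[0]):
        per_base = [int(counts[pos, b, 0] + counts[pos, b, 1]) for b in range(4)]
        depth = sum(per_base)
        if depth < min_coverage:
            consensus.append("N")
            continue
        best = max(per_base)
        tied = [b for b in range(4) if per_base[b] == best]
        if reference is not None and BASES.index(reference[pos]) in tied:
            cons = BASES.index(reference[pos])
        else:
            cons = tied[0]
        consensus.append(BASES[cons])
        minors = []
        for b in range(4):
            if b == cons or per_base[b] == 0:
                continue
            freq = per_base[b] / depth
            if freq < min_variant_frequency:
                continue
            if require_both_strands and not (
                counts[pos, b, 0] > 0 and counts[pos, b, 1] > 0
            ):
                continue
            minors.append((BASES[b], freq))
        if minors:
            variants[pos] = minors
    return "".join(consensus), variants


def nj_brute_force_4taxon(labels, d):
    """Best of the 3 unrooted 4-taxon topologies by exact least-squares fit.

    For each topology ((a,b),(c,d)) the 5 branch lengths have a closed-form
    least-squares solution; the additive topology fits with zero residual.
    Returns the frozenset pair partition of the best topology.
    """
    d = np.asarray(d, dtype=float)
    best = None
    for (i, j) in [(0, 1), (0, 2), (0, 3)]:
        k, l = [x for x in range(4) if x not in (i, j)]
        # path-length design matrix for branches (ei, ej, ek, el, internal)
        pairs = list(combinations(range(4), 2))
        A = np.zeros((6, 5))
        leaf_edge = {i: 0, j: 1, k: 2, l: 3}
        for row, (p, q) in enumerate(pairs):
            A[row, leaf_edge[p]] = 1
            A[row, leaf_edge[q]] = 1
            if {p, q} not in ({i, j}, {k, l}):
                A[row, 4] = 1
        y = np.array([d[p, q] for p, q in pairs])
        coef, residual, *_ = np.linalg.lstsq(A, y, rcond=None)
        rss = float(np.sum((A @ coef - y) ** 2))
        split = frozenset(
            [frozenset([labels[i], labels[j]]), frozenset([labels[k], labels[l]])]
        )
        if best is None or rss < best[0]:
            best = (rss, split)
    return best[1]


def random_additive_matrix(labels, rng, min_branch=0.05, max_branch=1.0):
    """Random binary tree over the labels -> (additive matrix, splits).

    Built by random sequential joining; leaf-to-leaf distances are path
    sums, so the matrix is additive by construction.  Returns the matrix
    and the set of non-trivial splits (as frozensets of one side's labels).
    """
    n = len(labels)
    # nodes: dict node_id -> (children, edge length to parent filled on join)
    next_id = n
    active = list(range(n))
    children: dict[int, list[tuple[int, float]]] = {i: [] for i in range(n)}
    while len(active) > 2:
        i, j = sorted(rng.choice(len(active), size=2, replace=False))
        a, b = active[i], active[j]
        la = float(rng.uniform(min_branch, max_branch))
        lb = float(rng.uniform(min_branch, max_branch))
        children[next_id] = [(a, la), (b, lb)]
        active = [x for x in active if x not in (a, b)] + [next_id]
        next_id += 1
    a, b = active
    l = float(rng.uniform(min_branch, max_branch))
    children[next_id] = [(a, l / 2), (b, l / 2)]
    root = next_id

    # leaf distances to every node by DFS
    def leaves_below(node):
        if node < n:
            return {node: 0.0}
        out = {}
        for child, length in children[node]:
            for leaf, dist in leaves_below(child).items():
                out[leaf] = dist + length
        return out

    dist = np.zeros((n, n))

    def fill(node):
        groups = []
        for child, length in children.get(node, []):
            groups.append(
                {leaf: d + length for leaf, d in leaves_below(child).items()}
            )
            fill(child)
        for g1, g2 in combinations(groups, 2):
            for leaf1, d1 in g1.items():
                for leaf2, d2 in g2.items():
                    dist[leaf1, leaf2] = dist[leaf2, leaf1] = d1 + d2

    fill(root)

    splits = set()

    def collect(node):
        if node < n:
            return {node}
        below = set()
        for child, _ in children[node]:
            below |= collect(child)
        if 2 <= len(below) <= n - 2:
            splits.add(frozenset(labels[i] for i in below))
        return below

    collect(root)
    return dist, splits
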