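"""Tree machinery: neighbor joining, bipartitions and tree-to-tree distances.

Trees are ``skbio.TreeNode`` objects throughout.  A tree whose root has
three (or more) children is treated as the canonical unrooted form.
"""

from __future__ import annotations

import numpy as np
from skbio import TreeNode

from .io_formats import DistanceMatrix

__all__ = [
    "neighbor_joining",
    "bipartitions",
    "bipartition_lengths",
    "robinson_foulds",
    "rf_normalized",
    "branch_score",
    "patristic_matrix",
    "leaf_names",
]


def leaf_names(tree: TreeNode) -> list:
    return [t.name for t in tree.tips()]


def _check_leaf_sets(t1: TreeNode, t2: TreeNode) -> frozenset:
    s1, s2 = frozenset(leaf_names(t1)), frozenset(leaf_names(t2))
    if s1 != s2:
        raise ValueError(
            "leaf sets differ: only in first tree %s; only in second tree %s"
            % (sorted(s1 - s2), sorted(s2 - s1))
        )
    return s1


# ---------------------------------------------------------------------------
# Neighbor joining
# ---------------------------------------------------------------------------

def neighbor_joining(dm: DistanceMatrix) -> TreeNode:
    """Saitou-Nei neighbor joining with deterministic tie-breaking.

    Ties in the Q criterion are broken by the lexicographically smallest
    (sorted) pair of representative labels, where an internal node is
    represented by its smallest descendant leaf.  Negative intermediate
    branch lengths are clamped to 0.  The returned tree is unrooted in
    the usual sense: its root is the final trifurcation.
    """
    n0 = len(dm)
    if n0 < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    if not np.all(np.isfinite(dm.values)):
        raise ValueError("distance matrix has non-finite entries")
    D = dm.values.copy()
    nodes = [TreeNode(name=lab) for lab in dm.labels]
    reps = list(dm.labels)  # smallest descendant leaf per active node

    while len(nodes) > 3:
        n = len(nodes)
        r = D.sum(axis=1)
        Q = (n - 2) * D - r[:, None] - r[None, :]
        # evaluation order makes Q asymmetric at the ulp level; keep only
        # the upper triangle so the argmin search is well defined
        Q[np.tril_indices(n)] = np.inf
        ties = np.argwhere(Q == Q.min())
        i, j = min(
            ((int(p[0]), int(p[1])) for p in ties),
            key=lambda p: tuple(sorted((reps[p[0]], reps[p[1]]))),
        )
        li = 0.5 * D[i, j] + (r[i] - r[j]) / (2.0 * (n - 2))
        lj = D[i, j] - li
        nodes[i].length = max(li, 0.0)
        nodes[j].length = max(lj, 0.0)
        parent = TreeNode(children=[nodes[i], nodes[j]])
        dnew = 0.5 * (D[i] + D[j] - D[i, j])
        dnew[i] = 0.0
        D[i] = dnew
        D[:, i] = dnew
        nodes[i] = parent
        reps[i] = min(reps[i], reps[j])
        keep = [k for k in range(n) if k != j]
        D = D[np.ix_(keep, keep)]
        del nodes[j], reps[j]

    # final 3-way join, closed form
    d01, d02, d12 = D[0, 1], D[0, 2], D[1, 2]
    b = [0.5 * (d01 + d02 - d12), 0.5 * (d01 + d12 - d02), 0.5 * (d02 + d12 - d01)]
    for node, length in zip(nodes, b):
        node.length = max(length, 0.0)
    return TreeNode(children=list(nodes))


# ---------------------------------------------------------------------------
# Bipartitions
# ---------------------------------------------------------------------------

def _clades(tree: TreeNode):
    """Yield (node, frozenset-of-tip-names) for every non-root node, postorder."""
    sets = {}
    for node in tree.postorder(include_self=True):
        if node.is_tip():
            sets[id(node)] = frozenset([node.name])
        else:
            s = frozenset().union(*(sets[id(c)] for c in node.children))
            sets[id(node)] = s
        if node.parent is not None:
            yield node, sets[id(node)]


def _canonical(clade: frozenset, full: frozenset, ref: str) -> frozenset:
    return full - clade if ref in clade else clade


def bipartitions(tree: TreeNode) -> frozenset:
    """Non-trivial bipartitions of the (unrooted) tree.

    Each bipartition is represented canonically by the side not
    containing the lexicographically smallest leaf.  Trivial
    bipartitions (a single leaf on one side) are excluded.
    """
    full = frozenset(leaf_names(tree))
    if len(full) != sum(1 for _ in tree.tips()):
        raise ValueError("duplicate leaf labels")
    ref = min(full)
    out = set()
    for _, clade in _clades(tree):
        side = _canonical(clade, full, ref)
        if 2 <= len(side) <= len(full) - 2:
            out.add(side)
    return frozenset(out)


def bipartition_lengths(tree: TreeNode, include_trivial: bool = True) -> dict:
    """Map canonical bipartition -> total branch length (missing lengths = 0).

    A root with exactly two children contributes a single unrooted edge;
    the two child lengths are summed.
    """
    full = frozenset(leaf_names(tree))
    ref = min(full)
    out: dict = {}
    for node, clade in _clades(tree):
        side = _canonical(clade, full, ref)
        if len(side) < 1 or len(side) > len(full) - 1:
            continue
        if not include_trivial and (len(side) == 1 or len(side) == len(full) - 1):
            continue
        out[side] = out.get(side, 0.0) + (node.length or 0.0)
    return out


def robinson_foulds(t1: TreeNode, t2: TreeNode) -> int:
    """Symmetric-difference count of non-trivial bipartitions."""
    _check_leaf_sets(t1, t2)
    return len(bipartitions(t1) ^ bipartitions(t2))


def rf_normalized(t1: TreeNode, t2: TreeNode) -> float:
    """RF divided by its maximum ``2(N-3)`` on binary trees; 0 for N <= 3."""
    n = len(frozenset(leaf_names(t1)))
    rf = robinson_foulds(t1, t2)
    if n <= 3:
        return 0.0
    return rf / (2.0 * (n - 3))


def branch_score(t1: TreeNode, t2: TreeNode) -> float:
    """Branch-score distance: sqrt of summed squared branch-length differences.

    The sum runs over the union of bipartitions of the two trees
    (external branches included); a bipartition absent from a tree
    contributes length 0, as does a branch without a stored length.
    """
    _check_leaf_sets(t1, t2)
    b1 = bipartition_lengths(t1, include_trivial=True)
    b2 = bipartition_lengths(t2, include_trivial=True)
    total = 0.0
    for key in set(b1) | set(b2):
        diff = b1.get(key, 0.0) - b2.get(key, 0.0)
        total += diff * diff
    return float(np.sqrt(total))


def patristic_matrix(tree: TreeNode) -> DistanceMatrix:
    """Leaf-to-leaf path-length matrix (missing branch lengths treated as 0)."""
    work = tree.copy()
    for node in work.traverse(include_self=False):
        if node.length is None:
            node.length = 0.0
    sk = work.tip_tip_distances()
    return DistanceMatrix(sk.data, list(sk.ids))
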