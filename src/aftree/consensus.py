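"""Consensus ensemble: majority-rule consensus, polytomy resolution,
weighted least-squares branch fitting, and branch-length averaging.

The pipeline mirrors the classic PHYLIP route: CONSENSE-style majority
rule (extended), zero-length resolution of multifurcations, FITCH-style
weighted least-squares branch lengths fitted once per source distance
matrix on the shared topology, and a final per-branch arithmetic mean.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import nnls
from skbio import TreeNode

from .io_formats import DistanceMatrix
from .phylo import bipartitions, leaf_names

__all__ = [
    "ConsensusTree",
    "majority_consensus",
    "resolve_multifurcations",
    "ls_branch_lengths",
    "ensemble_consensus",
]


@dataclass
class ConsensusTree:
    tree: TreeNode
    support: dict = field(repr=False)  # canonical bipartition -> frequency in (0, 1]


def _compatible(a: frozenset, b: frozenset) -> bool:
    # canonical sides both exclude the reference leaf, so unrooted
    # compatibility reduces to disjoint-or-nested
    return a.isdisjoint(b) or a <= b or b <= a


def _min_tip(node: TreeNode) -> str:
    if node.is_tip():
        return node.name
    return min(t.name for t in node.tips())


def _sort_children(tree: TreeNode) -> TreeNode:
    for node in tree.postorder(include_self=True):
        if node.children:
            node.children.sort(key=_min_tip)
    return tree


def _tree_from_clades(leaves: frozenset, clades) -> TreeNode:
    """Build a tree from a pairwise-compatible set of canonical clades.

    Clades exclude the reference (smallest) leaf; the root carries the
    reference leaf plus all top-level groups, i.e. the canonical
    unrooted form.
    """
    ordered = sorted(clades, key=lambda c: (-len(c), sorted(c)))
    root = TreeNode()
    nodes: list = []  # (clade, TreeNode), insertion = decreasing size
    for clade in ordered:
        parent = root
        best = None
        for other, node in nodes:
            if clade < other and (best is None or len(other) < len(best)):
                best, parent = other, node
        new = TreeNode()
        parent.append(new)
        nodes.append((clade, new))
    for leaf in sorted(leaves):
        parent = root
        best = None
        for other, node in nodes:
            if leaf in other and (best is None or len(other) < len(best)):
                best, parent = other, node
        parent.append(TreeNode(name=leaf))
    return _sort_children(root)


def majority_consensus(trees, threshold: float = 0.5, extended: bool = True) -> ConsensusTree:
    """Majority-rule consensus of trees sharing one leaf set.

    Bipartitions occurring in a fraction of trees strictly greater than
    ``threshold`` are retained.  With ``extended=True`` (the CONSENSE
    default behaviour) the remaining bipartitions are added greedily in
    decreasing frequency (ties by canonical order) when compatible with
    everything already retained.  The result may be multifurcating.
    """
    trees = list(trees)
    if len(trees) < 2:
        raise ValueError("consensus needs at least 2 trees")
    leaf_set = frozenset(leaf_names(trees[0]))
    counts: dict = {}
    for t in trees:
        if frozenset(leaf_names(t)) != leaf_set:
            raise ValueError("trees have different leaf sets")
        for bp in bipartitions(t):
            counts[bp] = counts.get(bp, 0) + 1
    ntrees = len(trees)
    freq = {bp: c / ntrees for bp, c in counts.items()}
    selected = [bp for bp, f in freq.items() if f > threshold]
    # majority bipartitions are mutually compatible by pigeonhole
    if extended:
        rest = sorted(
            (bp for bp, f in freq.items() if f <= threshold),
            key=lambda bp: (-freq[bp], sorted(bp)),
        )
        for bp in rest:
            if all(_compatible(bp, s) for s in selected):
                selected.append(bp)
    tree = _tree_from_clades(leaf_set, selected)
    return ConsensusTree(tree, {bp: freq[bp] for bp in selected})


def resolve_multifurcations(tree: TreeNode) -> TreeNode:
    """Resolve polytomies by inserting zero-length branches.

    Each polytomy becomes a caterpillar over its children sorted by
    smallest descendant label, so the output is deterministic.  A root
    with three or more children keeps exactly three (the canonical
    unrooted-binary form); every other node is reduced to two children.
    All inserted branches have length 0, so the positive-length
    bipartition set — and every patristic distance — is preserved.
    """
    work = tree.copy()
    for node in list(work.postorder(include_self=True)):
        target = 3 if (node.parent is None and len(node.children) >= 3) else 2
        if len(node.children) <= target:
            continue
        children = sorted(node.children, key=_min_tip)
        for c in children:
            node.remove(c)
        # fold the sorted children pairwise into a caterpillar
        current = children[0]
        for nxt in children[1 : len(children) - (target - 1)]:
            joint = TreeNode(length=0.0, children=[current, nxt])
            current = joint
        node.extend([current] + children[len(children) - (target - 1):])
    return _sort_children(work)


# ---------------------------------------------------------------------------
# FITCH-style weighted least squares
# ---------------------------------------------------------------------------

def _unrooted_edges(tree: TreeNode):
    """Edge variables of the unrooted tree.

    Returns (edge_nodes, membership) where ``edge_nodes[e]`` is the list
    of tree nodes whose parent branch realises edge ``e`` (two nodes for
    the single unrooted edge split by a degree-2 root) and ``membership``
    maps each edge to the frozenset of tips below it.
    """
    root = tree
    children_of_root = list(root.children)
    merge_root = len(children_of_root) == 2
    edges, members = [], []
    seen_root_child = False
    below = {}
    for node in tree.postorder(include_self=True):
        if node.is_tip():
            below[id(node)] = frozenset([node.name])
        else:
            below[id(node)] = frozenset().union(*(below[id(c)] for c in node.children))
        if node.parent is None:
            continue
        if merge_root and node.parent is root:
            if seen_root_child:
                # second root child: same unrooted edge as the first
                edges[root_edge_idx].append(node)
                continue
            seen_root_child = True
            root_edge_idx = len(edges)
        edges.append([node])
        members.append(below[id(node)])
    return edges, members


def ls_branch_lengths(topology: TreeNode, dm: DistanceMatrix, power: int = 2) -> TreeNode:
    """Fit non-negative branch lengths by weighted least squares.

    Minimizes ``sum_{i<j} w_ij (d_ij - p_ij)^2`` with ``w = 1/d^power``
    (FITCH's default ``power=2``), ``p`` the patristic distance, subject
    to all lengths >= 0.  Zero input distances borrow the smallest
    positive entry for their weight.  The topology is unchanged; the
    solver (non-negative least squares on the path-incidence normal
    equations) is deterministic.
    """
    if power not in (0, 1, 2):
        raise ValueError("power must be 0, 1 or 2")
    work = topology.copy()
    tips = sorted(leaf_names(work))
    if set(tips) != set(dm.labels):
        raise ValueError("topology leaves do not match distance-matrix labels")
    tip_index = {name: i for i, name in enumerate(tips)}
    edges, members = _unrooted_edges(work)
    ne, nt = len(edges), len(tips)

    M = np.zeros((ne, nt), dtype=bool)
    for e, mem in enumerate(members):
        for name in mem:
            M[e, tip_index[name]] = True

    ii, jj = np.triu_indices(nt, k=1)
    A = (M[:, ii] ^ M[:, jj]).T.astype(float)  # (pairs, edges) path incidence
    dmr = dm.reorder(tips)
    d = dmr.values[ii, jj]

    if power == 0:
        w = np.ones_like(d)
    else:
        dpos = d.copy()
        positive = dpos[dpos > 0]
        if positive.size == 0:
            w = np.ones_like(d)
        else:
            dpos[dpos == 0] = positive.min()
            w = dpos ** (-float(power))

    Aw = A * w[:, None]
    G = A.T @ Aw
    c = Aw.T @ d
    # reduce to a square NNLS via the Cholesky factor of the Gram matrix
    try:
        R = np.linalg.cholesky(G).T
    except np.linalg.LinAlgError as exc:
        raise ValueError("singular least-squares system for branch lengths") from exc
    rhs = np.linalg.solve(R.T, c)
    x, _ = nnls(R, rhs)

    for e, nodes in enumerate(edges):
        nodes[0].length = float(x[e])
        for extra in nodes[1:]:
            extra.length = 0.0  # merged root edge: put full length on one side
    return work


def ensemble_consensus(trees, dms) -> TreeNode:
    """Majority consensus topology with averaged least-squares branch lengths.

    One distance matrix per source method; the binary-resolved consensus
    topology is fitted against each matrix and the fitted lengths are
    averaged branch-wise.
    """
    dms = list(dms)
    if not dms:
        raise ValueError("need at least one distance matrix")
    cons = majority_consensus(trees)
    binary = resolve_multifurcations(cons.tree)
    fitted = [ls_branch_lengths(binary, dm) for dm in dms]
    out = fitted[0].copy()
    others = fitted[1:]
    walkers = [t.postorder(include_self=True) for t in others]
    for node in out.postorder(include_self=True):
        partners = [next(w) for w in walkers]
        if node.parent is None:
            continue
        lengths = [node.length or 0.0] + [(p.length or 0.0) for p in partners]
        node.length = float(np.mean(lengths))
    return out
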