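"""Gold-standard tree generation from rank-string taxonomy tables.

A taxonomy table maps each sequence id to an ordered list of rank
labels (domain ... species).  The generated tree has one internal node
per distinct rank *path*; empty rank slots create no node, so sequences
attach at their deepest named ancestor, and unary chains are collapsed
to keep the tree comparable with inferred phylogenies under RF.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from skbio import TreeNode

from . import phylo

__all__ = ["TaxonomyTable", "taxonomy_to_tree", "gold_standard_distance"]

RANK_NAMES = ("domain", "phylum", "class", "order", "family", "genus", "species")


@dataclass
class TaxonomyTable:
    """Mapping of sequence id -> ordered tuple of rank labels.

    Labels are kept verbatim (including any ``k__`` style prefixes);
    rank depth is positional.  Empty strings mark unassigned slots.
    """

    assignments: dict = field(repr=False)

    def __post_init__(self):
        self.assignments = {str(k): tuple(v) for k, v in self.assignments.items()}
        if not self.assignments:
            raise ValueError("empty taxonomy table")

    @property
    def ids(self):
        return list(self.assignments)

    @property
    def depth(self) -> int:
        return max(len(v) for v in self.assignments.values())

    def items(self):
        return self.assignments.items()

    def __len__(self):
        return len(self.assignments)

    def __getitem__(self, sid):
        return self.assignments[sid]


def taxonomy_to_tree(tax: TaxonomyTable) -> TreeNode:
    """Build the taxonomy ("gold standard") tree.

    Internal nodes are keyed by the full path of (rank position, label)
    pairs, so identical labels under different parents stay distinct.
    Empty labels are skipped.  Unary chains are collapsed bottom-up and
    a unary root is removed.  Child order is deterministic (by smallest
    descendant id).  The tree carries no branch lengths.
    """
    if len(tax) < 2:
        raise ValueError("need at least 2 sequences to build a tree")
    root = TreeNode()
    nodes = {(): root}
    for sid in sorted(tax.ids):
        path = ()
        for pos, label in enumerate(tax[sid]):
            if label == "":
                continue
            path = path + ((pos, label),)
            if path not in nodes:
                # the parent path was created on a previous iteration
                # (empty labels never enter the path)
                node = TreeNode(name=label)
                nodes[path[:-1]].append(node)
                nodes[path] = node
        nodes[path].append(TreeNode(name=sid))

    # collapse unary internal nodes bottom-up
    for node in list(root.postorder(include_self=False)):
        if not node.is_tip() and len(node.children) == 1:
            child = node.children[0]
            parent = node.parent
            node.remove(child)
            parent.remove(node)
            parent.append(child)
    while len(root.children) == 1 and not root.children[0].is_tip():
        root = root.children[0]
        root.parent = None

    for node in root.postorder(include_self=True):
        if node.children:
            node.children.sort(key=lambda c: c.name if c.is_tip() else min(t.name for t in c.tips()))

    got = set(phylo.leaf_names(root))
    expected = set(tax.ids)
    if got != expected:
        raise AssertionError(f"taxonomy tree leaves {got ^ expected} inconsistent")
    return root


_METRICS = {
    "rf": phylo.robinson_foulds,
    "rfn": phylo.rf_normalized,
    "bs": phylo.branch_score,
}


def gold_standard_distance(inferred: TreeNode, tax: TaxonomyTable, metric: str = "rf") -> float:
    """Distance of an inferred tree to the taxonomy gold standard.

    Smaller values indicate better resemblance of the taxonomy.
    """
    if metric not in _METRICS:
        raise ValueError(f"unknown metric {metric!r}; choose from {sorted(_METRICS)}")
    gold = taxonomy_to_tree(tax)
    return float(_METRICS[metric](inferred, gold))
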