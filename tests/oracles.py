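"""Independent reference implementations used to cross-check the package.

Deliberately naive: enumeration and third-party code paths only, so
they share nothing with the implementations they validate.
"""

from __future__ import annotations

import numpy as np


def brute_matching_stats(x: str, y: str) -> np.ndarray:
    """O(m^2) substring enumeration oracle for matching statistics.

    Substrings containing ``N`` never match anything (so a query ``N``
    yields 0 and matches never extend across ``N``).
    """
    subs = set()
    for i in range(len(y)):
        for j in range(i + 1, len(y) + 1):
            w = y[i:j]
            if "N" not in w:
                subs.add(w)
    out = []
    for i in range(len(x)):
        best = 0
        for j in range(i + 1, len(x) + 1):
            if x[i:j] in subs:
                best = j - i
            else:
                break
        out.append(best)
    return np.array(out, dtype=np.int64)


def dendropy_rf(newick1: str, newick2: str) -> int:
    """Robinson-Foulds symmetric difference via dendropy (unrooted)."""
    import dendropy
    from dendropy.calculate import treecompare

    tns = dendropy.TaxonNamespace()
    t1 = dendropy.Tree.get(data=newick1, schema="newick", taxon_namespace=tns)
    t2 = dendropy.Tree.get(data=newick2, schema="newick", taxon_namespace=tns)
    t1.encode_bipartitions()
    t2.encode_bipartitions()
    return int(treecompare.symmetric_difference(t1, t2))


def dendropy_bipartitions(newick: str) -> frozenset:
    """Non-trivial bipartitions (canonical: side without the smallest taxon)."""
    import dendropy

    tree = dendropy.Tree.get(data=newick, schema="newick")
    taxa = frozenset(l.taxon.label for l in tree.leaf_node_iter())
    ref = min(taxa)
    out = set()
    for edge in tree.preorder_edge_iter():
        node = edge.head_node
        if node.parent_node is None or node.is_leaf():
            continue
        clade = frozenset(l.taxon.label for l in node.leaf_iter())
        side = taxa - clade if ref in clade else clade
        if 2 <= len(side) <= len(taxa) - 2:
            out.add(side)
    return frozenset(out)


def random_sequence(rng, length: int, alphabet: str = "ACGT") -> str:
    return "".join(rng.choice(list(alphabet), size=length))


def random_newick(rng, leaves) -> str:
    """Uniform random binary topology over the given leaf names."""
    parts = [str(l) for l in leaves]
    while len(parts) > 1:
        i, j = sorted(rng.choice(len(parts), size=2, replace=False))
        b = parts.pop(j)
        a = parts.pop(i)
        parts.append(f"({a},{b})")
    return parts[0] + ";"
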