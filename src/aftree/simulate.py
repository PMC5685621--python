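"""Synthetic data generation and the end-to-end evaluation harnesses.

Everything here is a pure function of its seed.  The defaults are desk
scale (tens to a few hundred taxa, 500 bp sequences); larger runs are
reachable through :class:`SimConfig`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from skbio import TreeNode

from . import afdist, consensus, phylo, taxonomy
from .community import permanova, unifrac_matrix
from .io_formats import AbundanceTable, DistanceMatrix, SequenceRecord, SequenceSet

__all__ = [
    "SimConfig",
    "simulate_tree",
    "evolve_sequences",
    "derive_taxonomy",
    "simulate_communities",
    "random_binary_tree",
    "run_evaluation",
    "run_power_study",
]

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class SimConfig:
    """Knobs for the simulation harnesses.

    ``scale`` is the expected number of substitutions per site from root
    to tip; ``cut_depths`` are the (relative) depths at which taxonomy
    ranks are read off the true tree; ``n_permuted_labels`` injects the
    between-group community effect.
    """

    seed: int
    n_taxa: int = 64
    sequence_length: int = 500
    scale: float = 0.4
    cut_depths: tuple = (0.25, 0.5, 0.75)
    n_samples: int = 10
    n_otus: int = 200
    n_permuted_labels: int = 0
    sigma_baseline: float = 1.5
    sigma_noise: float = 0.6
    k: int = 6

    def __post_init__(self):
        if self.seed is None:
            raise ValueError("seed is mandatory")
        for name in ("n_taxa", "sequence_length", "n_samples", "n_otus"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0 <= self.n_permuted_labels <= self.n_otus:
            raise ValueError("n_permuted_labels must lie in [0, n_otus]")


# ---------------------------------------------------------------------------
# Trees and sequences
# ---------------------------------------------------------------------------

def simulate_tree(n_taxa: int, seed) -> TreeNode:
    """Yule (pure-birth) topology with exponential branch lengths.

    Branch lengths are iid Exp(1), then rescaled so the mean root-to-tip
    path length is exactly 1.  Leaves are named ``t1 .. tn`` in a fixed
    traversal order, so the output is deterministic given the seed.
    """
    if n_taxa < 3:
        raise ValueError("need at least 3 taxa")
    rng = np.random.default_rng(seed)
    root = TreeNode()
    tips = [TreeNode(), TreeNode()]
    root.extend(tips)
    while len(tips) < n_taxa:
        pick = int(rng.integers(len(tips)))
        node = tips.pop(pick)
        kids = [TreeNode(), TreeNode()]
        node.extend(kids)
        tips.extend(kids)
    for i, tip in enumerate(root.tips()):
        tip.name = f"t{i + 1}"
    for node in root.traverse(include_self=False):
        node.length = float(rng.exponential(1.0))
    depths = [tip.accumulate_to_ancestor(root) for tip in root.tips()]
    scale = float(np.mean(depths))
    for node in root.traverse(include_self=False):
        node.length /= scale
    return root


def random_binary_tree(leaves, seed) -> TreeNode:
    """Uniformly random binary topology by sequential random joins (no lengths)."""
    rng = np.random.default_rng(seed)
    nodes = [TreeNode(name=name) for name in leaves]
    while len(nodes) > 3:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        merged = TreeNode(children=[nodes[i], nodes[j]])
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)] + [merged]
    return TreeNode(children=nodes)


def evolve_sequences(tree: TreeNode, length: int, scale: float, seed) -> SequenceSet:
    """Forward Jukes-Cantor simulation along a tree.

    The root sequence is iid uniform over ACGT; each branch substitutes
    every site independently with probability
    ``p = 3/4 (1 - exp(-4 l scale / 3))`` (uniform choice among the
    other three bases).  Only leaf sequences are returned.
    """
    rng = np.random.default_rng(seed)
    root_seq = rng.integers(0, 4, size=length)
    seqs = {}

    def walk(node, seq):
        for child in node.children:
            bl = (child.length or 0.0) * scale
            p = 0.75 * (1.0 - np.exp(-4.0 * bl / 3.0))
            mutated = seq.copy()
            mask = rng.random(length) < p
            if mask.any():
                shift = rng.integers(1, 4, size=int(mask.sum()))
                mutated[mask] = (mutated[mask] + shift) % 4
            if child.is_tip():
                seqs[child.name] = mutated
            else:
                walk(child, mutated)

    walk(tree, root_seq)
    records = [
        SequenceRecord(name, "".join(_BASES[seqs[name]]))
        for name in sorted(seqs, key=lambda s: (len(s), s))
    ]
    return SequenceSet(records)


def derive_taxonomy(tree: TreeNode, cut_depths) -> taxonomy.TaxonomyTable:
    """Read a taxonomy off the true tree by cutting it at fixed depths.

    Rank ``r`` of a leaf is the lineage (edge) crossing depth
    ``cut_depths[r]`` on the leaf's root path; leaves shallower than a
    cut become their own cluster at that rank.  Labels are synthesized
    as ``r<rank>_<cluster index>``.
    """
    cut_depths = tuple(cut_depths)
    if any(b <= a for a, b in zip(cut_depths, cut_depths[1:])):
        raise ValueError("cut_depths must be strictly increasing")
    depth = {id(tree): 0.0}
    for node in tree.preorder(include_self=False):
        depth[id(node)] = depth[id(node.parent)] + (node.length or 0.0)

    assignments = {}
    for tip in tree.tips():
        path = [tip]
        node = tip
        while node.parent is not None:
            node = node.parent
            path.append(node)
        path.reverse()  # root ... tip
        ranks = []
        for cut in cut_depths:
            cluster = None
            for nd in path[1:]:
                if depth[id(nd)] > cut:
                    cluster = nd
                    break
            ranks.append(id(cluster) if cluster is not None else ("tip", tip.name))
        assignments[tip.name] = ranks

    # map raw cluster keys to stable per-rank indices (order of first use)
    labelled = {}
    for r in range(len(cut_depths)):
        seen: dict = {}
        for name in sorted(assignments):
            key = assignments[name][r]
            if key not in seen:
                seen[key] = len(seen) + 1
        for name in assignments:
            labelled.setdefault(name, [])
            labelled[name].append(f"r{r + 1}_{seen[assignments[name][r]]}")
    return taxonomy.TaxonomyTable({k: tuple(v) for k, v in labelled.items()})


# ---------------------------------------------------------------------------
# Communities
# ---------------------------------------------------------------------------

def simulate_communities(cfg: SimConfig, otu_ids=None):
    """Two-group community tables with a label-permutation effect.

    Baseline per-OTU abundances are log-normal; group 1 samples scatter
    around the baseline (log-normal noise), group 2 samples around a
    baseline whose values have been shuffled among ``n_permuted_labels``
    uniformly chosen OTUs — the effect touches labels only, never the
    phylogeny.  Returns ``(table_group1, table_group2, permuted_ids)``.
    """
    rng = np.random.default_rng(cfg.seed)
    if otu_ids is None:
        otu_ids = [f"t{i + 1}" for i in range(cfg.n_otus)]
    otu_ids = list(otu_ids)
    if len(otu_ids) != cfg.n_otus:
        raise ValueError("otu_ids length must equal n_otus")

    baseline = rng.lognormal(mean=0.0, sigma=cfg.sigma_baseline, size=cfg.n_otus)
    baseline2 = baseline.copy()
    chosen = rng.choice(cfg.n_otus, size=cfg.n_permuted_labels, replace=False)
    baseline2[chosen] = baseline[rng.permutation(chosen)]

    def draw(base, n):
        noise = rng.lognormal(mean=0.0, sigma=cfg.sigma_noise, size=(n, cfg.n_otus))
        return base[None, :] * noise

    g1 = AbundanceTable([f"g1_s{i + 1}" for i in range(cfg.n_samples)], otu_ids,
                        draw(baseline, cfg.n_samples))
    g2 = AbundanceTable([f"g2_s{i + 1}" for i in range(cfg.n_samples)], otu_ids,
                        draw(baseline2, cfg.n_samples))
    return g1, g2, [otu_ids[i] for i in sorted(chosen)]


def _merge_tables(g1: AbundanceTable, g2: AbundanceTable) -> tuple:
    table = AbundanceTable(g1.sample_ids + g2.sample_ids, g1.otu_ids,
                           np.vstack([g1.counts, g2.counts]))
    groups = ["g1"] * len(g1.sample_ids) + ["g2"] * len(g2.sample_ids)
    return table, groups


# ---------------------------------------------------------------------------
# Harnesses
# ---------------------------------------------------------------------------

def _infer_trees(seqs: SequenceSet, methods, k: int):
    dms = afdist.distance_matrices(seqs, methods, k=k)
    trees = {m: phylo.neighbor_joining(dms[m]) for m in methods}
    return dms, trees


def run_evaluation(cfg: SimConfig, methods=("acs", "cv", "kr"), replicates: int = 10,
                   metric: str = "rf", random_baseline: int = 0) -> pd.DataFrame:
    """Replicated end-to-end evaluation against the taxonomy gold standard.

    Per replicate: simulate a tree, evolve sequences, derive the
    taxonomy and its gold-standard tree, infer one tree per
    alignment-free method plus their consensus ensemble, and score every
    tree against the gold standard.  With ``random_baseline > 0``, that
    many uniformly random binary trees per replicate are scored as well
    (method ``random_baseline``).  Returns a long-format frame with
    per-replicate rows plus ``mean`` rows.
    """
    methods = tuple(methods)
    seeds = np.random.SeedSequence(cfg.seed).spawn(replicates)
    rows = []
    for rep, ss in enumerate(seeds):
        child = ss.spawn(3)
        tree = simulate_tree(cfg.n_taxa, child[0])
        seqs = evolve_sequences(tree, cfg.sequence_length, cfg.scale, child[1])
        tax = derive_taxonomy(tree, cfg.cut_depths)
        dms, trees = _infer_trees(seqs, methods, cfg.k)
        cons = consensus.ensemble_consensus([trees[m] for m in methods],
                                            [dms[m] for m in methods])
        scored = list(trees.items()) + [("consensus", cons)]
        for name, t in scored:
            rows.append({
                "replicate": rep,
                "method": name,
                "distance_to_gold": taxonomy.gold_standard_distance(t, tax, metric=metric),
                "metric": metric,
            })
        leaves = sorted(phylo.leaf_names(tree))
        for bseed in child[2].spawn(random_baseline):
            rows.append({
                "replicate": rep,
                "method": "random_baseline",
                "distance_to_gold": taxonomy.gold_standard_distance(
                    random_binary_tree(leaves, bseed), tax, metric=metric),
                "metric": metric,
            })
    df = pd.DataFrame(rows)
    means = (df.groupby("method", as_index=False)["distance_to_gold"].mean()
             .assign(replicate="mean", metric=metric))
    return pd.concat([df, means], ignore_index=True)


def run_power_study(cfg: SimConfig, levels=(0, 10, 25, 50, 100), n_sim: int = 20,
                    n_permutations: int = 999, alpha: float = 0.05,
                    reference_tree: TreeNode | None = None,
                    consensus_tree: TreeNode | None = None) -> pd.DataFrame:
    """Power of weighted-UniFrac PERMANOVA vs injected effect size.

    For each effect level (number of permuted OTU labels) and each
    simulation, two-group communities are tested with weighted UniFrac
    under (i) the reference (true) tree and (ii) the alignment-free
    ensemble consensus inferred from sequences evolved on it.  Returns a
    long-format frame of ω² and p per (level, simulation, tree).
    """
    master = np.random.SeedSequence(cfg.seed)
    setup, *level_seeds = master.spawn(1 + len(levels))
    if reference_tree is None:
        s1, s2 = setup.spawn(2)
        reference_tree = simulate_tree(cfg.n_otus, s1)
        if consensus_tree is None:
            seqs = evolve_sequences(reference_tree, cfg.sequence_length, cfg.scale, s2)
            dms, trees = _infer_trees(seqs, ("acs", "cv", "kr"), cfg.k)
            consensus_tree = consensus.ensemble_consensus(list(trees.values()),
                                                          list(dms.values()))
    if consensus_tree is None:
        raise ValueError("consensus_tree required when reference_tree is supplied")
    otu_ids = sorted(phylo.leaf_names(reference_tree))

    rows = []
    for level, lseed in zip(levels, level_seeds):
        for sim, sseed in enumerate(lseed.spawn(n_sim)):
            # a SeedSequence is a valid seed for numpy's default_rng
            sim_cfg = replace(cfg, n_permuted_labels=int(level), seed=sseed)
            g1, g2, _ = simulate_communities(sim_cfg, otu_ids=otu_ids)
            table, groups = _merge_tables(g1, g2)
            for tree_name, tree in (("reference", reference_tree),
                                    ("consensus", consensus_tree)):
                dm = unifrac_matrix(tree, table)
                res = permanova(dm, groups, n_permutations=n_permutations,
                                seed=sseed.spawn(1)[0])
                rows.append({
                    "level": int(level),
                    "sim": sim,
                    "tree": tree_name,
                    "omega2": res.omega2,
                    "r2": res.r2,
                    "pseudo_f": res.pseudo_f,
                    "p_value": res.p_value,
                    "reject": res.p_value <= alpha,
                })
    return pd.DataFrame(rows)
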