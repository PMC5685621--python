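"""Phylogeny-aware community statistics.

Weighted UniFrac (raw by default, normalized optional), classical PCoA
via Gower double-centering, group centering for ordination displays, and
PERMANOVA — one-factor with optional strata, and a sequential
(conditional) two-factor design — reporting pseudo-F, R² and the
bias-adjusted effect size ω².

Unrooted trees (root degree != 2) are midpoint-rooted before UniFrac;
root placement affects raw weighted UniFrac, so the rule is fixed here.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skbio import TreeNode

from .io_formats import AbundanceTable, DistanceMatrix
from .phylo import leaf_names

__all__ = [
    "PermanovaResult",
    "weighted_unifrac",
    "unifrac_matrix",
    "pcoa",
    "center_by_group",
    "permanova",
    "permanova_sequential",
]


# ---------------------------------------------------------------------------
# Weighted UniFrac
# ---------------------------------------------------------------------------

def _ensure_rooted(tree: TreeNode) -> TreeNode:
    if len(tree.children) == 2:
        return tree
    lengths = [n.length for n in tree.traverse(include_self=False)]
    if any(l is None for l in lengths) or not any(l and l > 0 for l in lengths):
        return tree  # cannot midpoint-root without branch lengths
    return tree.root_at_midpoint()


def _branch_profile(tree: TreeNode, otu_ids):
    """(lengths, membership) over all non-root branches.

    ``membership[e, o]`` is True when OTU ``o`` lies below branch ``e``.
    """
    tips = set(leaf_names(tree))
    missing = [o for o in otu_ids if o not in tips]
    if missing:
        raise ValueError(f"abundance labels not in tree: {missing[:5]}")
    index = {o: i for i, o in enumerate(otu_ids)}
    lengths, rows = [], []
    below = {}
    for node in tree.postorder(include_self=True):
        if node.is_tip():
            vec = np.zeros(len(otu_ids), dtype=bool)
            if node.name in index:
                vec[index[node.name]] = True
        else:
            vec = np.zeros(len(otu_ids), dtype=bool)
            for c in node.children:
                vec |= below[id(c)]
        below[id(node)] = vec
        if node.parent is not None:
            lengths.append(node.length or 0.0)
            rows.append(vec)
    return np.array(lengths), np.array(rows)


def _as_vector(v, otu_ids):
    arr = np.zeros(len(otu_ids))
    index = {o: i for i, o in enumerate(otu_ids)}
    for key, val in dict(v).items():
        arr[index[key]] = val
    return arr


def weighted_unifrac(tree: TreeNode, a, b, normalized: bool = False) -> float:
    """Weighted UniFrac distance between two abundance vectors (dicts).

    ``raw = sum_b l_b |p_A(b) - p_B(b)|`` with ``p_X(b)`` the fraction of
    community X's total abundance on leaves below branch ``b``; the
    normalized variant divides by ``sum_b l_b (p_A(b) + p_B(b))``.
    """
    a, b = dict(a), dict(b)
    otus = sorted(set(a) | set(b))
    rooted = _ensure_rooted(tree)
    lengths, members = _branch_profile(rooted, otus)
    va, vb = _as_vector(a, otus), _as_vector(b, otus)
    ta, tb = va.sum(), vb.sum()
    if ta <= 0 or tb <= 0:
        raise ValueError("each community needs positive total abundance")
    pa = members @ (va / ta)
    pb = members @ (vb / tb)
    raw = float(np.sum(lengths * np.abs(pa - pb)))
    if not normalized:
        return raw
    den = float(np.sum(lengths * (pa + pb)))
    return raw / den if den > 0 else 0.0


def unifrac_matrix(tree: TreeNode, table: AbundanceTable, normalized: bool = False) -> DistanceMatrix:
    """All-pairs weighted UniFrac over the samples of an abundance table."""
    rooted = _ensure_rooted(tree)
    lengths, members = _branch_profile(rooted, table.otu_ids)
    totals = table.counts.sum(axis=1)
    P = members.astype(float) @ (table.counts / totals[:, None]).T  # (branches, samples)
    diff = np.abs(P[:, :, None] - P[:, None, :])
    raw = np.einsum("e,eij->ij", lengths, diff)
    if normalized:
        den = np.einsum("e,eij->ij", lengths, P[:, :, None] + P[:, None, :])
        with np.errstate(invalid="ignore", divide="ignore"):
            raw = np.where(den > 0, raw / np.where(den > 0, den, 1.0), 0.0)
    np.fill_diagonal(raw, 0.0)
    return DistanceMatrix(0.5 * (raw + raw.T), table.sample_ids)


# ---------------------------------------------------------------------------
# PCoA
# ---------------------------------------------------------------------------

def _gower(D2: np.ndarray) -> np.ndarray:
    n = D2.shape[0]
    J = np.eye(n) - np.full((n, n), 1.0 / n)
    return -0.5 * J @ D2 @ J


def pcoa(dm: DistanceMatrix):
    """Classical (metric) multidimensional scaling.

    Returns ``(coordinates, eigenvalues)``: eigenvalues of the Gower
    matrix sorted descending (negatives reported), and sample
    coordinates on the axes with positive eigenvalues, scaled by the
    square root of the eigenvalue.
    """
    G = _gower(dm.values ** 2)
    vals, vecs = np.linalg.eigh(G)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    pos = vals > max(vals.max(), 0) * 1e-12
    coords = vecs[:, pos] * np.sqrt(vals[pos])
    return coords, vals


def center_by_group(coordinates: np.ndarray, groups) -> np.ndarray:
    """Subtract each group's centroid from its members' coordinates."""
    coords = np.asarray(coordinates, dtype=float).copy()
    groups = np.asarray(list(groups))
    if len(groups) != coords.shape[0]:
        raise ValueError("one group per sample required")
    for g in np.unique(groups):
        mask = groups == g
        coords[mask] -= coords[mask].mean(axis=0)
    return coords


# ---------------------------------------------------------------------------
# PERMANOVA
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PermanovaResult:
    factor: str
    df_effect: int
    df_residual: int
    ss_effect: float
    ss_residual: float
    ss_total: float
    pseudo_f: float
    r2: float
    omega2: float
    p_value: float
    n_permutations: int
    seed: object


def _labels_to_codes(labels):
    labels = np.asarray(list(labels))
    uniq, codes = np.unique(labels, return_inverse=True)
    return uniq, codes


def _align_factor(dm: DistanceMatrix, factor):
    """Accept either a mapping keyed by sample label or a sequence in label order."""
    if hasattr(factor, "keys"):
        return [factor[lab] for lab in dm.labels]
    factor = list(factor)
    if len(factor) != len(dm):
        raise ValueError("factor length does not match number of samples")
    return factor


def _ss_within(D2: np.ndarray, codes: np.ndarray, sizes: np.ndarray) -> float:
    total = 0.0
    for g, n_g in enumerate(sizes):
        u = (codes == g).astype(float)
        total += 0.5 * (u @ D2 @ u) / n_g
    return total


def _permutation_indices(rng, n_perm: int, n: int, strata_codes=None) -> np.ndarray:
    if strata_codes is None:
        return np.argsort(rng.random((n_perm, n)), axis=1)
    idx = np.tile(np.arange(n), (n_perm, 1))
    for s in np.unique(strata_codes):
        pos = np.flatnonzero(strata_codes == s)
        sub = np.argsort(rng.random((n_perm, pos.size)), axis=1)
        idx[:, pos] = pos[sub]
    return idx


def permanova(dm: DistanceMatrix, groups, n_permutations: int = 10000,
              seed=None, strata=None, factor: str = "factor") -> PermanovaResult:
    """One-factor PERMANOVA on a distance matrix.

    ``SS_total = sum_{i<j} d²/N``; ``SS_within`` sums within-group
    squared distances scaled by group size; ``F`` is the usual pseudo-F.
    The p-value permutes group labels (within strata when given) and
    uses the add-one estimator, so it is never 0 and is reproducible
    bit-for-bit given the seed.  ω² is reported raw (it may be
    negative under the null).
    """
    groups = _align_factor(dm, groups)
    uniq, codes = _labels_to_codes(groups)
    n = len(dm)
    a = len(uniq)
    sizes = np.bincount(codes)
    if a < 2:
        raise ValueError("need at least 2 groups")
    if sizes.min() < 2:
        small = uniq[np.argmin(sizes)]
        raise ValueError(f"group {small!r} has fewer than 2 samples")

    D2 = dm.values ** 2
    ss_total = D2.sum() / (2.0 * n)
    ss_within = _ss_within(D2, codes, sizes)
    ss_effect = ss_total - ss_within
    df_effect, df_residual = a - 1, n - a
    ms_residual = ss_within / df_residual
    f_obs = (ss_effect / df_effect) / ms_residual
    r2 = ss_effect / ss_total
    omega2 = (ss_effect - df_effect * ms_residual) / (ss_total + ms_residual)

    rng = np.random.default_rng(seed)
    strata_codes = None
    if strata is not None:
        strata_codes = _labels_to_codes(_align_factor(dm, strata))[1]
    idx = _permutation_indices(rng, n_permutations, n, strata_codes)
    codes_perm = codes[idx]  # (P, n)
    ssw = np.zeros(n_permutations)
    for g, n_g in enumerate(sizes):
        U = (codes_perm == g).astype(float)
        ssw += 0.5 * np.einsum("pi,pi->p", U @ D2, U) / n_g
    f_perm = ((ss_total - ssw) / df_effect) / (ssw / df_residual)
    exceed = int(np.sum(f_perm >= f_obs - 1e-12))
    p = (exceed + 1) / (n_permutations + 1)

    return PermanovaResult(factor, df_effect, df_residual, float(ss_effect),
                           float(ss_within), float(ss_total), float(f_obs),
                           float(r2), float(omega2), float(p), n_permutations, seed)


def _design(*factor_code_lists):
    """Intercept + drop-first dummy coding for the given coded factors."""
    n = len(factor_code_lists[0])
    cols = [np.ones(n)]
    for codes in factor_code_lists:
        for level in range(1, codes.max() + 1):
            cols.append((codes == level).astype(float))
    return np.column_stack(cols)


def _ss_model(X: np.ndarray, G: np.ndarray) -> tuple:
    """trace(H G) for the hat matrix of X, plus rank(X)."""
    q, r = np.linalg.qr(X)
    diag = np.abs(np.diag(r))
    keep = diag > diag.max() * 1e-10
    qk = q[:, keep]
    return float(np.sum((qk.T @ G) * qk.T)), int(keep.sum())


def permanova_sequential(dm: DistanceMatrix, factor_a, factor_b,
                         n_permutations: int = 10000, seed=None) -> PermanovaResult:
    """PERMANOVA for factor B conditional on factor A ("B | A").

    Uses the Gower inner-product formulation: ``SS(model) = trace(H G)``
    with ``H`` the projection onto the model design space;
    ``SS(B|A) = SS(A+B) - SS(A)``, residual taken from the full model.
    Permutations shuffle B assignments freely within the levels of A.
    """
    a_labels = _align_factor(dm, factor_a)
    b_labels = _align_factor(dm, factor_b)
    _, a_codes = _labels_to_codes(a_labels)
    _, b_codes = _labels_to_codes(b_labels)
    n = len(dm)

    G = _gower(dm.values ** 2)
    ss_total = float(np.trace(G))
    ss_a, rank_a = _ss_model(_design(a_codes), G)
    ss_ab, rank_ab = _ss_model(_design(a_codes, b_codes), G)
    df_b = rank_ab - rank_a
    if df_b == 0:
        raise ValueError("factor B is confounded with factor A (no rank increase)")
    ss_b = ss_ab - ss_a
    ss_res = ss_total - ss_ab
    df_res = n - rank_ab
    ms_res = ss_res / df_res
    f_obs = (ss_b / df_b) / ms_res
    r2 = ss_b / ss_total
    omega2 = (ss_b - df_b * ms_res) / (ss_total + ms_res)

    rng = np.random.default_rng(seed)
    idx = _permutation_indices(rng, n_permutations, n, a_codes)
    exceed = 0
    for p_row in idx:
        bp = b_codes[p_row]
        ss_ab_p, rank_ab_p = _ss_model(_design(a_codes, bp), G)
        df_b_p = max(rank_ab_p - rank_a, 1)
        ss_res_p = ss_total - ss_ab_p
        f_p = ((ss_ab_p - ss_a) / df_b_p) / (ss_res_p / max(n - rank_ab_p, 1))
        if f_p >= f_obs - 1e-12:
            exceed += 1
    p = (exceed + 1) / (n_permutations + 1)

    return PermanovaResult("B|A", df_b, df_res, float(ss_b), float(ss_res),
                           ss_total, float(f_obs), float(r2), float(omega2),
                           float(p), n_permutations, seed)
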