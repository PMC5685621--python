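"""Alignment-free pairwise distances over a shared exact-substring engine.

Three methods are provided:

* ``acs`` — average-common-substring distance built on matching
  statistics (the longest substring of X starting at each position that
  occurs anywhere in Y).
* ``kr`` — a shortest-unique-substring (shustring) estimator: the mean
  shustring length yields a directed mismatch estimate which is
  symmetrized and passed through the Jukes-Cantor transform.
* ``cv`` — composition vectors of Markov-background-corrected k-word
  frequencies compared by cosine.

``N`` never participates in exact matching: a query position holding
``N`` has matching statistic 0, subject substrings containing ``N``
never match, and k-mer windows containing ``N`` are skipped.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .io_formats import DistanceMatrix, SequenceRecord, SequenceSet

logger = logging.getLogger(__name__)

__all__ = [
    "MatchingStats",
    "ShustringStats",
    "CompositionVector",
    "matching_statistics",
    "shustring_stats",
    "acs_distance",
    "kr_distance",
    "composition_vector",
    "cvtree_distance",
    "distance_matrix",
    "distance_matrices",
]

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

#: mismatch cap keeping the Jukes-Cantor log finite
KR_PI_CAP = 0.74


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


class SuffixAutomaton:
    """Suffix automaton of a subject string (linear-time construction).

    Streams the longest common substring *ending* at each query position
    in amortized O(query length).  ``N`` in the query always resets the
    match; since an ``N`` transition can only be taken by an ``N``
    character, subject substrings containing ``N`` are unreachable for
    ACGT queries, so ``N`` never matches anything.
    """

    __slots__ = ("next", "link", "length")

    def __init__(self, s: str):
        self.next = [{}]
        self.link = [-1]
        self.length = [0]
        last = 0
        for c in s:
            cur = len(self.length)
            self.length.append(self.length[last] + 1)
            self.link.append(0)
            self.next.append({})
            p = last
            while p != -1 and c not in self.next[p]:
                self.next[p][c] = cur
                p = self.link[p]
            if p != -1:
                q = self.next[p][c]
                if self.length[p] + 1 == self.length[q]:
                    self.link[cur] = q
                else:
                    clone = len(self.length)
                    self.length.append(self.length[p] + 1)
                    self.next.append(dict(self.next[q]))
                    self.link.append(self.link[q])
                    while p != -1 and self.next[p].get(c) == q:
                        self.next[p][c] = clone
                        p = self.link[p]
                    self.link[q] = clone
                    self.link[cur] = clone
            last = cur

    def match_lengths_ending(self, query: str) -> np.ndarray:
        nxt, lnk, ln = self.next, self.link, self.length
        out = np.empty(len(query), dtype=np.int64)
        v, l = 0, 0
        for i, c in enumerate(query):
            if c == "N":
                v, l = 0, 0
            else:
                while v and c not in nxt[v]:
                    v = lnk[v]
                    l = ln[v]
                if c in nxt[v]:
                    v = nxt[v][c]
                    l += 1
                else:
                    l = 0
            out[i] = l
        return out


@dataclass(frozen=True)
class MatchingStats:
    """Per-position matching statistics of a query against a subject.

    ``l[i]`` is the length of the longest substring of the query
    starting at (0-based) position ``i`` that occurs anywhere in the
    subject; 0 if the query character at ``i`` is absent from it.
    """

    query_id: str
    subject_id: str
    l: np.ndarray = field(repr=False)
    n: int
    m: int

    @property
    def mean(self) -> float:
        return float(np.mean(self.l))

    @property
    def max(self) -> int:
        return int(np.max(self.l))


@dataclass(frozen=True)
class ShustringStats:
    """Shortest-unique-substring lengths: ``sl[i] = l[i] + 1``.

    When every prefix of the suffix starting at ``i`` occurs in the
    subject, the sentinel value ``(n - i) + 1`` (one past the suffix
    length) is produced automatically by the ``l + 1`` identity.
    """

    query_id: str
    subject_id: str
    sl: np.ndarray = field(repr=False)
    witnesses: tuple = field(repr=False)
    n: int
    m: int

    @property
    def mean(self) -> float:
        return float(np.mean(self.sl))


def _match_lengths_starting(automaton_rev: SuffixAutomaton, query: str) -> np.ndarray:
    # longest match starting at i == longest match ending at the mirrored
    # position of the reversed strings
    return automaton_rev.match_lengths_ending(query[::-1])[::-1].copy()


def _automaton_for(record: SequenceRecord) -> SuffixAutomaton:
    return SuffixAutomaton(record.seq[::-1])


def matching_statistics(x: SequenceRecord, y: SequenceRecord,
                        _automaton_rev: SuffixAutomaton | None = None) -> MatchingStats:
    """Matching statistics of ``x`` against ``y`` (directed)."""
    if len(x.seq) < 1 or len(y.seq) < 1:
        raise ValueError("sequences must be non-empty")
    auto = _automaton_rev if _automaton_rev is not None else _automaton_for(y)
    l = _match_lengths_starting(auto, x.seq)
    return MatchingStats(x.id, y.id, l, n=len(x.seq), m=len(y.seq))


def shustring_stats(x: SequenceRecord, y: SequenceRecord) -> ShustringStats:
    """Shortest substrings of ``x`` starting at each position absent from ``y``."""
    ms = matching_statistics(x, y)
    sl = ms.l + 1
    witnesses = tuple(x.seq[i : i + int(sl[i])] for i in range(len(x.seq)))
    return ShustringStats(x.id, y.id, sl, witnesses, n=ms.n, m=ms.m)


# ---------------------------------------------------------------------------
# ACS
# ---------------------------------------------------------------------------

def _acs_directed(mean_l: float, n: int, m: int) -> float:
    if mean_l == 0.0:
        logger.warning("no common substrings; capping L at 1/(2n)")
        mean_l = 1.0 / (2.0 * n)
    # self-average of matching statistics: mean of (n, n-1, ..., 1)
    self_l = (n + 1) / 2.0
    return math.log(m) / mean_l - math.log(n) / self_l


def acs_distance(x: SequenceRecord, y: SequenceRecord) -> float:
    """Symmetrized average-common-substring distance.

    ``d(X->Y) = ln(m)/L(X,Y) - ln(n)/L(X,X)`` with ``L`` the mean matching
    statistic; the self term makes the distance exactly 0 on identical
    sequences.  Tiny numeric negatives are clamped to 0.
    """
    if len(x.seq) < 2 or len(y.seq) < 2:
        raise ValueError("ACS requires sequences of length >= 2")
    dxy = _acs_directed(matching_statistics(x, y).mean, len(x.seq), len(y.seq))
    dyx = _acs_directed(matching_statistics(y, x).mean, len(y.seq), len(x.seq))
    d = 0.5 * (dxy + dyx)
    if d < -1e-9:
        raise AssertionError(f"ACS distance unexpectedly negative: {d}")
    return max(d, 0.0)


# ---------------------------------------------------------------------------
# Kr
# ---------------------------------------------------------------------------

def _kr_directed_pi(mean_sl: float, n: int) -> float:
    # self baseline: shustrings against an identical sequence are all
    # sentinels, mean of (n+1, n, ..., 2) = (n+3)/2
    self_sl = (n + 3) / 2.0
    return max(0.0, 1.0 / mean_sl - 1.0 / self_sl)


def kr_distance(x: SequenceRecord, y: SequenceRecord) -> float:
    """Shustring-based evolutionary distance with Jukes-Cantor correction.

    Directed mismatch estimates ``pi = 1/mean(sl(X,Y)) - 1/mean(sl(X,X))``
    are symmetrized, capped at ``KR_PI_CAP`` and transformed by
    ``-(3/4) ln(1 - (4/3) pi)``.  Exactly 0 on identical sequences.
    """
    if len(x.seq) < 2 or len(y.seq) < 2:
        raise ValueError("Kr requires sequences of length >= 2")
    pxy = _kr_directed_pi(float(np.mean(matching_statistics(x, y).l + 1)), len(x.seq))
    pyx = _kr_directed_pi(float(np.mean(matching_statistics(y, x).l + 1)), len(y.seq))
    pi = 0.5 * (pxy + pyx)
    if pi > KR_PI_CAP:
        logger.warning("Kr mismatch estimate %.3f capped at %.2f", pi, KR_PI_CAP)
        pi = KR_PI_CAP
    return -0.75 * math.log1p(-(4.0 / 3.0) * pi)


# ---------------------------------------------------------------------------
# CVTree
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CompositionVector:
    """Sparse vector of background-corrected k-word components.

    ``a(w) = (p(w) - p0(w)) / p0(w)`` where ``p0`` is the (k-1)-order
    Markov prediction; components that are exactly 0 (or whose
    prediction is 0) are omitted from ``components``.
    """

    id: str
    k: int
    components: dict = field(repr=False)

    def a(self, word: str) -> float:
        return self.components.get(word, 0.0)

    @property
    def norm(self) -> float:
        return math.sqrt(sum(v * v for v in self.components.values()))


def _word_probs(seq: str, klen: int) -> dict:
    counts: dict = {}
    total = 0
    for i in range(len(seq) - klen + 1):
        w = seq[i : i + klen]
        if "N" in w:
            continue
        counts[w] = counts.get(w, 0) + 1
        total += 1
    if total == 0:
        return {}
    inv = 1.0 / total
    return {w: c * inv for w, c in counts.items()}


def composition_vector(x: SequenceRecord, k: int = 6) -> CompositionVector:
    """Markov-background-corrected composition vector of word length ``k``."""
    if k < 3:
        raise ValueError("composition vectors require k >= 3")
    if len(x.seq) < k:
        raise ValueError(f"sequence {x.id!r} shorter than k={k}")
    pk = _word_probs(x.seq, k)
    pk1 = _word_probs(x.seq, k - 1)
    pk2 = _word_probs(x.seq, k - 2)
    comps = {}
    for w, p in pk.items():
        denom = pk2.get(w[1:-1], 0.0)
        if denom == 0.0:
            continue
        p0 = pk1.get(w[:-1], 0.0) * pk1.get(w[1:], 0.0) / denom
        if p0 <= 0.0:
            continue
        a = (p - p0) / p0
        if a != 0.0:
            comps[w] = a
    return CompositionVector(x.id, k, comps)


def cvtree_distance(u: CompositionVector, v: CompositionVector) -> float:
    """Cosine dissimilarity ``(1 - C)/2`` between two composition vectors."""
    if u.k != v.k:
        raise ValueError(f"mismatched word lengths: {u.k} vs {v.k}")
    nu, nv = u.norm, v.norm
    if nu == 0.0 or nv == 0.0:
        return 0.5  # convention: an all-zero vector is uninformative
    # iterate in sorted word order so the sum is bit-identical regardless
    # of argument order
    common = sorted(u.components.keys() & v.components.keys())
    dot = sum(u.components[w] * v.components[w] for w in common)
    c = dot / (nu * nv)
    return min(1.0, max(0.0, (1.0 - c) / 2.0))


# ---------------------------------------------------------------------------
# Matrix drivers
# ---------------------------------------------------------------------------

def _mean_match_matrix(records, automata, query_seqs=None) -> np.ndarray:
    """M[i, j] = mean matching statistic of sequence i against sequence j."""
    n = len(records)
    queries = [r.seq[::-1] for r in records] if query_seqs is None else [s[::-1] for s in query_seqs]
    M = np.zeros((n, n))
    for j in range(n):
        auto = automata[j]
        for i in range(n):
            if i == j and query_seqs is None:
                M[i, j] = (len(records[i].seq) + 1) / 2.0
            else:
                M[i, j] = float(np.mean(auto.match_lengths_ending(queries[i])))
    return M


def _acs_from_means(M: np.ndarray, lengths: np.ndarray) -> np.ndarray:
    n = len(lengths)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            dxy = _acs_directed(M[i, j], lengths[i], lengths[j])
            dyx = _acs_directed(M[j, i], lengths[j], lengths[i])
            D[i, j] = D[j, i] = max(0.5 * (dxy + dyx), 0.0)
    return D


def _kr_from_means(M: np.ndarray, lengths: np.ndarray) -> np.ndarray:
    n = len(lengths)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            pxy = _kr_directed_pi(M[i, j] + 1.0, lengths[i])
            pyx = _kr_directed_pi(M[j, i] + 1.0, lengths[j])
            pi = min(0.5 * (pxy + pyx), KR_PI_CAP)
            D[i, j] = D[j, i] = -0.75 * math.log1p(-(4.0 / 3.0) * pi)
    return D


def distance_matrices(seqs: SequenceSet, methods=("acs", "cv", "kr"), k: int = 6) -> dict:
    """Compute several distance matrices, sharing the substring engine.

    ACS and Kr both consume the matrix of mean matching statistics, so
    the (dominant) suffix-automaton scans are performed once.
    """
    methods = tuple(methods)
    unknown = set(methods) - {"acs", "cv", "kr"}
    if unknown:
        raise ValueError(f"unknown methods {sorted(unknown)}")
    if len(seqs) < 3:
        raise ValueError("need at least 3 sequences for a distance matrix")
    labels = seqs.ids
    lengths = np.array([len(r.seq) for r in seqs])
    out = {}
    if "acs" in methods or "kr" in methods:
        automata = [_automaton_for(r) for r in seqs]
        M = _mean_match_matrix(seqs.records, automata)
        if "acs" in methods:
            out["acs"] = DistanceMatrix(_acs_from_means(M, lengths), labels)
        if "kr" in methods:
            out["kr"] = DistanceMatrix(_kr_from_means(M, lengths), labels)
    if "cv" in methods:
        cvs = [composition_vector(r, k) for r in seqs]
        n = len(cvs)
        D = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                D[i, j] = D[j, i] = cvtree_distance(cvs[i], cvs[j])
        out["cv"] = DistanceMatrix(D, labels)
    return out


def distance_matrix(seqs: SequenceSet, method: str, k: int = 6, rc: bool = False) -> DistanceMatrix:
    """Pairwise distance matrix under one method (``acs``, ``cv`` or ``kr``).

    With ``rc=True`` the distance of each pair is the minimum over the
    two orientations of the second sequence (off by default: 16S
    amplicons are same-strand).
    """
    if not rc:
        return distance_matrices(seqs, (method,), k=k)[method]
    if method == "cv":
        cvs = [composition_vector(r, k) for r in seqs]
        rcs = [composition_vector(SequenceRecord(r.id + "_rc", reverse_complement(r.seq)), k) for r in seqs]
        n = len(cvs)
        D = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                D[i, j] = D[j, i] = min(cvtree_distance(cvs[i], cvs[j]),
                                        cvtree_distance(cvs[i], rcs[j]))
        return DistanceMatrix(D, seqs.ids)
    fn = acs_distance if method == "acs" else kr_distance
    if method not in ("acs", "kr"):
        raise ValueError(f"unknown method {method!r}")
    n = len(seqs)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            y = seqs.records[j]
            yrc = SequenceRecord(y.id + "_rc", reverse_complement(y.seq))
            D[i, j] = D[j, i] = min(fn(seqs.records[i], y), fn(seqs.records[i], yrc))
    return DistanceMatrix(D, seqs.ids)
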