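import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from aftree.afdist import (
    acs_distance,
    composition_vector,
    cvtree_distance,
    distance_matrices,
    distance_matrix,
    kr_distance,
    matching_statistics,
    shustring_stats,
)
from aftree.io_formats import SequenceRecord, SequenceSet

from oracles import brute_matching_stats, random_sequence

dna = st.text(alphabet="ACGTN", min_size=1, max_size=60)


class TestMatchingStatistics:
    def test_worked_example(self, toy_pair):
        x, y = toy_pair
        ms = matching_statistics(x, y)
        assert list(ms.l) == [1, 3, 2, 1, 0]
        assert ms.max == 3

    def test_self_statistics(self):
        r = SequenceRecord("a", "AAA")
        assert list(matching_statistics(r, r).l) == [3, 2, 1]

    def test_disjoint_alphabets(self):
        x, y = SequenceRecord("a", "ACG"), SequenceRecord("b", "TTT")
        assert list(matching_statistics(x, y).l) == [0, 0, 0]

    def test_n_never_matches(self):
        x, y = SequenceRecord("a", "ANA"), SequenceRecord("b", "ANA")
        assert list(matching_statistics(x, y).l) == [1, 0, 1]

    @settings(max_examples=100, deadline=None)
    @given(dna, dna)
    def test_matches_brute_force(self, x, y):
        got = matching_statistics(SequenceRecord("a", x), SequenceRecord("b", y)).l
        np.testing.assert_array_equal(got, brute_matching_stats(x, y))

    @settings(max_examples=50, deadline=None)
    @given(dna, dna)
    def test_suffix_extension_property(self, x, y):
        l = matching_statistics(SequenceRecord("a", x), SequenceRecord("b", y)).l
        n = len(x)
        assert all(0 <= l[i] <= n - i for i in range(n))
        assert all(l[i + 1] >= l[i] - 1 for i in range(n - 1))


class TestShustrings:
    def test_worked_example(self, kr_pair):
        x, y = kr_pair
        ss = shustring_stats(x, y)
        assert ss.witnesses[0] == "TCT"
        assert list(ss.sl) == [3, 2, 2, 2, 1]

    def test_all_sentinels_on_self(self):
        r = SequenceRecord("a", "ACGT")
        assert list(shustring_stats(r, r).sl) == [5, 4, 3, 2]

    def test_single_absent_letter(self):
        assert list(shustring_stats(SequenceRecord("a", "A"), SequenceRecord("b", "C")).sl) == [1]

    @settings(max_examples=50, deadline=None)
    @given(dna, dna)
    def test_sl_is_l_plus_one(self, x, y):
        xr, yr = SequenceRecord("a", x), SequenceRecord("b", y)
        np.testing.assert_array_equal(
            shustring_stats(xr, yr).sl, matching_statistics(xr, yr).l + 1
        )


class TestAcs:
    def test_identical_is_zero(self):
        r = SequenceRecord("a", "ACGTTGCA")
        assert acs_distance(r, r) == 0.0

    def test_worked_example_value(self, toy_pair):
        x, y = toy_pair
        # ln(5)/1.4 - ln(5)/3 averaged with ln(5)/1.6 - ln(5)/3
        expected = 0.5 * ((math.log(5) / 1.4 - math.log(5) / 3)
                          + (math.log(5) / 1.6 - math.log(5) / 3))
        assert acs_distance(x, y) == pytest.approx(expected)
        assert acs_distance(x, y) == pytest.approx(0.541, abs=5e-4)

    def test_symmetry(self, rng):
        for _ in range(100):
            x = SequenceRecord("a", random_sequence(rng, int(rng.integers(2, 40))))
            y = SequenceRecord("b", random_sequence(rng, int(rng.integers(2, 40))))
            assert acs_distance(x, y) == acs_distance(y, x) >= 0.0


class TestKr:
    def test_identical_is_zero(self):
        r = SequenceRecord("a", "ACGTTGCA")
        assert kr_distance(r, r) == 0.0

    def test_worked_example_value(self, kr_pair):
        x, y = kr_pair
        # sl(X,Y) = [3,2,2,2,1] mean 2; self baseline (5+3)/2 = 4
        # sl(Y,X) = [3,2,2,2,2] mean 2.2
        pi = 0.5 * ((1 / 2.0 - 1 / 4.0) + (1 / 2.2 - 1 / 4.0))
        expected = -0.75 * math.log(1 - 4 * pi / 3)
        assert kr_distance(x, y) == pytest.approx(expected)
        assert kr_distance(x, y) > 0.0

    def test_symmetry(self, rng):
        for _ in range(50):
            x = SequenceRecord("a", random_sequence(rng, int(rng.integers(2, 40))))
            y = SequenceRecord("b", random_sequence(rng, int(rng.integers(2, 40))))
            assert kr_distance(x, y) == kr_distance(y, x) >= 0.0


class TestCompositionVector:
    def test_homopolymer_is_perfectly_predicted(self):
        cv = composition_vector(SequenceRecord("a", "AAAA"), k=3)
        assert cv.a("AAA") == 0.0

    def test_components_match_direct_counts(self):
        seq = "ACGTACGT"
        cv = composition_vector(SequenceRecord("a", seq), k=3)

        def probs(klen):
            words = [seq[i:i + klen] for i in range(len(seq) - klen + 1)]
            return {w: words.count(w) / len(words) for w in set(words)}

        p3, p2, p1 = probs(3), probs(2), probs(1)
        for w, a in cv.components.items():
            p0 = p2[w[:2]] * p2[w[1:]] / p1[w[1]]
            assert a == pytest.approx((p3[w] - p0) / p0)

    def test_probabilities_normalize(self, rng):
        seq = random_sequence(rng, 100)
        from aftree.afdist import _word_probs
        assert sum(_word_probs(seq, 4).values()) == pytest.approx(1.0)

    def test_too_short_errors(self):
        with pytest.raises(ValueError):
            composition_vector(SequenceRecord("a", "AC"), k=3)
        with pytest.raises(ValueError):
            composition_vector(SequenceRecord("a", "ACGTACGT"), k=2)

    def test_n_windows_skipped(self):
        cv1 = composition_vector(SequenceRecord("a", "ACGTNACGT"), k=3)
        assert all("N" not in w for w in cv1.components)


class TestCvtreeDistance:
    def test_identical_nonzero_vector(self, rng):
        u = composition_vector(SequenceRecord("a", random_sequence(rng, 50)), k=3)
        assert cvtree_distance(u, u) == pytest.approx(0.0, abs=1e-12)

    def test_disjoint_supports(self):
        from aftree.afdist import CompositionVector
        u = CompositionVector("u", 3, {"AAA": 1.0})
        v = CompositionVector("v", 3, {"CCC": 1.0})
        assert cvtree_distance(u, v) == 0.5

    def test_opposite_vectors(self):
        from aftree.afdist import CompositionVector
        u = CompositionVector("u", 3, {"AAA": 1.0, "CCC": -2.0})
        v = CompositionVector("v", 3, {"AAA": -1.0, "CCC": 2.0})
        assert cvtree_distance(u, v) == pytest.approx(1.0)

    def test_all_zero_convention(self):
        from aftree.afdist import CompositionVector
        u = CompositionVector("u", 3, {})
        v = CompositionVector("v", 3, {"AAA": 1.0})
        assert cvtree_distance(u, v) == 0.5

    def test_mismatched_k_errors(self):
        from aftree.afdist import CompositionVector
        with pytest.raises(ValueError):
            cvtree_distance(CompositionVector("u", 3, {}), CompositionVector("v", 4, {}))


class TestDistanceMatrix:
    def _seqs(self, rng, n=5, length=30):
        return SequenceSet(
            [SequenceRecord(f"s{i}", random_sequence(rng, length)) for i in range(n)]
        )

    def test_identical_sequences_zero_matrix(self):
        seqs = SequenceSet([SequenceRecord(f"s{i}", "ACGTACGTAC") for i in range(3)])
        for method in ("acs", "cv", "kr"):
            dm = distance_matrix(seqs, method, k=3)
            np.testing.assert_allclose(dm.values, 0.0, atol=1e-12)

    def test_entries_match_per_pair_ops(self, rng):
        seqs = self._seqs(rng)
        dm_acs = distance_matrix(seqs, "acs")
        dm_kr = distance_matrix(seqs, "kr")
        dm_cv = distance_matrix(seqs, "cv", k=3)
        cvs = {r.id: composition_vector(r, 3) for r in seqs}
        for i, a in enumerate(seqs):
            for b in seqs.records[i + 1:]:
                assert dm_acs.between(a.id, b.id) == pytest.approx(acs_distance(a, b))
                assert dm_kr.between(a.id, b.id) == pytest.approx(kr_distance(a, b))
                assert dm_cv.between(a.id, b.id) == pytest.approx(
                    cvtree_distance(cvs[a.id], cvs[b.id]))

    def test_label_equivariance(self, rng):
        seqs = self._seqs(rng)
        perm = SequenceSet(seqs.records[::-1])
        dm = distance_matrix(seqs, "acs")
        dmp = distance_matrix(perm, "acs")
        np.testing.assert_allclose(dmp.reorder(dm.labels).values, dm.values, atol=1e-12)

    def test_shared_engine_agrees_with_single(self, rng):
        seqs = self._seqs(rng)
        both = distance_matrices(seqs, ("acs", "kr"))
        np.testing.assert_allclose(both["acs"].values, distance_matrix(seqs, "acs").values)
        np.testing.assert_allclose(both["kr"].values, distance_matrix(seqs, "kr").values)

    def test_too_few_sequences(self):
        seqs = SequenceSet([SequenceRecord("a", "ACGT"), SequenceRecord("b", "ACGT")])
        with pytest.raises(ValueError):
            distance_matrix(seqs, "acs")

    def test_rc_flag_symmetric(self, rng):
        seqs = self._seqs(rng, n=4)
        for method in ("acs", "kr", "cv"):
            dm = distance_matrix(seqs, method, k=3, rc=True)
            np.testing.assert_allclose(dm.values, dm.values.T)
            assert np.all(dm.values <= distance_matrix(seqs, method, k=3).values + 1e-12)


class TestJc69Monotonicity:
    def test_all_three_distances_increase_with_divergence(self):
        # JC69 pairs from a common ancestor over a divergence grid
        from scipy.stats import spearmanr
        from aftree.simulate import evolve_sequences
        from aftree.io_formats import read_newick

        divergences = np.linspace(0.01, 0.3, 20)
        vals = {"acs": [], "kr": [], "cv": []}
        for i, d in enumerate(divergences):
            t = read_newick(f"(a:{d / 2},b:{d / 2});")
            seqs = evolve_sequences(t, 2000, 1.0, seed=1000 + i)
            a, b = seqs["a"], seqs["b"]
            vals["acs"].append(acs_distance(a, b))
            vals["kr"].append(kr_distance(a, b))
            vals["cv"].append(cvtree_distance(composition_vector(a, 6), composition_vector(b, 6)))
        for method, v in vals.items():
            rho = spearmanr(divergences, v).statistic
            assert rho > 0.9, f"{method}: rho={rho}"
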