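"""Pair-counting, information-theoretic, matching and cover measures."""

import itertools

import numpy as np
import pytest
from sklearn import metrics as skm

from elcsim import (
    Clustering,
    ClusteringError,
    all_measures,
    nmi,
    omega,
    onmi,
    pair_counts,
    pair_measures,
    pm,
    vi,
)
from elcsim.synthetic import equal_partition, shuffle_fraction

from conftest import random_partition


def labels_in_order(c: Clustering) -> np.ndarray:
    cid_index = {cid: k for k, cid in enumerate(c.clusters)}
    order = sorted(c.elements)
    return np.array([cid_index[next(iter(c.memberships[e]))] for e in order])


def enumerate_pair_counts(a: Clustering, b: Clustering):
    """Oracle: classify every unordered pair explicitly."""
    n11 = n10 = n01 = n00 = 0
    for e1, e2 in itertools.combinations(sorted(a.elements), 2):
        in_a = a.memberships[e1] == a.memberships[e2]
        in_b = b.memberships[e1] == b.memberships[e2]
        n11 += in_a and in_b
        n10 += in_a and not in_b
        n01 += in_b and not in_a
        n00 += not in_a and not in_b
    return n11, n10, n01, n00


class TestPairCounts:
    def test_five_element_enumerated_example(self):
        a = Clustering({"1": ["a", "b", "c"], "2": ["d", "e"]})
        b = Clustering({"1": ["a", "b"], "2": ["c", "d", "e"]})
        pc = pair_counts(a, b)
        assert (pc.n11, pc.n10, pc.n01, pc.n00) == (2, 2, 2, 4)
        assert pc.total == 10

    def test_identical_partitions_no_disagreement(self, rng):
        a = random_partition(rng, 20, 4)
        pc = pair_counts(a, a)
        assert pc.n10 == 0 and pc.n01 == 0

    def test_singletons_have_no_co_pairs(self):
        a = Clustering({f"s{i}": [f"e{i}"] for i in range(6)})
        pc = pair_counts(a, a)
        assert pc.n11 == 0 and pc.n00 == 15

    def test_matches_pair_enumeration_oracle(self, rng):
        for _ in range(10):
            a = random_partition(rng, 15, 4)
            b = Clustering(random_partition(rng, 15, 3).clusters, a.elements)
            pc = pair_counts(a, b)
            assert (pc.n11, pc.n10, pc.n01, pc.n00) == enumerate_pair_counts(a, b)

    def test_overlapping_input_rejected(self):
        c = Clustering({"1": ["a", "b"], "2": ["b", "c"]})
        with pytest.raises(ClusteringError):
            pair_counts(c, c)


class TestPairMeasures:
    def test_enumerated_example_values(self):
        a = Clustering({"1": ["a", "b", "c"], "2": ["d", "e"]})
        b = Clustering({"1": ["a", "b"], "2": ["c", "d", "e"]})
        m = pair_measures(pair_counts(a, b))
        assert m["rand"] == pytest.approx(0.6)
        assert m["jaccard"] == pytest.approx(1 / 3)

    def test_identical_partitions_all_maximal(self, rng):
        a = random_partition(rng, 25, 5)
        m = pair_measures(pair_counts(a, a))
        for name in ("rand", "jaccard", "f_measure", "fowlkes_mallows", "ari"):
            assert m[name] == pytest.approx(1.0)

    def test_degenerate_counts_warn_and_return_zero(self):
        singles = Clustering({f"s{i}": [f"e{i}"] for i in range(4)})
        with pytest.warns(UserWarning):
            m = pair_measures(pair_counts(singles, singles))
        assert m["jaccard"] == 0.0

    def test_against_sklearn_on_random_partitions(self, rng):
        for _ in range(20):
            a = random_partition(rng, 40, 5)
            b = Clustering(random_partition(rng, 40, 4).clusters, a.elements)
            la, lb = labels_in_order(a), labels_in_order(b)
            m = pair_measures(pair_counts(a, b))
            assert m["ari"] == pytest.approx(
                skm.adjusted_rand_score(la, lb), abs=1e-12
            )
            assert m["rand"] == pytest.approx(skm.rand_score(la, lb), abs=1e-12)
            assert m["fowlkes_mallows"] == pytest.approx(
                skm.fowlkes_mallows_score(la, lb), abs=1e-12
            )

    def test_ari_near_zero_under_random_relabeling(self, rng):
        # Monte-Carlo oracle for the permutation-model null expectation
        base = equal_partition(60, 4)
        vals = []
        for _ in range(1000):
            other = shuffle_fraction(base, 1.0, rng)
            vals.append(pair_measures(pair_counts(base, other))["ari"])
        vals = np.array(vals)
        se = vals.std(ddof=1) / np.sqrt(len(vals))
        assert abs(vals.mean()) < 3 * se + 1e-3


class TestInformationMeasures:
    def test_identical_partitions(self, rng):
        a = random_partition(rng, 30, 5)
        assert nmi(a, a) == pytest.approx(1.0)
        assert vi(a, a) == pytest.approx(0.0, abs=1e-12)

    def test_against_sklearn_nmi(self, rng):
        for _ in range(20):
            a = random_partition(rng, 40, 6)
            b = Clustering(random_partition(rng, 40, 3).clusters, a.elements)
            la, lb = labels_in_order(a), labels_in_order(b)
            assert nmi(a, b) == pytest.approx(
                skm.normalized_mutual_info_score(la, lb, average_method="arithmetic"),
                abs=1e-10,
            )

    def test_normalization_variants_ordered(self, rng):
        a = random_partition(rng, 40, 6)
        b = Clustering(random_partition(rng, 40, 3).clusters, a.elements)
        # max-normalization is the most conservative
        assert nmi(a, b, "max") <= nmi(a, b, "sqrt") + 1e-12
        with pytest.raises(ClusteringError):
            nmi(a, b, "bogus")

    def test_single_cluster_vs_itself(self):
        c = Clustering({"all": ["a", "b", "c"]})
        assert nmi(c, c) == 1.0

    def test_vi_triangle_inequality(self, rng):
        for _ in range(15):
            a = random_partition(rng, 20, 4)
            b = Clustering(random_partition(rng, 20, 3).clusters, a.elements)
            c = Clustering(random_partition(rng, 20, 5).clusters, a.elements)
            assert vi(a, c) <= vi(a, b) + vi(b, c) + 1e-12


class TestPercentageMatching:
    def test_identical_partitions(self, rng):
        a = random_partition(rng, 20, 4)
        assert pm(a, a) == pytest.approx(1.0)

    def test_two_cluster_swap_hand_value(self):
        # K=2, N=10, swap one element between the clusters: 8/10 matched
        a = Clustering({"1": list("abcde"), "2": list("fghij")})
        b = Clustering({"1": list("fbcde"), "2": list("aghij")})
        assert pm(a, b) == pytest.approx(0.8)

    def test_optimal_assignment_beats_or_ties_greedy(self, rng):
        for _ in range(10):
            a = random_partition(rng, 30, 5)
            b = Clustering(random_partition(rng, 30, 4).clusters, a.elements)
            assert pm(a, b) >= pm(a, b, greedy=True) - 1e-12

    def test_exhaustive_matching_oracle(self, rng):
        from elcsim.classic import contingency_table

        for _ in range(10):
            a = random_partition(rng, 12, 3)
            b = Clustering(random_partition(rng, 12, 3).clusters, a.elements)
            ct = contingency_table(a, b)
            k_a, k_b = ct.counts.shape
            best = 0.0
            if k_a <= k_b:
                for chosen in itertools.permutations(range(k_b), k_a):
                    best = max(
                        best, sum(ct.counts[i, c] for i, c in enumerate(chosen))
                    )
            else:
                for chosen in itertools.permutations(range(k_a), k_b):
                    best = max(
                        best, sum(ct.counts[r, j] for j, r in enumerate(chosen))
                    )
            assert pm(a, b) == pytest.approx(best / 12)


class TestOnmi:
    def test_identical_covers(self):
        c = Clustering({"1": ["a", "b", "c"], "2": ["c", "d"]})
        assert onmi(c, c) == pytest.approx(1.0)

    def test_identical_partitions(self, rng):
        a = random_partition(rng, 20, 4)
        assert onmi(a, a) == pytest.approx(1.0)

    def test_half_shuffle_more_conservative_than_nmi(self, rng):
        base = equal_partition(1024, 32)
        shuffled = shuffle_fraction(base, 0.5, rng)
        assert onmi(base, shuffled) < nmi(base, shuffled)

    def test_bounded(self, rng):
        from conftest import random_overlapping

        for _ in range(8):
            a = random_overlapping(rng, 20, 4)
            b = Clustering(
                random_overlapping(rng, 20, 3).clusters, a.elements
            )
            assert 0.0 <= onmi(a, b) <= 1.0


class TestOmega:
    def test_identical_covers(self):
        c = Clustering({"1": ["a", "b", "c"], "2": ["c", "d"]})
        assert omega(c, c) == pytest.approx(1.0)

    def test_equals_ari_on_partitions(self, rng):
        for _ in range(100):
            n = int(rng.integers(8, 40))
            a = random_partition(rng, n, int(rng.integers(2, 6)))
            b = Clustering(
                random_partition(rng, n, int(rng.integers(2, 6))).clusters,
                a.elements,
            )
            ari = pair_measures(pair_counts(a, b))["ari"]
            assert omega(a, b) == pytest.approx(ari, abs=1e-12)

    def test_overlap_pair_not_co_occurring(self):
        # elements sharing zero clusters have shared-count 0 even though
        # each shares a cluster with a common neighbour
        a = Clustering({"y": ["4", "5", "6"], "g": ["6", "7", "8"]})
        from elcsim.classic import _binary_membership

        m = _binary_membership(a)
        t = m @ m.T
        i4 = a.elements.index("4")
        i7 = a.elements.index("7")
        assert t[i4, i7] == 0


class TestRandGraphEditIdentity:
    def test_rand_from_edge_set_symmetric_difference(self, rng):
        # Rand = 1 - GED(unweighted element graphs) / C(N,2)
        def offdiag_edges(c: Clustering) -> set[frozenset]:
            edges = set()
            for members in c.clusters.values():
                for e1, e2 in itertools.combinations(sorted(members), 2):
                    edges.add(frozenset((e1, e2)))
            return edges

        for _ in range(20):
            n = 18
            a = random_partition(rng, n, 4)
            b = Clustering(random_partition(rng, n, 3).clusters, a.elements)
            ged = len(offdiag_edges(a) ^ offdiag_edges(b))
            rand = pair_measures(pair_counts(a, b))["rand"]
            assert rand == pytest.approx(1 - ged / (n * (n - 1) / 2), abs=1e-12)


def test_registry_measures_are_maximal_on_identical_inputs(rng):
    a = random_partition(rng, 24, 4)
    expectations = {"vi": 0.0}
    for name, fn in all_measures().items():
        assert fn(a, a) == pytest.approx(expectations.get(name, 1.0), abs=1e-9)
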