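import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy.cluster import hierarchy

from loopmix import (AnnotationMap, enrich_terms, fisher_exact,
                     hypergeom_overlap, kmeans_clusters, kruskal_wallis,
                     map_to_ancestors, pca_partition, proportion_test,
                     qpcr_relative, venn_counts, ward_tree)
from loopmix.synthetic import generate_factor_matrix


def hypergeom_tail_oracle(N, K, n, k):
    """P(X >= k) by exact integer enumeration of the hypergeometric pmf."""
    total = math.comb(N, n)
    acc = 0
    for j in range(k, min(K, n) + 1):
        acc += math.comb(K, j) * math.comb(N - K, n - j)
    return acc / total


def fisher_oracle(table):
    """Two-sided Fisher p by summing tables as or less probable."""
    (a, b), (c, d) = table
    r1, r2, c1 = a + b, c + d, a + c
    N = r1 + r2
    def prob(x):
        return (math.comb(r1, x) * math.comb(r2, c1 - x)
                / math.comb(N, c1))
    p_obs = prob(a)
    lo = max(0, c1 - r2)
    hi = min(r1, c1)
    return sum(prob(x) for x in range(lo, hi + 1)
               if prob(x) <= p_obs * (1 + 1e-9))


class TestPCAPartition:
    def test_single_factor_limit(self, rng):
        X, labels, _ = generate_factor_matrix(sd_env=3.0, sd_rank=0.0,
                                              sd_noise=0.01, seed=0)
        part = pca_partition(X, labels, ["environment", "rank"])
        assert part.variance_percent[0] >= 99.0
        assert part.factor_assignment[0] == "environment"

    def test_sample_permutation_leaves_percentages(self, rng):
        X, labels, _ = generate_factor_matrix(seed=3)
        part = pca_partition(X, labels, ["environment", "rank"])
        perm = rng.permutation(len(X))
        part2 = pca_partition(X.iloc[perm], labels.iloc[perm],
                              ["environment", "rank"])
        assert part.variance_percent == pytest.approx(
            part2.variance_percent, abs=1e-8)

    def test_scores_orthogonal(self):
        X, labels, _ = generate_factor_matrix(seed=4)
        part = pca_partition(X, labels, ["environment"])
        G = part.scores.T @ part.scores
        off = G - np.diag(np.diag(G))
        assert np.abs(off).max() < 1e-6

    def test_underpopulated_level_rejected(self):
        X, labels, _ = generate_factor_matrix(seed=1)
        labels = labels.copy()
        labels.iloc[0, 0] = "oddball"
        with pytest.raises(ValueError, match="fewer than 2"):
            pca_partition(X, labels, ["environment"])


class TestClustering:
    def test_planted_two_block_recovery(self, rng):
        from sklearn.metrics import adjusted_rand_score
        up = np.tile([1.0, 1.0, -1.0, -1.0], (30, 6 // 2 * 1)).reshape(30, -1)
        up = np.repeat([[1.0] * 6 + [-1.0] * 6], 30, axis=0)
        down = -up
        X = np.vstack([up, down]) + rng.normal(0, 0.05, (60, 12))
        labels, _ = kmeans_clusters(X, k=2, seed=0)
        truth = [0] * 30 + [1] * 30
        assert adjusted_rand_score(truth, labels) == 1.0

    def test_identical_rows_collapse_to_one_cluster(self):
        X = np.ones((10, 6))
        labels, inertia = kmeans_clusters(X, k=2, seed=0)
        assert len(set(labels)) == 1
        assert inertia == 0.0

    def test_same_seed_reproduces(self, rng):
        X = rng.normal(size=(40, 8))
        a, _ = kmeans_clusters(X, k=3, seed=7)
        b, _ = kmeans_clusters(X, k=3, seed=7)
        assert (a == b).all()

    def test_k_larger_than_rows_rejected(self):
        with pytest.raises(ValueError):
            kmeans_clusters(np.ones((3, 2)), k=5, seed=0)

    def test_ward_duplicate_rows_merge_first(self, rng):
        X = rng.normal(size=(5, 4))
        X[3] = X[1]
        Z = ward_tree(X)
        assert {int(Z[0, 0]), int(Z[0, 1])} == {1, 3}
        assert Z[0, 2] == pytest.approx(0.0)

    def test_ward_three_point_merge_order_matches_criterion(self):
        # colinear points at 0, 1, 5: the 0-1 pair merges first, and the
        # second height follows the Ward (ESS increase) formula
        X = np.array([[0.0], [1.0], [5.0]])
        Z = ward_tree(X)
        assert {int(Z[0, 0]), int(Z[0, 1])} == {0, 1}
        # brute-force Ward distance between {0,1} and {5}:
        # sqrt(2*n1*n2/(n1+n2)) * ||centroid diff|| with scipy's scaling
        d = np.sqrt(2 * 2 * 1 / 3) * abs(0.5 - 5.0)
        assert Z[1, 2] == pytest.approx(d)

    def test_ward_heights_invariant_to_row_permutation(self, rng):
        X = rng.normal(size=(12, 5))
        h1 = np.sort(ward_tree(X)[:, 2])
        h2 = np.sort(ward_tree(X[rng.permutation(12)])[:, 2])
        assert h1 == pytest.approx(h2)

    def test_ward_rejects_nan(self):
        X = np.ones((3, 2))
        X[0, 0] = np.nan
        with pytest.raises(ValueError):
            ward_tree(X)


class TestVennCounts:
    def test_two_set_example(self):
        counts = venn_counts({1, 2, 3}, {2, 3, 4})
        assert counts[("A",)] == 1
        assert counts[("B",)] == 1
        assert counts[("A", "B")] == 2

    def test_disjoint_sets(self):
        counts = venn_counts({1}, {2})
        assert counts[("A", "B")] == 0

    def test_three_set_random_matches_enumeration(self, rng):
        for _ in range(20):
            sets = [set(rng.integers(0, 30, size=rng.integers(0, 20)))
                    for _ in range(3)]
            counts = venn_counts(*sets)
            assert sum(counts.values()) == len(set().union(*sets))
            for element in set().union(*sets):
                member = tuple(lab for lab, s in zip("ABC", sets)
                               if element in s)
                assert element in set().union(*sets)
                # each element falls in exactly the region of its membership
                region = set.intersection(*(sets["ABC".index(c)]
                                            for c in member))
                for lab, s in zip("ABC", sets):
                    if lab not in member:
                        region = region - s
                assert element in region


class TestHypergeomOverlap:
    def test_two_of_two_in_universe_four(self):
        res = hypergeom_overlap(2, 2, 2, 4)
        assert res.representation_factor == pytest.approx(2.0)
        assert res.p_value == pytest.approx(1 / 6)

    def test_rf_one_at_independence_expectation(self):
        res = hypergeom_overlap(10, 20, 4, 50)  # 10*20/50 = 4
        assert res.representation_factor == pytest.approx(1.0)

    def test_small_grid_matches_enumeration(self):
        for N in (5, 10, 17, 25):
            for n1 in range(0, N + 1, 3):
                for n2 in range(0, N + 1, 4):
                    for k in range(max(0, n1 + n2 - N), min(n1, n2) + 1, 2):
                        res = hypergeom_overlap(n1, n2, k, N)
                        want = hypergeom_tail_oracle(N, n1, n2, k)
                        assert res.p_value == pytest.approx(want, rel=1e-12,
                                                            abs=1e-300)

    def test_impossible_counts_rejected(self):
        with pytest.raises(ValueError):
            hypergeom_overlap(3, 3, 4, 10)
        with pytest.raises(ValueError):
            hypergeom_overlap(8, 8, 0, 10)  # 16 distinct genes in 10


class TestFisherExact:
    def test_strong_diagonal_table(self):
        assert fisher_exact([[1, 9], [9, 1]]) == pytest.approx(0.0011,
                                                               abs=1e-4)

    def test_balanced_table(self):
        assert fisher_exact([[5, 5], [5, 5]]) == pytest.approx(1.0)

    def test_random_tables_match_enumeration(self, rng):
        for _ in range(60):
            table = rng.integers(0, 16, size=(2, 2))
            assert fisher_exact(table) == pytest.approx(
                fisher_oracle(table), rel=1e-9, abs=1e-12)


class TestProportionTest:
    def test_symmetric_counts(self):
        res = proportion_test(10, 10)
        assert res["G"] == pytest.approx(0.0)
        assert res["p_G"] == pytest.approx(1.0)

    def test_published_up_down_split(self):
        # 404 vs 477 regulated transcripts: the equal-split G statistic
        res = proportion_test(404, 477)
        assert res["G"] == pytest.approx(6.0555, abs=1e-3)
        # hand computation: 2 * 36.5^2 / 440.5
        assert res["pearson_chi2"] == pytest.approx(6.0488, abs=1e-3)
        assert res["df"] == 1

    def test_one_sided_zero(self):
        res = proportion_test(0, 20)
        assert res["pearson_chi2"] == pytest.approx(20.0)

    def test_both_zero_rejected(self):
        with pytest.raises(ValueError):
            proportion_test(0, 0)


class TestEnrichment:
    def _map(self, members, universe):
        gene_terms = {}
        for term, genes in members.items():
            for g in genes:
                gene_terms.setdefault(g, set()).add(term)
        return AnnotationMap(gene_terms=gene_terms, slim={},
                             universe=set(universe))

    def test_exact_tail_example(self):
        universe = [f"g{i}" for i in range(20)]
        ann = self._map({"T": universe[:5]}, universe)
        res = enrich_terms(set(universe[:3] + universe[10:12]), ann,
                           universe)
        # N=20, K=5, n=5, k=3 -> 1126/15504
        row = res.table.iloc[0]
        assert row["p"] == pytest.approx(1126 / 15504, rel=1e-12)

    def test_zero_hits_gives_one(self):
        universe = [f"g{i}" for i in range(10)]
        ann = self._map({"T": universe[:3]}, universe)
        res = enrich_terms(set(universe[5:8]), ann, universe)
        assert res.table.iloc[0]["p"] == pytest.approx(1.0)

    def test_ease_shifts_single_hit_to_one(self):
        universe = [f"g{i}" for i in range(10)]
        ann = self._map({"T": universe[:3]}, universe)
        query = {universe[0], universe[5]}
        plain = enrich_terms(query, ann, universe, ease=False)
        eased = enrich_terms(query, ann, universe, ease=True)
        assert plain.table.iloc[0]["p"] < 1.0
        assert eased.table.iloc[0]["p"] == pytest.approx(1.0)

    def test_query_outside_background_rejected(self):
        ann = self._map({"T": ["g1"]}, ["g1", "g2"])
        with pytest.raises(ValueError):
            enrich_terms({"gX"}, ann, {"g1", "g2"})


class TestAncestorMapping:
    def _slim_map(self):
        return AnnotationMap(gene_terms={}, universe=set(),
                             slim={"t1": {"M"}, "t2": {"M", "D"}})

    def test_single_count_rule(self):
        res = map_to_ancestors(["t1", "t2"], self._slim_map())
        assert res.counts == {"M": 2, "D": 1}
        assert res.n_assigned == 2

    def test_unmapped_term_goes_to_unassigned(self):
        res = map_to_ancestors(["t1", "tX"], self._slim_map())
        assert res.n_unassigned == 1

    def test_list_semantics_counts_duplicates(self):
        res = map_to_ancestors(["t1", "t1"], self._slim_map())
        assert res.counts == {"M": 2}


class TestQpcr:
    def test_geometric_mean_normalization(self):
        rel = qpcr_relative([12.0], [[4.0, 9.0]])
        assert rel[0] == pytest.approx(2.0)

    def test_reference_group_scaled_to_one(self):
        rel = qpcr_relative([4.0, 8.0, 6.0, 12.0],
                            [[1.0], [1.0], [1.0], [1.0]],
                            groups=["a", "a", "b", "b"],
                            reference_group="a")
        assert rel[:2].mean() == pytest.approx(1.0)
        assert rel[2:].mean() == pytest.approx(1.5)

    def test_zero_housekeeping_rejected(self):
        with pytest.raises(ValueError):
            qpcr_relative([1.0], [[0.0, 2.0]])

    def test_kruskal_two_separated_groups(self):
        h, p = kruskal_wallis([1, 2, 3], [4, 5, 6])
        assert h == pytest.approx(3.857, abs=1e-3)

    def test_kruskal_identical_groups(self):
        h, p = kruskal_wallis([2, 2, 2], [2, 2, 2])
        assert h == 0.0 and p == 1.0

    def test_kruskal_invariant_under_monotone_transform(self, rng):
        a = rng.normal(size=10)
        b = rng.normal(size=12) + 0.5
        h1, _ = kruskal_wallis(a, b)
        h2, _ = kruskal_wallis(np.exp(a), np.exp(b))
        assert h1 == pytest.approx(h2)
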