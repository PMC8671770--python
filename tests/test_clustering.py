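"""Ward schedule, elbow rule, seeded K-means and diagnostic labeling."""

import numpy as np
import pytest

from edmood.clustering import (
    AgglomerationSchedule,
    ClusterSolution,
    detect_elbow,
    kmeans_partition,
    label_clusters,
    ward_schedule,
)

from conftest import four_blobs, two_blobs


def make_schedule(diffs, n):
    """Schedule whose per-stage merge costs are [first, *diffs-as-jumps]."""
    coeff = np.cumsum(diffs)
    return AgglomerationSchedule(
        coefficients=coeff,
        merged_pairs=np.zeros((len(coeff), 2), dtype=int),
        n_points=n,
    )


class TestWardSchedule:
    def test_three_point_hand_oracle(self):
        # identical pair merges free; full merge costs the total SS about the
        # grand mean (10/3, 10/3): 2*(200/9) + 800/9 = 1200/9
        sch = ward_schedule([(0, 0), (0, 0), (10, 10)])
        assert sch.coefficients[0] == pytest.approx(0.0)
        assert sch.coefficients[1] == pytest.approx(1200 / 9)

    def test_identical_points_all_zero(self):
        sch = ward_schedule([(2, 3)] * 6)
        assert np.allclose(sch.coefficients, 0.0)

    def test_coefficients_nondecreasing_and_conserve_total_ss(self):
        pts = four_blobs(30)
        sch = ward_schedule(pts)
        assert (np.diff(sch.coefficients) >= -1e-9).all()
        total_ss = ((pts - pts.mean(axis=0)) ** 2).sum()
        assert sch.coefficients[-1] == pytest.approx(total_ss, rel=1e-9)

    def test_two_points_rejected(self):
        with pytest.raises(ValueError):
            ward_schedule([(0, 0), (1, 1)])


def test_ward_matches_greedy_exhaustive_oracle():
    """scipy-backed schedule equals a brute-force greedy Ward on 8 points."""
    rng = np.random.default_rng(42)
    pts = rng.normal(size=(8, 2)) * [5, 1]

    def wss(g):
        sub = pts[list(g)]
        return ((sub - sub.mean(axis=0)) ** 2).sum()

    groups = [frozenset([i]) for i in range(8)]
    oracle_coeffs = []
    current = 0.0
    while len(groups) > 1:
        best = None
        for i in range(len(groups)):
            for j in range(i + 1, len(groups)):
                delta = wss(groups[i] | groups[j]) - wss(groups[i]) - wss(groups[j])
                if best is None or delta < best[0]:
                    best = (delta, i, j)
        delta, i, j = best
        merged = groups[i] | groups[j]
        groups = [g for k, g in enumerate(groups) if k not in (i, j)] + [merged]
        current += delta
        oracle_coeffs.append(current)
    sch = ward_schedule(pts)
    assert np.allclose(sch.coefficients, oracle_coeffs, rtol=1e-8)


class TestDetectElbow:
    def test_worked_example_max_jump_at_stage_1788(self):
        """n=1792 with the drastic coefficient jump after stage 1788 -> k=4."""
        rng = np.random.default_rng(0)
        costs = rng.uniform(0.2, 0.8, 1791)
        costs[1788] = 500.0  # jump between coefficients 1788 and 1789
        costs[1789] = 300.0
        costs[1790] = 420.0
        sch = make_schedule(costs, n=1792)
        assert detect_elbow(sch, n=1792) == 4
        assert detect_elbow(sch, n=1792, criterion="absolute") == 4

    def test_two_separated_blobs_give_k_two(self):
        pts = two_blobs(25)
        sch = ward_schedule(pts)
        assert detect_elbow(sch) == 2
        assert detect_elbow(sch, criterion="absolute") == 2

    def test_four_separated_blobs_give_k_four(self):
        sch = ward_schedule(four_blobs(50))
        assert detect_elbow(sch) == 4

    def test_linear_growth_ties_break_to_earliest_window_stage(self):
        sch = make_schedule(np.ones(99), n=100)
        assert detect_elbow(sch, max_k=15) == 15

    def test_invariant_to_point_ordering(self):
        pts = four_blobs(40, seed=9)
        sch = ward_schedule(pts)
        rng = np.random.default_rng(1)
        sch_perm = ward_schedule(pts[rng.permutation(len(pts))])
        assert detect_elbow(sch) == detect_elbow(sch_perm)
        assert np.allclose(sch.coefficients, sch_perm.coefficients)

    def test_too_few_stages_rejected(self):
        with pytest.raises(ValueError):
            detect_elbow(make_schedule([1.0, 2.0], n=3))


class TestKmeans:
    def test_k_one_returns_grand_mean(self):
        pts = four_blobs(10)
        sol = kmeans_partition(pts, 1, seed=0)
        assert np.allclose(sol.centroids[0], pts.mean(axis=0))

    def test_recovers_four_blob_centers(self):
        pts = four_blobs(80, seed=2)
        sol = kmeans_partition(pts, 4, seed=0)
        got = np.sort(sol.centroids[:, 0])
        assert np.allclose(got, [2.0, 7.0, 12.0, 19.0], atol=0.35)

    def test_centroids_are_means_of_assigned_points(self):
        pts = four_blobs(30)
        sol = kmeans_partition(pts, 3, seed=5)
        for c in range(1, 4):
            assert np.allclose(
                sol.centroids[c - 1], pts[sol.assignments == c].mean(axis=0)
            )

    def test_row_permutation_gives_same_partition(self):
        pts = four_blobs(40, seed=6)
        rng = np.random.default_rng(0)
        perm = rng.permutation(len(pts))
        a = kmeans_partition(pts, 4, seed=3)
        b = kmeans_partition(pts[perm], 4, seed=3)
        order_a = np.argsort(a.centroids[:, 0])
        order_b = np.argsort(b.centroids[:, 0])
        assert np.allclose(a.centroids[order_a], b.centroids[order_b], atol=1e-8)

    def test_ward_means_init_matches_plusplus_on_separated_data(self):
        pts = four_blobs(60, seed=8)
        a = kmeans_partition(pts, 4, seed=0, init="plusplus")
        b = kmeans_partition(pts, 4, seed=0, init="ward_means")
        assert np.allclose(
            np.sort(a.centroids[:, 0]), np.sort(b.centroids[:, 0]), atol=1e-8
        )

    def test_k_exceeding_distinct_points_rejected(self):
        with pytest.raises(ValueError):
            kmeans_partition([(0, 0)] * 5 + [(1, 1)] * 5, 3, seed=0)


def make_solution(centroids):
    centroids = np.asarray(centroids, dtype=float)
    k = len(centroids)
    return ClusterSolution(
        k=k,
        assignments=np.arange(1, k + 1),
        centroids=centroids,
        inertia=0.0,
        seed=0,
    )


class TestLabelClusters:
    published = [(1.84, 0.56), (6.61, 1.45), (12.30, 2.42), (18.89, 3.49)]

    def test_published_cluster_means_get_canonical_labels(self):
        sol = label_clusters(make_solution(self.published))
        assert sol.labels == [
            "not_depressed_or_anxious",
            "mixed_depression_anxiety",
            "moderate_depression_anxiety",
            "high_depression_anxiety",
        ]
        assert sol.consistent

    def test_permuted_cluster_indices_label_identically(self):
        sol = label_clusters(make_solution(self.published[::-1]))
        assert sol.labels[0] == "not_depressed_or_anxious"
        assert np.array_equal(sol.assignments, [4, 3, 2, 1])

    def test_all_subclinical_clusters_are_flagged(self):
        sol = label_clusters(make_solution([(1, 0), (3, 1), (5, 1), (8, 2)]))
        assert not sol.consistent
        assert sol.labels == ["cluster_1", "cluster_2", "cluster_3", "cluster_4"]
        assert sol.warnings

    def test_non_four_k_gets_ordinal_labels(self):
        sol = label_clusters(make_solution([(1, 0), (10, 2), (18, 4)]))
        assert sol.labels == ["cluster_1", "cluster_2", "cluster_3"]
        assert sol.warnings
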