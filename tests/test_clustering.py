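"""K-means and fuzzy C-means: examples, invariants, enumeration oracle."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dermseg.clustering import (
    fcm,
    fcm_centers,
    fcm_membership,
    fcm_objective,
    kmeans,
)
from oracles import best_of_pairs_kmeans, exhaustive_two_cluster_optimum


class TestKMeans:
    def test_two_separated_values(self):
        res = kmeans(np.array([0.0, 0.0, 10.0, 10.0]), K=2)
        assert sorted(res.centroids.ravel()) == [0.0, 10.0]
        # points sharing a value share a cluster
        assert res.assignment[0] == res.assignment[1]
        assert res.assignment[2] == res.assignment[3]
        assert res.assignment[0] != res.assignment[2]

    def test_outlier_partition(self):
        """{1,2,3} vs {100} is the optimal 2-partition by enumeration."""
        res = kmeans(np.array([1.0, 2.0, 3.0, 100.0]), K=2)
        assert sorted(res.centroids.ravel()) == [2.0, 100.0]
        assert res.inertia == pytest.approx(exhaustive_two_cluster_optimum([1, 2, 3, 100]))

    def test_true_means_are_a_fixed_point(self):
        X = np.array([0.0, 1.0, 10.0, 11.0])
        init = np.array([[0.5], [10.5]])
        res = kmeans(X, K=2, init_centroids=init)
        assert res.iterations == 1
        assert np.allclose(res.centroids, init)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError, match="exceeds the number of points"):
            kmeans(np.array([1.0, 2.0]), K=3)
        with pytest.raises(ValueError, match="non-empty"):
            kmeans(np.empty((0, 1)), K=1)

    def test_matches_enumeration_optimum_on_small_instances(self, rng):
        """Best-of-restarts from every distinct point pair attains the
        exhaustive-partition optimum of the within-cluster sum of squares."""
        for _ in range(10):
            n = int(rng.integers(4, 9))
            d = int(rng.integers(1, 3))
            X = rng.normal(0, 5, size=(n, d)).round(2)
            assert best_of_pairs_kmeans(X) == pytest.approx(
                exhaustive_two_cluster_optimum(X), abs=1e-9
            )


class TestFCMMembership:
    def test_equidistant_two_centers(self):
        u = fcm_membership(np.array([[5.0]]), np.array([[0.0], [10.0]]), k=2)
        assert np.allclose(u[:, 0], [0.5, 0.5])

    def test_point_on_center_is_crisp(self):
        u = fcm_membership(np.array([[0.0]]), np.array([[0.0], [10.0]]), k=2)
        assert np.allclose(u[:, 0], [1.0, 0.0])

    def test_equidistant_three_centers(self):
        centers = np.array([[1.0, 0.0], [-0.5, np.sqrt(3) / 2], [-0.5, -np.sqrt(3) / 2]])
        u = fcm_membership(np.zeros((1, 2)), centers, k=2)
        assert np.allclose(u[:, 0], 1 / 3)

    def test_membership_decreases_with_distance(self):
        u = fcm_membership(np.array([[1.0], [9.0]]), np.array([[0.0], [10.0]]), k=2)
        assert u[0, 0] > u[1, 0] and u[1, 1] > u[0, 1]

    @settings(deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=2**31 - 1), st.floats(min_value=1.1, max_value=5.0))
    def test_columns_sum_to_one(self, seed, k):
        r = np.random.default_rng(seed)
        X = r.normal(size=(20, 2))
        centers = r.normal(size=(4, 2))
        u = fcm_membership(X, centers, k=k)
        assert np.allclose(u.sum(axis=0), 1.0, atol=1e-9)
        assert (u >= 0).all() and (u <= 1).all()


class TestFCMCenters:
    def test_crisp_memberships_reduce_to_plain_means(self, rng):
        X = rng.normal(size=(10, 2))
        labels = rng.integers(0, 2, size=10)
        labels[:2] = [0, 1]  # both clusters populated
        U = np.stack([(labels == 0).astype(float), (labels == 1).astype(float)])
        centers = fcm_centers(X, U, k=2)
        for j in (0, 1):
            assert np.allclose(centers[j], X[labels == j].mean(axis=0))

    def test_uniform_memberships_collapse_to_global_mean(self, rng):
        X = rng.normal(size=(12, 1))
        U = np.full((3, 12), 1 / 3)
        centers = fcm_centers(X, U, k=1.7)
        assert np.allclose(centers, X.mean())

    def test_identity_case(self):
        centers = fcm_centers(np.array([0.0, 2.0]), np.array([[1.0, 0.0], [0.0, 1.0]]), k=2)
        assert np.allclose(centers.ravel(), [0.0, 2.0])


class TestFCMObjective:
    def test_unit_distances(self):
        e = fcm_objective(np.array([0.0, 2.0]), np.ones((1, 2)), np.array([[1.0]]), k=2)
        assert e == pytest.approx(2.0)

    def test_zero_at_centers(self):
        e = fcm_objective(np.array([0.0, 2.0]), np.array([[1.0, 0.0], [0.0, 1.0]]),
                          np.array([[0.0], [2.0]]), k=2)
        assert e == 0.0

    def test_quadratic_homogeneity(self, rng):
        X = rng.normal(size=(8, 1))
        U = fcm_membership(X, np.array([[-1.0], [1.0]]), k=2)
        c = np.array([[-1.0], [1.0]])
        assert fcm_objective(2 * X, U, 2 * c, k=2) == pytest.approx(
            4 * fcm_objective(X, U, c, k=2)
        )


class TestFCM:
    def test_recovers_separated_blobs(self, rng):
        means = np.array([0.0, 20.0])
        X = np.concatenate([rng.normal(m, 0.5, size=200) for m in means])
        state = fcm(X, C=2, k=2)
        centers = np.sort(state.centers.ravel())
        assert np.abs(centers - means).max() < 0.1
        hard = np.argmax(state.memberships, axis=0)
        truth = (np.arange(400) >= 200).astype(int)
        frac = (hard == truth).mean()
        assert frac in (0.0, 1.0)  # label identity matches up to permutation

    def test_single_cluster_is_global_mean(self, rng):
        X = rng.normal(size=30)
        state = fcm(X, C=1, k=2)
        assert np.allclose(state.centers.ravel(), X.mean())

    def test_objective_monotone_nonincreasing(self, rng):
        X = rng.normal(size=(100, 2))
        state = fcm(X, C=3, k=2)
        diffs = np.diff(state.objective_history)
        assert (diffs <= 1e-9).all()

    def test_deterministic_repeat(self, rng):
        X = rng.normal(size=(50, 1))
        a, b = fcm(X, C=3, k=2), fcm(X, C=3, k=2)
        assert np.array_equal(a.memberships, b.memberships)
        assert np.array_equal(a.centers, b.centers)
        assert a.objective == b.objective

    def test_fuzziness_must_exceed_one(self):
        with pytest.raises(ValueError, match="k must be > 1"):
            fcm(np.arange(5.0), C=2, k=1.0)
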