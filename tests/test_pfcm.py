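"""Pythagorean fuzzy c-means clustering."""

import numpy as np
import pytest
from scipy.spatial.distance import cdist
from sklearn.metrics import adjusted_rand_score

from fuzzymoth import pfcm, pfn as pf
from fuzzymoth.pfcm import _sq_degrees


def two_group_pfn_set(n=60, sep=0.45, seed=1):
    """Crisp features fuzzified into PFNs, two groups ``sep`` apart."""
    rng = np.random.default_rng(seed)
    labels = np.repeat([0, 1], n // 2)
    mu = np.where(labels[:, None] == 0, 0.25, 0.25 + sep) \
        + 0.05 * rng.standard_normal((n, 4))
    return pf.arr_fuzzify(np.clip(mu, 0.01, 0.99)), labels


def reference_fcm(Phi, c, m, Phi0, tol=1e-5, max_iter=200):
    """Classic crisp FCM (independent oracle) on flattened coordinates."""
    V = Phi0.copy()
    U_prev = None
    for _ in range(max_iter):
        d2 = np.maximum(cdist(V, Phi, "sqeuclidean"), 1e-30)
        inv = d2 ** (-1.0 / (m - 1))
        U = inv / inv.sum(axis=0)
        V = (U**m @ Phi) / (U**m).sum(axis=1)[:, None]
        if U_prev is not None and np.max(np.abs(U - U_prev)) < tol:
            break
        U_prev = U
    return U


class TestMembershipUpdate:
    def test_point_on_centroid_gets_full_membership(self):
        data = pf.arr_fuzzify(np.array([[0.2, 0.8], [0.7, 0.1]]))
        V = data.copy()
        U = pfcm.update_memberships(data, V)
        np.testing.assert_allclose(U, np.eye(2), atol=1e-12)

    def test_equidistant_point_splits_evenly(self):
        data = pf.arr_fuzzify(np.array([[0.5, 0.5]]))
        V = pf.arr_fuzzify(np.array([[0.4, 0.5], [0.6, 0.5],
                                     [0.5, 0.4], [0.5, 0.6]]))
        U = pfcm.update_memberships(data, V)
        np.testing.assert_allclose(U, 0.25, atol=1e-9)

    def test_membership_formula_hand_value(self):
        # c=2, m=2, distances (1, 2): u = (0.8, 0.2)
        d = np.array([[1.0], [2.0]])
        inv = d ** (-2.0)
        expected = inv / inv.sum(axis=0)
        np.testing.assert_allclose(expected[:, 0], [0.8, 0.2])
        # same ratios via actual PFN data: coincide distances by construction
        data = pf.arr_fuzzify(np.array([[0.5]]))
        # pick centroids whose distances to the point are in ratio 1:2
        V = pf.arr_fuzzify(np.array([[0.6], [0.7]]))
        d2 = ((_sq_degrees(data)[None, :, :, :]
               - _sq_degrees(V)[:, None, :, :]) ** 2).sum((2, 3))[:, 0]
        U = pfcm.update_memberships(data, V)
        r = (d2[0] / d2[1])
        np.testing.assert_allclose(U[:, 0], [1 / (1 + r), 1 / (1 + 1 / r)],
                                   atol=1e-9)

    def test_columns_sum_to_one(self):
        rng = np.random.default_rng(3)
        data = pf.arr_fuzzify(rng.random((40, 5)))
        V = pf.arr_fuzzify(rng.random((4, 5)))
        U = pfcm.update_memberships(data, V)
        np.testing.assert_allclose(U.sum(axis=0), 1.0, atol=1e-9)


class TestCentroidUpdate:
    def test_one_hot_memberships_give_squared_degree_means(self):
        data = pf.arr_fuzzify(np.array([[0.6], [0.8]]))
        U = np.array([[1.0, 1.0]])
        V = pfcm.update_centroids(data, U)
        expected_mu = np.sqrt((0.6**2 + 0.8**2) / 2)
        assert V[0, 0, 0] == pytest.approx(expected_mu)
        assert pf.is_valid_arr(V).all()

    def test_single_point_cluster_reproduces_the_point(self):
        data = pf.arr_fuzzify(np.array([[0.3, 0.9]]))
        V = pfcm.update_centroids(data, np.array([[1.0]]))
        np.testing.assert_allclose(V[0], data[0], atol=1e-12)

    def test_outputs_always_valid(self):
        rng = np.random.default_rng(4)
        data = pf.arr_fuzzify(rng.random((30, 6)))
        U = rng.random((3, 30))
        U /= U.sum(axis=0)
        assert pf.is_valid_arr(pfcm.update_centroids(data, U)).all()


class TestObjective:
    def test_perfect_clustering_scores_zero(self):
        data = pf.arr_fuzzify(np.array([[0.2], [0.8]]))
        U = np.eye(2)
        assert pfcm.pfcm_objective(data, U, data) == pytest.approx(0.0)

    def test_matches_brute_force_summation(self):
        rng = np.random.default_rng(5)
        data = pf.arr_fuzzify(rng.random((4, 3)))
        V = pf.arr_fuzzify(rng.random((2, 3)))
        U = rng.random((2, 4))
        U /= U.sum(axis=0)
        m = 2.0
        brute = 0.0
        for i in range(2):
            for j in range(4):
                d = pf.pfn_vector_distance(data[j], V[i])
                brute += U[i, j] ** m * d**2
        brute /= 2 * 4
        assert pfcm.pfcm_objective(data, U, V, m) == pytest.approx(brute)


class TestClustering:
    def test_trace_non_increasing_and_u_column_stochastic(self):
        data, _ = two_group_pfn_set()
        U, V, trace = pfcm.pfcm_cluster(data, pfcm.ClusterConfig(c=3, seed=0))
        assert all(b <= a + 1e-9 for a, b in zip(trace, trace[1:]))
        np.testing.assert_allclose(U.sum(axis=0), 1.0, atol=1e-9)
        assert pf.is_valid_arr(V).all()

    def test_exact_equivalence_with_reference_fcm(self):
        for t in range(5):
            rng = np.random.default_rng(t)
            data = pf.arr_fuzzify(rng.random((25, 4)))
            idx = np.random.default_rng(50 + t).choice(25, 3, replace=False)
            V0 = data[idx]
            U, _, _ = pfcm.pfcm_cluster(
                data, pfcm.ClusterConfig(c=3), V0=V0)
            Phi = _sq_degrees(data).reshape(25, -1)
            U_ref = reference_fcm(Phi, 3, 2.0, _sq_degrees(V0).reshape(3, -1))
            np.testing.assert_allclose(U, U_ref, atol=1e-7)

    def test_recovers_separated_groups(self):
        data, labels = two_group_pfn_set()
        km = pfcm.PythagoreanFuzzyCMeans(n_clusters=2, random_state=0).fit(data)
        assert adjusted_rand_score(labels, km.labels_) == 1.0

    def test_estimator_predict_matches_fit_labels(self):
        data, _ = two_group_pfn_set()
        km = pfcm.PythagoreanFuzzyCMeans(n_clusters=2, random_state=0).fit(data)
        np.testing.assert_array_equal(km.predict(data), km.labels_)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            pfcm.pfcm_cluster(pf.arr_fuzzify(np.array([[0.5]])),
                              pfcm.ClusterConfig(c=2))

    def test_crisp_input_is_fuzzified_on_the_fly(self):
        X = np.random.default_rng(6).random((10, 3))
        km = pfcm.PythagoreanFuzzyCMeans(n_clusters=2, random_state=1).fit(X)
        assert km.membership_matrix_.shape == (2, 10)


class TestWWOInit:
    def test_returns_valid_centroids_deterministically(self):
        data, _ = two_group_pfn_set()
        cfg = pfcm.ClusterConfig(c=2, init="wwo", wwo_budget=60, seed=5)
        V1 = pfcm.wwo_init_centroids(data, cfg, np.random.default_rng(5))
        V2 = pfcm.wwo_init_centroids(data, cfg, np.random.default_rng(5))
        np.testing.assert_array_equal(V1, V2)
        assert pf.is_valid_arr(V1).all()

    def test_wwo_init_no_worse_than_random_on_average(self):
        data, _ = two_group_pfn_set()
        J_rand, J_wwo = [], []
        for s in range(8):
            _, _, tr = pfcm.pfcm_cluster(data, pfcm.ClusterConfig(c=2, seed=s))
            J_rand.append(tr[-1])
            _, _, tw = pfcm.pfcm_cluster(
                data, pfcm.ClusterConfig(c=2, init="wwo", wwo_budget=80,
                                         seed=s))
            J_wwo.append(tw[-1])
        assert np.mean(J_wwo) <= np.mean(J_rand) + 1e-12


class TestGroupTrainingSet:
    def test_floor_zero_includes_all_positive(self):
        U = np.array([[0.5, 0.2, 0.0], [0.5, 0.8, 1.0]])
        idx, w = pfcm.group_training_set(None, U, 0, u_floor=0.0)
        np.testing.assert_array_equal(idx, [0, 1])
        np.testing.assert_allclose(w, [0.5, 0.2])

    def test_floor_one_is_always_empty(self):
        U = np.array([[1.0], [0.0]])
        with pytest.raises(ValueError, match="lower u_floor"):
            pfcm.group_training_set(None, U, 0, u_floor=1.0)

    def test_uniform_memberships_above_floor_keep_everything(self):
        U = np.full((5, 8), 0.2)
        for i in range(5):
            idx, w = pfcm.group_training_set(None, U, i, u_floor=0.1)
            assert idx.size == 8
            np.testing.assert_allclose(w, 0.2)
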