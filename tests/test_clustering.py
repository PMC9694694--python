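import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from csarima.clustering import (
    ClusteringError,
    ClusterSearchGrid,
    ClusterSet,
    fukuyama_sugeno,
    partial_distance,
    pdsfcm_fit,
    score_membership,
    select_clustering,
    update_centroids,
    update_memberships,
)
from csarima.synthetic import generate_pp_set


def reference_fcm(X, n_clusters, m, W0, tol=1e-5, max_iter=200):
    """Plain-loop standard fuzzy C-means on complete data (independent oracle).

    Follows the textbook alternating updates with explicit Python loops and
    ordinary Euclidean distances; shares nothing with the package's
    vectorized partial-distance implementation beyond the initial membership
    matrix.
    """
    N, D = X.shape
    W = W0.copy()
    for _ in range(max_iter):
        V = np.zeros((n_clusters, D))
        for i in range(n_clusters):
            num = np.zeros(D)
            den = 0.0
            for j in range(N):
                num += W[j, i] ** m * X[j]
                den += W[j, i] ** m
            V[i] = num / den
        W_new = np.zeros_like(W)
        for j in range(N):
            d2 = np.array([np.sum((X[j] - V[i]) ** 2) for i in range(n_clusters)])
            if np.any(d2 == 0):
                W_new[j, d2 == 0] = 1.0 / np.sum(d2 == 0)
            else:
                for i in range(n_clusters):
                    W_new[j, i] = 1.0 / np.sum((d2[i] / d2) ** (1.0 / (m - 1)))
        delta = np.abs(W_new - W).max()
        W = W_new
        if delta < tol:
            break
    obj = 0.0
    for j in range(N):
        for i in range(n_clusters):
            obj += W[j, i] ** m * np.sum((X[j] - V[i]) ** 2)
    return V, W, obj


# ------------------------------------------------------------- partial distance


def test_partial_distance_identity():
    x = np.arange(48, dtype=float)
    assert partial_distance(x, x) == 0.0


def test_partial_distance_reduces_to_euclidean_when_complete():
    x = np.zeros(48)
    v = np.zeros(48)
    v[0], v[1] = 3.0, 4.0
    assert partial_distance(x, v) == pytest.approx(5.0)


def test_partial_distance_toy_scaling():
    # D=2, one observed coordinate: d^2 = (2/1) * (1-2)^2 = 2
    d = partial_distance(np.array([1.0, np.nan]), np.array([2.0, 5.0]))
    assert d == pytest.approx(np.sqrt(2.0))


def test_partial_distance_all_missing_errors():
    with pytest.raises(ClusteringError):
        partial_distance(np.array([np.nan, np.nan]), np.array([1.0, 2.0]))


@given(st.integers(0, 2**32 - 1))
@settings(max_examples=25, deadline=None)
def test_partial_distance_equals_euclidean_on_complete_profiles(seed):
    rng = np.random.default_rng(seed)
    x, v = rng.normal(size=(2, 48))
    assert partial_distance(x, v) == pytest.approx(float(np.linalg.norm(x - v)))


# ----------------------------------------------------------- membership update


def test_equidistant_memberships_uniform():
    x = np.zeros((1, 2))
    V = np.array([[1.0, 0], [-1.0, 0], [0, 1.0], [0, -1.0]])
    W = update_memberships(x, V, m=2.0)
    np.testing.assert_allclose(W, [[0.25, 0.25, 0.25, 0.25]])


def test_membership_hand_case_point8():
    # d1 = 1, d2 = 2, m = 2: w1 = 1 / (1 + (1/4)) = 0.8
    x = np.array([[0.0, 0.0]])
    V = np.array([[1.0, 0.0], [2.0, 0.0]])
    W = update_memberships(x, V, m=2.0)
    np.testing.assert_allclose(W, [[0.8, 0.2]])


def test_zero_distance_membership_crisp():
    x = np.array([[1.0, 2.0]])
    V = np.array([[1.0, 2.0], [5.0, 5.0]])
    W = update_memberships(x, V, m=2.0)
    np.testing.assert_array_equal(W, [[1.0, 0.0]])


@given(st.integers(0, 2**32 - 1))
@settings(max_examples=25, deadline=None)
def test_membership_rows_sum_to_one(seed):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(12, 48))
    X[rng.random(X.shape) < 0.2] = np.nan
    X[np.isnan(X).all(axis=1), 0] = 0.0  # keep every profile scoreable
    V = rng.normal(size=(4, 48))
    W = update_memberships(X, V, m=1.7)
    assert np.all(W >= 0) and np.all(W <= 1)
    np.testing.assert_allclose(W.sum(axis=1), 1.0, atol=1e-9)


# ------------------------------------------------------------- centroid update


def test_centroid_uniform_weights_is_mean():
    rng = np.random.default_rng(1)
    X = rng.normal(size=(10, 4))
    W = np.full((10, 1), 0.5)
    V = update_centroids(X, W, m=2.0)
    np.testing.assert_allclose(V[0], X.mean(axis=0))


def test_centroid_single_profile():
    X = np.array([[3.0, 1.0, 4.0]])
    V = update_centroids(X, np.array([[0.7]]), m=2.0)
    np.testing.assert_allclose(V[0], X[0])


def test_centroid_hand_weighted_case():
    # points {0, 10}, w = (0.8, 0.2), m = 2 -> (0.64*0 + 0.04*10)/0.68
    X = np.array([[0.0], [10.0]])
    W = np.array([[0.8], [0.2]])
    V = update_centroids(X, W, m=2.0)
    assert V[0, 0] == pytest.approx(0.4 / 0.68)


def test_centroid_unobserved_coordinate_errors():
    X = np.array([[1.0, np.nan], [2.0, np.nan]])
    with pytest.raises(ClusteringError, match="coordinate"):
        update_centroids(X, np.array([[1.0], [1.0]]), m=2.0)


# --------------------------------------------------------------------- fitting


def test_pdsfcm_recovers_separated_blobs():
    X, labels = generate_pp_set(K=2, n_per_cluster=15, noise_sd=2.0, seed=3)
    fit = pdsfcm_fit(X, 2, m=2.0, seed=0)
    hard = fit.hard_assignments()
    # memberships nearly crisp and prototypes near the blob means
    acc = max(
        np.mean(hard == labels), np.mean(hard == 1 - labels)
    )
    assert acc == 1.0
    assert np.max(fit.memberships.min(axis=1)) < 0.01
    for i in range(2):
        blob = np.nanmean(X[hard == i], axis=0)
        assert np.linalg.norm(fit.prototypes[i] - blob) < 2.0 * np.sqrt(48)


def test_pdsfcm_identical_profiles_zero_objective():
    X = np.tile(np.linspace(100, 200, 48), (5, 1))
    fit = pdsfcm_fit(X, 2, m=2.0, seed=0)
    assert fit.objective_history[-1] == pytest.approx(0.0, abs=1e-9)
    np.testing.assert_allclose(fit.prototypes[0], X[0])


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_objective_history_non_increasing(seed):
    rng = np.random.default_rng(seed)
    X = rng.normal(120, 20, size=(30, 48))
    X[rng.random(X.shape) < 0.15] = np.nan
    fit = pdsfcm_fit(X, 3, m=1.8, seed=seed)
    hist = np.array(fit.objective_history)
    assert np.all(np.diff(hist) <= 1e-8 * np.abs(hist[:-1]).max())


def test_pdsfcm_too_few_profiles_errors():
    with pytest.raises(ClusteringError):
        pdsfcm_fit(np.zeros((3, 48)), 3, m=2.0)


def test_pdsfcm_matches_reference_fcm_on_complete_data():
    """On complete data the partial-distance FCM is standard FCM (oracle check)."""
    X, _ = generate_pp_set(K=3, n_per_cluster=10, noise_sd=3.0, seed=11)
    assert not np.isnan(X).any()
    grid = ClusterSearchGrid(nC_range=(3,), restarts=1)
    seed = 5
    fit = pdsfcm_fit(X, 3, m=2.0, grid=grid, seed=seed)
    W0 = np.random.default_rng(seed).dirichlet(np.ones(3), size=X.shape[0])
    V_ref, W_ref, obj_ref = reference_fcm(X, 3, 2.0, W0)
    assert fit.objective_history[-1] == pytest.approx(obj_ref, abs=1e-6 * obj_ref)
    # same partition up to label permutation
    hard = fit.hard_assignments()
    hard_ref = np.argmax(W_ref, axis=1)
    assert any(
        np.array_equal(np.array(p)[hard], hard_ref)
        for p in itertools.permutations(range(3))
    )


# ------------------------------------------------------------ validity & search


def test_fs_negative_for_perfectly_compact_clusters():
    base = np.zeros(48)
    far = np.full(48, 100.0)
    X = np.vstack([base, base, far, far])
    W = np.array([[1.0, 0], [1.0, 0], [0, 1.0], [0, 1.0]])
    V = np.vstack([base, far])
    fs = fukuyama_sugeno(X, W, V, m=2.0)
    assert fs < 0  # compactness term vanishes, separation term dominates


def test_fs_doubles_when_profiles_duplicated():
    X, _ = generate_pp_set(K=2, n_per_cluster=8, noise_sd=4.0, seed=2)
    fit = pdsfcm_fit(X, 2, m=2.0, seed=0)
    fs1 = fukuyama_sugeno(X, fit.memberships, fit.prototypes, 2.0)
    X2 = np.vstack([X, X])
    W2 = np.vstack([fit.memberships, fit.memberships])
    fs2 = fukuyama_sugeno(X2, W2, fit.prototypes, 2.0)
    assert fs2 == pytest.approx(2 * fs1, rel=1e-9)


def test_fs_prefers_true_cluster_count():
    X, _ = generate_pp_set(K=3, n_per_cluster=15, noise_sd=2.0, seed=4)
    fits = {
        nc: pdsfcm_fit(X, nc, m=2.0, seed=0) for nc in (2, 3)
    }
    assert fits[3].validity < fits[2].validity


def test_fs_invariant_under_label_permutation():
    X, _ = generate_pp_set(K=2, n_per_cluster=10, noise_sd=3.0, seed=6)
    fit = pdsfcm_fit(X, 2, m=1.8, seed=1)
    perm = [1, 0]
    fs_perm = fukuyama_sugeno(
        X, fit.memberships[:, perm], fit.prototypes[perm], 1.8
    )
    assert fs_perm == pytest.approx(fit.validity, rel=1e-12)


def test_select_clustering_single_cell_and_determinism():
    X, _ = generate_pp_set(K=2, n_per_cluster=10, noise_sd=3.0, seed=9)
    grid = ClusterSearchGrid(nC_range=(2,), m_grid=(2.0,), restarts=2)
    a = select_clustering(X, grid, seed=3)
    b = select_clustering(X, grid, seed=3)
    assert a.n_clusters == 2
    np.testing.assert_array_equal(a.prototypes, b.prototypes)
    np.testing.assert_array_equal(a.memberships, b.memberships)
    assert a.validity == b.validity


def test_select_clustering_rejects_tiny_clusters():
    # 4 profiles cannot populate 2 clusters of >= 3 members
    X = np.vstack([np.zeros(48), np.zeros(48), np.full(48, 50.0), np.full(48, 50.0)])
    grid = ClusterSearchGrid(nC_range=(2,), m_grid=(2.0,), restarts=1)
    with pytest.raises(ClusteringError):
        select_clustering(X + np.random.default_rng(0).normal(0, 0.1, X.shape), grid, seed=0)


# ------------------------------------------------------------ scoring new data


def test_score_membership_prefix_matches_prototype():
    X, _ = generate_pp_set(K=3, n_per_cluster=10, noise_sd=2.0, seed=12)
    fit = pdsfcm_fit(X, 3, m=2.0, seed=0)
    partial = np.full(48, np.nan)
    partial[:10] = fit.prototypes[2][:10]
    w = score_membership(partial, fit)
    assert np.argmax(w) == 2
    assert w.sum() == pytest.approx(1.0, abs=1e-9)


def test_score_membership_symmetric_prefix():
    protos = np.vstack([np.zeros(48), np.full(48, 10.0)])
    cs = ClusterSet(
        n_clusters=2, fuzzifier=2.0, prototypes=protos,
        memberships=np.zeros((0, 2)), objective_history=(), validity=0.0, seed=0,
    )
    partial = np.full(48, np.nan)
    partial[:4] = 5.0  # equidistant from both prototypes
    np.testing.assert_allclose(score_membership(partial, cs), [0.5, 0.5])


def test_score_membership_single_cluster_degenerate():
    cs = ClusterSet(
        n_clusters=1, fuzzifier=2.0, prototypes=np.zeros((1, 48)),
        memberships=np.zeros((0, 1)), objective_history=(), validity=0.0, seed=0,
    )
    partial = np.full(48, np.nan)
    partial[0] = 1.0
    np.testing.assert_array_equal(score_membership(partial, cs), [1.0])


def test_score_membership_all_missing_errors():
    cs = ClusterSet(
        n_clusters=2, fuzzifier=2.0, prototypes=np.zeros((2, 48)),
        memberships=np.zeros((0, 2)), objective_history=(), validity=0.0, seed=0,
    )
    with pytest.raises(ClusteringError):
        score_membership(np.full(48, np.nan), cs)
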