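"""Local entropy estimation, anomaly features and the K-entropy."""

import numpy as np
import pytest

from entrofuse.entropy import (
    AnomalyFeatureMap,
    EntropyConfig,
    anomaly_feature_matrix,
    anomaly_features,
    anomaly_kernels,
    k_entropy,
    knn_mean_distance,
    local_entropy,
    local_entropy_kernel,
)
from entrofuse.kernels import (
    DistanceMatrix,
    GramMatrix,
    KernelSpec,
    cross_gram,
    gram,
    kernel_distance,
    self_diagonal,
)

LIN = KernelSpec("linear")


def euclid_distance_matrix(points):
    pts = np.asarray(points, dtype=float)[:, None]
    return DistanceMatrix(np.abs(pts - pts.T))


def test_knn_mean_distance_brute_force():
    D = euclid_distance_matrix([0.0, 1.0, 3.0])
    assert knn_mean_distance(D, 1) == pytest.approx([1.0, 1.0, 2.0])
    # k = n-1: mean of all off-diagonal entries per row
    assert knn_mean_distance(D, 2) == pytest.approx([2.0, 1.5, 2.5])


def test_knn_mean_distance_duplicated_point():
    D = euclid_distance_matrix([2.0, 2.0, 5.0])
    assert knn_mean_distance(D, 1)[:2] == pytest.approx([0.0, 0.0])


def test_knn_mean_distance_invalid_k():
    D = euclid_distance_matrix([0.0, 1.0])
    for k in (0, 2, 5):
        with pytest.raises(ValueError):
            knn_mean_distance(D, k)


def test_local_entropy_scaling():
    D = euclid_distance_matrix([0.0, 1.0, 3.0])
    h0 = local_entropy(D, EntropyConfig(alpha=0.0, k=1))
    assert h0 == pytest.approx(knn_mean_distance(D, 1))
    h_half = local_entropy(D, EntropyConfig(alpha=0.5, k=1))
    assert h_half == pytest.approx(2.0 * h0)


def test_local_entropy_identical_points():
    D = euclid_distance_matrix([1.0, 1.0, 1.0])
    assert local_entropy(D, EntropyConfig(k=2)) == pytest.approx(np.zeros(3))


def test_entropy_config_validation():
    with pytest.raises(ValueError):
        EntropyConfig(alpha=1.0)
    with pytest.raises(ValueError):
        EntropyConfig(k=0)


def test_local_entropy_kernel_outer_product(rng):
    assert local_entropy_kernel([1.0, 2.0]).values == pytest.approx(
        np.array([[1.0, 2.0], [2.0, 4.0]])
    )
    assert local_entropy_kernel(np.zeros(3)).values == pytest.approx(np.zeros((3, 3)))
    h = rng.uniform(size=6)
    w = np.linalg.eigvalsh(local_entropy_kernel(h).values)
    assert w.min() >= -1e-12
    assert (w > 1e-10).sum() <= 1  # rank at most one


def test_anomaly_features_single_point():
    F = anomaly_features([gram(LIN, np.array([[3.0]]))])
    assert F.values == pytest.approx(np.array([[0.0]]))


def test_anomaly_features_two_points_linear():
    """S = {0, 2} in 1-D: each point's mean distance to the rest is 2."""
    F = anomaly_features([gram(LIN, np.array([[0.0], [2.0]]))])
    assert F.values[:, 0] == pytest.approx([2.0, 2.0])


def test_far_point_has_largest_feature():
    X = np.array([[0.0], [0.1], [0.2], [10.0]])
    F = anomaly_features([gram(LIN, X)])
    assert np.argmax(F.values[:, 0]) == 3
    assert F.values[3, 0] > F.values[:3, 0].max()


def test_anomaly_features_brute_force_oracle(rng):
    """phi_j(x_i) = mean_{l != i} d_Kj(x_i, x_l), all kernel families."""
    X = rng.normal(size=(7, 2))
    bank = [KernelSpec("gaussian", sigma=0.5), LIN, KernelSpec("polynomial")]
    grams = [gram(s, X) for s in bank]
    F = anomaly_features(grams)
    for j, g in enumerate(grams):
        D = kernel_distance(g).values
        for i in range(7):
            expected = np.delete(D[i], i).mean()
            assert F.values[i, j] == pytest.approx(expected)


def test_anomaly_features_new_points(rng):
    X = rng.normal(size=(6, 2))
    X_new = rng.normal(size=(3, 2))
    bank = [KernelSpec("gaussian", sigma=2.0), LIN]
    grams = [gram(s, X) for s in bank]
    cross = [cross_gram(s, X_new, X) for s in bank]
    diags = [self_diagonal(s, X_new) for s in bank]
    F = anomaly_features(grams, cross_list=cross, self_diag=diags)
    for j, s in enumerate(bank):
        for i in range(3):
            d = [
                np.sqrt(
                    max(
                        0.0,
                        self_diagonal(s, X_new[i : i + 1])[0]
                        + self_diagonal(s, X[l : l + 1])[0]
                        - 2.0 * cross[j][i, l],
                    )
                )
                for l in range(6)
            ]
            assert F.values[i, j] == pytest.approx(np.mean(d))


def test_anomaly_feature_matrix_matches_gram_path(rng):
    """The data-direct fast path agrees with the Gram-matrix path."""
    X = rng.normal(size=(9, 3))
    X_new = rng.normal(size=(4, 3))
    bank = [KernelSpec("gaussian", sigma=0.3), LIN, KernelSpec("polynomial")]
    grams = [gram(s, X) for s in bank]

    F_fast = anomaly_feature_matrix(X, bank)
    F_ref = anomaly_features(grams)
    assert F_fast.values == pytest.approx(F_ref.values, abs=1e-8)

    cross = [cross_gram(s, X_new, X) for s in bank]
    diags = [self_diagonal(s, X_new) for s in bank]
    F_fast_new = anomaly_feature_matrix(X, bank, X_new=X_new)
    F_ref_new = anomaly_features(grams, cross_list=cross, self_diag=diags)
    assert F_fast_new.values == pytest.approx(F_ref_new.values, abs=1e-8)

    # k-NN aggregation variant agrees too
    F_fast_k = anomaly_feature_matrix(X, bank, k=3)
    F_ref_k = anomaly_features(grams, k=3)
    assert F_fast_k.values == pytest.approx(F_ref_k.values, abs=1e-8)


def test_anomaly_features_permutation_equivariance(rng):
    X = rng.normal(size=(8, 2))
    bank = [LIN, KernelSpec("gaussian", sigma=1.0)]
    perm = rng.permutation(8)
    F = anomaly_feature_matrix(X, bank)
    Fp = anomaly_feature_matrix(X[perm], bank)
    assert Fp.values == pytest.approx(F.values[perm])


def test_radial_monotonicity_of_features():
    """Moving a point away from the rest cannot shrink its linear-kernel phi."""
    base = [0.0, 0.5, 1.0]
    prev = -np.inf
    for far in (2.0, 4.0, 8.0, 16.0):
        X = np.array(base + [far])[:, None]
        phi = anomaly_features([gram(LIN, X)]).values[-1, 0]
        assert phi >= prev
        prev = phi


def test_anomaly_kernels_outer_products():
    F = AnomalyFeatureMap(
        values=np.array([[1.0, 0.0], [2.0, 0.0]]), kernel_bank=[LIN, LIN]
    )
    ks = anomaly_kernels(F)
    assert ks[0].values == pytest.approx(np.array([[1.0, 2.0], [2.0, 4.0]]))
    assert ks[1].values == pytest.approx(np.zeros((2, 2)))
    assert np.trace(ks[0].values) == pytest.approx((F.values[:, 0] ** 2).sum())


def test_feature_map_rejects_negative_entries():
    with pytest.raises(ValueError):
        AnomalyFeatureMap(values=np.array([[-1.0]]), kernel_bank=[LIN])


@pytest.mark.parametrize(
    "mat,expected",
    [
        (np.ones((2, 2)), 4.0),
        (np.eye(5), 5.0),
        (np.array([[1.0, -2.0], [-2.0, 1.0]]), 6.0),
    ],
)
def test_k_entropy_values(mat, expected):
    assert k_entropy(GramMatrix(mat)) == pytest.approx(expected)


def test_k_entropy_permutation_invariance(rng):
    M = rng.normal(size=(6, 6))
    M = M + M.T
    perm = rng.permutation(6)
    assert k_entropy(GramMatrix(M[np.ix_(perm, perm)])) == pytest.approx(
        k_entropy(GramMatrix(M))
    )


def test_k_entropy_rank_one_identity(rng):
    """For K = phi phi^T with phi >= 0, the K-entropy is (sum phi)^2."""
    phi = rng.uniform(size=10)
    K = GramMatrix(np.outer(phi, phi))
    assert k_entropy(K) == pytest.approx(phi.sum() ** 2)
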