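"""Fusion schemes: average, entropy weighting, and the SPD Karcher mean."""

import numpy as np
import pytest
from scipy.linalg import expm, inv, logm, sqrtm

from conftest import random_psd, random_spd
from entrofuse.combine import (
    CombinationWeights,
    SPDConfig,
    average_combination,
    entropy_combination,
    entropy_weights,
    entropy_weights_from_features,
    karcher_mean,
    spd_distance,
)
from entrofuse.entropy import AnomalyFeatureMap, anomaly_kernels, k_entropy
from entrofuse.kernels import GramMatrix, KernelSpec


def test_average_combination_cases(rng):
    A = GramMatrix(np.array([[2.0, 1.0], [1.0, 2.0]]))
    assert average_combination([A]).values == pytest.approx(A.values)
    B1, B2 = GramMatrix(np.eye(2)), GramMatrix(3 * np.eye(2))
    assert average_combination([B1, B2]).values == pytest.approx(2 * np.eye(2))
    mats = [GramMatrix(random_psd(rng, 5)) for _ in range(4)]
    w = np.linalg.eigvalsh(average_combination(mats).values)
    assert w.min() >= -1e-10


def test_average_combination_size_mismatch():
    with pytest.raises(ValueError):
        average_combination([GramMatrix(np.eye(2)), GramMatrix(np.eye(3))])


def test_entropy_weights_closed_form():
    # two kernels with equal K-entropy -> equal weights
    A = GramMatrix(np.eye(2))
    B = GramMatrix(np.diag([2.0, 0.0]))
    w = entropy_weights([A, B])
    assert w.lambdas == pytest.approx([0.5, 0.5])
    # entropies (1, 3) -> weights (0.25, 0.75)
    C = GramMatrix(np.array([[1.0]]))
    D = GramMatrix(np.array([[3.0]]))
    w2 = entropy_weights([C, D])
    assert w2.lambdas == pytest.approx([0.25, 0.75])
    assert w2.upper_bounds == pytest.approx(w2.lambdas)


def test_entropy_weights_sum_to_one(rng):
    mats = [GramMatrix(random_psd(rng, 4)) for _ in range(6)]
    assert entropy_weights(mats).lambdas.sum() == pytest.approx(1.0)


def test_entropy_weights_degenerate_input():
    with pytest.raises(ValueError):
        entropy_weights([GramMatrix(np.zeros((3, 3)))])


def test_entropy_weights_from_features_matches_matrix_path(rng):
    phi = rng.uniform(size=(8, 3))
    F = AnomalyFeatureMap(values=phi, kernel_bank=[KernelSpec("linear")] * 3)
    w_fast = entropy_weights_from_features(F)
    w_ref = entropy_weights(anomaly_kernels(F))
    assert w_fast.lambdas == pytest.approx(w_ref.lambdas)


def test_entropy_combination_cases(rng):
    mats = [GramMatrix(np.eye(3)), GramMatrix(np.eye(3) * 2)]
    w = entropy_weights(mats)
    combo = entropy_combination(mats, w)
    manual = w.lambdas[0] * mats[0].values + w.lambdas[1] * mats[1].values
    assert combo.values == pytest.approx(manual)
    # a kernel with zero entropy contributes nothing
    mats2 = [GramMatrix(np.zeros((2, 2))), GramMatrix(np.ones((2, 2)))]
    combo2 = entropy_combination(mats2, entropy_weights(mats2))
    assert combo2.values == pytest.approx(np.ones((2, 2)))


def test_entropy_combination_subadditivity(rng):
    """K-entropy of a mixture is at most the mixture of K-entropies."""
    for _ in range(10):
        mats = [GramMatrix(random_psd(rng, 4)) for _ in range(3)]
        w = entropy_weights(mats)
        lhs = k_entropy(entropy_combination(mats, w))
        rhs = sum(l * k_entropy(m) for l, m in zip(w.lambdas, mats))
        assert lhs <= rhs + 1e-10


def test_combination_weights_validation():
    with pytest.raises(ValueError):
        CombinationWeights(lambdas=[0.5, 0.6], upper_bounds=[1.0, 1.0])
    with pytest.raises(ValueError):
        CombinationWeights(lambdas=[-0.1, 1.1], upper_bounds=[1.0, 1.0])


def test_spd_distance_cases(rng):
    A = random_spd(rng, 3)
    assert spd_distance(A, A) == pytest.approx(0.0, abs=1e-10)
    assert spd_distance(np.eye(2), np.e**2 * np.eye(2)) == pytest.approx(
        2.0 * np.sqrt(2.0)
    )
    B = random_spd(rng, 3)
    assert spd_distance(A, B) == pytest.approx(spd_distance(B, A))
    # inversion invariance of the affine-invariant metric
    assert spd_distance(inv(A), inv(B)) == pytest.approx(spd_distance(A, B))


def test_spd_distance_rejects_indefinite():
    with pytest.raises(np.linalg.LinAlgError):
        spd_distance(np.diag([1.0, -1.0]), np.eye(2))


def test_karcher_single_matrix(rng):
    A = random_spd(rng, 3)
    X, rep = karcher_mean([GramMatrix(A)], SPDConfig(ridge=1e-12))
    assert rep.converged
    assert X.values == pytest.approx(A, abs=1e-9)


def test_karcher_commuting_scalar_case():
    X, _ = karcher_mean(
        [GramMatrix(2.0 * np.eye(3)), GramMatrix(8.0 * np.eye(3))],
        SPDConfig(ridge=1e-14, tol=1e-12),
    )
    assert X.values == pytest.approx(4.0 * np.eye(3), abs=1e-8)


def test_karcher_two_matrix_geodesic_midpoint(rng):
    A, B = random_spd(rng, 4), random_spd(rng, 4)
    As = sqrtm(A)
    Ais = inv(As)
    midpoint = As @ sqrtm(Ais @ B @ Ais) @ As
    X, rep = karcher_mean(
        [GramMatrix(A), GramMatrix(B)], SPDConfig(ridge=1e-14, tol=1e-12)
    )
    assert np.abs(X.values - np.real(midpoint)).max() < 1e-8
    assert rep.residual <= 10 * 1e-12 * max(1.0, rep.history[0])


def test_karcher_commuting_log_euclidean(rng):
    """For commuting inputs the Karcher mean is exp(mean(log K_i))."""
    Q, _ = np.linalg.qr(rng.normal(size=(4, 4)))
    mats = [(Q * rng.uniform(0.5, 2.0, size=4)) @ Q.T for _ in range(3)]
    expected = expm(sum(logm(m) for m in mats) / 3)
    X, _ = karcher_mean(
        [GramMatrix(m) for m in mats], SPDConfig(ridge=1e-14, tol=1e-12)
    )
    assert np.abs(X.values - np.real(expected)).max() < 1e-8


def test_karcher_congruence_equivariance(rng):
    mats = [random_spd(rng, 3) for _ in range(4)]
    G = rng.normal(size=(3, 3)) + 3 * np.eye(3)
    cfg = SPDConfig(ridge=1e-14, tol=1e-11)
    X1, _ = karcher_mean([GramMatrix(G @ m @ G.T) for m in mats], cfg)
    X0, _ = karcher_mean([GramMatrix(m) for m in mats], cfg)
    assert np.abs(X1.values - G @ X0.values @ G.T).max() < 1e-6


def test_karcher_permutation_invariance(rng):
    mats = [random_spd(rng, 3) for _ in range(5)]
    cfg = SPDConfig(ridge=1e-14, tol=1e-11)
    X1, _ = karcher_mean([GramMatrix(m) for m in mats], cfg)
    X2, _ = karcher_mean([GramMatrix(m) for m in mats[::-1]], cfg)
    assert np.abs(X1.values - X2.values).max() < 1e-8


def test_karcher_minimizes_summed_squared_distance(rng):
    """f(X) = sum d_P(X, K_i)^2 is smallest at the returned mean."""
    mats = [random_spd(rng, 3) for _ in range(4)]
    X, _ = karcher_mean([GramMatrix(m) for m in mats], SPDConfig(ridge=1e-14))
    f_opt = sum(spd_distance(X.values, m) ** 2 for m in mats)
    for _ in range(10):
        Y = random_spd(rng, 3)
        f_alt = sum(spd_distance(Y, m) ** 2 for m in mats)
        assert f_opt <= f_alt + 1e-8


def test_karcher_handles_rank_one_inputs(rng):
    """Ridging makes the paper's singular rank-one kernels usable."""
    cols = rng.uniform(0.1, 2.0, size=(6, 3))
    mats = [GramMatrix(np.outer(c, c)) for c in cols.T]
    X, rep = karcher_mean(mats, SPDConfig(ridge=1e-6, tol=1e-7, max_iter=500))
    assert rep.converged
    assert np.linalg.eigvalsh(X.values).min() > 0


def test_karcher_nonconvergence_warns(rng):
    mats = [GramMatrix(random_spd(rng, 3)) for _ in range(3)]
    with pytest.warns(RuntimeWarning):
        karcher_mean(mats, SPDConfig(tol=1e-14, max_iter=1))
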