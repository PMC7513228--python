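"""Local entropy estimation and entropy-based anomaly features.

The local entropy of a point is estimated from nearest-neighbour distances:
``h_alpha(x) = dbar_k(x, S_n) / (1 - alpha)`` where ``dbar_k`` is the mean
distance from ``x`` to its ``k`` nearest neighbours in the sample. With the
Hartley order ``alpha = 0`` (the default) the estimator is the k-NN mean
distance itself.

Anomaly features lift a base kernel ``K_j`` to a one-dimensional sparsity
measure: ``phi_j(x)`` is the average kernel-induced distance from ``x`` to the
training sample. Points off the bulk of the data get large ``phi_j``, so the
rank-one kernels ``K_j = phi_j phi_j^T`` concentrate regular data near the
origin of the combined feature space.

The K-entropy of a sample under a kernel is the sum of absolute Gram entries:
large when the representation is scattered, small when it is concentrated.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .kernels import (
    DistanceMatrix,
    GramMatrix,
    KernelSpec,
    cross_gram,
    cross_kernel_distance,
    gram,
    kernel_distance,
    self_diagonal,
)

__all__ = [
    "EntropyConfig",
    "AnomalyFeatureMap",
    "default_k",
    "knn_mean_distance",
    "local_entropy",
    "local_entropy_kernel",
    "anomaly_features",
    "anomaly_feature_matrix",
    "anomaly_kernels",
    "k_entropy",
]


def default_k(n: int) -> int:
    """Locality default ``ceil(sqrt(n))``, clipped to the valid range."""
    return min(max(1, math.ceil(math.sqrt(n))), max(1, n - 1))


@dataclass(frozen=True)
class EntropyConfig:
    """Entropy order ``alpha`` (Renyi; 0 = Hartley) and neighbourhood size ``k``.

    ``k=None`` resolves to ``ceil(sqrt(n))`` at call time.
    """

    alpha: float = 0.0
    k: int | None = None

    def __post_init__(self) -> None:
        if self.alpha == 1:
            raise ValueError("alpha = 1 is excluded (estimator undefined)")
        if self.alpha < 0:
            raise ValueError("alpha must be >= 0")
        if self.k is not None and self.k < 1:
            raise ValueError("k must be a positive integer")


@dataclass
class AnomalyFeatureMap:
    """n x m matrix of per-kernel anomaly scores ``phi_j(x_i)`` (all >= 0)."""

    values: np.ndarray
    kernel_bank: list[KernelSpec]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("feature map must be 2-D (n points x m kernels)")
        if self.values.shape[1] != len(self.kernel_bank):
            raise ValueError("column count must match the kernel bank")
        if self.values.min(initial=0.0) < 0:
            raise ValueError("anomaly features must be nonnegative")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def m(self) -> int:
        return self.values.shape[1]


def knn_mean_distance(D: DistanceMatrix, k: int) -> np.ndarray:
    """Mean distance from each point to its ``k`` nearest neighbours.

    Reads row ``i`` of the distance matrix, drops the self-distance, and
    averages the ``k`` smallest remaining entries.
    """
    values = D.values
    n = values.shape[0]
    if not 1 <= k <= n - 1:
        raise ValueError(f"k must satisfy 1 <= k <= n-1, got k={k}, n={n}")
    work = values.copy().astype(float)
    np.fill_diagonal(work, np.inf)
    part = np.partition(work, k - 1, axis=1)[:, :k]
    return part.mean(axis=1)


def local_entropy(D: DistanceMatrix, cfg: EntropyConfig) -> np.ndarray:
    """k-NN local-entropy estimate ``dbar_k / (1 - alpha)`` per point."""
    k = cfg.k if cfg.k is not None else default_k(D.n)
    return knn_mean_distance(D, k) / (1.0 - cfg.alpha)


def local_entropy_kernel(h: np.ndarray) -> GramMatrix:
    """Rank-one kernel ``h h^T`` built from a local-entropy profile."""
    h = np.asarray(h, dtype=float).ravel()
    return GramMatrix(values=np.outer(h, h), kernel="derived")


def _phi_from_square(dist: np.ndarray, k: int | None) -> np.ndarray:
    """Point-to-sample aggregation for training points (self excluded)."""
    n = dist.shape[0]
    if n == 1:
        return np.zeros(1)
    if k is None:
        return dist.sum(axis=1) / (n - 1)
    return knn_mean_distance(DistanceMatrix(dist), min(k, n - 1))


def _phi_from_rect(dist: np.ndarray, k: int | None) -> np.ndarray:
    """Point-to-sample aggregation for new points (all reference points)."""
    if k is None:
        return dist.mean(axis=1)
    kk = min(k, dist.shape[1])
    return np.partition(dist, kk - 1, axis=1)[:, :kk].mean(axis=1)


def anomaly_features(
    gram_list: Sequence[GramMatrix],
    cross_list: Sequence[np.ndarray] | None = None,
    self_diag: Sequence[np.ndarray] | None = None,
    k: int | None = None,
) -> AnomalyFeatureMap:
    """Per-kernel anomaly scores ``phi_j(x) = mean_i d_Kj(x, x_i)``.

    With only ``gram_list`` the features are computed for the training points
    themselves (each point's distance to itself is excluded from the mean).
    Passing ``cross_list`` (new-vs-train kernel values, one rectangular matrix
    per kernel) together with ``self_diag`` (per-kernel ``K(x, x)`` of the new
    points) scores new points against the training sample instead.

    ``k`` switches the aggregation from the full mean (default) to the mean
    over the ``k`` nearest training points.
    """
    m = len(gram_list)
    if m == 0:
        raise ValueError("need at least one kernel")
    n = gram_list[0].n
    if any(g.n != n for g in gram_list):
        raise ValueError("all Gram matrices must share the sample size")
    bank = [g.kernel if isinstance(g.kernel, KernelSpec) else None for g in gram_list]
    bank = [b if b is not None else KernelSpec("linear") for b in bank]

    if cross_list is None:
        cols = [
            _phi_from_square(kernel_distance(g).values, k) for g in gram_list
        ]
    else:
        if self_diag is None or len(cross_list) != m or len(self_diag) != m:
            raise ValueError(
                "cross_list and self_diag must both be given, one entry per kernel"
            )
        cols = []
        for g, C, d_new in zip(gram_list, cross_list, self_diag):
            dist = cross_kernel_distance(C, d_new, np.diag(g.values))
            cols.append(_phi_from_rect(dist, k))
    return AnomalyFeatureMap(values=np.column_stack(cols), kernel_bank=bank)


def anomaly_feature_matrix(
    X_train: np.ndarray,
    bank: Sequence[KernelSpec],
    X_new: np.ndarray | None = None,
    k: int | None = None,
) -> AnomalyFeatureMap:
    """Anomaly features computed directly from data, one kernel at a time.

    Equivalent to building every Gram matrix and calling
    :func:`anomaly_features`, but holds a single pairwise matrix in memory at
    any moment: all bank kernels are functions of the linear Gram matrix, which
    is computed once and reused. This is the path the pipeline uses at the
    experiments' sample sizes (thousands of points, 11 kernels).
    """
    X_train = np.atleast_2d(np.asarray(X_train, dtype=float))
    n = X_train.shape[0]
    X_eval = X_train if X_new is None else np.atleast_2d(np.asarray(X_new, dtype=float))

    G = X_eval @ X_train.T
    sq_train = np.einsum("ij,ij->i", X_train, X_train)
    sq_eval = sq_train if X_new is None else np.einsum("ij,ij->i", X_eval, X_eval)
    # Euclidean squared distances, shared by the whole Gaussian grid
    D2 = np.maximum(sq_eval[:, None] + sq_train[None, :] - 2.0 * G, 0.0)

    cols = []
    for spec in bank:
        if spec.family == "gaussian":
            d2 = 2.0 - 2.0 * np.exp(-spec.sigma * D2)
        elif spec.family == "linear":
            d2 = D2
        else:
            Kc = (G + spec.offset) ** spec.degree
            dn = (sq_eval + spec.offset) ** spec.degree
            dt = (sq_train + spec.offset) ** spec.degree
            d2 = dn[:, None] + dt[None, :] - 2.0 * Kc
        np.maximum(d2, 0.0, out=d2)
        dist = np.sqrt(d2)
        if X_new is None:
            np.fill_diagonal(dist, 0.0)
            cols.append(_phi_from_square(dist, k))
        else:
            cols.append(_phi_from_rect(dist, k))
    return AnomalyFeatureMap(values=np.column_stack(cols), kernel_bank=list(bank))


def anomaly_kernels(F: AnomalyFeatureMap) -> list[GramMatrix]:
    """Rank-one anomaly kernels ``K_j = phi_j phi_j^T``, one per base kernel."""
    return [
        GramMatrix(values=np.outer(F.values[:, j], F.values[:, j]), kernel="derived")
        for j in range(F.m)
    ]


def k_entropy(g: GramMatrix) -> float:
    """K-entropy of a sample: sum of absolute Gram-matrix entries."""
    return float(np.abs(g.values).sum())
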