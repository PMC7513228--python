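"""Base Mercer kernels, Gram matrices and the kernel-induced distance.

A Mercer kernel :math:`K` embeds the data in a feature space where it acts as
an inner product; the induced metric is

.. math:: d_K^2(x, y) = K(x, x) + K(y, y) - 2 K(x, y).

The default kernel bank mirrors the grid used throughout the experiments:
nine Gaussian kernels :math:`K_G(x, y) = e^{-\\sigma \\|x - y\\|^2}` with
``sigma`` in ``{1e-3, 1e-2, 0.1, 1, 10, 50, 100, 500, 1e3}``, the linear
kernel and the second-degree polynomial kernel ``(<x, y> + 1)^2``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence, Union

import numpy as np
from sklearn.metrics.pairwise import linear_kernel, polynomial_kernel, rbf_kernel

__all__ = [
    "KernelSpec",
    "GramMatrix",
    "DistanceMatrix",
    "SIGMA_GRID",
    "default_kernel_bank",
    "evaluate_kernel",
    "gram",
    "cross_gram",
    "self_diagonal",
    "kernel_distance",
    "cross_kernel_distance",
]

#: Gaussian width grid used by the experiments.
SIGMA_GRID: tuple[float, ...] = (1e-3, 1e-2, 0.1, 1.0, 10.0, 50.0, 100.0, 500.0, 1e3)

#: Relative tolerance on the minimum eigenvalue when validating PSD-ness.
PSD_RTOL = 1e-8


@dataclass(frozen=True)
class KernelSpec:
    """A base kernel: ``gaussian`` (width ``sigma``), ``linear`` or ``polynomial``.

    The Gaussian kernel is parameterized as ``exp(-sigma * ||x - y||^2)`` —
    ``sigma`` multiplies the squared distance. The polynomial kernel is
    ``(<x, y> + offset) ** degree`` with ``degree=2`` and ``offset=1`` by
    default.
    """

    family: str
    sigma: float | None = None
    degree: int = 2
    offset: float = 1.0

    def __post_init__(self) -> None:
        if self.family not in ("gaussian", "linear", "polynomial"):
            raise ValueError(f"unknown kernel family {self.family!r}")
        if self.family == "gaussian":
            if self.sigma is None or self.sigma <= 0:
                raise ValueError("gaussian kernel requires sigma > 0")
        if self.family == "polynomial" and self.degree < 1:
            raise ValueError("polynomial kernel requires degree >= 1")

    def label(self) -> str:
        if self.family == "gaussian":
            return f"gaussian(sigma={self.sigma:g})"
        if self.family == "polynomial":
            return f"polynomial(degree={self.degree},offset={self.offset:g})"
        return "linear"


@dataclass
class GramMatrix:
    """Symmetric PSD evaluation of a kernel on a sample.

    ``kernel`` records the generating :class:`KernelSpec`, or the tag
    ``"derived"`` for anomaly / combined kernels that are not evaluations of a
    base kernel.
    """

    values: np.ndarray
    kernel: Union[KernelSpec, str] = "derived"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] != self.values.shape[1]:
            raise ValueError("Gram matrix must be square")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def check_symmetric(self, tol: float = 1e-8) -> None:
        scale = max(1.0, float(np.abs(self.values).max(initial=0.0)))
        if np.abs(self.values - self.values.T).max(initial=0.0) > tol * scale:
            raise ValueError("Gram matrix is not symmetric within tolerance")

    def check_psd(self, rtol: float = PSD_RTOL) -> None:
        self.check_symmetric()
        w = np.linalg.eigvalsh(self.values)
        radius = max(float(np.abs(w).max(initial=0.0)), np.finfo(float).tiny)
        if w.min(initial=0.0) < -rtol * radius:
            raise ValueError("Gram matrix is not PSD within tolerance")


@dataclass
class DistanceMatrix:
    """Pairwise kernel-induced distances: nonnegative, symmetric, zero diagonal."""

    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)

    @property
    def n(self) -> int:
        return self.values.shape[0]


def default_kernel_bank(
    sigmas: Sequence[float] = SIGMA_GRID,
    include_linear: bool = True,
    include_polynomial: bool = True,
) -> list[KernelSpec]:
    """The experiments' 11-kernel bank: Gaussian grid + linear + polynomial."""
    bank = [KernelSpec("gaussian", sigma=float(s)) for s in sigmas]
    if include_linear:
        bank.append(KernelSpec("linear"))
    if include_polynomial:
        bank.append(KernelSpec("polynomial", degree=2, offset=1.0))
    return bank


def _as_2d(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.ndim == 1:
        x = x[None, :]
    return x


def evaluate_kernel(spec: KernelSpec, x: np.ndarray, y: np.ndarray) -> float:
    """Evaluate the kernel on a single pair of feature vectors."""
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.shape != y.shape:
        raise ValueError("x and y must have the same dimension")
    return float(cross_gram(spec, x[None, :], y[None, :])[0, 0])


def gram(spec: KernelSpec, X: np.ndarray) -> GramMatrix:
    """Evaluate ``spec`` on all pairs of rows of ``X``."""
    X = _as_2d(X)
    if X.shape[0] < 1:
        raise ValueError("sample must contain at least one row")
    values = cross_gram(spec, X, X)
    # enforce exact symmetry against rounding in the pairwise routines
    values = 0.5 * (values + values.T)
    return GramMatrix(values=values, kernel=spec)


def cross_gram(spec: KernelSpec, X_new: np.ndarray, X_ref: np.ndarray) -> np.ndarray:
    """Rectangular kernel evaluation of new points against a reference sample."""
    X_new, X_ref = _as_2d(X_new), _as_2d(X_ref)
    if X_new.shape[1] != X_ref.shape[1]:
        raise ValueError("feature dimensions do not match")
    if spec.family == "gaussian":
        return rbf_kernel(X_new, X_ref, gamma=spec.sigma)
    if spec.family == "linear":
        return linear_kernel(X_new, X_ref)
    return polynomial_kernel(
        X_new, X_ref, degree=spec.degree, gamma=1.0, coef0=spec.offset
    )


def self_diagonal(spec: KernelSpec, X: np.ndarray) -> np.ndarray:
    """``K(x, x)`` for each row of ``X`` without forming the full Gram matrix."""
    X = _as_2d(X)
    if spec.family == "gaussian":
        return np.ones(X.shape[0])
    sq = np.einsum("ij,ij->i", X, X)
    if spec.family == "linear":
        return sq
    return (sq + spec.offset) ** spec.degree


def kernel_distance(g: GramMatrix, tol: float = 1e-8) -> DistanceMatrix:
    """Pairwise feature-space distances induced by a Gram matrix.

    Entries are ``sqrt(max(0, K_ii + K_jj - 2 K_ij))``; the clip guards the
    exact nonnegativity of the quadratic form against floating-point noise.
    """
    g.check_symmetric(tol=tol)
    K = g.values
    d = np.diag(K)
    sq = d[:, None] + d[None, :] - 2.0 * K
    np.maximum(sq, 0.0, out=sq)
    values = np.sqrt(sq)
    np.fill_diagonal(values, 0.0)
    return DistanceMatrix(values=0.5 * (values + values.T))


def cross_kernel_distance(
    cross: np.ndarray, diag_new: np.ndarray, diag_ref: np.ndarray
) -> np.ndarray:
    """Feature-space distances of new points to reference points.

    ``cross`` holds ``K(x_new, x_ref)``; ``diag_new`` and ``diag_ref`` the
    self-similarities ``K(x, x)`` of each set.
    """
    cross = np.asarray(cross, dtype=float)
    diag_new = np.asarray(diag_new, dtype=float).ravel()
    diag_ref = np.asarray(diag_ref, dtype=float).ravel()
    if cross.shape != (diag_new.size, diag_ref.size):
        raise ValueError("cross matrix shape does not match the diagonals")
    sq = diag_new[:, None] + diag_ref[None, :] - 2.0 * cross
    np.maximum(sq, 0.0, out=sq)
    return np.sqrt(sq)
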