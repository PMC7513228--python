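"""Kernel fusion schemes: uniform average, K-entropy weighting, Karcher mean.

Three ways to merge ``m`` PSD kernel matrices into a single Mercer kernel:

* **mean** — the arithmetic average ``(1/m) sum K_j``;
* **entropy** — the convex combination with weights proportional to each
  kernel's K-entropy, ``lambda_j = E_{K_j} / sum_l E_{K_l}``.  These weights
  are the closed-form solution of the semidefinite program
  ``max sum lambda_j E_{K_j}`` subject to ``sum lambda_j K_j >= 0``,
  ``sum lambda_j = 1`` and ``0 <= lambda_j <= u_j`` when each upper bound is
  set to the normalized entropy itself;
* **karcher** — the Karcher (Frechet) mean on the cone of SPD matrices under
  the affine-invariant metric ``d_P(A,B) = ||log(A^{-1/2} B A^{-1/2})||_F``:
  the minimizer of ``sum_i d_P(X, K_i)^2`` and the unique SPD solution of
  ``sum_i log(K_i^{-1} X) = 0``.

Rank-one anomaly kernels are singular, so every manifold operation first adds
a scale-aware ridge ``eps * (tr(K)/n) * I`` to its inputs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .entropy import AnomalyFeatureMap, k_entropy
from .kernels import GramMatrix

__all__ = [
    "CombinationWeights",
    "SPDConfig",
    "KarcherReport",
    "average_combination",
    "entropy_weights",
    "entropy_weights_from_features",
    "entropy_combination",
    "spd_distance",
    "karcher_mean",
]


@dataclass
class CombinationWeights:
    """Nonnegative kernel weights summing to one, with their upper bounds."""

    lambdas: np.ndarray
    upper_bounds: np.ndarray
    scheme: str = "entropy"

    def __post_init__(self) -> None:
        self.lambdas = np.asarray(self.lambdas, dtype=float).ravel()
        self.upper_bounds = np.asarray(self.upper_bounds, dtype=float).ravel()
        if self.lambdas.min(initial=0.0) < 0:
            raise ValueError("weights must be nonnegative")
        if abs(self.lambdas.sum() - 1.0) > 1e-12:
            raise ValueError("weights must sum to 1")
        if self.scheme == "entropy" and np.any(
            self.lambdas > self.upper_bounds + 1e-12
        ):
            raise ValueError("entropy weights must respect their upper bounds")


@dataclass(frozen=True)
class SPDConfig:
    """Numerical policy for operations on the SPD cone.

    ``ridge`` is the relative magnitude of the identity shift that makes
    singular inputs strictly positive definite; ``tol`` the convergence
    tolerance on the Frobenius norm of the tangent-space mean (relative to the
    first iterate's); ``max_iter`` the fixed-point iteration cap.
    """

    ridge: float = 1e-6
    tol: float = 1e-8
    max_iter: int = 200

    def __post_init__(self) -> None:
        if self.ridge <= 0 or self.tol <= 0 or self.max_iter < 1:
            raise ValueError("ridge and tol must be positive, max_iter >= 1")


@dataclass
class KarcherReport:
    """Convergence record of the Karcher fixed-point iteration."""

    converged: bool
    n_iter: int
    tangent_norm: float
    residual: float  # ||sum_i log(K_i^{-1} X)||_F at the returned X
    history: list[float] = field(default_factory=list)


def _stack(gram_list: Sequence[GramMatrix]) -> list[np.ndarray]:
    if len(gram_list) == 0:
        raise ValueError("need at least one kernel matrix")
    n = gram_list[0].n
    if any(g.n != n for g in gram_list):
        raise ValueError("kernel matrices must share their size")
    return [g.values for g in gram_list]


def average_combination(gram_list: Sequence[GramMatrix]) -> GramMatrix:
    """Uniform mixture ``(1/m) sum_j K_j`` of the kernel matrices."""
    mats = _stack(gram_list)
    return GramMatrix(values=sum(mats) / len(mats), kernel="derived")


def entropy_weights(gram_list: Sequence[GramMatrix]) -> CombinationWeights:
    """Closed-form K-entropy weights ``lambda_j = E_{K_j} / sum_l E_{K_l}``."""
    _stack(gram_list)
    e = np.array([k_entropy(g) for g in gram_list])
    return _weights_from_entropies(e)


def entropy_weights_from_features(F: AnomalyFeatureMap) -> CombinationWeights:
    """Entropy weights straight from the feature map.

    For the rank-one anomaly kernel ``K_j = phi_j phi_j^T`` with nonnegative
    ``phi_j``, the K-entropy collapses to ``(sum_i phi_j(x_i))^2``, so the
    weights never require the n x n matrices.
    """
    e = F.values.sum(axis=0) ** 2
    return _weights_from_entropies(e)


def _weights_from_entropies(e: np.ndarray) -> CombinationWeights:
    total = e.sum()
    if total <= 0:
        raise ValueError("all K-entropies are zero: weighting is degenerate")
    lam = e / total
    return CombinationWeights(lambdas=lam, upper_bounds=lam.copy(), scheme="entropy")


def entropy_combination(
    gram_list: Sequence[GramMatrix], w: CombinationWeights
) -> GramMatrix:
    """Weighted mixture ``sum_j lambda_j K_j``."""
    mats = _stack(gram_list)
    if len(mats) != w.lambdas.size:
        raise ValueError("weight count must match the kernel count")
    out = np.zeros_like(mats[0])
    for lam, m in zip(w.lambdas, mats):
        out += lam * m
    return GramMatrix(values=out, kernel="derived")


# --- SPD cone ---------------------------------------------------------------


def _ridged(mat: np.ndarray, ridge: float) -> np.ndarray:
    n = mat.shape[0]
    scale = float(np.trace(mat)) / n
    if scale <= 0:
        scale = 1.0
    return mat + ridge * scale * np.eye(n)


def _eigh_pd(mat: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    w, V = np.linalg.eigh(0.5 * (mat + mat.T))
    if w.min() <= 0:
        raise np.linalg.LinAlgError(
            "matrix is not positive definite (after ridging); increase the ridge"
        )
    return w, V


def _sym_fun(mat: np.ndarray, fun) -> np.ndarray:
    """Spectral function of a symmetric matrix (no definiteness assumed)."""
    w, V = np.linalg.eigh(0.5 * (mat + mat.T))
    return (V * fun(w)) @ V.T


def _logm_pd(mat: np.ndarray) -> np.ndarray:
    w, V = _eigh_pd(mat)
    return (V * np.log(w)) @ V.T


def spd_distance(
    A: GramMatrix | np.ndarray,
    B: GramMatrix | np.ndarray,
    ridge: float = 0.0,
) -> float:
    """Affine-invariant Riemannian distance between SPD matrices.

    ``d_P(A, B) = ||log(A^{-1/2} B A^{-1/2})||_F``; invariant to congruence
    ``(A, B) -> (G A G^T, G B G^T)`` and to joint inversion.
    """
    Av = A.values if isinstance(A, GramMatrix) else np.asarray(A, dtype=float)
    Bv = B.values if isinstance(B, GramMatrix) else np.asarray(B, dtype=float)
    if ridge > 0:
        Av, Bv = _ridged(Av, ridge), _ridged(Bv, ridge)
    w, V = _eigh_pd(Av)
    inv_sqrt = (V / np.sqrt(w)) @ V.T
    M = inv_sqrt @ Bv @ inv_sqrt
    mw, _ = _eigh_pd(M)
    return float(np.sqrt(np.sum(np.log(mw) ** 2)))


def karcher_mean(
    gram_list: Sequence[GramMatrix],
    cfg: SPDConfig = SPDConfig(),
) -> tuple[GramMatrix, KarcherReport]:
    """Karcher mean of PSD matrices by the Riemannian fixed-point iteration.

    Inputs are ridged to strict positive definiteness, the iteration starts at
    the arithmetic mean, and each step is

    ``X <- X^{1/2} exp( theta * (1/m) sum_i log(X^{-1/2} K_i X^{-1/2}) ) X^{1/2}``.

    The step ``theta`` starts at 1 (the plain fixed point) and is halved —
    restarting from the best iterate seen — whenever the tangent norm fails
    to decrease; the unit step oscillates on strongly ill-conditioned inputs
    such as ridged rank-one anomaly kernels. Iteration stops when the
    Frobenius norm of the tangent mean falls below ``cfg.tol`` (relative to
    the first iterate's norm when that exceeds one).
    The report carries the residual of the characteristic matrix equation,
    ``||sum_i log(K_i^{-1} X)||_F``, evaluated through the congruence identity
    ``sum_i log(K_i^{-1} X) = -X^{-1/2} (m T) X^{1/2}`` with ``T`` the tangent
    mean — no extra matrix logarithms are needed.
    """
    mats = [_ridged(m, cfg.ridge) for m in _stack(gram_list)]
    m = len(mats)
    X = sum(mats) / m

    def tangent(Xc: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
        w, V = _eigh_pd(Xc)
        sqrt_Xc = (V * np.sqrt(w)) @ V.T
        inv_sqrt_Xc = (V / np.sqrt(w)) @ V.T
        Tc = np.zeros_like(Xc)
        for K in mats:
            Tc += _logm_pd(inv_sqrt_Xc @ K @ inv_sqrt_Xc)
        Tc = 0.5 * (Tc + Tc.T) / m
        return sqrt_Xc, Tc, float(np.linalg.norm(Tc))

    history: list[float] = []
    converged = False
    theta = 1.0
    sqrt_X, T, tnorm = tangent(X)
    history.append(tnorm)
    tol_abs = cfg.tol * max(1.0, tnorm)
    best = (tnorm, X, sqrt_X, T)
    it = 0
    while history[-1] > tol_abs and it < cfg.max_iter:
        it += 1
        if tnorm > best[0]:
            # overshoot: damp the step and restart from the best iterate
            theta *= 0.5
            _, X, sqrt_X, T = best
        else:
            best = (tnorm, X, sqrt_X, T)
        X = sqrt_X @ _sym_fun(theta * T, np.exp) @ sqrt_X
        X = 0.5 * (X + X.T)
        sqrt_X, T, tnorm = tangent(X)
        history.append(tnorm)
    if history[-1] <= tol_abs:
        converged = True
    elif best[0] < tnorm:
        # return the best iterate seen rather than the last overshoot
        tnorm, X, sqrt_X, T = best

    w, V = _eigh_pd(X)
    inv_sqrt_X = (V / np.sqrt(w)) @ V.T
    sqrt_X = (V * np.sqrt(w)) @ V.T
    residual = float(m * np.linalg.norm(inv_sqrt_X @ T @ sqrt_X))
    if not converged:
        warnings.warn(
            f"Karcher mean did not reach tol={cfg.tol:g} in {cfg.max_iter} "
            f"iterations (tangent norm {tnorm:.3e}); returning best iterate",
            RuntimeWarning,
            stacklevel=2,
        )
    report = KarcherReport(
        converged=converged,
        n_iter=it,
        tangent_norm=tnorm,
        residual=residual,
        history=history,
    )
    return GramMatrix(values=X, kernel="derived"), report
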