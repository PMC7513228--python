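"""Synthetic data generators for the simulation studies.

Three designs:

* **functional mixture** — Gaussian-process curves
  ``X(t) = xi_1 sin(pi t) + xi_2 sin(2 pi t) + eps(t)`` on [0, 1] with inlier
  coefficients ``xi ~ N((1, 2), I)``, a known contamination fraction ``nu``
  of outlier curves whose coefficients are shifted to mean ``(4, 5)``, and
  per-curve stationary AR(1) observation noise;
* **conditionally normal bivariate** — regular points Gibbs-sampled from the
  conditionally specified family with joint density proportional to
  ``exp(-0.5 * (a x^2 y^2 + x^2 + y^2 - 2 b x y))`` (both full conditionals
  are normal), contaminated with three unit-variance Gaussian clusters away
  from the regular mode;
* **harmonic model** — noiseless curves ``X(t) = xi_1 sin(t) + xi_2 cos(t)``
  on [0, pi] with ``xi ~ N(0, [[0.75, -0.5], [-0.5, 0.75]])``, replicated to
  study the robustness of the Karcher mean of estimated coefficient
  covariances against one anomalous covariance matrix.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
from scipy.stats import chi2

from .combine import SPDConfig, karcher_mean, spd_distance
from .functional import FunctionalSample
from .kernels import GramMatrix

__all__ = [
    "FunctionalSimConfig",
    "ConditionalGaussianConfig",
    "HarmonicSimConfig",
    "EllipseParams",
    "RobustnessReport",
    "simulate_functional",
    "simulate_conditional_gaussian",
    "simulate_harmonic",
    "ellipse_params",
    "nearest_pd",
    "robustness_experiment",
]


@dataclass
class FunctionalSimConfig:
    """Functional mixture design: n curves, contamination nu, AR(1) noise."""

    n: int = 4000
    nu: float = 0.1
    grid: np.ndarray = field(default_factory=lambda: np.linspace(0.0, 1.0, 30))
    mu_inlier: tuple[float, float] = (1.0, 2.0)
    mu_outlier: tuple[float, float] = (4.0, 5.0)
    coef_cov: np.ndarray = field(default_factory=lambda: np.eye(2))
    error_sd: float = 0.3
    error_corr: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.nu < 1:
            raise ValueError("nu must lie in (0, 1)")
        if not 0 <= self.error_corr < 1:
            raise ValueError("error_corr must lie in [0, 1)")
        self.grid = np.asarray(self.grid, dtype=float).ravel()
        self.coef_cov = np.asarray(self.coef_cov, dtype=float)

    def to_metadata(self) -> dict:
        d = asdict(self)
        d["grid"] = self.grid.tolist()
        d["coef_cov"] = self.coef_cov.tolist()
        return d


def _ar1_noise(
    rng: np.random.Generator, n: int, p: int, sd: float, rho: float
) -> np.ndarray:
    """Stationary AR(1) rows: marginal sd ``sd``, lag-one correlation ``rho``."""
    if sd == 0:
        return np.zeros((n, p))
    e = np.empty((n, p))
    e[:, 0] = rng.normal(0.0, sd, size=n)
    innov_sd = sd * np.sqrt(1.0 - rho**2)
    for t in range(1, p):
        e[:, t] = rho * e[:, t - 1] + rng.normal(0.0, innov_sd, size=n)
    return e


def simulate_functional(cfg: FunctionalSimConfig) -> FunctionalSample:
    """Draw the functional mixture; exactly ``floor(nu * n)`` outlier curves."""
    rng = np.random.default_rng(cfg.seed)
    n_out = int(np.floor(cfg.nu * cfg.n))
    n_in = cfg.n - n_out
    basis = np.stack(
        [np.sin(np.pi * cfg.grid), np.sin(2.0 * np.pi * cfg.grid)]
    )  # 2 x p
    xi = rng.multivariate_normal(cfg.mu_inlier, cfg.coef_cov, size=n_in)
    zeta = rng.multivariate_normal(cfg.mu_outlier, cfg.coef_cov, size=n_out)
    coeffs = np.vstack([xi, zeta])
    curves = coeffs @ basis + _ar1_noise(
        rng, cfg.n, cfg.grid.size, cfg.error_sd, cfg.error_corr
    )
    labels = np.r_[np.zeros(n_in, dtype=int), np.ones(n_out, dtype=int)]
    perm = rng.permutation(cfg.n)
    return FunctionalSample(grid=cfg.grid, curves=curves[perm], labels=labels[perm])


@dataclass
class ConditionalGaussianConfig:
    """Conditionally specified bivariate family plus three outlier clusters.

    Full conditionals of the regular-data density are
    ``x | y ~ N(b y / (1 + a y^2), 1 / (1 + a y^2))`` and symmetrically in
    ``y | x``; ``a = 0, b = 0`` degenerates to two independent standard
    normals.
    """

    n: int = 1000
    contamination: float = 0.1
    a: float = 1.0
    b: float = 0.5
    centers: np.ndarray = field(
        default_factory=lambda: np.array([[5.0, 0.0], [-4.0, 4.0], [0.0, -5.0]])
    )
    burnin: int = 500
    thin: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.contamination < 1:
            raise ValueError("contamination must lie in [0, 1)")
        if self.burnin < 10 or self.thin < 1:
            warnings.warn(
                "very short burn-in/thinning: the Gibbs chain may not have mixed",
                RuntimeWarning,
                stacklevel=2,
            )
        self.centers = np.atleast_2d(np.asarray(self.centers, dtype=float))


def simulate_conditional_gaussian(
    cfg: ConditionalGaussianConfig,
) -> tuple[np.ndarray, np.ndarray]:
    """Gibbs-sample the regular points, add Gaussian outlier clusters.

    Returns ``(X, labels)`` with ``floor(contamination * n)`` outliers drawn
    round-robin from the unit-variance clusters at ``cfg.centers``.
    """
    rng = np.random.default_rng(cfg.seed)
    n_out = int(np.floor(cfg.contamination * cfg.n))
    n_reg = cfg.n - n_out

    x, y = 0.0, 0.0
    draws = np.empty((n_reg, 2))
    total = cfg.burnin + n_reg * cfg.thin
    kept = 0
    for step in range(total):
        prec_x = 1.0 + cfg.a * y * y
        x = rng.normal(cfg.b * y / prec_x, 1.0 / np.sqrt(prec_x))
        prec_y = 1.0 + cfg.a * x * x
        y = rng.normal(cfg.b * x / prec_y, 1.0 / np.sqrt(prec_y))
        if step >= cfg.burnin and (step - cfg.burnin) % cfg.thin == cfg.thin - 1:
            draws[kept] = (x, y)
            kept += 1
    assert kept == n_reg

    clusters = cfg.centers[np.arange(n_out) % len(cfg.centers)]
    outliers = clusters + rng.normal(size=(n_out, 2))
    X = np.vstack([draws, outliers])
    labels = np.r_[np.zeros(n_reg, dtype=int), np.ones(n_out, dtype=int)]
    perm = rng.permutation(cfg.n)
    return X[perm], labels[perm]


@dataclass
class HarmonicSimConfig:
    """Replicated harmonic curves for the covariance-robustness study."""

    n: int = 100
    replicates: int = 10
    cov: np.ndarray = field(
        default_factory=lambda: np.array([[0.75, -0.5], [-0.5, 0.75]])
    )
    cov_anomalous: np.ndarray = field(
        default_factory=lambda: np.array([[7.5, -10.0], [-10.0, 7.5]])
    )
    grid: np.ndarray = field(default_factory=lambda: np.linspace(0.0, np.pi, 50))
    seed: int = 0

    def __post_init__(self) -> None:
        self.cov = np.asarray(self.cov, dtype=float)
        self.cov_anomalous = np.asarray(self.cov_anomalous, dtype=float)
        self.grid = np.asarray(self.grid, dtype=float).ravel()
        if np.linalg.eigvalsh(self.cov).min() <= 0:
            raise ValueError("cov must be positive definite")


def _harmonic_basis(grid: np.ndarray) -> np.ndarray:
    return np.stack([np.sin(grid), np.cos(grid)])  # 2 x p


def _ml_cov(coeffs: np.ndarray) -> np.ndarray:
    """Maximum-likelihood covariance (centered, divisor n)."""
    n = coeffs.shape[0]
    if n < 3:
        warnings.warn(
            "covariance estimate from fewer than 3 curves is rank deficient",
            RuntimeWarning,
            stacklevel=2,
        )
    c = coeffs - coeffs.mean(axis=0)
    return (c.T @ c) / n


def project_coefficients(fs: FunctionalSample) -> np.ndarray:
    """Least-squares projection of curves onto the (sin t, cos t) pair."""
    B = _harmonic_basis(fs.grid)
    coef, *_ = np.linalg.lstsq(B.T, fs.curves.T, rcond=None)
    return coef.T


def simulate_harmonic(
    cfg: HarmonicSimConfig,
) -> tuple[list[FunctionalSample], list[np.ndarray]]:
    """Independent replicates of the harmonic model with their ML covariances."""
    rng = np.random.default_rng(cfg.seed)
    B = _harmonic_basis(cfg.grid)
    samples, covs = [], []
    for _ in range(cfg.replicates):
        xi = rng.multivariate_normal(np.zeros(2), cfg.cov, size=cfg.n)
        fs = FunctionalSample(grid=cfg.grid, curves=xi @ B)
        samples.append(fs)
        covs.append(_ml_cov(project_coefficients(fs)))
    return samples, covs


@dataclass
class EllipseParams:
    """Axes and orientation of a chi-square confidence ellipse in the plane."""

    lambda1: float
    lambda2: float
    theta: float
    level: float = 0.99

    @property
    def axis_lengths(self) -> tuple[float, float]:
        q = chi2.ppf(self.level, df=2)
        return float(np.sqrt(self.lambda1 * q)), float(np.sqrt(self.lambda2 * q))


def ellipse_params(cov_hat: np.ndarray, level: float = 0.99) -> EllipseParams:
    """Eigen-structure of a 2x2 covariance as a confidence-ellipse description.

    ``theta`` is the angle of the leading eigenvector against the first
    coordinate axis, normalized into ``(-pi/2, pi/2]``.
    """
    cov_hat = np.asarray(cov_hat, dtype=float)
    if cov_hat.shape != (2, 2):
        raise ValueError("covariance must be 2x2")
    w, V = np.linalg.eigh(0.5 * (cov_hat + cov_hat.T))
    if w.min() <= 0:
        raise ValueError("covariance must be positive definite")
    lam1, lam2 = float(w[1]), float(w[0])
    v = V[:, 1]
    theta = float(np.arctan2(v[1], v[0]))
    if theta <= -np.pi / 2:
        theta += np.pi
    elif theta > np.pi / 2:
        theta -= np.pi
    return EllipseParams(lambda1=lam1, lambda2=lam2, theta=theta, level=level)


def nearest_pd(mat: np.ndarray, floor: float = 1e-3) -> np.ndarray:
    """Symmetric projection with eigenvalues floored at ``floor``."""
    mat = 0.5 * (np.asarray(mat, dtype=float) + np.asarray(mat, dtype=float).T)
    w, V = np.linalg.eigh(mat)
    return (V * np.maximum(w, floor)) @ V.T


@dataclass
class RobustnessReport:
    """Mean-vs-Karcher displacement of covariance averages under contamination."""

    mean_clean: np.ndarray
    karcher_clean: np.ndarray
    mean_contaminated: np.ndarray
    karcher_contaminated: np.ndarray
    mean_displacement: float
    karcher_displacement: float
    ellipses_clean: list[EllipseParams]
    contaminant: np.ndarray
    contaminant_projected: bool


def robustness_experiment(
    cfg: HarmonicSimConfig,
    contaminant: np.ndarray | None = None,
    spd: SPDConfig = SPDConfig(),
) -> RobustnessReport:
    """Compare arithmetic and Karcher means of replicate covariances.

    Estimates one coefficient covariance per replicate, averages them
    arithmetically and on the SPD manifold, then repeats with one anomalous
    covariance appended and reports each mean's affine-invariant displacement.
    A non-PD contaminant (the default anomalous covariance has a negative
    eigenvalue) is projected to the nearest PD matrix with a warning.
    """
    _, covs = simulate_harmonic(cfg)
    C = cfg.cov_anomalous if contaminant is None else np.asarray(contaminant, float)
    projected = False
    if np.linalg.eigvalsh(0.5 * (C + C.T)).min() <= 0:
        warnings.warn(
            "anomalous covariance is not positive definite; "
            "projecting to the nearest PD matrix",
            RuntimeWarning,
            stacklevel=2,
        )
        C = nearest_pd(C)
        projected = True

    def _means(mats: list[np.ndarray]) -> tuple[np.ndarray, np.ndarray]:
        arith = sum(mats) / len(mats)
        kar, _ = karcher_mean([GramMatrix(m) for m in mats], spd)
        return arith, kar.values

    mean_clean, kar_clean = _means(covs)
    mean_cont, kar_cont = _means(covs + [C])
    return RobustnessReport(
        mean_clean=mean_clean,
        karcher_clean=kar_clean,
        mean_contaminated=mean_cont,
        karcher_contaminated=kar_cont,
        mean_displacement=spd_distance(mean_clean, mean_cont),
        karcher_displacement=spd_distance(kar_clean, kar_cont),
        ellipses_clean=[ellipse_params(c) for c in covs],
        contaminant=C,
        contaminant_projected=projected,
    )
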