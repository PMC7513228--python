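"""Finite-dimensional representation of sampled curves.

A curve observed on a grid is smoothed by kernel ridge regression in the RKHS
of a smoother kernel (the representer solution ``c = (K + n*gamma*I)^{-1} y``
on the grid) and then projected onto the leading eigenvectors of the
smoother's grid Gram matrix — the empirical surrogate for the eigenfunctions
of the kernel's integral operator. The projection coefficients are the
finite-dimensional representation that feeds the multivariate detection
pipeline; the detection pipeline may equally consume the raw grid values.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist

from .kernels import KernelSpec, gram

__all__ = [
    "FunctionalSample",
    "RepresentationConfig",
    "default_smoother",
    "represent",
    "reconstruct",
    "read_wide_csv",
    "write_wide_csv",
    "read_long_csv",
    "write_long_csv",
]


@dataclass
class FunctionalSample:
    """Curves sampled on a shared, strictly increasing grid."""

    grid: np.ndarray
    curves: np.ndarray
    labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float).ravel()
        self.curves = np.atleast_2d(np.asarray(self.curves, dtype=float))
        if np.any(np.diff(self.grid) <= 0):
            raise ValueError("grid must be strictly increasing")
        if self.curves.shape[1] != self.grid.size:
            raise ValueError("curves must have one column per grid point")
        if np.isnan(self.curves).any():
            raise ValueError("curves contain missing values")
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=int).ravel()
            if self.labels.size != self.curves.shape[0]:
                raise ValueError("one label per curve required")

    @property
    def n_curves(self) -> int:
        return self.curves.shape[0]


@dataclass(frozen=True)
class RepresentationConfig:
    """Smoother kernel, ridge penalty ``gamma`` and eigenbasis truncation."""

    smoother: KernelSpec | None = None  # None -> median-distance Gaussian
    gamma: float = 1e-3
    n_components: int = 10

    def __post_init__(self) -> None:
        if self.gamma <= 0:
            raise ValueError("gamma must be positive")
        if self.n_components < 1:
            raise ValueError("n_components must be >= 1")


def default_smoother(grid: np.ndarray) -> KernelSpec:
    """Gaussian smoother with width set by the median pairwise grid distance."""
    grid = np.asarray(grid, dtype=float).ravel()
    if grid.size < 2:
        return KernelSpec("gaussian", sigma=1.0)
    med = float(np.median(pdist(grid[:, None])))
    return KernelSpec("gaussian", sigma=1.0 / max(med, np.finfo(float).eps) ** 2)


def _basis(cfg: RepresentationConfig, grid: np.ndarray) -> tuple[np.ndarray, KernelSpec]:
    grid = np.asarray(grid, dtype=float).ravel()
    smoother = cfg.smoother or default_smoother(grid)
    K = gram(smoother, grid[:, None]).values
    q = min(cfg.n_components, grid.size)
    w, V = np.linalg.eigh(K)
    order = np.argsort(w)[::-1][:q]
    V = V[:, order]
    # deterministic sign: largest-magnitude component of each eigenvector positive
    for j in range(V.shape[1]):
        i = np.argmax(np.abs(V[:, j]))
        if V[i, j] < 0:
            V[:, j] = -V[:, j]
    return V, smoother


def represent(fs: FunctionalSample, cfg: RepresentationConfig) -> np.ndarray:
    """Coefficients of each curve in the smoother's leading eigenbasis.

    Each curve is first fitted by kernel ridge regression on the grid
    (``n`` = number of grid points in the penalty, matching the empirical-risk
    normalization), then the fitted values are projected onto the leading
    ``n_components`` eigenvectors of the smoother's grid Gram matrix.
    """
    V, smoother = _basis(cfg, fs.grid)
    K = gram(smoother, fs.grid[:, None]).values
    n = fs.grid.size
    C = np.linalg.solve(K + n * cfg.gamma * np.eye(n), fs.curves.T)
    fitted = (K @ C).T  # n_curves x n_grid
    return fitted @ V


def reconstruct(
    coeffs: np.ndarray, cfg: RepresentationConfig, grid: np.ndarray
) -> np.ndarray:
    """Curves rebuilt from eigenbasis coefficients on the grid."""
    coeffs = np.atleast_2d(np.asarray(coeffs, dtype=float))
    V, _ = _basis(cfg, grid)
    if coeffs.shape[1] != V.shape[1]:
        raise ValueError("coefficient count must equal n_components")
    return coeffs @ V.T


# --- CSV I/O ----------------------------------------------------------------


def write_wide_csv(fs: FunctionalSample, path: str | Path) -> None:
    """One row per curve, one column per grid point (grid in the header)."""
    cols = [f"{t:.12g}" for t in fs.grid]
    df = pd.DataFrame(fs.curves, columns=cols)
    if fs.labels is not None:
        df.insert(0, "label", fs.labels)
    df.to_csv(path, index=False)


def read_wide_csv(path: str | Path) -> FunctionalSample:
    df = pd.read_csv(path)
    labels = None
    if "label" in df.columns:
        labels = df.pop("label").to_numpy(dtype=int)
    grid = np.array([float(c) for c in df.columns])
    return FunctionalSample(grid=grid, curves=df.to_numpy(dtype=float), labels=labels)


def write_long_csv(fs: FunctionalSample, path: str | Path) -> None:
    """Tidy format: columns ``curve_id, t, value`` (plus ``label`` if known)."""
    n, p = fs.curves.shape
    df = pd.DataFrame(
        {
            "curve_id": np.repeat(np.arange(n), p),
            "t": np.tile(fs.grid, n),
            "value": fs.curves.ravel(),
        }
    )
    if fs.labels is not None:
        df["label"] = np.repeat(fs.labels, p)
    df.to_csv(path, index=False)


def read_long_csv(path: str | Path) -> FunctionalSample:
    df = pd.read_csv(path)
    wide = df.pivot(index="curve_id", columns="t", values="value").sort_index()
    grid = wide.columns.to_numpy(dtype=float)
    labels = None
    if "label" in df.columns:
        labels = (
            df.drop_duplicates("curve_id").set_index("curve_id").sort_index()["label"]
        ).to_numpy(dtype=int)
    return FunctionalSample(
        grid=grid, curves=wide.to_numpy(dtype=float), labels=labels
    )
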