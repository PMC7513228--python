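"""Scores, contamination-calibrated thresholding, and TPR/TNR/AUC metrics.

The combined anomaly kernel concentrates regular points near the origin of
its feature space, so a point's anomaly score is its squared feature-space
norm — the diagonal of the combined Gram matrix. With the contamination rate
``nu`` known a priori, the detector flags the top ``ceil(nu * n)`` training
scores; the threshold (the largest unflagged training score) transfers to new
data.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.metrics import roc_auc_score

from .kernels import GramMatrix

__all__ = [
    "DetectionResult",
    "Metrics",
    "score_from_kernel",
    "scores_from_features",
    "threshold_by_contamination",
    "flags_top",
    "evaluate",
]


@dataclass
class DetectionResult:
    """Scores (higher = more anomalous), threshold, 0/1 flags, contamination."""

    scores: np.ndarray
    threshold: float
    flags: np.ndarray
    nu: float


@dataclass
class Metrics:
    """Percent sensitivity (TPR), specificity (TNR) and ROC AUC."""

    tpr: float | None = None
    tnr: float | None = None
    auc: float | None = None

    def as_dict(self) -> dict:
        return {"tpr": self.tpr, "tnr": self.tnr, "auc": self.auc}


def score_from_kernel(g: GramMatrix) -> np.ndarray:
    """Diagonal of a combined anomaly kernel: squared feature-space norms."""
    return np.diag(g.values).copy()


def scores_from_features(F_values: np.ndarray, lambdas: np.ndarray) -> np.ndarray:
    """Scores of a weighted rank-one combination without the n x n matrix.

    ``diag(sum_j lambda_j phi_j phi_j^T) = sum_j lambda_j phi_j^2``.
    """
    F_values = np.atleast_2d(np.asarray(F_values, dtype=float))
    return (F_values**2) @ np.asarray(lambdas, dtype=float)


def _flag_count(n: int, nu: float) -> int:
    if not 0 <= nu < 1:
        raise ValueError("contamination nu must lie in [0, 1)")
    return int(math.ceil(nu * n)) if nu > 0 else 0


def threshold_by_contamination(scores_train: np.ndarray, nu: float) -> float:
    """Empirical (1 - nu)-quantile threshold: flags the top ``ceil(nu*n)``.

    Returns the largest unflagged training score, so ``score > threshold``
    reproduces the training flags (ties broken by stable order).
    """
    s = np.asarray(scores_train, dtype=float).ravel()
    n = s.size
    F = _flag_count(n, nu)
    if np.ptp(s) == 0:
        warnings.warn(
            "all scores identical: threshold degenerates to the maximum score",
            RuntimeWarning,
            stacklevel=2,
        )
        return float(s.max())
    if F == 0:
        return float(s.max())
    if F >= n:
        return -np.inf
    order = np.argsort(-s, kind="stable")
    return float(s[order[F]])


def flags_top(scores: np.ndarray, n_flags: int) -> np.ndarray:
    """0/1 flags of the ``n_flags`` highest scores, ties by stable order."""
    s = np.asarray(scores, dtype=float).ravel()
    flags = np.zeros(s.size, dtype=int)
    if n_flags > 0:
        order = np.argsort(-s, kind="stable")
        flags[order[:n_flags]] = 1
    return flags


def detect(scores: np.ndarray, nu: float, threshold: float | None = None) -> DetectionResult:
    """Flag anomalies from scores.

    With ``threshold=None`` the threshold is calibrated on ``scores`` itself
    (training split: exactly ``ceil(nu * n)`` flags). Passing a training
    threshold applies it to a new split via ``score > threshold``.
    """
    s = np.asarray(scores, dtype=float).ravel()
    if threshold is None:
        threshold = threshold_by_contamination(s, nu)
        flags = flags_top(s, _flag_count(s.size, nu))
    else:
        flags = (s > threshold).astype(int)
    return DetectionResult(scores=s, threshold=float(threshold), flags=flags, nu=nu)


def evaluate(
    truth: np.ndarray,
    flags: np.ndarray | None = None,
    scores: np.ndarray | None = None,
) -> Metrics:
    """TPR/TNR (percent) from flags; AUC (percent) from scores.

    Truth codes outliers as 1. AUC is the Mann-Whitney rank statistic (ties
    count one half) and requires both classes in ``truth``.
    """
    truth = np.asarray(truth, dtype=int).ravel()
    out = Metrics()
    P = int((truth == 1).sum())
    N = int((truth == 0).sum())
    if flags is not None:
        flags = np.asarray(flags, dtype=int).ravel()
        if flags.size != truth.size:
            raise ValueError("flags and truth lengths differ")
        if P > 0:
            out.tpr = 100.0 * int(((flags == 1) & (truth == 1)).sum()) / P
        if N > 0:
            out.tnr = 100.0 * int(((flags == 0) & (truth == 0)).sum()) / N
    if scores is not None:
        scores = np.asarray(scores, dtype=float).ravel()
        if scores.size != truth.size:
            raise ValueError("scores and truth lengths differ")
        if P == 0 or N == 0:
            raise ValueError("AUC undefined: truth must contain both classes")
        out.auc = 100.0 * float(roc_auc_score(truth, scores))
    return out
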