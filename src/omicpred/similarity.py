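"""Dataset-level (di)similarity between omic layers.

Each layer is reduced to a configuration of PCA scores; the configurations
are aligned by generalized Procrustes analysis (GPA: iterative translation,
rotation/reflection and isotropic scaling toward a consensus, Gower 1975),
pairwise similarity is the Procrustes correlation 1 - m^2 (m^2 the scaled
residual statistic), and 1 - similarity enters a classical-scaling PCoA.
Predicted-value dissimilarity between predictors is 1 - Pearson r between
hold-out predictions, aggregated as the element-wise median across
cross-validation replicates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.linalg import orthogonal_procrustes

from .datatypes import CVResult, FeatureMatrix

__all__ = [
    "Configuration",
    "DissimilarityMatrix",
    "pca_scores",
    "gpa_align",
    "procrustes_m2",
    "procrustes_dissimilarity",
    "pcoa",
    "predicted_value_distance",
]


@dataclass
class Configuration:
    """PCA score configuration of one omic layer (samples x components)."""

    sample_ids: list[str]
    coordinates: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, float)
        if self.coordinates.shape[0] != len(self.sample_ids):
            raise ValueError("coordinate rows must match sample ids")


@dataclass
class DissimilarityMatrix:
    labels: list[str]
    matrix: np.ndarray
    source: str  # "gpa" | "predicted_value_correlation"

    def __post_init__(self) -> None:
        D = np.asarray(self.matrix, float)
        if not np.allclose(D, D.T, atol=1e-9):
            raise ValueError("dissimilarity matrix must be symmetric")
        if not np.allclose(np.diag(D), 0.0, atol=1e-9):
            raise ValueError("dissimilarity diagonal must be zero")
        if D.min() < -1e-9:
            raise ValueError("dissimilarities must be >= 0")
        self.matrix = np.clip((D + D.T) / 2.0, 0.0, None)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=self.labels, columns=self.labels)


# ---------------------------------------------------------------------------
# PCA scores
# ---------------------------------------------------------------------------

def pca_scores(fm: FeatureMatrix, k: int) -> Configuration:
    """Scores of the top-k principal components of the column-standardized
    matrix, with a deterministic sign convention (the largest-magnitude
    loading of each component is positive)."""
    n = fm.n_samples
    if k > n - 1:
        raise ValueError(f"k must be <= n-1 = {n - 1}, got {k}")
    W = fm.values.to_numpy(float)
    if np.isnan(W).any():
        raise ValueError("feature matrix must be complete (impute first)")
    mu, sd = W.mean(axis=0), W.std(axis=0, ddof=0)
    Wstar = (W - mu) / np.where(sd == 0, 1.0, sd)
    U, S, Vt = np.linalg.svd(Wstar, full_matrices=False)
    for j in range(min(k, S.size)):
        i_max = np.argmax(np.abs(Vt[j]))
        if Vt[j, i_max] < 0:
            Vt[j] *= -1.0
            U[:, j] *= -1.0
    scores = U[:, :k] * S[:k]
    if scores.shape[1] < k:  # rank-deficient: pad with zero columns
        scores = np.hstack([scores, np.zeros((n, k - scores.shape[1]))])
    return Configuration(fm.sample_ids, scores, label=fm.layer)


# ---------------------------------------------------------------------------
# Generalized Procrustes analysis
# ---------------------------------------------------------------------------

def _center_scale(X: np.ndarray) -> np.ndarray:
    Xc = X - X.mean(axis=0)
    norm = np.linalg.norm(Xc)
    if norm == 0:
        raise ValueError("degenerate (all-zero) configuration")
    return Xc / norm


def gpa_align(
    configs: Sequence[Configuration],
    tol: float = 1e-10,
    max_iter: int = 100,
) -> tuple[list[Configuration], Configuration]:
    """Align configurations by translation, rotation (reflections allowed)
    and isotropic scaling to a consensus.

    Configurations with fewer score columns than the widest one are padded
    with zero columns.  Iterates until the consensus residual sum of
    squares changes by less than ``tol`` or ``max_iter`` sweeps.
    """
    if len(configs) < 2:
        raise ValueError("GPA needs at least two configurations")
    ids = configs[0].sample_ids
    for c in configs[1:]:
        if c.sample_ids != ids:
            raise ValueError("configurations must share samples and ordering")
    k = max(c.coordinates.shape[1] for c in configs)
    X = []
    for c in configs:
        coords = c.coordinates
        if coords.shape[1] < k:
            coords = np.hstack([coords, np.zeros((coords.shape[0], k - coords.shape[1]))])
        X.append(_center_scale(coords))
    m = len(X)
    consensus = np.mean(X, axis=0)
    prev_rss = np.inf
    for _ in range(max_iter):
        for i in range(m):
            R, _ = orthogonal_procrustes(X[i], consensus)
            X[i] = X[i] @ R
        # isotropic scaling under the constraint sum_i ||rho_i X_i||^2 = m
        consensus = np.mean(X, axis=0)
        inner = np.array([np.sum(x * consensus) for x in X])
        norms2 = np.array([np.sum(x * x) for x in X])
        rho = np.sqrt(m / np.sum(inner**2 / norms2)) * inner / norms2
        X = [r * x for r, x in zip(rho, X)]
        consensus = np.mean(X, axis=0)
        rss = sum(np.sum((x - consensus) ** 2) for x in X)
        if abs(prev_rss - rss) < tol:
            break
        prev_rss = rss
    aligned = [
        Configuration(ids, x, label=c.label) for x, c in zip(X, configs)
    ]
    return aligned, Configuration(ids, consensus, label="consensus")


def procrustes_m2(a: np.ndarray, b: np.ndarray) -> float:
    """Scaled Procrustes residual m^2 in [0, 1] between two configurations.

    Both are centered and scaled to unit Frobenius norm; after the optimal
    rotation (reflections allowed) and scaling,
    m^2 = 1 - (sum of singular values of A^T B)^2.
    """
    A, B = _center_scale(np.asarray(a, float)), _center_scale(np.asarray(b, float))
    if A.shape[1] != B.shape[1]:
        k = max(A.shape[1], B.shape[1])
        A = np.hstack([A, np.zeros((A.shape[0], k - A.shape[1]))])
        B = np.hstack([B, np.zeros((B.shape[0], k - B.shape[1]))])
    s = np.linalg.svd(A.T @ B, compute_uv=False)
    return float(max(0.0, 1.0 - s.sum() ** 2))


def procrustes_dissimilarity(configs: Sequence[Configuration]) -> DissimilarityMatrix:
    """Pairwise 1 - similarity with similarity the Procrustes correlation
    1 - m^2; the result lives in [0, 1]."""
    m = len(configs)
    D = np.zeros((m, m))
    for i in range(m):
        for j in range(i + 1, m):
            m2 = procrustes_m2(configs[i].coordinates, configs[j].coordinates)
            D[i, j] = D[j, i] = m2  # 1 - (1 - m^2)
    return DissimilarityMatrix(
        labels=[c.label for c in configs], matrix=D, source="gpa"
    )


# ---------------------------------------------------------------------------
# Principal coordinates analysis (classical scaling)
# ---------------------------------------------------------------------------

def pcoa(
    d: DissimilarityMatrix, n_axes: Optional[int] = None
) -> tuple[pd.DataFrame, pd.Series]:
    """Classical scaling of a dissimilarity matrix.

    Double-centers -1/2 D^2, eigendecomposes, drops negative eigenvalues
    (with a warning when they are non-trivial), and reports the percent of
    variance per retained axis over the positive eigenvalues.
    """
    D = d.matrix
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D**2) @ J
    vals, vecs = np.linalg.eigh((B + B.T) / 2.0)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    tol = max(1e-12, 1e-10 * max(abs(vals[0]), 1.0))
    neg = vals < -tol
    if neg.any():
        warnings.warn(
            f"dropping {int(neg.sum())} negative PCoA eigenvalues "
            f"(most negative {vals[neg].min():.3g})",
            stacklevel=2,
        )
    pos = np.flatnonzero(vals > tol)
    if n_axes is None:
        n_axes = pos.size
    if n_axes > pos.size:
        warnings.warn(
            f"only {pos.size} positive eigenvalues; truncating n_axes", stacklevel=2
        )
        n_axes = pos.size
    take = pos[:n_axes]
    coords = vecs[:, take] * np.sqrt(vals[take])
    percent = 100.0 * vals[take] / vals[pos].sum() if pos.size else np.array([])
    axes = [f"PCo{i + 1}" for i in range(len(take))]
    return (
        pd.DataFrame(coords, index=d.labels, columns=axes),
        pd.Series(percent, index=axes, name="percent_variance"),
    )


# ---------------------------------------------------------------------------
# Predicted-value distance
# ---------------------------------------------------------------------------

def predicted_value_distance(cv_results: dict[str, CVResult]) -> DissimilarityMatrix:
    """Correlation-based distance between predictors' hold-out predictions.

    Per CV replicate, the hold-out predictions of each predictor are
    concatenated over folds into one vector per sample; the pairwise
    distance is 1 - Pearson r, and the element-wise median across
    replicates is returned.  Predictors must have been cross-validated with
    shared fold partitions.  A constant prediction vector is treated as
    r = 0 (distance 1) with a warning.
    """
    labels = list(cv_results)
    first = cv_results[labels[0]]
    if first.predictions is None:
        raise ValueError("run cross_validate with keep_predictions=True")
    n_rep = first.predictions.shape[0]
    for lab in labels[1:]:
        cv = cv_results[lab]
        if cv.predictions is None or cv.predictions.shape != first.predictions.shape:
            raise ValueError(f"predictor {lab!r} has incompatible predictions")
        if cv.sample_ids != first.sample_ids:
            raise ValueError("predictors cover different samples")
    m = len(labels)
    per_rep = np.zeros((n_rep, m, m))
    flagged = 0
    for r in range(n_rep):
        vecs = [cv_results[lab].predictions[r] for lab in labels]
        sds = [v.std() for v in vecs]
        for i in range(m):
            for j in range(i + 1, m):
                if sds[i] == 0 or sds[j] == 0:
                    flagged += 1
                    dist = 1.0
                else:
                    dist = 1.0 - float(np.corrcoef(vecs[i], vecs[j])[0, 1])
                per_rep[r, i, j] = per_rep[r, j, i] = dist
    if flagged:
        warnings.warn(
            f"{flagged} constant prediction vectors treated as r=0", stacklevel=2
        )
    D = np.median(per_rep, axis=0)
    np.fill_diagonal(D, 0.0)
    return DissimilarityMatrix(
        labels=labels, matrix=D, source="predicted_value_correlation"
    )
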