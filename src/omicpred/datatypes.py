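"""Core data containers shared across the pipeline.

Feature matrices are oriented samples x features (inbred lines in rows),
with ``NaN`` as the single missing-value sentinel.  Relationship kernels
are dense n x n symmetric matrices tagged with the omic layer and the
number of features they were built from.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

#: Omic-layer tags used throughout (seedling = ``_s``, leaf = ``_l``).
LAYERS = (
    "SNP", "SV", "dSV", "tSV",
    "ePAV_s", "ePAV_l", "ePAV_ls",
    "GE_s", "GE_l", "TE_s", "TE_l",
    "M",
)


@dataclass
class FeatureMatrix:
    """Numeric samples x features matrix for one omic layer.

    Parameters
    ----------
    values
        DataFrame with sample ids as index and feature ids as columns;
        missing entries are ``NaN``.
    layer
        Omic-layer tag (free-form, but see :data:`LAYERS`).
    feature_meta
        Optional per-feature metadata indexed by feature id (e.g. gene id,
        within-gene position, SIFT score).
    """

    values: pd.DataFrame
    layer: str
    feature_meta: Optional[pd.DataFrame] = None

    def __post_init__(self) -> None:
        idx, cols = self.values.index, self.values.columns
        if idx.duplicated().any():
            dup = idx[idx.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample ids: {dup}")
        if cols.duplicated().any():
            dup = cols[cols.duplicated()].unique().tolist()
            raise ValueError(f"duplicate feature ids: {dup}")
        if self.feature_meta is not None:
            missing = cols.difference(self.feature_meta.index)
            if len(missing):
                raise ValueError(
                    f"feature_meta lacks {len(missing)} feature ids "
                    f"(e.g. {missing[:3].tolist()})"
                )

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    @property
    def missing_mask(self) -> pd.DataFrame:
        return self.values.isna()

    def subset_features(self, feature_ids: Sequence[str]) -> "FeatureMatrix":
        meta = None
        if self.feature_meta is not None:
            meta = self.feature_meta.loc[list(feature_ids)]
        return FeatureMatrix(self.values[list(feature_ids)].copy(), self.layer, meta)

    def with_layer(self, layer: str) -> "FeatureMatrix":
        return FeatureMatrix(self.values, layer, self.feature_meta)


@dataclass
class Kernel:
    """Additive relationship matrix G = W* W*^T / m for one omic layer."""

    sample_ids: list[str]
    matrix: np.ndarray
    m: int
    layer: str

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        n = len(self.sample_ids)
        if self.matrix.shape != (n, n):
            raise ValueError(f"kernel shape {self.matrix.shape} != ({n}, {n})")
        if not np.allclose(self.matrix, self.matrix.T, atol=1e-10):
            raise ValueError("kernel is not symmetric")

    @property
    def n(self) -> int:
        return len(self.sample_ids)

    def restrict(self, ids: Sequence[str]) -> "Kernel":
        """Sub-kernel over ``ids`` in the given order."""
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        try:
            take = [pos[s] for s in ids]
        except KeyError as e:
            raise KeyError(f"sample {e.args[0]!r} not in kernel") from None
        return Kernel(list(ids), self.matrix[np.ix_(take, take)], self.m, self.layer)

    def cross(self, rows: Sequence[str], cols: Sequence[str]) -> np.ndarray:
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        r = [pos[s] for s in rows]
        c = [pos[s] for s in cols]
        return self.matrix[np.ix_(r, c)]

    def min_eigenvalue(self) -> float:
        return float(np.linalg.eigvalsh((self.matrix + self.matrix.T) / 2.0)[0])


@dataclass
class GeneModel:
    """Gene span on a chromosome, 1-based inclusive coordinates."""

    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.gene_id}: strand must be '+' or '-', got {self.strand!r}")
        if self.end < self.start:
            raise ValueError(f"{self.gene_id}: end ({self.end}) < start ({self.start})")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class VarianceComponents:
    """REML variance components for the replicated phenotype/metabolite models."""

    sigma2_G: float
    sigma2_e: float
    sigma2_E: Optional[float] = None
    sigma2_GxE: Optional[float] = None
    nu_bar: Optional[float] = None
    degenerate: bool = False

    def __post_init__(self) -> None:
        for name in ("sigma2_G", "sigma2_e", "sigma2_E", "sigma2_GxE", "nu_bar"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValueError(f"{name} must be >= 0, got {v}")


@dataclass
class EntryMeans:
    """Adjusted entry means (genotype fixed) and their variance-covariance."""

    trait: str
    means: pd.Series                  # genotype -> adjusted mean
    varcov: pd.DataFrame              # genotypes x genotypes
    model_used: str                   # "multi_env" | "single_env"
    low_replication: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.means.index.equals(self.varcov.index):
            raise ValueError("means and varcov indexed differently")
        C = self.varcov.to_numpy()
        if not np.allclose(C, C.T, atol=1e-8):
            raise ValueError("varcov not symmetric")

    def nu_bar(self) -> float:
        """Mean variance of a difference between two adjusted entry means.

        Averages C_ii + C_jj - 2 C_ij over all unordered genotype pairs.
        """
        C = self.varcov.to_numpy()
        n = C.shape[0]
        if n < 2:
            raise ValueError("need >= 2 genotypes")
        d = np.diag(C)
        # sum_{i<j} (Cii + Cjj - 2Cij) = (n-1) sum_i Cii - (sum(C) - sum_i Cii)
        total = (n - 1) * d.sum() - (C.sum() - d.sum())
        return float(total / (n * (n - 1) / 2))


@dataclass
class GBLUPFit:
    """A fitted single-kernel GBLUP model on a training set."""

    mu_hat: float
    lambda_hat: float                 # residual-to-genetic variance ratio
    u_hat: pd.Series                  # genotypic effect per training sample
    training_ids: list[str]
    alpha: np.ndarray                 # (K_train + lambda I)^{-1} (y - mu)
    sigma2_u: float = float("nan")
    sigma2_e: float = float("nan")


@dataclass
class CVResult:
    """Replicated k-fold cross-validation output for one predictor."""

    abilities: np.ndarray             # (n_replicates, n_folds)
    fold_assignments: np.ndarray      # (n_replicates, n_samples) fold index per sample
    replicate_seeds: list[int]
    sample_ids: list[str]
    predictions: Optional[np.ndarray] = None   # (n_replicates, n_samples) hold-out preds

    @property
    def median_per_replicate(self) -> np.ndarray:
        return np.median(self.abilities, axis=1)

    @property
    def median_of_medians(self) -> float:
        return float(np.median(self.median_per_replicate))


@dataclass
class GridSearchResult:
    """Grid-search summary over weight vectors on the simplex lattice."""

    table: pd.DataFrame               # one row per weight vector + 'ability'
    best_weights: tuple
    best_ability: float
    kernel_layers: list[str]
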