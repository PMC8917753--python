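"""Feature QC and standardized relationship kernels for every omic layer.

The additive relationship matrix for a predictor is G = W* W*^T / m, where
W* is the samples x features matrix with every column centered and scaled
to unit variance.  Population variance (divisor n) is used so that
trace(G) = n exactly and the average diagonal element is 1, the common
GBLUP convention.  The kernel is invariant to any affine recoding of a
feature, so the {0,1} inbred genotype coding is without loss of generality.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import FeatureMatrix, Kernel

__all__ = [
    "qc_filter",
    "impute_mean",
    "build_kernel",
    "classify_sift",
    "call_epav",
    "combine_epav",
    "epav_to_numeric",
    "EPavCalls",
    "QCReport",
    "kernel_from_features",
]

#: SIFT decision boundary: deleterious if score <= 0.05, tolerant if > 0.05.
SIFT_THRESHOLD = 0.05

#: ePAV ambiguity zone: 0 < value < EPAV_NA_FRACTION * per-gene max -> NA.
EPAV_NA_FRACTION = 0.1


@dataclass
class QCReport:
    n_input: int
    n_removed_missing: int
    n_removed_monomorphic: int
    n_retained: int
    removed_missing: list[str] = field(default_factory=list)
    removed_monomorphic: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "n_removed_missing": self.n_removed_missing,
            "n_removed_monomorphic": self.n_removed_monomorphic,
            "n_retained": self.n_retained,
        }


def qc_filter(
    fm: FeatureMatrix, max_missing_rate: float = 0.2
) -> tuple[FeatureMatrix, QCReport]:
    """Drop features with missing rate strictly above the threshold, then
    features monomorphic among their non-missing entries."""
    vals = fm.values
    miss_rate = vals.isna().mean(axis=0)
    high_miss = miss_rate.index[miss_rate > max_missing_rate]
    kept = vals.drop(columns=high_miss)
    variances = kept.var(axis=0, ddof=0)  # NaN-aware; ddof irrelevant for ==0 test
    mono = variances.index[(variances == 0) | variances.isna()]
    kept = kept.drop(columns=mono)
    if kept.shape[1] == 0:
        raise ValueError(
            f"all {fm.n_features} features removed by QC "
            f"({len(high_miss)} high-missing, {len(mono)} monomorphic)"
        )
    report = QCReport(
        n_input=fm.n_features,
        n_removed_missing=len(high_miss),
        n_removed_monomorphic=len(mono),
        n_retained=kept.shape[1],
        removed_missing=list(high_miss),
        removed_monomorphic=list(mono),
    )
    meta = fm.feature_meta.loc[kept.columns] if fm.feature_meta is not None else None
    return FeatureMatrix(kept, fm.layer, meta), report


def impute_mean(fm: FeatureMatrix) -> FeatureMatrix:
    """Replace missing entries by the per-feature mean of observed entries."""
    vals = fm.values
    imputed = vals.fillna(vals.mean(axis=0))
    if imputed.isna().any().any():
        bad = imputed.columns[imputed.isna().any()].tolist()
        raise ValueError(f"features with no observed entries: {bad[:5]}")
    return FeatureMatrix(imputed, fm.layer, fm.feature_meta)


def build_kernel(fm: FeatureMatrix) -> Kernel:
    """G = W* W*^T / m with columns centered and scaled to unit population variance."""
    W = fm.values.to_numpy(float)
    if np.isnan(W).any():
        raise ValueError("feature matrix contains missing values; impute first")
    n, m = W.shape
    if m < 1:
        raise ValueError("kernel needs at least one feature")
    mu = W.mean(axis=0)
    sd = W.std(axis=0, ddof=0)
    if np.any(sd == 0):
        bad = [fm.feature_ids[i] for i in np.flatnonzero(sd == 0)[:5]]
        raise ValueError(f"zero-variance features present (run qc_filter): {bad}")
    Wstar = (W - mu) / sd
    G = (Wstar @ Wstar.T) / m
    G = (G + G.T) / 2.0
    return Kernel(sample_ids=fm.sample_ids, matrix=G, m=m, layer=fm.layer)


def kernel_from_features(
    fm: FeatureMatrix, max_missing_rate: float = 0.2
) -> tuple[Kernel, QCReport]:
    """QC -> mean imputation -> kernel, the standard per-layer path."""
    filtered, report = qc_filter(fm, max_missing_rate)
    return build_kernel(impute_mean(filtered)), report


# ---------------------------------------------------------------------------
# SIFT partition
# ---------------------------------------------------------------------------

def classify_sift(
    fm: FeatureMatrix, score_column: str = "sift_score"
) -> tuple[FeatureMatrix, FeatureMatrix, list[str]]:
    """Partition sequence variants into deleterious (SIFT <= 0.05) and
    tolerant (> 0.05) subsets.

    Variants without a score are excluded from both subsets and returned
    as the third element.
    """
    if fm.feature_meta is None or score_column not in fm.feature_meta.columns:
        raise ValueError(f"feature_meta with a {score_column!r} column is required")
    scores = fm.feature_meta[score_column].reindex(fm.feature_ids)
    unscored = list(scores.index[scores.isna()])
    scored = scores.dropna()
    del_ids = list(scored.index[scored <= SIFT_THRESHOLD])
    tol_ids = list(scored.index[scored > SIFT_THRESHOLD])
    dsv = fm.subset_features(del_ids).with_layer("dSV")
    tsv = fm.subset_features(tol_ids).with_layer("tSV")
    return dsv, tsv, unscored


# ---------------------------------------------------------------------------
# ePAV calling
# ---------------------------------------------------------------------------

@dataclass
class EPavCalls:
    """Presence/absence calls per (sample, gene): 1 present, 0 absent, NaN no call."""

    calls: pd.DataFrame
    tissue: str

    @property
    def sample_ids(self) -> list[str]:
        return list(self.calls.index)


def call_epav(ge: FeatureMatrix, tissue: str) -> EPavCalls:
    """Expression presence/absence variation from gene expression.

    Per gene with column maximum Mx: expression 0 is an absence call,
    values in the open interval (0, 0.1*Mx) get no call (NA), and values
    >= 0.1*Mx are presence calls.  An all-zero gene is absent everywhere.
    """
    vals = ge.values
    arr = vals.to_numpy(float)
    if np.nanmin(arr) < 0:
        raise ValueError("expression must be non-negative")
    mx = np.nanmax(arr, axis=0)
    cut = EPAV_NA_FRACTION * mx
    calls = np.where(arr == 0, 0.0, np.where(arr < cut, np.nan, 1.0))
    calls = np.where(np.isnan(arr), np.nan, calls)
    return EPavCalls(
        calls=pd.DataFrame(calls, index=vals.index, columns=vals.columns),
        tissue=tissue,
    )


def combine_epav(epav_s: EPavCalls, epav_l: EPavCalls) -> EPavCalls:
    """Across-tissue ePAV: present if present in any tissue; absent if every
    available (non-NA) call is absent; NA when no tissue yields a call.

    The gene sets of the two tissues may differ; the union is used, and a
    gene covered by a single tissue keeps that tissue's calls.
    """
    if list(epav_s.calls.index) != list(epav_l.calls.index):
        raise ValueError("tissues must cover the same samples in the same order")
    genes = epav_s.calls.columns.union(epav_l.calls.columns, sort=False)
    a = epav_s.calls.reindex(columns=genes)
    b = epav_l.calls.reindex(columns=genes)
    present = (a == 1) | (b == 1)
    absent = ~present & ((a == 0) | (b == 0))
    combined = np.where(present, 1.0, np.where(absent, 0.0, np.nan))
    return EPavCalls(
        calls=pd.DataFrame(combined, index=a.index, columns=genes), tissue="ls"
    )


def epav_to_numeric(epav: EPavCalls) -> FeatureMatrix:
    """ePAV calls as a numeric 0/1 feature matrix (NA -> missing) ready for
    the standard qc_filter -> impute_mean -> build_kernel path."""
    layer = f"ePAV_{epav.tissue}"
    return FeatureMatrix(epav.calls.copy(), layer)
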