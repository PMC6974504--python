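"""Feature cleaning, stratified splitting, scaling and kNN imputation.

The pipeline order is fixed: clean -> split -> log/centre/scale with
train-derived parameters -> impute.  Scaling parameters are estimated on the
training set only and applied unchanged to the test set, so no information
leaks across the split.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
from sklearn.impute import KNNImputer

from .dataio import PeakTable

logger = logging.getLogger(__name__)


@dataclass
class ScalingParams:
    """Train-derived column transformation: optional natural log, then
    centre by ``means`` and scale by ``sds`` (unit variance)."""

    log_applied: bool
    means: np.ndarray
    sds: np.ndarray

    def __post_init__(self):
        self.means = np.asarray(self.means, float)
        self.sds = np.asarray(self.sds, float)
        if self.means.shape != self.sds.shape:
            raise ValueError("means and sds must have equal length")
        if np.any(self.sds <= 0):
            raise ValueError("all scaling standard deviations must be positive")


@dataclass
class SplitIndices:
    train_idx: np.ndarray
    test_idx: np.ndarray


def clean_features(pt: PeakTable, rsd_max: float = 20.0,
                   missing_max: float = 10.0) -> PeakTable:
    """Retain metabolites with QC RSD < ``rsd_max`` and missing-data
    percentage < ``missing_max`` (both comparisons strict).

    If the table carries no QC metadata the filter cannot be applied; the
    table is returned unchanged with a logged warning (some public studies
    report no QC replicates).
    """
    if pt.qc_rsd is None or pt.perc_missing is None:
        logger.warning("no QC RSD / missingness metadata: cleaning step skipped")
        return pt
    keep = (pt.qc_rsd < rsd_max) & (pt.perc_missing < missing_max)
    if not keep.any():
        raise ValueError(
            f"feature cleaning at RSD<{rsd_max}% and missing<{missing_max}% "
            "removed every metabolite"
        )
    return pt.subset_metabolites(np.nonzero(keep)[0])


def stratified_split(pt: PeakTable, test_fraction: float = 1 / 3,
                     seed: int = 0) -> SplitIndices:
    """Stratified random train/test split (default 2:1).

    Per-class test counts are the rounded class share of the requested test
    size, so train and test class proportions match the full set to within
    one sample.  Deterministic given ``seed``.
    """
    y = pt.class_labels
    rng = np.random.default_rng(seed)
    test_idx = []
    for cls in (0, 1):
        members = np.nonzero(y == cls)[0]
        if members.size < 2:
            raise ValueError(f"class {cls} has fewer than 2 samples")
        n_test = int(round(members.size * test_fraction))
        n_test = min(max(n_test, 1), members.size - 1)
        test_idx.append(rng.choice(members, n_test, replace=False))
    test_idx = np.sort(np.concatenate(test_idx))
    train_idx = np.setdiff1d(np.arange(pt.n_samples), test_idx)
    return SplitIndices(train_idx=train_idx, test_idx=test_idx)


def fit_transform_train(X_train: np.ndarray, log: bool = True
                        ) -> Tuple[np.ndarray, ScalingParams]:
    """Natural-log transform, mean-centre and scale to unit variance.

    Means and standard deviations are computed over the non-missing entries
    of each column; missing entries stay missing (imputation happens after
    scaling).  Non-positive values are incompatible with the log transform
    and raise, naming the offending column.
    """
    X = np.asarray(X_train, float).copy()
    if log:
        bad = np.nonzero(np.any(X <= 0, axis=0, where=~np.isnan(X)))[0]
        if bad.size:
            raise ValueError(
                f"non-positive values in column(s) {bad.tolist()}: "
                "natural log transform requires positive concentrations"
            )
        X = np.log(X)
    means = np.nanmean(X, axis=0)
    sds = np.nanstd(X, axis=0, ddof=1)
    zero = np.nonzero(sds <= 0)[0]
    if zero.size:
        raise ValueError(f"zero variance in column(s) {zero.tolist()}")
    return (X - means) / sds, ScalingParams(log_applied=log, means=means, sds=sds)


def transform_test(X_test: np.ndarray, params: ScalingParams) -> np.ndarray:
    """Apply train-derived log/centre/scale parameters to new samples."""
    X = np.asarray(X_test, float).copy()
    if X.shape[1] != params.means.size:
        raise ValueError(
            f"column count {X.shape[1]} does not match scaling parameters "
            f"({params.means.size})"
        )
    if params.log_applied:
        if np.any(X <= 0, where=~np.isnan(X)):
            raise ValueError("non-positive test values under log transform")
        X = np.log(X)
    return (X - params.means) / params.sds


def knn_impute(X: np.ndarray, k: int = 3) -> np.ndarray:
    """k-nearest-neighbour imputation of missing entries.

    Each missing entry is replaced by the mean of that feature over the k
    nearest samples, with distances computed as Euclidean over mutually
    observed features rescaled for the missing dimensions.  Observed entries
    are returned unchanged.
    """
    X = np.asarray(X, float)
    if not np.isnan(X).any():
        return X.copy()
    if np.isnan(X).all(axis=1).any():
        raise ValueError("a sample has all entries missing; cannot impute")
    if np.isnan(X).all(axis=0).any():
        raise ValueError("a feature has all entries missing; cannot impute")
    if k >= X.shape[0]:
        raise ValueError("k must be smaller than the number of samples")
    return KNNImputer(n_neighbors=k, weights="uniform").fit_transform(X)
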