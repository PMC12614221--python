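"""Batch-balanced training set of averaged expression profiles.

The clustering engine never iterates over raw cells.  Instead, each batch is
partitioned into a large number of small k-means++ groups in PCA space and
the group-mean expression profiles become the working "cells".  This keeps
training balanced across batches, denser than single-cell rows, and separate
from the data the fitted models finally score.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import median_filter
from sklearn.cluster import KMeans

from .data_io import CellMetadata, DataIOError, ExpressionMatrix

__all__ = [
    "HVGResult",
    "PCAModel",
    "TrainingSet",
    "select_hvgs",
    "compute_pca",
    "build_training_set",
    "derive_seed",
]


def derive_seed(global_seed: int, *indices: int) -> int:
    """Deterministic per-subtask seed below 2**31.

    Uses SeedSequence entropy mixing so that (seed, run) pairs give
    well-separated streams while remaining order-independent.
    """
    ss = np.random.SeedSequence([int(global_seed)] + [int(i) for i in indices])
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31 - 1))


@dataclass
class HVGResult:
    """Features ranked most- to least-variable with their trend residuals."""

    feature_ids: np.ndarray
    scores: np.ndarray

    def __post_init__(self) -> None:
        self.feature_ids = np.asarray(self.feature_ids, dtype=object)
        self.scores = np.asarray(self.scores, dtype=float)
        if np.any(np.diff(self.scores) > 1e-12):
            raise ValueError("HVG scores must be non-increasing in rank order")


@dataclass
class PCAModel:
    """Standardization statistics plus loadings/scores of a fitted PCA."""

    means: np.ndarray
    sds: np.ndarray
    loadings: np.ndarray  # features x n_pcs, unit-norm columns
    scores: np.ndarray  # items x n_pcs
    n_pcs: int
    explained_variance: np.ndarray | None = None
    kept_features: np.ndarray | None = None  # mask over input features

    def transform(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if self.kept_features is not None:
            X = X[:, self.kept_features]
        return ((X - self.means) / self.sds) @ self.loadings


@dataclass
class TrainingSet:
    """A x m matrix of group-averaged profiles with batch labels."""

    profiles: np.ndarray
    profile_batch: np.ndarray
    membership: list[np.ndarray]  # per profile: member cell ids
    source_features: np.ndarray

    @property
    def n_profiles(self) -> int:
        return self.profiles.shape[0]

    @property
    def group_sizes(self) -> np.ndarray:
        return np.array([len(m) for m in self.membership])


def select_hvgs(X: ExpressionMatrix, n: int = 2000) -> HVGResult:
    """Rank features by variance in excess of a mean-dependent trend.

    The trend is a running median (31-point window) of per-feature variance
    against per-feature mean on the log scale; features are scored by the
    residual variance - trend(mean) and the top ``n`` are returned.  Ties
    (including the fully degenerate all-equal case) are broken by input
    feature order, making selection deterministic.
    """
    m = X.n_features
    if n > m:
        raise ValueError(f"requested {n} HVGs but matrix has {m} features")
    means = X.values.mean(axis=0)
    variances = X.values.var(axis=0, ddof=1) if X.n_cells > 1 else np.zeros(m)
    order = np.argsort(means, kind="stable")
    # mirror padding: nearest-style edge replication would let an extreme-
    # mean feature dominate its own window and zero its own residual
    trend_sorted = median_filter(variances[order], size=min(31, m), mode="mirror")
    trend = np.empty(m)
    trend[order] = trend_sorted
    resid = variances - trend
    # stable sort on negated residual keeps input order among ties
    rank = np.argsort(-resid, kind="stable")[:n]
    return HVGResult(X.feature_ids[rank], resid[rank])


def compute_pca(
    X: np.ndarray, n_pcs: int = 30, standardize: bool = True
) -> PCAModel:
    """PCA with a deterministic sign convention.

    Data are optionally Z-scored feature-wise (zero-variance features are
    dropped and recorded in ``kept_features``), decomposed by full SVD, and
    each loading column is flipped so its largest-magnitude entry is
    positive.  Scores are standardized data times loadings.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("PCA needs a 2-D matrix with at least 2 rows")
    sds_all = X.std(axis=0, ddof=0)
    keep = sds_all > 1e-12 * np.maximum(1.0, np.abs(X.mean(axis=0)))
    if standardize:
        if not keep.any():
            raise ValueError("no feature with non-zero variance")
        Xk = X[:, keep]
        means = Xk.mean(axis=0)
        sds = Xk.std(axis=0, ddof=0)
    else:
        keep = np.ones(X.shape[1], dtype=bool)
        Xk = X
        means = Xk.mean(axis=0)
        sds = np.ones(Xk.shape[1])
    n_pcs = int(min(n_pcs, min(Xk.shape)))
    Z = (Xk - means) / sds
    _, svals, vt = np.linalg.svd(Z, full_matrices=False)
    loadings = vt[:n_pcs].T
    # sign convention: largest-|entry| of each column positive
    flip = np.sign(loadings[np.argmax(np.abs(loadings), axis=0), np.arange(n_pcs)])
    flip[flip == 0] = 1.0
    loadings = loadings * flip
    scores = Z @ loadings
    expl = (svals[:n_pcs] ** 2) / Z.shape[0]
    return PCAModel(
        means=means,
        sds=sds,
        loadings=loadings,
        scores=scores,
        n_pcs=n_pcs,
        explained_variance=expl,
        kept_features=keep,
    )


def build_training_set(
    X: ExpressionMatrix,
    meta: CellMetadata,
    hvgs: HVGResult,
    n_groups: int = 500,
    n_pcs: int = 30,
    seed: int = 0,
) -> TrainingSet:
    """Average batch-wise k-means++ groups into training profiles.

    PCA is fitted once on the HVG submatrix of all cells jointly; k-means++
    then runs separately inside each batch in that shared space with
    k = min(n_groups, cells in batch).  Each profile is the arithmetic mean
    of its member cells' HVG expression rows.  Per-batch k-means seeds are a
    deterministic function of the global seed and the batch index, so the
    result is invariant to cell order.
    """
    meta = meta.aligned_to(X)
    Xh = X.subset_features(hvgs.feature_ids)
    pca = compute_pca(Xh.values, n_pcs=n_pcs, standardize=True)
    levels = meta.batch_levels
    profiles, batches, membership = [], [], []
    for b_idx, level in enumerate(levels):
        mask = meta.batch == level
        if not mask.any():
            raise DataIOError(f"batch level {level!r} has no cells")
        idx = np.flatnonzero(mask)
        # iterate batch members in cell-id order so the k-means++ draw,
        # and hence the profiles, are invariant to input cell order
        idx = idx[np.argsort(X.cell_ids[idx].astype(str), kind="stable")]
        pts = pca.scores[idx]
        k = int(min(n_groups, len(idx)))
        if k == len(idx):
            groups = np.arange(len(idx))
        else:
            km = KMeans(
                n_clusters=k,
                init="k-means++",
                n_init=1,
                random_state=derive_seed(seed, b_idx),
            ).fit(pts)
            groups = km.labels_
        for g in range(k):
            members = idx[groups == g]
            if len(members) == 0:
                continue  # sklearn relocates empty clusters, but stay safe
            profiles.append(Xh.values[members].mean(axis=0))
            batches.append(level)
            membership.append(X.cell_ids[members])
    return TrainingSet(
        profiles=np.asarray(profiles),
        profile_batch=np.asarray(batches, dtype=object),
        membership=membership,
        source_features=np.asarray(hvgs.feature_ids, dtype=object),
    )
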