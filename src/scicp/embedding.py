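"""Integrated linear embedding from concatenated cluster probabilities.

The per-run, per-round probability matrices are concatenated column-wise,
centred and scaled, and decomposed by PCA.  Because cluster probabilities
are already batch-mixed by construction, the leading components form an
integrated embedding suitable for downstream clustering or non-linear
projection.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.neighbors import NearestNeighbors

from .divisive_icp import MultiRunResult

__all__ = [
    "EmbeddingModel",
    "concatenate_probabilities",
    "embed",
    "knn_batch_mixing",
]


@dataclass
class EmbeddingModel:
    """Frozen column statistics + loadings of the probability PCA."""

    col_means: np.ndarray
    col_sds: np.ndarray  # zero-variance columns carry the sentinel 1.0
    loadings: np.ndarray  # columns x d
    scores: np.ndarray  # cells x d
    d: int
    col_names: list
    source: dict  # {"kept_runs": [...], "rounds": ...}
    explained_variance: np.ndarray | None = None

    def transform(self, M: np.ndarray) -> np.ndarray:
        """Project new probability rows with the frozen statistics."""
        M = np.asarray(M, dtype=float)
        if M.shape[1] != len(self.col_means):
            raise ValueError(
                f"expected {len(self.col_means)} probability columns, got {M.shape[1]}"
            )
        return ((M - self.col_means) / self.col_sds) @ self.loadings


def _select_rounds(res: MultiRunResult, rounds) -> list[int]:
    n_rounds = len(res.runs[0])
    if rounds == "last":
        return [n_rounds]
    if rounds == "all":
        return list(range(1, n_rounds + 1))
    qs = sorted(int(q) for q in rounds)
    if any(q < 1 or q > n_rounds for q in qs):
        raise ValueError(f"rounds {qs} outside 1..{n_rounds}")
    return qs


def concatenate_probabilities(res: MultiRunResult, rounds="last"):
    """Stack per-cell probability tables across kept runs and rounds.

    Column blocks are ordered by (run, round, cluster) and named
    ``run:round:cluster`` with 1-based run/round and the cluster's label,
    so any block can be traced back to its model.

    Returns
    -------
    (matrix, col_names) : cells x sum(k) float array and its column names.
    """
    if len(res.kept_runs) == 0:
        raise ValueError("no runs survived the ARI cutoff; nothing to concatenate")
    qs = _select_rounds(res, rounds)
    blocks, names = [], []
    for l in res.kept_runs:
        for q in qs:
            rr = res.runs[l][q - 1]
            blocks.append(rr.cell_probs.probs)
            names.extend(f"{l + 1}:{q}:{c}" for c in rr.cell_probs.classes)
    return np.hstack(blocks), names


def embed(M: np.ndarray, d: int = 30, *, col_names=None, source=None) -> EmbeddingModel:
    """Centre and scale probability columns, then PCA with a fixed sign rule.

    Zero-variance columns get the scale sentinel 1.0 so they contribute
    exactly 0 after centring.  Each loading column is flipped so its
    largest-magnitude entry is positive, making the embedding deterministic.
    """
    M = np.asarray(M, dtype=float)
    n, p = M.shape
    d = int(d)
    if d > min(n, p):
        raise ValueError(f"d={d} exceeds min(cells, columns)={min(n, p)}")
    means = M.mean(axis=0)
    sds = M.std(axis=0, ddof=0)
    # relative tolerance: a numerically-constant column must get the
    # sentinel, or division amplifies representation noise into a signal
    tol = 1e-12 * np.maximum(1.0, np.abs(means))
    sds = np.where(sds > tol, sds, 1.0)
    Z = (M - means) / sds
    _, svals, vt = np.linalg.svd(Z, full_matrices=False)
    loadings = vt[:d].T
    flip = np.sign(loadings[np.argmax(np.abs(loadings), axis=0), np.arange(d)])
    flip[flip == 0] = 1.0
    loadings = loadings * flip
    return EmbeddingModel(
        col_means=means,
        col_sds=sds,
        loadings=loadings,
        scores=Z @ loadings,
        d=d,
        col_names=list(col_names) if col_names is not None else list(range(p)),
        source=source or {},
        explained_variance=(svals[:d] ** 2) / n,
    )


def knn_batch_mixing(scores: np.ndarray, batches, k: int = 30) -> float:
    """Neighbourhood batch-mixing score in [0, 1]; 1 = perfectly mixed.

    For each cell the fraction of same-batch cells among its k nearest
    neighbours (self excluded) is compared with the fraction expected under
    perfect mixing; the mean excess over expectation, rescaled to [0, 1]
    and reversed, is returned.  A single batch is defined as perfectly
    mixed.
    """
    scores = np.asarray(scores, dtype=float)
    batches = np.asarray(batches)
    n = scores.shape[0]
    levels, inv = np.unique(batches, return_inverse=True)
    if len(levels) < 2:
        return 1.0
    if k >= n:
        raise ValueError(f"k={k} must be below the number of cells {n}")
    nn = NearestNeighbors(n_neighbors=k + 1).fit(scores)
    _, idx = nn.kneighbors(scores)
    neigh = inv[idx[:, 1:]]  # drop self
    own_frac = (neigh == inv[:, None]).mean(axis=1)
    counts = np.bincount(inv)
    expected = (counts[inv] - 1) / (n - 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        excess = (own_frac - expected) / (1.0 - expected)
    excess = np.clip(np.nan_to_num(excess, nan=1.0), 0.0, 1.0)
    return float(1.0 - excess.mean())
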