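"""Iterative clustering projection (ICP) inner loop.

ICP is self-supervised clustering by agreement: fit a one-vs-rest
L1-regularized logistic classifier on the current cluster labels, project
every working item to its most probable cluster, and accept the projection
as the next clustering only when the adjusted Rand index between clustering
and projection strictly improves.  Epochs that do not improve are retried
(with a fresh training subset) up to ``r`` times before the loop stops.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.linear_model import LogisticRegression

__all__ = [
    "ICPParams",
    "ClusteringState",
    "LogisticModel",
    "ProbabilityMatrix",
    "ClusterCollapseError",
    "adjusted_rand_index",
    "fit_ovr_l1",
    "predict_probabilities",
    "project_clustering",
    "icp_iterate",
]


class ClusterCollapseError(RuntimeError):
    """A cluster expected in the training labels has no members."""


@dataclass
class ICPParams:
    """Knobs of the ICP inner loop.

    cost
        liblinear cost C of the regularized logistic fit (large C = weak
        penalty; C is the inverse of the penalty weight on the coefficient
        norm).  The default keeps the L1 budget small enough that the
        classifier cannot reproduce arbitrary partitions of training sets
        in the hundreds-to-thousands range — the accept/reject loop only
        migrates toward density structure in that regime.  The relaxed
        setting C=1 with train_knn_prop=0.45 and ari_cutoff=0.1 trades
        that pressure for full-K cluster retention on hard data.
    r
        reiteration budget: consecutive non-improving epochs tolerated
        before the loop stops.
    train_knn_prop
        proportionality constant of the refined training subset (number of
        neighbours per representative = floor(prop * |cluster| / B)).
    ari_cutoff
        runs whose terminal accepted ARI falls below this are excluded from
        downstream concatenation (applied by the divisive driver).
    """

    r: int = 5
    max_iter: int = 200
    cost: float = 0.05
    penalty: str = "l1"
    train_knn_prop: float = 0.3
    ari_cutoff: float = 0.3
    allow_free_k: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.r < 1 or self.max_iter < 1:
            raise ValueError("r and max_iter must be >= 1")
        if not 0 < self.train_knn_prop < 1:
            raise ValueError("train_knn_prop must be in (0, 1)")
        if self.penalty not in ("l1", "l2"):
            raise ValueError("penalty must be 'l1' or 'l2'")


@dataclass
class ClusteringState:
    """Mutable record of one ICP run: labels, epoch count, accepted ARIs."""

    assignments: np.ndarray  # integer labels in 1..k
    k: int
    epoch: int = 0
    ari_history: list = field(default_factory=list)
    reiterations_used: int = 0


@dataclass
class LogisticModel:
    """One-vs-rest coefficients: one weight row (plus intercept) per cluster."""

    coefficients: np.ndarray  # k x (m+1); last column is the intercept
    classes: np.ndarray  # cluster labels, ascending
    cost: float
    penalty: str
    feature_ids: np.ndarray | None = None

    @property
    def weights(self) -> np.ndarray:
        return self.coefficients[:, :-1]

    @property
    def intercepts(self) -> np.ndarray:
        return self.coefficients[:, -1]

    @property
    def n_classes(self) -> int:
        return len(self.classes)


@dataclass
class ProbabilityMatrix:
    """Items x clusters assignment probabilities; rows sum to one."""

    probs: np.ndarray
    classes: np.ndarray
    item_ids: np.ndarray | None = None

    def __post_init__(self) -> None:
        rs = self.probs.sum(axis=1)
        if not np.allclose(rs, 1.0, atol=1e-8):
            raise ValueError("probability rows must sum to 1")

    @property
    def p_max(self) -> np.ndarray:
        return self.probs.max(axis=1)


def adjusted_rand_index(a, b) -> float:
    """Chance-corrected partition agreement from the contingency table.

    Returns 1 for identical partitions (up to relabeling), ~0 for random
    ones.  Implemented directly from the pair-counting formula so the
    accept/reject decision of the loop does not depend on any external
    library's conventions.
    """
    a = np.asarray(a)
    b = np.asarray(b)
    if a.shape != b.shape:
        raise ValueError(f"length mismatch: {a.shape} vs {b.shape}")
    n = a.size
    if n < 2:
        raise ValueError("need at least 2 items")
    _, ai = np.unique(a, return_inverse=True)
    _, bi = np.unique(b, return_inverse=True)
    ka, kb = ai.max() + 1, bi.max() + 1
    cont = np.zeros((ka, kb), dtype=np.int64)
    np.add.at(cont, (ai, bi), 1)

    def comb2(x):
        x = np.asarray(x, dtype=np.float64)
        return x * (x - 1.0) / 2.0

    sum_ij = comb2(cont).sum()
    sum_a = comb2(cont.sum(axis=1)).sum()
    sum_b = comb2(cont.sum(axis=0)).sum()
    total = comb2(n)
    expected = sum_a * sum_b / total
    max_index = 0.5 * (sum_a + sum_b)
    denom = max_index - expected
    if denom == 0:
        # both partitions trivial (all-singleton or single-cluster): identical
        return 1.0
    return float((sum_ij - expected) / denom)


def fit_ovr_l1(
    X_train: np.ndarray,
    y_train: np.ndarray,
    params: ICPParams,
    *,
    expected_classes=None,
    feature_ids=None,
) -> LogisticModel:
    """Fit one binary L1 (or L2) logistic classifier per cluster, sequentially.

    Each cluster label in turn plays "one" against the rest.  Raises
    :class:`ClusterCollapseError` when an expected cluster has no training
    items, signalling collapse to the caller.
    """
    X_train = np.asarray(X_train, dtype=float)
    y_train = np.asarray(y_train)
    present = np.unique(y_train)
    classes = np.asarray(sorted(expected_classes)) if expected_classes is not None else present
    missing = set(classes) - set(present)
    if missing:
        raise ClusterCollapseError(f"clusters with no training items: {sorted(missing)}")
    if len(classes) < 2:
        raise ValueError("need at least 2 classes to fit one-vs-rest models")
    m = X_train.shape[1]
    coef = np.zeros((len(classes), m + 1))
    for row, cls in enumerate(classes):
        y_bin = (y_train == cls).astype(int)
        clf = LogisticRegression(
            l1_ratio=1.0 if params.penalty == "l1" else 0.0,
            C=params.cost,
            solver="liblinear",
            random_state=params.seed,
            tol=1e-4,
            max_iter=1000,
        ).fit(X_train, y_bin)
        if clf.classes_[1] == 1:
            coef[row, :m] = clf.coef_[0]
            coef[row, m] = clf.intercept_[0]
        else:  # liblinear fitted with flipped class order
            coef[row, :m] = -clf.coef_[0]
            coef[row, m] = -clf.intercept_[0]
    return LogisticModel(
        coefficients=coef,
        classes=np.asarray(classes),
        cost=params.cost,
        penalty=params.penalty,
        feature_ids=None if feature_ids is None else np.asarray(feature_ids, dtype=object),
    )


def predict_probabilities(
    model: LogisticModel, X: np.ndarray, *, feature_ids=None, item_ids=None
) -> ProbabilityMatrix:
    """Per-cluster sigmoid scores normalized to sum 1 per item.

    When both the model and the call carry feature ids, columns of ``X``
    are aligned to the model's feature order by id; missing features raise.
    """
    X = np.asarray(X, dtype=float)
    if feature_ids is not None and model.feature_ids is not None:
        import pandas as pd

        pos = pd.Index(list(feature_ids)).get_indexer(list(model.feature_ids))
        if (pos < 0).any():
            missing = list(np.asarray(model.feature_ids)[pos < 0])
            raise ValueError(f"features required by model missing from input: {missing[:5]}")
        X = X[:, pos]
    if X.shape[1] != model.weights.shape[1]:
        raise ValueError(
            f"feature mismatch: model has {model.weights.shape[1]}, input {X.shape[1]}"
        )
    z = X @ model.weights.T + model.intercepts
    scores = 1.0 / (1.0 + np.exp(-z))
    # guard the all-zero row (every sigmoid can underflow only at z -> -inf)
    totals = scores.sum(axis=1)
    totals[totals == 0] = 1.0
    probs = scores / totals[:, None]
    return ProbabilityMatrix(probs=probs, classes=model.classes, item_ids=item_ids)


def project_clustering(P: ProbabilityMatrix) -> np.ndarray:
    """Assign each item to its highest-probability cluster (lowest index wins ties)."""
    # np.argmax returns the first maximum, which is the lowest class index
    return P.classes[np.argmax(P.probs, axis=1)]


def _compact_labels(labels: np.ndarray) -> np.ndarray:
    """Relabel to consecutive integers 1..k preserving order of appearance of sorted labels."""
    uniq = np.unique(labels)
    lut = {lab: i + 1 for i, lab in enumerate(uniq)}
    return np.asarray([lut[lab] for lab in labels], dtype=int)


def icp_iterate(
    X_work: np.ndarray,
    work_batches: np.ndarray,
    init: np.ndarray,
    params: ICPParams,
    subset_fn=None,
):
    """Run the ICP accept/reject loop to convergence.

    Parameters
    ----------
    X_work
        Working matrix (training profiles) the loop clusters.
    work_batches
        Batch label per working item (forwarded to ``subset_fn``).
    init
        Initial integer cluster labels with at least 2 distinct values.
    subset_fn
        Callback ``(assignments, P_prev, epoch) -> index array`` selecting
        the training subset; epoch 1 always trains on everything.  ``None``
        trains on the full working set every epoch.

    Returns
    -------
    (ClusteringState, LogisticModel, ProbabilityMatrix)
        The last accepted clustering, the model that produced it and the
        associated probability matrix.  If no epoch improved on ARI 0, the
        initial clustering is returned with the last attempted model.
    """
    X_work = np.asarray(X_work, dtype=float)
    assignments = _compact_labels(np.asarray(init))
    if len(np.unique(assignments)) < 2:
        raise ValueError("initial clustering must have at least 2 clusters")
    n = X_work.shape[0]
    if len(assignments) != n:
        raise ValueError("init length does not match working matrix")

    best_ari = 0.0
    reiter = 0
    epoch = 0
    ari_history: list[float] = []
    P_prev = None
    accepted = None  # (assignments, model, P)
    last_fit = None
    while epoch < params.max_iter:
        epoch += 1
        if subset_fn is None or epoch == 1 or P_prev is None:
            subset = np.arange(n)
        else:
            subset = np.asarray(subset_fn(assignments, P_prev, epoch))
        try:
            model = fit_ovr_l1(
                X_work[subset],
                assignments[subset],
                params,
                expected_classes=np.unique(assignments),
            )
        except ClusterCollapseError:
            # training subset lost a cluster: count as a failed reiteration
            reiter += 1
            if reiter >= params.r:
                break
            continue
        P = predict_probabilities(model, X_work)
        proj = project_clustering(P)
        last_fit = (model, P)
        P_prev = P
        surviving = np.unique(proj)
        collapsed = len(surviving) < len(np.unique(assignments))
        if collapsed and not params.allow_free_k:
            reiter += 1
            if reiter >= params.r:
                break
            continue
        if len(surviving) < 2:
            # projection merged everything; cannot accept a 1-cluster state
            reiter += 1
            if reiter >= params.r:
                break
            continue
        ari = adjusted_rand_index(assignments, proj)
        if ari > best_ari:
            best_ari = ari
            ari_history.append(ari)
            assignments = _compact_labels(proj)
            accepted = (assignments, model, P)
            reiter = 0
        else:
            reiter += 1
            if reiter >= params.r:
                break

    if accepted is None:
        if last_fit is None:
            # never managed a single successful fit
            raise ClusterCollapseError("ICP could not fit any epoch")
        model, P = last_fit
        final_assign = _compact_labels(np.asarray(init))
    else:
        final_assign, model, P = accepted
    state = ClusteringState(
        assignments=final_assign,
        k=len(np.unique(final_assign)),
        epoch=epoch,
        ari_history=ari_history,
        reiterations_used=min(reiter, params.r),
    )
    return state, model, P
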