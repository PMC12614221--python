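"""Divisive multi-round ICP: the outer integration loop.

Each run starts from a two-cluster partition of the training profiles cut
at batch-wise medians of the first principal component, runs the ICP inner
loop to convergence, then doubles the cluster count by splitting every
cluster at batch-wise medians of its members' maximum assignment
probability.  Rounds continue until the target K = 2^Q clusters; the whole
procedure is repeated L times with independent seeds, and every round's
fitted model finally scores all real cells.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from joblib import Parallel, delayed
from sklearn.neighbors import NearestNeighbors

from .data_io import CellMetadata, ExpressionMatrix
from .icp_core import (
    ClusteringState,
    ICPParams,
    LogisticModel,
    ProbabilityMatrix,
    icp_iterate,
    predict_probabilities,
)
from .training_set import (
    PCAModel,
    TrainingSet,
    build_training_set,
    compute_pca,
    derive_seed,
    select_hvgs,
)

__all__ = [
    "DivisiveParams",
    "RoundResult",
    "MultiRunResult",
    "initialize_clusters_pc1",
    "split_clusters",
    "refine_training_subset",
    "run_divisive_icp",
]


@dataclass
class DivisiveParams:
    """Configuration of the divisive outer loop.

    K must be a power of two: each round doubles the cluster count
    (k = 2^q) until K is reached.  ``divisive_method`` selects batch-wise
    ("pc1_batch") or global ("cluster") medians for initialization and
    splitting; the global mode is meant for unbatched reference data.
    """

    K: int = 16
    L: int = 50
    icp: ICPParams = field(default_factory=ICPParams)
    divisive_method: str = "pc1_batch"
    n_threads: int = 1
    n_hvgs: int = 2000
    n_groups: int = 500
    n_pcs: int = 30

    def __post_init__(self) -> None:
        q = np.log2(self.K)
        if self.K < 2 or q != int(q):
            raise ValueError(f"K must be a power of two >= 2, got {self.K}")
        if self.L < 1:
            raise ValueError("L must be >= 1")
        if self.divisive_method not in ("pc1_batch", "cluster"):
            raise ValueError("divisive_method must be 'pc1_batch' or 'cluster'")

    @property
    def n_rounds(self) -> int:
        return int(np.log2(self.K))


@dataclass
class RoundResult:
    """One accepted ICP round: its model and probabilities on both spaces."""

    round_q: int
    model: LogisticModel
    cell_probs: ProbabilityMatrix
    train_probs: ProbabilityMatrix
    state: ClusteringState

    @property
    def k(self) -> int:
        return self.model.n_classes


@dataclass
class MultiRunResult:
    """All L runs x Q rounds of divisive ICP over one dataset."""

    runs: list  # L lists of RoundResult
    params: DivisiveParams
    kept_runs: np.ndarray  # run indices (0-based) surviving ari_cutoff
    rng_seeds: np.ndarray
    cell_ids: np.ndarray
    feature_ids: np.ndarray  # HVG feature ids the models were trained on

    @property
    def n_runs(self) -> int:
        return len(self.runs)

    def terminal_ari(self, run: int) -> float:
        hist = self.runs[run][-1].state.ari_history
        return float(hist[-1]) if hist else 0.0


def initialize_clusters_pc1(
    train: TrainingSet, pca: PCAModel, batches=None
) -> np.ndarray:
    """Two starting clusters cut at batch-wise medians of PC1.

    Profiles at or below their batch's median PC1 score go to cluster 1,
    the rest to cluster 2.  With ``batches=None`` a single global median is
    used (unbatched mode).
    """
    pc1 = pca.scores[:, 0]
    if batches is None:
        batches = np.zeros(len(pc1), dtype=int)
    batches = np.asarray(batches)
    labels = np.ones(len(pc1), dtype=int)
    for b in np.unique(batches):
        mask = batches == b
        eta = np.median(pc1[mask])
        labels[mask & (pc1 > eta)] = 2
    return labels


def split_clusters(
    assignments: np.ndarray, P: ProbabilityMatrix, batches=None
) -> np.ndarray:
    """Split every cluster in two at batch-wise medians of max probability.

    Members with maximum assignment probability at or below their
    (cluster, batch) median go to the low child (label 2j-1), the rest to
    the high child (2j).  Degenerate clusters simply pass through with an
    empty high side.
    """
    assignments = np.asarray(assignments)
    p_max = P.p_max
    if len(p_max) != len(assignments):
        raise ValueError("probability matrix not aligned with assignments")
    if batches is None:
        batches = np.zeros(len(assignments), dtype=int)
    batches = np.asarray(batches)
    out = np.empty(len(assignments), dtype=int)
    for j in np.unique(assignments):
        cmask = assignments == j
        for b in np.unique(batches[cmask]):
            mask = cmask & (batches == b)
            tau = np.median(p_max[mask])
            low = mask & (p_max <= tau)
            high = mask & (p_max > tau)
            out[low] = 2 * j - 1
            out[high] = 2 * j
    return out


def refine_training_subset(
    assignments: np.ndarray,
    P: ProbabilityMatrix,
    batches: np.ndarray,
    X_profiles: np.ndarray | None = None,
    prop: float = 0.3,
    nn: NearestNeighbors | None = None,
) -> np.ndarray:
    """Batch-balanced training subset for epochs after the first.

    For each (cluster j, batch b) with members, the representative is the
    member with the highest assigned-cluster probability (the row maximum,
    since every item sits in its argmax cluster).  Its
    ``max(1, floor(prop * |C_j| / B))`` nearest neighbours among *all*
    profiles (cross-batch, Euclidean in profile feature space) join the
    subset together with the representative itself.

    Either a raw profile matrix or a prefitted ``NearestNeighbors`` index
    on it must be supplied.
    """
    assignments = np.asarray(assignments)
    batches = np.asarray(batches)
    p_max = P.p_max
    if nn is None:
        if X_profiles is None:
            raise ValueError("need X_profiles or a prefitted NearestNeighbors index")
        X_profiles = np.asarray(X_profiles, dtype=float)
        nn = NearestNeighbors().fit(X_profiles)
    query_X = X_profiles if X_profiles is not None else nn._fit_X
    n_items = nn.n_samples_fit_
    B = len(np.unique(batches))
    chosen: set[int] = set()
    for j in np.unique(assignments):
        cmask = assignments == j
        cluster_size = int(cmask.sum())
        n_neigh = max(1, int(np.floor(prop * cluster_size / B)))
        for b in np.unique(batches[cmask]):
            members = np.flatnonzero(cmask & (batches == b))
            rep = members[np.argmax(p_max[members])]
            chosen.add(int(rep))
            k_query = min(n_neigh + 1, n_items)
            _, idx = nn.kneighbors(
                np.asarray(query_X)[rep][None, :], n_neighbors=k_query
            )
            neighbours = [i for i in idx[0] if i != rep][:n_neigh]
            chosen.update(int(i) for i in neighbours)
    return np.asarray(sorted(chosen), dtype=int)


def _run_one(
    l: int,
    run_seed: int,
    train: TrainingSet,
    X_cells: np.ndarray,
    cell_ids: np.ndarray,
    effective_batches: np.ndarray | None,
    pca1: PCAModel,
    nn: NearestNeighbors,
    params: DivisiveParams,
) -> list[RoundResult]:
    icp_params = replace(params.icp, seed=run_seed)
    prop = icp_params.train_knn_prop
    refine_batches = (
        effective_batches
        if effective_batches is not None
        else np.zeros(train.n_profiles, dtype=int)
    )

    def subset_fn(assignments, P_prev, epoch):
        return refine_training_subset(
            assignments, P_prev, refine_batches,
            X_profiles=train.profiles, prop=prop, nn=nn,
        )

    rounds: list[RoundResult] = []
    init = initialize_clusters_pc1(train, pca1, batches=effective_batches)
    for q in range(1, params.n_rounds + 1):
        if q > 1:
            prev = rounds[-1]
            init = split_clusters(
                prev.state.assignments, prev.train_probs, batches=effective_batches
            )
        state, model, P_train = icp_iterate(
            train.profiles,
            train.profile_batch,
            init,
            icp_params,
            subset_fn=subset_fn,
        )
        cell_probs = predict_probabilities(model, X_cells, item_ids=cell_ids)
        rounds.append(
            RoundResult(
                round_q=q,
                model=model,
                cell_probs=cell_probs,
                train_probs=P_train,
                state=state,
            )
        )
    return rounds


def run_divisive_icp(
    X: ExpressionMatrix,
    meta: CellMetadata,
    params: DivisiveParams | None = None,
    seed: int = 0,
) -> MultiRunResult:
    """Fit the full multi-level integration engine on log-normalized data.

    Builds the batch-wise averaged training set on the HVG feature space,
    then executes L independent divisive ICP runs (each Q = log2(K) rounds)
    and scores every real cell against every round's model.  Runs whose
    terminal accepted ARI falls below ``params.icp.ari_cutoff`` are flagged
    out of ``kept_runs`` (but retained for audit).
    """
    params = params or DivisiveParams()
    meta = meta.aligned_to(X)
    n_hvgs = min(params.n_hvgs, X.n_features)
    hvgs = select_hvgs(X, n=n_hvgs)
    train = build_training_set(
        X,
        meta,
        hvgs,
        n_groups=params.n_groups,
        n_pcs=params.n_pcs,
        seed=derive_seed(seed, 987),
    )
    X_cells = X.subset_features(hvgs.feature_ids).values
    # PC1 of the standardized profile matrix drives the first split
    pca1 = compute_pca(train.profiles, n_pcs=1, standardize=True)
    effective_batches = (
        np.asarray(train.profile_batch)
        if params.divisive_method == "pc1_batch"
        else None
    )
    nn = NearestNeighbors().fit(train.profiles)
    rng_seeds = np.asarray([derive_seed(seed, l) for l in range(params.L)])
    worker = delayed(_run_one)
    jobs = (
        worker(
            l, int(rng_seeds[l]), train, X_cells, X.cell_ids,
            effective_batches, pca1, nn, params,
        )
        for l in range(params.L)
    )
    if params.n_threads > 1:
        runs = Parallel(n_jobs=params.n_threads)(jobs)
    else:
        runs = [f(*a, **kw) for f, a, kw in jobs]
    result = MultiRunResult(
        runs=runs,
        params=params,
        kept_runs=np.empty(0, dtype=int),
        rng_seeds=rng_seeds,
        cell_ids=X.cell_ids,
        feature_ids=np.asarray(hvgs.feature_ids, dtype=object),
    )
    cutoff = params.icp.ari_cutoff
    kept = [l for l in range(params.L) if result.terminal_ari(l) >= cutoff]
    result.kept_runs = np.asarray(kept, dtype=int)
    return result
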