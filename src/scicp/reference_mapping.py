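"""Reference mapping: train on an annotated reference, transfer labels to queries.

A fitted divisive-ICP ensemble plus its probability PCA form a frozen
:class:`ReferenceModel`.  Query cells are scored by the reference's ICP
models, projected into the reference PCA space with the reference's own
column statistics, and labelled by k-nearest-neighbour majority vote among
reference cells, with the winning vote fraction reported as a confidence
score.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.neighbors import NearestNeighbors

from .data_io import CellMetadata, ExpressionMatrix
from .divisive_icp import DivisiveParams, MultiRunResult, run_divisive_icp
from .embedding import EmbeddingModel, _select_rounds, concatenate_probabilities, embed
from .icp_core import predict_probabilities

__all__ = [
    "ReferenceModel",
    "MappingResult",
    "build_reference",
    "project_query",
    "knn_transfer",
    "mapping_accuracy",
    "majority_voting_features",
]


@dataclass
class ReferenceModel:
    """Frozen ICP ensemble + embedding + labels; the unit of label transfer."""

    icp: MultiRunResult
    embedding: EmbeddingModel
    ref_labels: np.ndarray
    ref_scores: np.ndarray
    k_nn: int = 10
    rounds: object = "last"

    def __post_init__(self) -> None:
        if self.k_nn < 1:
            raise ValueError("k_nn must be >= 1")
        if len(self.ref_labels) != self.ref_scores.shape[0]:
            raise ValueError("labels and reference scores misaligned")

    @property
    def feature_ids(self) -> np.ndarray:
        return self.icp.feature_ids


@dataclass
class MappingResult:
    """Predicted label, confidence in (0, 1], and embedding per query cell."""

    predicted: np.ndarray
    confidence: np.ndarray
    query_scores: np.ndarray
    cell_ids: np.ndarray | None = None

    def to_frame(self) -> pd.DataFrame:
        ids = (
            self.cell_ids
            if self.cell_ids is not None
            else np.arange(len(self.predicted))
        )
        return pd.DataFrame(
            {
                "cell_id": list(ids),
                "predicted_label": list(self.predicted),
                "confidence": self.confidence,
            }
        )


def build_reference(
    X_ref: ExpressionMatrix,
    meta: CellMetadata,
    params: DivisiveParams | None = None,
    *,
    seed: int = 0,
    d: int = 30,
    k_nn: int = 10,
    rounds="last",
) -> ReferenceModel:
    """Run divisive ICP on annotated data and freeze the result for mapping."""
    if meta.label is None:
        raise ValueError("reference metadata must carry cell-type labels")
    meta = meta.aligned_to(X_ref)
    res = run_divisive_icp(X_ref, meta, params, seed=seed)
    M, names = concatenate_probabilities(res, rounds=rounds)
    d_eff = min(d, min(M.shape))
    emb = embed(
        M,
        d=d_eff,
        col_names=names,
        source={"kept_runs": list(res.kept_runs), "rounds": rounds},
    )
    return ReferenceModel(
        icp=res,
        embedding=emb,
        ref_labels=np.asarray(meta.label, dtype=object),
        ref_scores=emb.scores,
        k_nn=k_nn,
        rounds=rounds,
    )


def project_query(
    ref: ReferenceModel,
    X_query: ExpressionMatrix,
    *,
    min_feature_overlap: float = 0.5,
) -> np.ndarray:
    """Score query cells with the reference models and project into its PCA.

    Query features are aligned to the reference HVG set by id; features
    absent from the query are zero-filled (log-normalized absence) and
    extra query features are ignored.  An overlap below
    ``min_feature_overlap`` of the model features is refused.
    """
    model_feats = list(ref.feature_ids)
    pos = pd.Index(list(X_query.feature_ids)).get_indexer(model_feats)
    overlap = float((pos >= 0).mean())
    if overlap < min_feature_overlap:
        raise ValueError(
            f"query shares only {overlap:.1%} of the {len(model_feats)} model "
            f"features (floor {min_feature_overlap:.0%})"
        )
    Xq = np.zeros((X_query.n_cells, len(model_feats)))
    have = pos >= 0
    Xq[:, have] = X_query.values[:, pos[have]]
    res = ref.icp
    qs = _select_rounds(res, ref.rounds)
    blocks = []
    for l in res.kept_runs:
        for q in qs:
            model = res.runs[l][q - 1].model
            blocks.append(predict_probabilities(model, Xq).probs)
    M = np.hstack(blocks)
    return ref.embedding.transform(M)


def knn_transfer(ref: ReferenceModel, query_scores: np.ndarray) -> MappingResult:
    """Label query cells by majority vote of their k nearest reference cells.

    Vote ties are broken by the smaller mean neighbour distance, then
    lexicographically by label, making the transfer deterministic.
    Confidence is the winning vote fraction, in {1/k_nn, ..., 1}.
    """
    query_scores = np.asarray(query_scores, dtype=float)
    k = ref.k_nn
    if k > ref.ref_scores.shape[0]:
        raise ValueError(
            f"k_nn={k} exceeds the {ref.ref_scores.shape[0]} reference cells"
        )
    nn = NearestNeighbors(n_neighbors=k).fit(ref.ref_scores)
    dist, idx = nn.kneighbors(query_scores)
    predicted = np.empty(query_scores.shape[0], dtype=object)
    confidence = np.empty(query_scores.shape[0])
    labels = ref.ref_labels
    for i in range(query_scores.shape[0]):
        neigh_labels = labels[idx[i]]
        cands = {}
        for lab, dd in zip(neigh_labels, dist[i]):
            votes, total = cands.get(lab, (0, 0.0))
            cands[lab] = (votes + 1, total + dd)
        best = min(
            cands.items(),
            key=lambda kv: (-kv[1][0], kv[1][1] / kv[1][0], str(kv[0])),
        )
        predicted[i] = best[0]
        confidence[i] = best[1][0] / k
    return MappingResult(predicted=predicted, confidence=confidence, query_scores=query_scores)


def mapping_accuracy(pred, truth):
    """Overall fraction of correct labels plus the full confusion table.

    Returns
    -------
    (accuracy, confusion) : float in [0, 1] and a pandas crosstab
        (rows = truth, columns = predicted).  Labels predicted outside the
        truth vocabulary simply count as errors.
    """
    pred = np.asarray(pred, dtype=object)
    truth = np.asarray(truth, dtype=object)
    if pred.shape != truth.shape:
        raise ValueError("prediction and truth must have equal length")
    acc = float((pred == truth).mean())
    confusion = pd.crosstab(
        pd.Series(truth, name="truth"), pd.Series(pred, name="predicted")
    )
    return acc, confusion


def majority_voting_features(res: MultiRunResult, labels) -> dict:
    """Best-matching final-round cluster per label, with its coefficients.

    Per kept run, every cell is assigned to its argmax final-round cluster;
    for each label the cluster holding the plurality of that label's cells
    is selected (lowest cluster label on ties) and its one-vs-rest weight
    vector retrieved.  The across-run mean weight per feature is the
    label's consensus marker profile.

    Returns
    -------
    dict with ``per_run`` (label -> list of (run, cluster, weights)) and
    ``mean`` (features x labels DataFrame of mean weights).
    """
    labels = np.asarray(labels, dtype=object)
    if len(labels) != len(res.cell_ids):
        raise ValueError("labels must cover every cell")
    uniq = sorted(set(labels))
    counts = pd.Series(labels).value_counts()
    empty = [u for u in uniq if counts.get(u, 0) == 0]
    if empty:
        raise ValueError(f"labels with zero cells: {empty}")
    per_run: dict = {u: [] for u in uniq}
    for l in res.kept_runs:
        rr = res.runs[l][-1]
        assigned = rr.cell_probs.classes[np.argmax(rr.cell_probs.probs, axis=1)]
        for u in uniq:
            member_clusters = assigned[labels == u]
            vals, cnts = np.unique(member_clusters, return_counts=True)
            best = vals[np.argmax(cnts)]  # ties -> lowest label (unique is sorted)
            row = int(np.flatnonzero(rr.model.classes == best)[0])
            per_run[u].append((int(l), int(best), rr.model.weights[row].copy()))
    mean = pd.DataFrame(
        {u: np.mean([w for _, _, w in per_run[u]], axis=0) for u in uniq},
        index=list(res.feature_ids),
    )
    return {"per_run": per_run, "mean": mean}
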