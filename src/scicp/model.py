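"""Model/Results facade over the integration engine.

:class:`MultiLevelIntegration` is constructed from a log-normalized
expression matrix plus cell metadata; ``fit()`` runs the full divisive ICP
ensemble and returns an :class:`IntegrationResults` object carrying the
per-run models, the integrated embedding, run diagnostics and a
``summary()`` table, with reference building and cell-state scoring
hanging off it.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import cell_states as _states
from .data_io import CellMetadata, ExpressionMatrix
from .divisive_icp import DivisiveParams, MultiRunResult, run_divisive_icp
from .embedding import EmbeddingModel, concatenate_probabilities, embed, knn_batch_mixing
from .icp_core import ICPParams
from .reference_mapping import ReferenceModel, build_reference

__all__ = ["MultiLevelIntegration", "IntegrationResults"]


class MultiLevelIntegration:
    """Divisive-ICP integration model over one multi-batch dataset.

    Parameters
    ----------
    X
        Log-normalized cells x features expression.
    meta
        Per-cell batch (and optionally cell-type) metadata, joined by id.
    params
        :class:`DivisiveParams`; keyword shortcuts (K, L, divisive_method,
        n_hvgs, ...) build one when not given.
    """

    def __init__(
        self,
        X: ExpressionMatrix,
        meta: CellMetadata,
        params: DivisiveParams | None = None,
        **kwargs,
    ):
        self.X = X
        self.meta = meta.aligned_to(X)
        if params is None:
            icp_kwargs = {
                k: kwargs.pop(k)
                for k in list(kwargs)
                if k in ICPParams.__dataclass_fields__
            }
            params = DivisiveParams(icp=ICPParams(**icp_kwargs), **kwargs)
        elif kwargs:
            raise TypeError(f"params given; unexpected keywords {sorted(kwargs)}")
        self.params = params

    @classmethod
    def from_dataframe(
        cls,
        expr: pd.DataFrame,
        meta: pd.DataFrame,
        *,
        batch_col: str = "batch",
        label_col: str | None = None,
        **kwargs,
    ) -> "MultiLevelIntegration":
        """Build from a cells x features DataFrame and a metadata DataFrame."""
        X = ExpressionMatrix(
            expr.to_numpy(dtype=float),
            expr.index.astype(str).to_numpy(),
            expr.columns.astype(str).to_numpy(),
        )
        cm = CellMetadata(
            meta.index.astype(str).to_numpy(),
            meta[batch_col].astype(str).to_numpy(),
            meta[label_col].astype(str).to_numpy() if label_col else None,
        )
        return cls(X, cm, **kwargs)

    def fit(self, seed: int = 0, *, embed_d: int = 30, rounds="last") -> "IntegrationResults":
        """Run the ensemble and embed the concatenated probabilities."""
        res = run_divisive_icp(self.X, self.meta, self.params, seed=seed)
        emb = None
        if len(res.kept_runs):
            M, names = concatenate_probabilities(res, rounds=rounds)
            emb = embed(
                M,
                d=min(embed_d, min(M.shape)),
                col_names=names,
                source={"kept_runs": list(res.kept_runs), "rounds": rounds},
            )
        return IntegrationResults(self, res, emb, seed=seed, rounds=rounds)


class IntegrationResults:
    """Fitted ensemble: probability models, embedding, and diagnostics."""

    def __init__(
        self,
        model: MultiLevelIntegration,
        multirun: MultiRunResult,
        embedding: EmbeddingModel | None,
        *,
        seed: int,
        rounds,
    ):
        self.model = model
        self.multirun = multirun
        self.embedding = embedding
        self.seed = seed
        self.rounds = rounds

    @property
    def scores(self) -> np.ndarray:
        """Integrated embedding coordinates (cells x d)."""
        if self.embedding is None:
            raise ValueError("no kept runs; embedding unavailable")
        return self.embedding.scores

    def summary(self) -> pd.DataFrame:
        """Per-run diagnostics: k per round, terminal ARI, kept flag."""
        rows = []
        for l, rounds in enumerate(self.multirun.runs):
            rows.append(
                {
                    "run": l + 1,
                    "seed": int(self.multirun.rng_seeds[l]),
                    **{f"k_round{rr.round_q}": rr.k for rr in rounds},
                    "epochs_final": rounds[-1].state.epoch,
                    "terminal_ari": self.multirun.terminal_ari(l),
                    "kept": l in set(self.multirun.kept_runs.tolist()),
                }
            )
        return pd.DataFrame(rows)

    def batch_mixing(self, k: int = 30) -> float:
        """kNN batch-mixing score of the integrated embedding (1 = mixed)."""
        return knn_batch_mixing(self.scores, self.model.meta.batch, k=k)

    def state_scores(self, rounds=None) -> _states.StateScore:
        """Per-cell mean assignment-probability (cell-state) scores."""
        return _states.state_scores(self.multirun, rounds=rounds or self.rounds)

    def build_reference(self, *, k_nn: int = 10) -> ReferenceModel:
        """Freeze this fit plus the metadata labels into a mapping reference."""
        if self.model.meta.label is None:
            raise ValueError("metadata has no cell-type labels")
        if self.embedding is None:
            raise ValueError("no kept runs; cannot build a reference")
        return ReferenceModel(
            icp=self.multirun,
            embedding=self.embedding,
            ref_labels=np.asarray(self.model.meta.label, dtype=object),
            ref_scores=self.embedding.scores,
            k_nn=k_nn,
            rounds=self.rounds,
        )
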