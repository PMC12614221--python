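"""Probability-based cell-state scoring.

A cell's mean assigned-cluster probability across the ensemble runs acts
as a stability score: cells in transient states sit near cluster
boundaries and score low, cells in stable terminal states score high.
Binning cells on this score within each cell type and correlating binned
gene expression against binned probability surfaces the genes that track
the state axis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data_io import ExpressionMatrix
from .divisive_icp import MultiRunResult
from .embedding import _select_rounds

__all__ = [
    "StateScore",
    "BinTable",
    "state_scores",
    "bin_by_probability",
    "gene_state_correlation",
    "top_correlated",
]


@dataclass
class StateScore:
    """Per-cell mean max-probability across kept runs, plus min-max scaling."""

    mean_prob: np.ndarray
    scaled_prob: np.ndarray
    cell_ids: np.ndarray


@dataclass
class BinTable:
    """Equal-count probability bins per cell type.

    ``bins[label]`` is a list of cell-index arrays ordered by ascending bin
    mean probability; ``bin_mean_prob[label]`` carries the per-bin means.
    """

    bins: dict
    bin_mean_prob: dict
    cell_ids: np.ndarray

    def n_bins(self, label) -> int:
        return len(self.bins[label])


def state_scores(res: MultiRunResult, rounds="last") -> StateScore:
    """Mean over kept runs of each cell's maximum assignment probability.

    Uses the final round by default (the finest cluster level); min-max
    scaling to [0, 1] is attached for display.  A constant score vector
    scales to all zeros.
    """
    if len(res.kept_runs) == 0:
        raise ValueError("no kept runs; cannot score cell states")
    qs = _select_rounds(res, rounds)
    maxima = [
        res.runs[l][q - 1].cell_probs.p_max for l in res.kept_runs for q in qs
    ]
    mean_prob = np.mean(maxima, axis=0)
    lo, hi = mean_prob.min(), mean_prob.max()
    scaled = (mean_prob - lo) / (hi - lo) if hi > lo else np.zeros_like(mean_prob)
    return StateScore(mean_prob=mean_prob, scaled_prob=scaled, cell_ids=res.cell_ids)


def bin_by_probability(scores: StateScore, labels, n_bins: int = 20) -> BinTable:
    """Cut each cell type into equal-count bins of ascending state score.

    Cells are sorted by (mean probability, cell id) for determinism and
    sliced into ``n_bins`` contiguous bins; when the count does not divide
    evenly the remainder is spread over the lowest bins, so bin sizes
    differ by at most one.  Types with fewer cells than bins fall back to
    one cell per bin.
    """
    labels = np.asarray(labels, dtype=object)
    if len(labels) != len(scores.mean_prob):
        raise ValueError("labels must align with scores")
    bins: dict = {}
    bin_means: dict = {}
    for lab in sorted(set(labels)):
        idx = np.flatnonzero(labels == lab)
        order = idx[np.lexsort((np.asarray(scores.cell_ids)[idx], scores.mean_prob[idx]))]
        nb = min(n_bins, len(order))
        base, rem = divmod(len(order), nb)
        sizes = [base + 1 if i < rem else base for i in range(nb)]
        out, start = [], 0
        for s in sizes:
            out.append(order[start : start + s])
            start += s
        bins[lab] = out
        bin_means[lab] = np.array([scores.mean_prob[b].mean() for b in out])
    return BinTable(bins=bins, bin_mean_prob=bin_means, cell_ids=scores.cell_ids)


def gene_state_correlation(X: ExpressionMatrix, bins: BinTable) -> pd.DataFrame:
    """Pearson r between bin-mean probability and bin-mean expression per gene.

    Computed independently per cell type across its probability bins.
    Genes with zero variance across bins, or types with fewer than 3 bins,
    yield missing r.

    Returns
    -------
    DataFrame with columns (label, gene, r), one row per (type, gene).
    """
    rows = []
    for lab, cell_bins in bins.bins.items():
        p = bins.bin_mean_prob[lab]
        if len(cell_bins) < 3:
            r = np.full(X.n_features, np.nan)
        else:
            E = np.vstack([X.values[b].mean(axis=0) for b in cell_bins])
            pc = p - p.mean()
            Ec = E - E.mean(axis=0)
            denom = np.sqrt((pc**2).sum()) * np.sqrt((Ec**2).sum(axis=0))
            with np.errstate(divide="ignore", invalid="ignore"):
                r = (pc @ Ec) / denom
            r[~np.isfinite(r)] = np.nan
            if (pc**2).sum() == 0:
                r[:] = np.nan
        rows.append(
            pd.DataFrame({"label": lab, "gene": list(X.feature_ids), "r": r})
        )
    return pd.concat(rows, ignore_index=True)


def top_correlated(
    table: pd.DataFrame, label, k: int = 5, positive: bool = True
) -> pd.DataFrame:
    """Top-k positively (or negatively) state-correlated genes for one type."""
    sub = table[(table["label"] == label) & table["r"].notna()]
    sub = sub.sort_values("r", ascending=not positive, kind="stable")
    return sub.head(k).reset_index(drop=True)
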