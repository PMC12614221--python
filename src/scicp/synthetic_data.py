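"""Synthetic multi-batch scRNA-seq-like data with known ground truth.

Counts are drawn from a negative-binomial model: each gene has a baseline
log-mean, cell types add a log-fold-change on their differential gene
sets, batches add shifts on their own gene sets, and library sizes vary
log-normally per cell.  "Similar" type pairs share a stated fraction of
differential genes, ablation zeroes a type out of a batch, and trajectory
mode interpolates the progenitor and terminal type means along a
pseudotime axis.  Every draw is reproducible from the design seed and the
truth tables (differential genes, batch genes, pseudotime) are returned
alongside the counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data_io import CellMetadata, ExpressionMatrix, filter_unexpressed, log_normalize

__all__ = ["SimDesign", "simulate", "make_scenario", "scenario_data"]


@dataclass
class SimDesign:
    """Design of one simulated dataset.

    cells_per_type_per_batch is an (n_types x n_batches) integer matrix;
    a zero entry ablates that type from that batch.  de_lfc is the
    log-scale shift added to a type's differential genes; batch_lfc the
    magnitude of batch shifts (random sign per gene); similarity_pairs is
    a list of (type_a, type_b, shared_fraction) making pair members share
    that fraction of their differential gene sets.  trajectory, when set,
    is (progenitor_type, terminal_type_or_types, n_steps): progenitor
    cells sit near the unsigned baseline (an undifferentiated state is the
    absence of lineage signatures) and each lineage ramps its terminal
    type's signature up with pseudotime, so one or several lineages
    radiate from a shared hub.
    """

    n_types: int
    cells_per_type_per_batch: np.ndarray
    m_genes: int
    de_frac: float = 0.05
    de_lfc: float = 1.0
    similarity_pairs: list = field(default_factory=list)
    batch_lfc: float = 0.3
    batch_gene_frac: float = 0.2
    trajectory: tuple | None = None
    seed: int = 0
    dispersion_range: tuple = (0.1, 0.4)
    libsize_sigma: float = 0.3

    def __post_init__(self) -> None:
        self.cells_per_type_per_batch = np.asarray(
            self.cells_per_type_per_batch, dtype=int
        )
        if self.cells_per_type_per_batch.ndim != 2:
            raise ValueError("cells_per_type_per_batch must be 2-D (types x batches)")
        if self.cells_per_type_per_batch.shape[0] != self.n_types:
            raise ValueError("row count must equal n_types")
        if (self.cells_per_type_per_batch < 0).any():
            raise ValueError("cell counts must be >= 0")
        if self.cells_per_type_per_batch.sum() == 0:
            raise ValueError("design has no cells at all")
        for frac in (self.de_frac, self.batch_gene_frac):
            if not 0 <= frac <= 1:
                raise ValueError("fractions must lie in [0, 1]")

    @property
    def n_batches(self) -> int:
        return self.cells_per_type_per_batch.shape[1]


def _de_sets(design: SimDesign, rng: np.random.Generator) -> list[np.ndarray]:
    """Per-type differential gene sets honouring the similarity pairs."""
    m = design.m_genes
    n_de = max(1, round(design.de_frac * m))
    sets: list[np.ndarray | None] = [None] * design.n_types
    pair_of = {}
    for a, b, share in design.similarity_pairs:
        pair_of[b] = (a, share)
    for t in range(design.n_types):
        if t in pair_of and sets[pair_of[t][0]] is not None:
            a, share = pair_of[t]
            n_shared = int(round(share * n_de))
            shared = rng.choice(sets[a], size=min(n_shared, len(sets[a])), replace=False)
            pool = np.setdiff1d(np.arange(m), sets[a])
            fresh = rng.choice(pool, size=n_de - len(shared), replace=False)
            sets[t] = np.sort(np.concatenate([shared, fresh]))
        else:
            sets[t] = np.sort(rng.choice(m, size=n_de, replace=False))
    return sets


def simulate(design: SimDesign):
    """Draw counts and metadata for a design.

    Returns
    -------
    (counts, meta, truth)
        counts : cells x genes integer array of NB draws
        meta : CellMetadata with batch and true type label
        truth : dict with per-type differential genes (``de_genes``),
            per-batch shifted genes (``batch_genes``), ``pseudotime`` (NaN
            off-trajectory) and, in trajectory mode, ``late_genes`` (genes
            monotonically increasing toward the terminal state).
    """
    rng = np.random.default_rng(design.seed)
    m = design.m_genes
    baseline = rng.normal(1.0, 0.8, size=m)
    dispersion = rng.uniform(*design.dispersion_range, size=m)
    de = _de_sets(design, rng)
    type_effect = np.zeros((design.n_types, m))
    for t in range(design.n_types):
        type_effect[t, de[t]] = design.de_lfc
    n_batch_genes = round(design.batch_gene_frac * m)
    batch_genes, batch_effect = [], np.zeros((design.n_batches, m))
    for b in range(design.n_batches):
        genes = np.sort(rng.choice(m, size=n_batch_genes, replace=False))
        signs = rng.choice([-1.0, 1.0], size=n_batch_genes)
        batch_effect[b, genes] = signs * design.batch_lfc
        batch_genes.append(genes)

    traj = design.trajectory
    if traj is not None:
        prog, terms, n_steps = traj
        terms = (terms,) if np.isscalar(terms) else tuple(terms)
    rows, batches, labels, pseudotime = [], [], [], []
    counter = 0
    for b in range(design.n_batches):
        for t in range(design.n_types):
            c = design.cells_per_type_per_batch[t, b]
            if c == 0:
                continue
            on_traj = traj is not None and (t == prog or t in terms)
            if on_traj:
                # trajectory cells sample a pseudotime grid along their
                # lineage; progenitor cells are spread over the lineages
                # near the hub (u < 0.5), terminal cells continue their
                # own lineage outward (u >= 0.5)
                grid = rng.integers(0, n_steps, size=c) / max(n_steps - 1, 1)
                if t == prog:
                    grid = grid * 0.5
                    lineage = rng.choice(terms, size=c)
                else:
                    grid = 0.5 + grid * 0.5
                    lineage = np.full(c, t)
                log_mu = (
                    baseline
                    + grid[:, None] * type_effect[lineage]
                    + batch_effect[b]
                )
                pseudotime.extend(grid)
            else:
                log_mu = np.tile(
                    baseline + type_effect[t] + batch_effect[b], (c, 1)
                )
                pseudotime.extend([np.nan] * c)
            lib = rng.lognormal(0.0, design.libsize_sigma, size=c)
            mu = np.exp(log_mu) * lib[:, None]
            r = 1.0 / dispersion
            p = r / (r + mu)
            rows.append(rng.negative_binomial(np.broadcast_to(r, mu.shape), p))
            batches.extend([f"batch{b + 1}"] * c)
            labels.extend([f"type{t + 1}"] * c)
            counter += c
    counts = np.vstack(rows)
    cell_ids = [f"c{i:05d}" for i in range(counts.shape[0])]
    gene_ids = [f"g{j:04d}" for j in range(m)]
    meta = CellMetadata(
        cell_ids=np.asarray(cell_ids, dtype=object),
        batch=np.asarray(batches, dtype=object),
        label=np.asarray(labels, dtype=object),
    )
    truth = {
        "de_genes": {f"type{t + 1}": de[t] for t in range(design.n_types)},
        "batch_genes": {f"batch{b + 1}": batch_genes[b] for b in range(design.n_batches)},
        "pseudotime": np.asarray(pseudotime),
        "gene_ids": gene_ids,
    }
    if traj is not None:
        truth["late_genes"] = {
            f"type{t + 1}": np.setdiff1d(de[t], de[prog]) for t in terms
        }
    return counts, meta, truth


def make_scenario(name: str, scale: str = "tiny") -> SimDesign:
    """Frozen, documented designs mirroring the benchmark settings.

    balanced
        every type present with equal counts in both batches.
    imbalanced
        types downsampled in batch 2 to 5%, 10% and 100% of the balanced
        count (the complete-absence member of that series is the separate
        ``ablated`` scenario).
    ablated
        exactly one type absent from one batch.
    similar_pairs
        one transcriptionally similar pair (80% shared differential genes)
        with one member absent per batch — the hardest integration setting.
    trajectory
        a single batch with a progenitor and a terminal type joined by a
        20-step pseudotime axis.
    """
    if scale not in ("tiny", "small"):
        raise ValueError("scale must be 'tiny' or 'small'")
    tiny = scale == "tiny"
    # type abundances are deliberately unequal: real tissues never carry
    # equal cell-type proportions, and perfectly symmetric types give the
    # probability-median splits no confidence differential to work with
    if name == "balanced":
        base = np.array([60, 45, 30]) if tiny else np.array([210, 180, 120, 90])
        m = 150 if tiny else 300
        cells = np.column_stack([base, base])
        return SimDesign(n_types=len(base), cells_per_type_per_batch=cells, m_genes=m)
    if name == "imbalanced":
        base = np.array([60, 50, 40, 30]) if tiny else np.array([210, 180, 120, 90])
        m = 150 if tiny else 300
        cells = np.column_stack([base, base])
        cells[0, 1] = max(1, round(0.05 * base[0]))
        cells[1, 1] = max(1, round(0.10 * base[1]))
        return SimDesign(n_types=len(base), cells_per_type_per_batch=cells, m_genes=m)
    if name == "ablated":
        base = np.array([60, 50, 40, 30]) if tiny else np.array([210, 180, 120, 90])
        m = 150 if tiny else 300
        cells = np.column_stack([base, base])
        cells[0, 1] = 0
        return SimDesign(n_types=len(base), cells_per_type_per_batch=cells, m_genes=m)
    if name == "similar_pairs":
        base = (
            np.array([90, 75, 60, 45, 30]) if tiny else np.array([450, 375, 300, 225, 150])
        )
        m = 200 if tiny else 600
        cells = np.column_stack([base, base])
        cells[3, 1] = 0  # pair member A only in batch 1
        cells[4, 0] = 0  # pair member B only in batch 2
        return SimDesign(
            n_types=len(base),
            cells_per_type_per_batch=cells,
            m_genes=m,
            similarity_pairs=[(3, 4, 0.8)],
        )
    if name == "trajectory":
        # one progenitor hub with three lineages radiating from it; the
        # competing lineage signatures make the undifferentiated hub
        # genuinely ambiguous, as in haematopoietic differentiation
        base = np.array([[90], [50], [50], [50]]) if tiny else np.array(
            [[240], [140], [140], [140]]
        )
        m = 150 if tiny else 300
        return SimDesign(
            n_types=4,
            cells_per_type_per_batch=base,
            m_genes=m,
            trajectory=(0, (1, 2, 3), 20),
            de_frac=0.1,
            de_lfc=2.0,
        )
    raise ValueError(f"unknown scenario {name!r}")


def scenario_data(design_or_name, scale: str = "tiny", seed: int = 0):
    """Simulate a design and return analysis-ready inputs.

    Accepts a :class:`SimDesign` or a scenario name; counts are
    log-normalized and never-expressed genes dropped, as for real data.

    Returns
    -------
    (X, meta, truth) : ExpressionMatrix, CellMetadata, truth dict.
    """
    if isinstance(design_or_name, str):
        design = make_scenario(design_or_name, scale)
        design.seed = seed
    else:
        design = design_or_name
    counts, meta, truth = simulate(design)
    X = log_normalize(
        counts, cell_ids=meta.cell_ids, feature_ids=truth["gene_ids"]
    )
    return filter_unexpressed(X), meta, truth
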