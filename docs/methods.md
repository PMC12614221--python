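# Methods

`scicp` integrates multi-batch single-cell expression data by divisive
iterative clustering projection (ICP), an ensemble of self-supervised
clusterings whose assignment probabilities define an integrated linear
embedding, a reference-mapping classifier, and a per-cell state score.
This note records the model, the choices behind its defaults, what the
synthetic data generator does and does not emulate, and the numerical
conventions.

## The model

**Working set.** The engine never iterates over raw cells. Cells are first
log-normalized (`ln(1 + c·s/total)`, scale factor `s = 10 000`,
pseudocount 1), restricted to highly variable genes (HVGs, default 2000),
and each batch is partitioned into a large number of k-means++ groups
(default 500 per batch, computed in a joint 30-PC space of the
standardized HVG matrix). The group-mean profiles — a few cells each —
form the training matrix. This balances batches (each contributes up to
500 profiles regardless of its cell count), denoises, and separates the
data the classifiers are trained on from the cells they finally score.

**ICP inner loop.** Given a k-clustering of the profiles, one
L1-regularized binary logistic classifier is fitted per cluster
(one-vs-rest, liblinear), every profile is re-assigned to its
highest-probability cluster (sigmoid scores normalized to sum 1 per row;
exact ties go to the lowest cluster index), and the adjusted Rand index
(ARI) between clustering and projection is computed from the contingency
table. The projection is accepted as the next clustering only when this
ARI strictly exceeds the best accepted value (initialized at 0);
otherwise the same clustering is retried, up to `r = 5` consecutive
failures or `max_iter = 200` epochs in total. Epoch 1 trains on all
profiles; every later epoch trains on a batch-balanced refinement: for
each (cluster j, batch b) the member with the highest assignment
probability is the representative, and it joins the subset together with
its `max(1, floor(prop·|C_j|/B))` nearest profiles (Euclidean, in HVG
expression space, across all batches), `prop = 0.3` by default.

**Divisive outer loop.** Round 1 initializes two clusters by cutting the
profiles at batch-wise medians of their first principal component
(standardized data, all non-zero-variance features). After each round
converges, every cluster is split in two at batch-wise medians of its
members' maximum assignment probability (members at or below their
(cluster, batch) median form the low child), and ICP runs again, so round
q targets `k = 2^q` clusters up to `K = 16` by default. With
`allow_free_k = True` (default) clusters that lose all members are
dropped; setting it `False` treats such epochs as failed reiterations,
which together with the relaxed setting (`cost = 1`,
`train_knn_prop = 0.45`, `ari_cutoff = 0.1`) enforces exactly K clusters.
The whole procedure runs `L = 50` times (defaults; the tests and the
acceptance experiments use `L = 8` to fit their compute budget — problem
sizes are stated below) with per-run seeds derived deterministically from
the global seed, and every real cell is scored by every round's model.
Runs whose terminal accepted ARI falls below `ari_cutoff = 0.3` are
excluded from downstream concatenation (they remain in the result object
for audit; if every run falls below the cutoff downstream steps refuse
rather than silently proceed).

**Embedding, mapping, states.** Per-cell probability tables of the kept
runs (final round by default; any subset of rounds on request) are
concatenated column-wise, centred and scaled per column (numerically
constant columns get a unit sentinel so they contribute zero), and
decomposed by PCA with a deterministic sign convention (each loading
column's largest-magnitude entry is positive). A reference model freezes
the fitted ICP models, the embedding statistics and the reference labels;
query cells are scored by the same models (features aligned by id,
missing ones zero-filled — the neutral value for log-normalized absence —
with a 50% overlap floor), projected with the reference's column
statistics, and labelled by majority vote among their 10 nearest
reference cells, ties broken by smaller mean neighbour distance then
lexicographically; the winning vote fraction is the confidence. The
cell-state score is the mean over kept runs of each cell's maximum
assignment probability; per cell type, cells are sorted by score and cut
into 20 equal-count bins ("evenly sized" read as equal counts — robust to
skewed score distributions; remainders go to the lowest bins, ties broken
by cell id), and each gene's Pearson correlation between bin-mean score
and bin-mean expression ranks genes along the state axis.

## Why the default cost is 0.05

The liblinear cost C (inverse penalty weight) is the one load-bearing
free parameter. The accept/reject loop only works when the classifier
*cannot* reproduce an arbitrary partition: then projections drift toward
partitions representable by few genes — real cluster structure — and ARI
climbs as the labels lock onto it. At C ≥ 0.1 a liblinear L1 fit
reproduces any labelling of ~1000 profiles essentially exactly
(self-agreement ARI 1.0 after one epoch), so the loop freezes on the
initial PC1 cut and never migrates. At C = 0.05 arbitrary cuts reach only
~0.7 training accuracy while marker-aligned cuts remain representable,
and planted types are recovered. The default is therefore 0.05, calibrated
once on the synthetic scenarios and frozen; C = 1 remains the documented
relaxed setting for forcing the full cluster count.

## Synthetic data: what it emulates, what it does not

Counts are negative-binomial with gene-wise dispersion ~ U(0.1, 0.4),
gene baseline log-means ~ N(1, 0.8), and per-cell lognormal library-size
factors (σ = 0.3) so that log-normalization is non-trivially exercised.
Cell types add `de_lfc` (default 1.0, natural-log scale) on a planted
fraction of genes (default 5%); "similar" type pairs share a stated
fraction of their differential genes; batches add ±0.3 shifts on 20% of
genes each. The batch magnitude was set once so that same-type cells
across batches remain closer than different-type cells — the premise that
makes horizontal integration possible at all; shifts as large as the type
separation would make batches disjoint clouds with no pairing signal, a
regime no integration method addresses. Scenario type proportions are
deliberately unequal (real tissues are imbalanced; perfectly symmetric
types give the batch-wise probability-median split no confidence
differential to act on — a pathology of exact symmetry that real data
never exhibits).

Trajectory mode emulates multi-lineage differentiation: a progenitor hub
sits at the unsigned baseline (an undifferentiated state is the absence
of lineage signatures) and one or more lineages ramp their terminal
signatures linearly with pseudotime. The competing lineages make hub
cells genuinely ambiguous, which is what gives the state score its
positive correlation with pseudotime. The trajectory and the
reference-mapping scenarios use strong signatures (`de_frac = 0.1`,
`de_lfc = 2.0`, ≈ 7-fold change — terminal differentiation markers in
real data easily exceed this); the integration scenarios keep the harder
defaults.

Not emulated: nested or cell-type-specific batch effects, doublets,
ambient RNA, zero-inflation beyond NB sampling, and realistic
mean-variance trends of UMI data. Passing tests therefore demonstrate the
machinery's behaviour under controlled conditions, not performance claims
on real tissue atlases.

## Problem sizes used by the tests and acceptance experiments

- Integration recovery: 2 batches × 5 NB types with one 80%-similar pair
  cross-ablated (each member present in one batch only), 3000 cells, 600
  genes, `L = 8`, `K = 8`; k-means at the true k (`n_init = 50`) on the
  integrated embedding, 8 data seeds.
- Reference mapping: symmetric batches of 600 cells × 4 well-separated
  types, 300 genes, single-batch references built in global ("cluster")
  mode with `L = 8`, `K = 8`; accuracies averaged over 5 seeds. The
  confidence experiment ablates the similar pair member from the
  reference and uses the default (harder) effect sizes.
- Cell states: one batch, 620 cells on a 3-lineage trajectory, 300
  genes, 20-step pseudotime grid, 5 seeds.

## Numerical conventions and edge cases

- ARI from the pair-counting contingency formula; when both partitions
  are trivially identical in structure (denominator 0) the value is 1.
- Deterministic everywhere given the seed: per-run and per-batch seeds
  derive from `SeedSequence(global_seed, index)`; batch members are
  processed in cell-id order so results are invariant to input row order;
  k-means++ and liblinear receive derived integer seeds.
- Probability rows are validated to sum to 1 ± 1e-8 at construction.
- Standardization treats features whose standard deviation is below
  `1e-12·max(1, |mean|)` as constant (dropped in PCA, sentinel 1 in the
  embedding) — genuine zero variance stored in floating point can
  otherwise leak representation noise into the decomposition.
- The mean–variance trend for HVG selection is a 31-point running median
  over features sorted by mean, with mirror padding at the edges
  (nearest-style padding would let an extreme-mean feature dominate its
  own window and cancel its own residual).
- During reiterations the refinement subset is recomputed from the most
  recent probability matrix (including rejected epochs'), so retries
  explore rather than repeat verbatim.
- The batch-mixing score compares each cell's observed same-batch
  neighbour fraction (k = 30, self excluded) with the expectation under
  perfect mixing, rescaled so 1 means mixed and 0 means fully separated;
  a single batch is defined as perfectly mixed.

## Known limitations

- Ensemble diversity across the L runs is low by construction: the
  initialization, training set and refinement are deterministic, so runs
  differ only through the solver seed. The ensemble hedges against
  solver-level degeneracy, not against a poor round-1 cut shared by all
  runs.
- The divisive split keys on assignment confidence; co-clustered types
  with near-identical confidence profiles (possible under exact symmetry)
  give it nothing to act on.
- On data with very few cells per batch the 500-group default makes
  profiles singletons and the averaging stage is inoperative.
- No rejection class: a query type absent from (and dissimilar to
  everything in) the reference is still assigned a reference label,
  possibly with high confidence; only similarity to a present sibling
  depresses confidence.
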