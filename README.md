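# scicp

Multi-batch single-cell integration by **divisive iterative clustering
projection (ICP)**, with reference mapping (label transfer with
confidence scores) and probability-based cell-state inference.

Single-cell experiments routinely combine datasets from different
samples, donors or platforms, whose systematic expression shifts (batch
effects) confound clustering and annotation — especially when similar
cell types are imbalanced across batches or missing from some of them.
`scicp` is for computational biologists who need to (i) cluster cells
jointly across batches, (ii) transfer cell-type labels from an annotated
reference to new data without retraining, and (iii) rank cells within a
type by how stable or transient their expression state is.

## The method

ICP is self-supervised clustering by agreement. Given a partition
π_k = {C_1, …, C_k} of the working set, it fits one L1-regularized
logistic classifier per cluster (one-vs-rest, the liblinear problem
min_w { Σ_i log(1 + e^{−y_i wᵀx_i}) + λ‖w‖₁ }), projects every item to
its most probable cluster, and accepts the projection π̃_k as the next
partition only when ARI(π_k, π̃_k) strictly increases; non-improving
epochs are retried up to r = 5 times. Because the L1 budget cannot
represent arbitrary boundaries, the accepted partitions migrate toward
splits supported by small sets of marker genes.

Around this loop sit four batch-aware stages:

1. **Training set** — each batch is condensed into up to 500 k-means++
   group-average profiles over 2000 highly variable genes, balancing
   batch representation.
2. **Divisive rounds** — round 1 cuts profiles at batch-wise medians of
   PC1; after convergence every cluster C_j is split at batch-wise
   medians τ_jb of its members' maximum assignment probability, doubling
   k = 2^q per round up to K. Training subsets after epoch 1 are the
   per-(cluster, batch) top-confidence representatives plus their
   floor(0.3·|C_j|/B) nearest profiles.
3. **Ensemble + embedding** — the procedure runs L times with independent
   seeds; all per-cell probability tables are concatenated, z-scored and
   decomposed by PCA into the integrated embedding.
4. **Downstream** — kNN majority voting in the reference embedding
   transfers labels with a vote-fraction confidence; the mean maximum
   assignment probability across runs scores cell states, and binning
   cells on it (20 equal-count bins per type) ranks genes by the Pearson
   correlation of bin-mean expression with bin-mean probability.

See `docs/methods.md` for assumptions, defaults and limitations.

## Worked example

Everything runs on simulated data with known ground truth — no downloads.
The hardest built-in scenario has five negative-binomial cell types in
two batches, where two types share 80% of their differential genes and
each member of that pair exists in only one batch:

```python
import numpy as np
from sklearn.cluster import KMeans
from scicp import MultiLevelIntegration, adjusted_rand_index
from scicp.synthetic_data import scenario_data

X, meta, truth = scenario_data("similar_pairs", "small", seed=101)
model = MultiLevelIntegration(X, meta, K=8, L=8)
results = model.fit(seed=1)
print(results.summary())

km = KMeans(5, n_init=50, random_state=0).fit(results.scores)
print("ARI vs true types:", adjusted_rand_index(km.labels_, meta.label))
print("batch mixing:", results.batch_mixing())
```

Output (2625 cells × 600 genes):

```
 run        seed  k_round1  k_round2  k_round3  epochs_final  terminal_ari  kept
   1  1835504127         2         4         8             6      0.526823  True
   ...
   8  2097731053         2         4         8             6      0.535100  True
k-means ARI vs true types: 0.750
batch mixing (1 = perfectly mixed): 0.910
```

Each row is one divisive run: the cluster count per round (2 → 4 → 8),
the epochs of the final round, the terminal clustering–projection ARI,
and whether the run survived the ARI cutoff. k-means at the true k on
the integrated embedding recovers the planted types (ARI 0.75 despite the
cross-ablated similar pair), and the embedding mixes the two batches
almost perfectly (0.91) where unintegrated PCA keeps them apart (≈ 0.00).

Label transfer from a fitted, labelled reference:

```python
ref = results.build_reference(k_nn=10)          # needs meta labels
from scicp import project_query, knn_transfer, mapping_accuracy
mapped = knn_transfer(ref, project_query(ref, X_query))
```

## Command line

```bash
scicp simulate --scenario similar_pairs --scale small --seed 1 --out data/
scicp integrate --matrix data/matrix.mtx --meta data/metadata.tsv \
      --normalize --k 8 --l 8 --seed 1 --out run/
scicp map --reference run/ref.scicp --matrix query.mtx --out mapped/
scicp states --model run/model.scicp --matrix data/matrix.mtx \
      --meta data/metadata.tsv --label-col label --out states/
```

Every command echoes its resolved configuration, seeds and input
checksums into the output directory.

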