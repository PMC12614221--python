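import numpy as np
import pytest
from sklearn.cluster import KMeans

from scicp.data_io import CellMetadata, ExpressionMatrix
from scicp.divisive_icp import (
    DivisiveParams,
    initialize_clusters_pc1,
    refine_training_subset,
    run_divisive_icp,
    split_clusters,
)
from scicp.icp_core import ICPParams, ProbabilityMatrix, adjusted_rand_index
from scicp.training_set import PCAModel, TrainingSet, compute_pca, select_hvgs


def _pm(p_by_item):
    """Two-column probability matrix with the given max per item."""
    p = np.asarray(p_by_item, dtype=float)
    return ProbabilityMatrix(
        probs=np.column_stack([p, 1 - p]), classes=np.array([1, 2])
    )


def _train_with_scores(pc1, batches):
    n = len(pc1)
    profiles = np.column_stack([pc1, np.zeros(n)])
    pca = PCAModel(
        means=np.zeros(2), sds=np.ones(2),
        loadings=np.eye(2), scores=profiles.copy(), n_pcs=2,
    )
    ts = TrainingSet(
        profiles=profiles,
        profile_batch=np.asarray(batches, dtype=object),
        membership=[np.array([f"c{i}"]) for i in range(n)],
        source_features=np.array(["f1", "f2"], dtype=object),
    )
    return ts, pca


class TestInitializePC1:
    def test_single_batch_median_cut(self):
        ts, pca = _train_with_scores([-2.0, -1.0, 1.0, 2.0], ["b"] * 4)
        labels = initialize_clusters_pc1(ts, pca, batches=ts.profile_batch)
        np.testing.assert_array_equal(labels, [1, 1, 2, 2])

    def test_batch_offsets_split_within_each_batch(self):
        pc1 = [-102, -101, -99, -98, 98, 99, 101, 102]
        batches = ["a"] * 4 + ["b"] * 4
        ts, pca = _train_with_scores(pc1, batches)
        labels = initialize_clusters_pc1(ts, pca, batches=ts.profile_batch)
        # each batch is cut at its own median, so both clusters contain
        # profiles from both batches despite the +-100 offset
        for cluster in (1, 2):
            assert {b for b, l in zip(batches, labels) if l == cluster} == {"a", "b"}

    def test_all_equal_scores_fall_to_cluster_one(self):
        ts, pca = _train_with_scores([0.5] * 5, ["b"] * 5)
        labels = initialize_clusters_pc1(ts, pca, batches=ts.profile_batch)
        np.testing.assert_array_equal(labels, 1)

    def test_global_median_when_unbatched(self):
        ts, pca = _train_with_scores([-2.0, -1.0, 1.0, 2.0], ["a", "a", "b", "b"])
        labels = initialize_clusters_pc1(ts, pca, batches=None)
        np.testing.assert_array_equal(labels, [1, 1, 2, 2])


class TestSplitClusters:
    def test_single_batch_median_threshold(self):
        P = _pm([0.9, 0.8, 0.6, 0.5])
        out = split_clusters(np.ones(4, dtype=int), P, batches=None)
        # tau = 0.7: low side {0.6, 0.5} -> 2j-1 = 1, high side -> 2
        np.testing.assert_array_equal(out, [2, 2, 1, 1])

    def test_singleton_cluster_goes_to_low_side(self):
        P = _pm([0.8])
        out = split_clusters(np.array([1]), P, batches=None)
        np.testing.assert_array_equal(out, [1])

    def test_two_batches_split_at_their_own_medians(self):
        # batch a: maxima 0.9/0.8/0.7/0.6 (tau 0.75), batch b: 0.58/0.56/0.54/0.52
        p = [0.9, 0.8, 0.7, 0.6, 0.58, 0.56, 0.54, 0.52]
        batches = np.array(["a"] * 4 + ["b"] * 4)
        out = split_clusters(np.ones(8, dtype=int), _pm(p), batches=batches)
        expected = []
        for b in ("a", "b"):
            mask = batches == b
            tau = np.median(np.asarray(p)[mask])
            expected.extend(1 if v <= tau else 2 for v in np.asarray(p)[mask])
        np.testing.assert_array_equal(out, expected)

    def test_cluster_indices_spawn_disjoint_children(self):
        p = [0.9, 0.5, 0.9, 0.5]
        assignments = np.array([1, 1, 2, 2])
        out = split_clusters(assignments, _pm(p), batches=None)
        np.testing.assert_array_equal(out, [2, 1, 4, 3])


class TestRefineTrainingSubset:
    def test_neighbour_budget_floor(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(100, 4))
        batches = np.repeat(["a", "b", "c"], [34, 33, 33])
        P = ProbabilityMatrix(
            probs=np.column_stack([np.full(100, 0.8), np.full(100, 0.2)]),
            classes=np.array([1, 2]),
        )
        # |C_j| = 100, B = 3 -> floor(0.3*100/3) = 10 neighbours per rep
        subset = refine_training_subset(
            np.ones(100, dtype=int), P, batches, X_profiles=X, prop=0.3
        )
        assert len(subset) <= 3 * 11 and len(subset) >= 11

    def test_floor_clamped_to_one(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(10, 3))
        batches = np.repeat(["a", "b", "c", "d"], [3, 3, 2, 2])
        P = ProbabilityMatrix(
            probs=np.column_stack([np.linspace(0.6, 0.9, 10), 1 - np.linspace(0.6, 0.9, 10)]),
            classes=np.array([1, 2]),
        )
        # floor(0.3*10/4) = 0 -> clamped to 1 neighbour per representative
        subset = refine_training_subset(
            np.ones(10, dtype=int), P, batches, X_profiles=X, prop=0.3
        )
        assert 4 <= len(subset) <= 8

    def test_matches_exhaustive_distance_sort_oracle(self):
        rng = np.random.default_rng(2)
        n = 40
        X = rng.normal(size=(n, 5))
        batches = np.array(["a", "b"] * 20)
        assignments = np.array([1] * 20 + [2] * 20)
        probs = rng.dirichlet(np.ones(2), size=n)
        P = ProbabilityMatrix(probs=probs, classes=np.array([1, 2]))
        got = set(
            refine_training_subset(assignments, P, batches, X_profiles=X, prop=0.3)
        )
        expected = set()
        B = 2
        for j in (1, 2):
            members_j = np.flatnonzero(assignments == j)
            n_neigh = max(1, int(np.floor(0.3 * len(members_j) / B)))
            for b in ("a", "b"):
                members = [i for i in members_j if batches[i] == b]
                rep = max(members, key=lambda i: probs[i].max())
                expected.add(rep)
                dists = sorted(
                    (np.linalg.norm(X[i] - X[rep]), i) for i in range(n) if i != rep
                )
                expected.update(i for _, i in dists[:n_neigh])
        assert got == expected


class TestRunDivisive:
    def test_structure_rows_sum_and_k_bounds(self, tiny_multirun):
        res = tiny_multirun
        for rounds in res.runs:
            prev_k = 0
            for rr in rounds:
                assert rr.k <= 2 ** rr.round_q
                assert rr.k >= prev_k  # cluster count never decreases
                prev_k = rr.k
                np.testing.assert_allclose(
                    rr.cell_probs.probs.sum(axis=1), 1.0, atol=1e-8
                )
                np.testing.assert_allclose(
                    rr.train_probs.probs.sum(axis=1), 1.0, atol=1e-8
                )

    def test_same_seed_identical_result(self, tiny_balanced, tiny_params):
        X, meta, _ = tiny_balanced
        r1 = run_divisive_icp(X, meta, tiny_params, seed=3)
        r2 = run_divisive_icp(X, meta, tiny_params, seed=3)
        for a, b in zip(r1.runs, r2.runs):
            for ra, rb in zip(a, b):
                np.testing.assert_array_equal(ra.cell_probs.probs, rb.cell_probs.probs)
                np.testing.assert_array_equal(ra.model.coefficients, rb.model.coefficients)
        np.testing.assert_array_equal(r1.kept_runs, r2.kept_runs)

    def test_invalid_k_rejected(self):
        with pytest.raises(ValueError):
            DivisiveParams(K=6)

    def test_median_assignment_probability_decreases_with_rounds(self, tiny_multirun):
        # finer clusters are harder to claim confidently: the grand median
        # of per-cluster median maxima should not rise between rounds
        for rounds in tiny_multirun.runs:
            meds = []
            for rr in rounds:
                p_max = rr.cell_probs.p_max
                labels = rr.cell_probs.classes[np.argmax(rr.cell_probs.probs, axis=1)]
                meds.append(
                    np.median(
                        [np.median(p_max[labels == c]) for c in np.unique(labels)]
                    )
                )
            for earlier, later in zip(meds, meds[1:]):
                assert later <= earlier + 0.05

    def test_batch_mixing_beats_unintegrated_kmeans_entropy(self):
        # batches share all types but carry a strong technical shift:
        # k-means on raw PCA splits clusters by batch (entropy ~0) while
        # the integrated clusters keep both batches mixed
        from scicp.synthetic_data import SimDesign, scenario_data

        base = np.array([60, 45, 30])
        design = SimDesign(
            n_types=3,
            cells_per_type_per_batch=np.column_stack([base, base]),
            m_genes=150,
            batch_lfc=0.6,
            batch_gene_frac=0.3,
            seed=11,
        )
        X, meta, _ = scenario_data(design)
        res = run_divisive_icp(
            X, meta,
            DivisiveParams(K=4, L=2, n_groups=60, n_pcs=10, n_hvgs=120, icp=ICPParams()),
            seed=3,
        )

        def mean_entropy(labels):
            ent = []
            batches = np.asarray(meta.batch)
            for c in np.unique(labels):
                sub = batches[labels == c]
                freqs = np.unique(sub, return_counts=True)[1] / len(sub)
                ent.append(-(freqs * np.log(freqs)).sum())
            return float(np.mean(ent))

        rr = res.runs[0][-1]
        icp_labels = rr.cell_probs.classes[np.argmax(rr.cell_probs.probs, axis=1)]
        hv = select_hvgs(X, 120)
        pca = compute_pca(X.subset_features(hv.feature_ids).values, n_pcs=10)
        km = KMeans(len(np.unique(icp_labels)), n_init=10, random_state=0).fit(pca.scores)
        assert mean_entropy(icp_labels) > mean_entropy(km.labels_ + 1)

    def test_missing_metadata_cells_rejected(self, tiny_balanced, tiny_params):
        X, meta, _ = tiny_balanced
        short = CellMetadata(meta.cell_ids[:-5], meta.batch[:-5], None)
        with pytest.raises(Exception):
            run_divisive_icp(X, short, tiny_params, seed=0)
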