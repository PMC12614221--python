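import numpy as np
import pytest

from scicp.data_io import CellMetadata, ExpressionMatrix
from scicp.divisive_icp import DivisiveParams
from scicp.icp_core import ICPParams
from scicp.reference_mapping import (
    ReferenceModel,
    build_reference,
    knn_transfer,
    majority_voting_features,
    mapping_accuracy,
    project_query,
)
from scicp.synthetic_data import SimDesign, scenario_data


@pytest.fixture(scope="module")
def tiny_reference():
    X, meta, _ = scenario_data("balanced", "tiny", seed=21)
    params = DivisiveParams(K=4, L=2, n_groups=60, n_pcs=10, n_hvgs=120, icp=ICPParams())
    return X, meta, build_reference(X, meta, params, seed=1, d=10, k_nn=5)


class TestBuildReference:
    def test_stores_labels_and_scores(self, tiny_reference):
        X, meta, ref = tiny_reference
        assert set(ref.ref_labels) == set(meta.label)
        assert ref.ref_scores.shape == (X.n_cells, ref.embedding.d)

    def test_same_seed_reproducible(self, tiny_reference):
        X, meta, ref = tiny_reference
        params = DivisiveParams(K=4, L=2, n_groups=60, n_pcs=10, n_hvgs=120, icp=ICPParams())
        ref2 = build_reference(X, meta, params, seed=1, d=10, k_nn=5)
        np.testing.assert_allclose(ref.ref_scores, ref2.ref_scores, atol=0)

    def test_single_batch_uses_cluster_mode(self):
        X, meta, _ = scenario_data("balanced", "tiny", seed=22)
        mask = np.asarray(meta.batch) == "batch1"
        Xb = ExpressionMatrix(X.values[mask], X.cell_ids[mask], X.feature_ids)
        mb = CellMetadata(meta.cell_ids[mask], meta.batch[mask], meta.label[mask])
        params = DivisiveParams(
            K=4, L=2, n_groups=50, n_pcs=10, n_hvgs=120,
            divisive_method="cluster", icp=ICPParams(ari_cutoff=0.0),
        )
        ref = build_reference(Xb, mb, params, seed=0, d=8)
        assert ref.ref_scores.shape[0] == int(mask.sum())

    def test_missing_labels_rejected(self, tiny_balanced):
        X, meta, _ = tiny_balanced
        unlabelled = CellMetadata(meta.cell_ids, meta.batch, None)
        with pytest.raises(ValueError):
            build_reference(X, unlabelled, DivisiveParams(K=4, L=1))


class TestProjectQuery:
    def test_self_projection_recovers_reference_scores(self, tiny_reference):
        X, _, ref = tiny_reference
        scores = project_query(ref, X)
        np.testing.assert_allclose(scores, ref.ref_scores, atol=1e-8)

    def test_feature_permutation_invariance(self, tiny_reference):
        X, _, ref = tiny_reference
        rng = np.random.default_rng(0)
        perm = rng.permutation(X.n_features)
        Xp = ExpressionMatrix(X.values[:, perm], X.cell_ids, X.feature_ids[perm])
        np.testing.assert_allclose(
            project_query(ref, Xp), project_query(ref, X), atol=1e-10
        )

    def test_small_feature_dropout_perturbs_scores_boundedly(self):
        # zero-filling ~10% of the model features: bounds below were
        # measured once on this design (max score perturbation ~1.0,
        # mean prediction agreement ~0.84) and frozen with margin.
        # Sparse L1 models concentrate on few genes, so single draws vary.
        base = np.array([[60], [50], [40]])
        design = SimDesign(
            n_types=3, cells_per_type_per_batch=base, m_genes=150,
            de_frac=0.1, de_lfc=2.0, seed=21,
        )
        X, meta, _ = scenario_data(design)
        params = DivisiveParams(
            K=4, L=2, n_groups=60, n_pcs=10, n_hvgs=120,
            divisive_method="cluster", icp=ICPParams(ari_cutoff=0.0),
        )
        ref = build_reference(X, meta, params, seed=1, d=10, k_nn=5)
        full_scores = project_query(ref, X)
        full = knn_transfer(ref, full_scores)
        pos = {f: i for i, f in enumerate(X.feature_ids)}
        rels, agreements = [], []
        for s in range(5):
            keep = np.random.default_rng(s).random(len(ref.feature_ids)) > 0.10
            feats = np.asarray(ref.feature_ids)[keep]
            Xq = ExpressionMatrix(
                X.values[:, [pos[f] for f in feats]], X.cell_ids, feats
            )
            dropped_scores = project_query(ref, Xq)
            rels.append(
                np.linalg.norm(dropped_scores - full_scores)
                / np.linalg.norm(full_scores)
            )
            dropped = knn_transfer(ref, dropped_scores)
            agreements.append((dropped.predicted == full.predicted).mean())
        assert max(rels) <= 1.5
        assert np.mean(agreements) >= 0.7

    def test_low_overlap_refused(self, tiny_reference):
        X, _, ref = tiny_reference
        few = list(ref.feature_ids[:10])
        sub = X.subset_features(few)
        with pytest.raises(ValueError, match="floor"):
            project_query(ref, sub)


class TestKnnTransfer:
    def test_coincident_query_inherits_label_with_full_confidence(self):
        rng = np.random.default_rng(2)
        scores = np.vstack([rng.normal(0, 0.1, (20, 3)), rng.normal(8, 0.1, (20, 3))])
        labels = np.array(["a"] * 20 + ["b"] * 20, dtype=object)
        ref = _fake_ref(scores, labels, k_nn=10)
        res = knn_transfer(ref, scores[:1])
        assert res.predicted[0] == "a" and res.confidence[0] == 1.0

    def test_even_vote_broken_by_mean_distance(self):
        # 5 reference points per label; the "near" label sits closer
        near = np.tile([[0.0, 0.0]], (5, 1)) + np.arange(5)[:, None] * 0.01
        far = np.tile([[1.0, 0.0]], (5, 1)) + np.arange(5)[:, None] * 0.01
        scores = np.vstack([near, far])
        labels = np.array(["near"] * 5 + ["far"] * 5, dtype=object)
        ref = _fake_ref(scores, labels, k_nn=10)
        res = knn_transfer(ref, np.array([[0.3, 0.0]]))
        assert res.predicted[0] == "near"
        assert res.confidence[0] == pytest.approx(0.5)

    def test_matches_brute_force_vote_oracle(self):
        rng = np.random.default_rng(3)
        scores = rng.normal(size=(60, 4))
        labels = rng.choice(["x", "y", "z"], size=60).astype(object)
        ref = _fake_ref(scores, labels, k_nn=7)
        queries = rng.normal(size=(25, 4))
        res = knn_transfer(ref, queries)
        for i, q in enumerate(queries):
            order = np.argsort([np.linalg.norm(q - s) for s in scores], kind="stable")[:7]
            neigh = labels[order]
            dists = np.array([np.linalg.norm(q - scores[j]) for j in order])
            cands = {}
            for lab in set(neigh):
                mask = neigh == lab
                cands[lab] = (-mask.sum(), dists[mask].mean(), str(lab))
            winner = min(cands, key=cands.get)
            assert res.predicted[i] == winner

    def test_k_nn_larger_than_reference_rejected(self):
        scores = np.zeros((3, 2))
        ref = _fake_ref(scores, np.array(["a", "b", "c"], dtype=object), k_nn=5)
        with pytest.raises(ValueError):
            knn_transfer(ref, np.zeros((1, 2)))


def _fake_ref(scores, labels, k_nn):
    from scicp.embedding import EmbeddingModel

    emb = EmbeddingModel(
        col_means=np.zeros(scores.shape[1]),
        col_sds=np.ones(scores.shape[1]),
        loadings=np.eye(scores.shape[1]),
        scores=scores,
        d=scores.shape[1],
        col_names=list(range(scores.shape[1])),
        source={},
    )
    return ReferenceModel(
        icp=None, embedding=emb, ref_labels=labels, ref_scores=scores, k_nn=k_nn
    )


class TestMappingAccuracy:
    def test_trivial_fractions(self):
        acc, _ = mapping_accuracy(["a", "b", "c", "c"], ["a", "b", "c", "a"])
        assert acc == 0.75
        acc, _ = mapping_accuracy(["a"] * 4, ["a"] * 4)
        assert acc == 1.0

    def test_matches_confusion_trace(self):
        rng = np.random.default_rng(4)
        truth = rng.choice(["a", "b", "c"], size=200)
        pred = np.where(rng.random(200) < 0.7, truth, rng.choice(["a", "b", "c"], size=200))
        acc, conf = mapping_accuracy(pred, truth)
        trace = sum(conf.loc[l, l] for l in conf.index if l in conf.columns)
        assert acc == pytest.approx(trace / conf.values.sum())


class TestMajorityVotingFeatures:
    def test_planted_markers_surface_in_top_coefficients(self):
        base = np.array([70, 60, 50, 40])
        design = SimDesign(
            n_types=4,
            cells_per_type_per_batch=np.column_stack([base, base]),
            m_genes=150,
            de_frac=0.08,
            de_lfc=2.0,
            seed=31,
        )
        X, meta, truth = scenario_data(design)
        from scicp.divisive_icp import run_divisive_icp

        params = DivisiveParams(K=8, L=4, n_groups=80, n_pcs=10, n_hvgs=150, icp=ICPParams())
        res = run_divisive_icp(X, meta, params, seed=2)
        out = majority_voting_features(res, meta.label)
        hits = 0
        for t in ("type1", "type2", "type3", "type4"):
            markers = {f"g{g:04d}" for g in truth["de_genes"][t]}
            top5 = set(out["mean"][t].sort_values(ascending=False).head(5).index)
            hits += bool(top5 & markers)
        assert hits >= 3  # at least 3 of 4 types recover a planted marker

    def test_label_with_zero_cells_rejected(self, tiny_multirun):
        labels = np.asarray(["only_one"] * len(tiny_multirun.cell_ids), dtype=object)
        # declare a vocabulary that includes an empty label via pandas
        with pytest.raises(ValueError):
            majority_voting_features(tiny_multirun, labels[:-1])
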