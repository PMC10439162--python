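import numpy as np
import pytest

from epistates.features import FeatureMatrix, znormalize
from epistates.model import BrainStateLabel
from epistates.prototyping import (
    PrototypeSet,
    build_prototypes,
    fit_pca,
    kmeans_cluster,
    match_centroids,
)


class TestFitPca:
    def test_scores_consistent_with_projection(self, small_feature_matrix):
        proj, scores = fit_pca(small_feature_matrix)
        again = proj.project(small_feature_matrix.values)
        assert np.allclose(scores, again, atol=1e-8)

    def test_collinear_features_rank_one(self):
        base = np.linspace(-1, 1, 50)
        vals = np.column_stack([(i + 1) * base for i in range(11)])
        fm = znormalize(FeatureMatrix(vals))
        proj, _ = fit_pca(fm)
        assert proj.explained_variance_ratio[0] == pytest.approx(1.0)
        assert np.all(proj.explained_variance_ratio[1:] < 1e-10)

    def test_loadings_orthonormal_and_ratios_sorted(self, small_feature_matrix):
        proj, _ = fit_pca(small_feature_matrix)
        gram = proj.coefficients.T @ proj.coefficients
        assert np.allclose(gram, np.eye(4), atol=1e-8)
        evr = proj.explained_variance_ratio
        assert np.all(np.diff(evr) <= 1e-12) and evr.sum() <= 1 + 1e-9

    def test_sign_convention_fixed(self, small_feature_matrix):
        proj, _ = fit_pca(small_feature_matrix)
        for j in range(proj.coefficients.shape[1]):
            col = proj.coefficients[:, j]
            assert col[np.argmax(np.abs(col))] > 0

    def test_too_few_segments_rejected(self):
        with pytest.raises(ValueError):
            fit_pca(FeatureMatrix(np.zeros((3, 11))))


class TestKmeansCluster:
    def test_recovers_separated_blobs(self, rng):
        means = np.array(
            [[10, 0, 0, 0], [-10, 0, 0, 0], [0, 10, 0, 0], [0, -10, 0, 0]], float
        )
        pts = np.vstack([m + 0.5 * rng.normal(size=(50, 4)) for m in means])
        centroids, assign = kmeans_cluster(pts, k=4, seed=0)
        # each fitted centroid lies within sampling error of one true mean
        for m in means:
            d = np.linalg.norm(centroids - m, axis=1).min()
            assert d < 3 * 0.5 / np.sqrt(50) * np.sqrt(4)
        # perfect assignment: every blob maps to a single cluster
        for i in range(4):
            assert len(set(assign[i * 50 : (i + 1) * 50])) == 1

    def test_k_one_gives_grand_mean(self, rng):
        pts = rng.normal(size=(100, 4))
        centroids, _ = kmeans_cluster(pts, k=1, seed=0)
        assert np.allclose(centroids[0], pts.mean(axis=0), atol=1e-8)

    def test_beats_random_centroid_sets(self, rng):
        pts = rng.normal(size=(120, 4))
        centroids, assign = kmeans_cluster(pts, k=4, seed=1)
        wcss = sum(
            np.sum((pts[assign == c] - centroids[c]) ** 2) for c in range(4)
        )
        for _ in range(100):
            cand = pts[rng.choice(len(pts), 4, replace=False)]
            d = ((pts[:, None, :] - cand[None]) ** 2).sum(axis=2)
            rand_wcss = d.min(axis=1).sum()
            assert wcss <= rand_wcss + 1e-9

    def test_reproducible_given_seed(self, rng):
        pts = rng.normal(size=(80, 4))
        c1, a1 = kmeans_cluster(pts, seed=7)
        c2, a2 = kmeans_cluster(pts, seed=7)
        assert np.array_equal(c1, c2) and np.array_equal(a1, a2)

    def test_degenerate_duplicates_rejected(self):
        pts = np.tile([[1.0, 2.0, 3.0, 4.0]], (20, 1))
        with pytest.raises(ValueError):
            kmeans_cluster(pts, k=4, seed=0)


class TestMatchCentroids:
    def test_centroids_at_type_means_get_all_labels(self, rng):
        scores = np.vstack(
            [[10 * t, 0, 0, 0] + 0.1 * rng.normal(size=(20, 4)) for t in range(1, 5)]
        )
        labels = np.repeat([1, 2, 3, 4], 20)
        centroids = np.array([[10 * t, 0, 0, 0] for t in range(1, 5)], float)
        proto = match_centroids(centroids, scores, labels)
        assert [int(l) for l in proto.labels] == [1, 2, 3, 4]

    def test_duplicate_label_keeps_larger_region(self):
        # two centroids both majority-ictal with regions of 30 and 10 votes
        scores = np.vstack(
            [
                np.tile([0.0, 0, 0, 0], (30, 1)),
                np.tile([10.0, 0, 0, 0], (10, 1)),
                np.tile([20.0, 0, 0, 0], (25, 1)),
            ]
        )
        labels = np.array([4] * 30 + [4] * 10 + [1] * 25)
        centroids = np.array(
            [[0.0, 0, 0, 0], [10.0, 0, 0, 0], [20.0, 0, 0, 0]], float
        )
        proto = match_centroids(centroids, scores, labels)
        assert [int(l) for l in proto.labels] == [1, 4]
        ictal_idx = [int(l) for l in proto.labels].index(4)
        assert np.allclose(proto.centroids[ictal_idx], [0.0, 0, 0, 0])
        assert proto.provenance["n_vote_segments"][4] == 30

    def test_empty_region_dropped(self):
        scores = np.tile([0.0, 0, 0, 0], (10, 1))
        labels = np.full(10, 2)
        centroids = np.array([[0.0, 0, 0, 0], [100.0, 0, 0, 0]])
        with pytest.warns(UserWarning):
            proto = match_centroids(centroids, scores, labels)
        assert [int(l) for l in proto.labels] == [2]

    def test_vote_partition_sums_to_all_segments(self, small_feature_matrix):
        from epistates.prototyping import fit_pca, kmeans_cluster
        from scipy.spatial.distance import cdist

        proj, scores = fit_pca(small_feature_matrix)
        centroids, _ = kmeans_cluster(scores, seed=0)
        nearest = np.argmin(cdist(scores, centroids), axis=1)
        sizes = np.bincount(nearest, minlength=4)
        assert sizes.sum() == small_feature_matrix.n_segments

    def test_labels_invariant_under_centroid_permutation(self, rng):
        scores = np.vstack(
            [[5 * t, 0, 0, 0] + 0.1 * rng.normal(size=(15, 4)) for t in range(1, 5)]
        )
        labels = np.repeat([1, 2, 3, 4], 15)
        centroids = np.array([[5 * t, 0, 0, 0] for t in range(1, 5)], float)
        a = match_centroids(centroids, scores, labels)
        perm = [2, 0, 3, 1]
        b = match_centroids(centroids[perm], scores, labels)
        pairs_a = {int(l): tuple(c) for l, c in zip(a.labels, a.centroids)}
        pairs_b = {int(l): tuple(c) for l, c in zip(b.labels, b.centroids)}
        assert pairs_a == pairs_b

    def test_all_regions_empty_impossible_but_no_votes_fatal(self):
        with pytest.raises(ValueError):
            match_centroids(np.zeros((2, 4)), np.zeros((0, 4)), np.zeros(0, dtype=int))


class TestBuildPrototypes:
    def test_model_driven_build_yields_four_types(self, small_feature_matrix):
        proto = build_prototypes(small_feature_matrix, small_feature_matrix, seed=0)
        assert sorted(int(l) for l in proto.labels) == [1, 2, 3, 4]

    def test_self_consistency_of_generating_segments(self, small_feature_matrix):
        from epistates.classification import classify

        proto = build_prototypes(small_feature_matrix, small_feature_matrix, seed=0)
        preds = classify(small_feature_matrix, proto)
        agree = np.mean(
            [
                int(p.predicted_label) == int(t)
                for p, t in zip(preds, small_feature_matrix.true_labels)
            ]
        )
        assert agree >= 0.95

    def test_deterministic_given_seed(self, small_feature_matrix):
        a = build_prototypes(small_feature_matrix, small_feature_matrix, seed=3)
        b = build_prototypes(small_feature_matrix, small_feature_matrix, seed=3)
        assert np.array_equal(a.centroids, b.centroids)
        assert a.labels == b.labels

    def test_degenerate_dataset_fails(self):
        vals = np.tile(np.arange(11.0), (20, 1))
        fm = FeatureMatrix(vals, true_labels=np.ones(20, dtype=int))
        with pytest.raises(ValueError), pytest.warns(UserWarning):
            build_prototypes(fm, fm, seed=0)


class TestPrototypeSerialization:
    def test_json_round_trip(self, small_feature_matrix):
        proto = build_prototypes(small_feature_matrix, small_feature_matrix, seed=0)
        restored = PrototypeSet.from_json(proto.to_json())
        assert np.allclose(restored.centroids, proto.centroids)
        assert restored.labels == proto.labels
        assert np.allclose(
            restored.projection.coefficients, proto.projection.coefficients
        )

    def test_duplicate_labels_rejected(self):
        from epistates.prototyping import Projection

        with pytest.raises(ValueError):
            PrototypeSet(
                np.zeros((2, 4)),
                [BrainStateLabel.ICTAL, BrainStateLabel.ICTAL],
                Projection(np.eye(4), np.zeros(4)),
            )
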