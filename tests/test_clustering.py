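"""Explanation weighting, SVD reduction, K-means, and the metric triple.

Every metric is checked against an independent brute-force implementation on
small random instances, plus exact hand-computed examples.
"""

import itertools

import numpy as np
import pytest
from sklearn.datasets import make_blobs

from xwclust import (ImportanceMap, assign_unseen, davies_bouldin, kmeans,
                     rand_index, reduce_features, select_k, silhouette,
                     weight_image)
from xwclust.errors import (DegenerateDataError, DimensionError, MetricError,
                            ParameterError, ReductionError)

# ---------------------------------------------------------------------------
# independent brute-force oracles


def rand_brute(a, b):
    n = len(a)
    agree = sum(
        ((a[i] == a[j]) == (b[i] == b[j]))
        for i, j in itertools.combinations(range(n), 2))
    return agree / (n * (n - 1) / 2)


def silhouette_brute(x, labels):
    x = np.asarray(x, dtype=float)
    labels = np.asarray(labels)
    scores = []
    for i in range(len(x)):
        own = labels[i]
        same = np.flatnonzero((labels == own))
        same = same[same != i]
        if same.size == 0:
            scores.append(0.0)  # singleton cluster
            continue
        a = np.mean([np.linalg.norm(x[i] - x[j]) for j in same])
        b = min(
            np.mean([np.linalg.norm(x[i] - x[j])
                     for j in np.flatnonzero(labels == other)])
            for other in np.unique(labels) if other != own)
        scores.append((b - a) / max(a, b))
    return float(np.mean(scores))


def davies_bouldin_brute(x, labels):
    x = np.asarray(x, dtype=float)
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    cents = {k: x[labels == k].mean(axis=0) for k in uniq}
    scatter = {k: np.mean([np.linalg.norm(p - cents[k]) for p in x[labels == k]])
               for k in uniq}
    ratios = []
    for k in uniq:
        ratios.append(max(
            (scatter[k] + scatter[j]) / np.linalg.norm(cents[k] - cents[j])
            for j in uniq if j != k))
    return float(np.mean(ratios))


# ---------------------------------------------------------------------------


class TestWeightImage:
    def test_unit_weight_is_identity(self, rng):
        img = rng.random((8, 8, 3))
        np.testing.assert_array_equal(weight_image(img, np.ones((8, 8))), img)

    def test_zero_or_negative_weight_blanks_image(self, rng):
        img = rng.random((8, 8, 3))
        np.testing.assert_array_equal(weight_image(img, np.zeros((8, 8))),
                                      np.zeros((8, 8, 3)))
        np.testing.assert_array_equal(weight_image(img, -np.ones((8, 8))),
                                      np.zeros((8, 8, 3)))

    def test_mask_weight_cuts_out_shape(self, rng):
        img = rng.random((8, 8, 3))
        mask = np.zeros((8, 8))
        mask[2:5, 3:6] = 1.0
        out = weight_image(img, mask)
        np.testing.assert_array_equal(out[2:5, 3:6], img[2:5, 3:6])
        assert (out[mask == 0] == 0.0).all()

    def test_accepts_importance_map(self, rng):
        img = rng.random((4, 4, 3))
        imp = ImportanceMap(values=np.full((4, 4), 0.5), stage="smoothed")
        np.testing.assert_allclose(weight_image(img, imp), 0.5 * img)

    def test_monotone_in_explanation(self, rng):
        img = rng.random((6, 6, 3))
        w = rng.random((6, 6))
        w2 = w.copy()
        w2[3, 3] += 0.2
        d = weight_image(img, w2) - weight_image(img, w)
        assert (d >= 0).all()

    def test_never_exceeds_source_image(self, rng):
        img = rng.random((6, 6, 3))
        w = rng.uniform(-1, 1, size=(6, 6))
        out = weight_image(img, w)
        assert (out <= img + 1e-15).all() and (out >= 0.0).all()

    def test_shape_mismatch(self, rng):
        with pytest.raises(DimensionError):
            weight_image(rng.random((8, 8, 3)), np.ones((4, 4)))


class TestReduceFeatures:
    def test_rank_one_matrix_needs_one_component(self, rng):
        base = rng.random(10)
        x = np.outer(rng.random(12), base)
        red = reduce_features(x, variance_fraction=0.9)
        assert red.n_cols == 1
        assert red.explained_variance_ratio[0] == pytest.approx(1.0)

    def test_two_cluster_toy_separated_by_first_component(self, rng):
        e1 = np.zeros(8)
        e1[0] = 1.0
        x = np.array([e1 + rng.normal(0, 1e-3, 8) for _ in range(6)]
                     + [-e1 + rng.normal(0, 1e-3, 8) for _ in range(6)])
        red = reduce_features(x, target_dim=2)
        signs = np.sign(red.values[:, 0])
        assert (signs[:6] == signs[0]).all() and (signs[6:] == -signs[0]).all()

    def test_near_full_rank_preserves_distances(self, rng):
        x = rng.random((10, 6))
        red = reduce_features(x, target_dim=5)
        # dropped energy bounds the distortion of any pairwise distance
        xc = x - x.mean(axis=0)
        s = np.linalg.svd(xc, compute_uv=False)
        d_orig = np.linalg.norm(x[:, None] - x[None, :], axis=-1)
        d_red = np.linalg.norm(red.values[:, None] - red.values[None, :], axis=-1)
        assert np.abs(d_orig - d_red).max() <= 2 * s[-1] + 1e-9

    def test_transform_matches_training_projection(self, rng):
        x = rng.random((12, 7))
        red = reduce_features(x, target_dim=3)
        np.testing.assert_allclose(red.transform(x), red.values, atol=1e-9)

    def test_deterministic(self, rng):
        x = rng.random((15, 9))
        a = reduce_features(x, variance_fraction=0.9)
        b = reduce_features(x, variance_fraction=0.9)
        np.testing.assert_array_equal(a.values, b.values)

    def test_errors(self, rng):
        with pytest.raises(ReductionError):
            reduce_features(rng.random((1, 5)))
        with pytest.raises(ReductionError):
            reduce_features(rng.random((5, 3)), target_dim=4)
        bad = rng.random((5, 3))
        bad[0, 0] = np.nan
        with pytest.raises(ReductionError):
            reduce_features(bad)


class TestKMeans:
    def test_separable_clouds_recovered(self, rng):
        x, y = make_blobs(n_samples=40, centers=2, cluster_std=0.2,
                          center_box=(-8, 8), random_state=7)
        res = kmeans(x, 2, seed=0)
        assert rand_index(y, res.labels) == 1.0
        assert res.sizes == [20, 20] or sorted(res.sizes) == [20, 20]

    def test_k_equals_n_rows_gives_zero_inertia(self, rng):
        x = rng.random((6, 3))
        res = kmeans(x, 6, seed=0)
        assert res.inertia == pytest.approx(0.0, abs=1e-12)

    def test_one_dimensional_hand_instance(self):
        x = np.array([[0.0], [0.1], [10.0], [10.1]])
        res = kmeans(x, 2, seed=0)
        assert res.labels[0] == res.labels[1]
        assert res.labels[2] == res.labels[3]
        assert res.labels[0] != res.labels[2]
        # optimal inertia: 2 * (0.05^2 + 0.05^2) = 0.01
        assert res.inertia == pytest.approx(0.01)

    def test_restarts_never_hurt(self, rng):
        x = rng.random((30, 4))
        many = kmeans(x, 4, seed=0, n_restarts=10)
        one = kmeans(x, 4, seed=0, n_restarts=1)
        assert many.inertia <= one.inertia + 1e-12

    def test_k_larger_than_n_rejected(self, rng):
        with pytest.raises(DegenerateDataError):
            kmeans(rng.random((3, 2)), 4)
        with pytest.raises(ParameterError):
            kmeans(rng.random((5, 2)), 1)


class TestSelectK:
    def test_three_blobs_recovered(self):
        x, _ = make_blobs(n_samples=60, centers=3, cluster_std=0.3,
                          center_box=(-10, 10), random_state=11)
        sel = select_k(x, 2, 6, seed=0)
        assert sel.k_star == 3
        assert sel.table["silhouette"].idxmax() == 1  # K=3 row
        # silhouette maximum verified directly per K
        for _, row in sel.table.iterrows():
            res = sel.results[int(row["k"])]
            assert row["silhouette"] == pytest.approx(
                silhouette(x, res.labels))

    def test_single_blob_flags_weak_structure(self):
        x, _ = make_blobs(n_samples=40, centers=1, cluster_std=1.0,
                          n_features=10, random_state=3)
        sel = select_k(x, 2, 4, seed=0)
        assert sel.weak_structure
        assert (sel.table["silhouette"] < 0.25).all()

    def test_invalid_range_rejected(self, rng):
        with pytest.raises(ParameterError):
            select_k(rng.random((10, 2)), 3, 2)
        with pytest.raises(ParameterError):
            select_k(rng.random((10, 2)), 2, 10)


class TestRandIndex:
    def test_identical_and_permuted_labelings(self):
        assert rand_index([0, 0, 1, 1], [0, 0, 1, 1]) == 1.0
        assert rand_index([0, 0, 1, 1], [1, 1, 0, 0]) == 1.0

    def test_hand_example_third(self):
        # pairs: (01) together/apart, (23) ... 2 of 6 agree
        assert rand_index([0, 0, 1, 1], [0, 1, 0, 1]) == pytest.approx(1 / 3)

    def test_matches_brute_force(self):
        for seed in range(50):
            r = np.random.default_rng(seed)
            n = int(r.integers(5, 25))
            a = r.integers(0, 4, size=n)
            b = r.integers(0, 4, size=n)
            assert rand_index(a, b) == pytest.approx(rand_brute(a, b), abs=1e-9)

    def test_length_mismatch(self):
        with pytest.raises(DimensionError):
            rand_index([0, 1], [0, 1, 1])


class TestSilhouette:
    def test_two_point_masses_score_one(self):
        x = np.array([[0.0, 0], [0, 0], [5, 0], [5, 0]])
        assert silhouette(x, [0, 0, 1, 1]) == 1.0

    def test_swapped_two_plus_two_hand_value(self):
        # points 0,0 and 5,5 on a line; labels swapped pairwise:
        # for each point a = 5 (distance to its co-labelled far point),
        # b = 2.5 (mean distance to the other cluster) -> (b-a)/max = -0.5
        x = np.array([[0.0], [0.0], [5.0], [5.0]])
        labels = [0, 1, 0, 1]
        assert silhouette(x, labels) == pytest.approx(-0.5)
        assert silhouette_brute(x, labels) == pytest.approx(-0.5)

    def test_matches_brute_force(self):
        for seed in range(50):
            r = np.random.default_rng(seed)
            n = int(r.integers(6, 25))
            x = r.random((n, 3))
            labels = r.integers(0, 3, size=n)
            if len(np.unique(labels)) < 2:
                continue
            assert silhouette(x, labels) == pytest.approx(
                silhouette_brute(x, labels), abs=1e-9)

    def test_single_cluster_rejected(self, rng):
        with pytest.raises(MetricError):
            silhouette(rng.random((5, 2)), [0] * 5)


class TestDaviesBouldin:
    def test_point_masses_score_zero(self):
        x = np.array([[0.0, 0], [0, 0], [3, 0], [3, 0]])
        assert davies_bouldin(x, [0, 0, 1, 1]) == pytest.approx(0.0)

    def test_hand_value_one_dimensional(self):
        # clusters {0,2} and {10,12}: scatters 1 and 1, centroid gap 10
        x = np.array([[0.0], [2.0], [10.0], [12.0]])
        assert davies_bouldin(x, [0, 0, 1, 1]) == pytest.approx(0.2)

    def test_matches_brute_force(self):
        for seed in range(50):
            r = np.random.default_rng(seed + 1000)
            n = int(r.integers(6, 25))
            x = r.random((n, 3))
            labels = r.integers(0, 3, size=n)
            if len(np.unique(labels)) < 2:
                continue
            assert davies_bouldin(x, labels) == pytest.approx(
                davies_bouldin_brute(x, labels), abs=1e-9)

    def test_single_cluster_rejected(self, rng):
        with pytest.raises(MetricError):
            davies_bouldin(rng.random((5, 2)), [0] * 5)


class TestAssignUnseen:
    def test_point_on_centroid_gets_its_label(self, rng):
        x = rng.random((12, 3)) + np.repeat([[0], [5]], 6, axis=0)
        res = kmeans(x, 2, seed=0)
        labels = assign_unseen(res, res.centroids)
        assert list(labels) == [0, 1]

    def test_equidistant_point_takes_lowest_index(self):
        x = np.array([[0.0, 0], [0, 0], [4, 0], [4, 0]])
        res = kmeans(x, 2, seed=0)
        mid = res.centroids.mean(axis=0, keepdims=True)
        assert assign_unseen(res, mid)[0] == 0

    def test_dimension_mismatch(self, rng):
        res = kmeans(rng.random((8, 3)), 2, seed=0)
        with pytest.raises(DimensionError):
            assign_unseen(res, rng.random((2, 5)))
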