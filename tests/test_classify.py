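import numpy as np
import pytest

from benthoscan import classify as cl
from benthoscan.classify import (
    UNLABELED,
    AnnotationSet,
    LabelMap,
    MahalanobisClassifier,
    PixelDataset,
    evaluate,
    extract_dataset,
    metrics_from_confusion,
    pool_datasets,
    predict_map,
    rasterize_annotations,
    split_dataset,
    train_classifier,
)
from benthoscan.cube_io import SpectralCube


def rect(l0, s0, l1, s1):
    return np.array([[l0, s0], [l0, s1], [l1, s1], [l1, s0]], dtype=float)


def brute_force_point_in_polygon(point, verts):
    """Scalar even-odd crossing test with explicit edge check."""
    y, x = point
    n = len(verts)
    inside = False
    for i in range(n):
        y0, x0 = verts[i]
        y1, x1 = verts[(i + 1) % n]
        # on-edge check
        cross = (y - y0) * (x1 - x0) - (x - x0) * (y1 - y0)
        seg2 = (y1 - y0) ** 2 + (x1 - x0) ** 2
        if seg2 > 0:
            t = ((y - y0) * (y1 - y0) + (x - x0) * (x1 - x0)) / seg2
            if abs(cross) <= 1e-9 * np.sqrt(seg2) and -1e-9 <= t <= 1 + 1e-9:
                return True
        if (y0 <= y) != (y1 <= y):
            x_cross = x0 + (y - y0) * (x1 - x0) / (y1 - y0)
            if x < x_cross:
                inside = not inside
    return inside


class TestRasterize:
    def test_axis_aligned_square_counts_100_pixels(self):
        ann = AnnotationSet([(rect(2.0, 3.0, 11.0, 12.0), "Coral")])
        lm = rasterize_annotations(ann, (20, 20))
        assert int((lm.indices != UNLABELED).sum()) == 100

    def test_empty_set_all_sentinel(self):
        lm = rasterize_annotations(AnnotationSet([]), (5, 7))
        assert np.all(lm.indices == UNLABELED)

    def test_degenerate_polygon_skipped_with_warning(self):
        ann = AnnotationSet(
            [(np.array([[1.0, 1.0], [1.0, 1.0], [1.0, 1.0]]), "Zero"),
             (rect(0, 0, 2, 2), "Ok")]
        )
        with pytest.warns(UserWarning, match="degenerate"):
            lm = rasterize_annotations(ann, (5, 5))
        assert set(lm.legend.values()) == {"Zero", "Ok"}
        labeled = {lm.legend[i] for i in np.unique(lm.indices) if i != UNLABELED}
        assert labeled == {"Ok"}

    def test_overlap_last_polygon_wins(self):
        ann = AnnotationSet([(rect(0, 0, 4, 4), "A"), (rect(2, 2, 6, 6), "B")])
        lm = rasterize_annotations(ann, (8, 8))
        assert lm.legend[lm.indices[3, 3]] == "B"
        assert lm.legend[lm.indices[1, 1]] == "A"

    def test_out_of_bounds_polygon_rejected(self):
        with pytest.raises(ValueError, match="bounds"):
            rasterize_annotations(AnnotationSet([(rect(0, 0, 30, 3), "A")]), (10, 10))

    def test_matches_brute_force_oracle_on_random_polygons(self, rng):
        shape = (18, 22)
        for _ in range(10):
            n_verts = int(rng.integers(3, 8))
            verts = np.column_stack(
                [rng.uniform(0.5, shape[0] - 1.5, n_verts), rng.uniform(0.5, shape[1] - 1.5, n_verts)]
            )
            lm = rasterize_annotations(AnnotationSet([(verts, "X")]), shape)
            got = lm.indices != UNLABELED
            for l in range(shape[0]):
                for s in range(shape[1]):
                    assert got[l, s] == brute_force_point_in_polygon((float(l), float(s)), verts), (
                        l, s, verts,
                    )


class TestExtractDataset:
    @pytest.fixture()
    def labeled_cube(self, rng):
        wl = np.linspace(400, 900, 480)
        cube = SpectralCube(rng.uniform(0.1, 1.0, (12, 15, 480)), wl)
        indices = np.full((12, 15), UNLABELED, dtype=np.int32)
        indices[2:6, 3:9] = 0
        indices[8:11, 10:14] = 1
        return cube, LabelMap(indices, {0: "A", 1: "B"})

    def test_hsi_rows_are_z_normed(self, labeled_cube):
        cube, lm = labeled_cube
        ds = extract_dataset(cube, lm, mode="hsi")
        np.testing.assert_allclose(ds.features.mean(axis=1), 0.0, atol=1e-9)
        np.testing.assert_allclose(ds.features.std(axis=1), 1.0, atol=1e-9)

    def test_hsi_feature_count_matches_brute_force_band_count(self, labeled_cube):
        cube, lm = labeled_cube
        ds = extract_dataset(cube, lm, mode="hsi")
        expected = sum(1 for w in cube.wavelengths if 400.0 <= w <= 750.0)
        assert ds.n_features == expected

    def test_z_norm_is_gain_and_offset_invariant(self, rng):
        wl = np.linspace(400, 750, 50)
        base = rng.uniform(0.1, 1.0, 50)
        values = np.stack([[base, 3.0 * base + 0.7]])
        cube = SpectralCube(values, wl)
        lm = LabelMap(np.zeros((1, 2), dtype=np.int32), {0: "A"})
        ds = extract_dataset(cube, lm, mode="hsi")
        np.testing.assert_allclose(ds.features[0], ds.features[1], atol=1e-9)

    def test_rgb_mode_raw_three_bands(self, labeled_cube):
        cube, lm = labeled_cube
        ds = extract_dataset(cube, lm, mode="rgb")
        assert ds.n_features == 3
        from benthoscan.cube_io import band_index

        l, s = ds.provenance[0][1], ds.provenance[0][2]
        for j, w in enumerate((640.0, 540.0, 460.0)):
            assert ds.features[0, j] == cube.values[l, s, band_index(cube, w)]

    def test_scan_order_deterministic(self, labeled_cube):
        cube, lm = labeled_cube
        ds = extract_dataset(cube, lm, mode="rgb")
        coords = [(l, s) for _, l, s in ds.provenance]
        assert coords == sorted(coords)

    def test_zero_sd_pixel_excluded_with_warning(self):
        wl = np.linspace(400, 750, 10)
        values = np.ones((1, 2, 10))
        values[0, 1] = np.linspace(1, 2, 10)
        cube = SpectralCube(values, wl)
        lm = LabelMap(np.zeros((1, 2), dtype=np.int32), {0: "A"})
        with pytest.warns(UserWarning, match="zero-SD"):
            ds = extract_dataset(cube, lm, mode="hsi")
        assert ds.n == 1


class TestSplitDataset:
    def make_ds(self, sizes, rng):
        feats, labels = [], []
        for name, n in sizes.items():
            feats.append(rng.random((n, 4)))
            labels += [name] * n
        X = np.vstack(feats)
        return PixelDataset(X, np.array(labels, dtype=object),
                            [("img", i, 0) for i in range(X.shape[0])])

    def test_hundred_rows_split_75_25(self, rng):
        ds = self.make_ds({"A": 100}, rng)
        with pytest.raises(ValueError):
            train_classifier(ds)  # single class cannot train, but split works:
        tr, va = split_dataset(ds, seed=1)
        assert tr.n == 75 and va.n == 25

    def test_seed_reproducible(self, rng):
        ds = self.make_ds({"A": 40, "B": 17}, rng)
        t1, v1 = split_dataset(ds, seed=5)
        t2, v2 = split_dataset(ds, seed=5)
        np.testing.assert_array_equal(t1.features, t2.features)
        assert t1.provenance == t2.provenance

    def test_stratified_counts_within_one_row(self, rng):
        sizes = {f"C{i}": int(n) for i, n in enumerate(rng.integers(4, 200, 8))}
        ds = self.make_ds(sizes, rng)
        tr, va = split_dataset(ds, seed=2)
        for name, n in sizes.items():
            n_train = int((tr.labels == name).sum())
            assert abs(n_train - 0.75 * n) <= 1.0
            assert n_train + int((va.labels == name).sum()) == n

    def test_disjoint_and_exhaustive(self, rng):
        ds = self.make_ds({"A": 20, "B": 9}, rng)
        tr, va = split_dataset(ds, seed=0)
        assert set(tr.provenance).isdisjoint(va.provenance)
        assert set(tr.provenance) | set(va.provenance) == set(ds.provenance)

    def test_tiny_class_rejected_by_name(self, rng):
        ds = self.make_ds({"A": 10, "Rare": 3}, rng)
        with pytest.raises(ValueError, match="Rare"):
            split_dataset(ds)


def gaussian_blobs(rng, n_per_class=200, spread=1.0, sep=10.0, F=3, K=2):
    X, y = [], []
    for k in range(K):
        center = np.zeros(F)
        center[k % F] = sep * k
        X.append(center + spread * rng.standard_normal((n_per_class, F)))
        y += [f"class_{k}"] * n_per_class
    X = np.vstack(X)
    return PixelDataset(X, np.array(y, dtype=object), [("img", i, 0) for i in range(len(X))])


class TestTrainClassifier:
    @pytest.mark.parametrize("algorithm", ["perceptron", "mahalanobis", "svm_linear"])
    def test_separable_classes_fit_perfectly(self, algorithm, rng):
        ds = gaussian_blobs(rng, sep=10.0)
        model = train_classifier(ds, algorithm, seed=0)
        pred = model.predict(ds.features)
        assert (pred == ds.labels).mean() == 1.0

    def test_mahalanobis_zero_distance_at_class_mean(self, rng):
        ds = gaussian_blobs(rng, K=3, F=4)
        model = train_classifier(ds, "mahalanobis")
        est = model.estimator
        for k, name in enumerate(model.classes):
            assert model.predict(est.means_[k][None, :])[0] == name
            assert est.distances(est.means_[k][None, :])[0, k] == pytest.approx(0.0, abs=1e-9)

    @pytest.mark.parametrize("covariance", ["pooled", "per_class"])
    def test_mahalanobis_equals_brute_force_oracle(self, covariance, rng):
        """Vectorized classifier vs explicit per-point loop with matrix solve."""
        K, F = 3, 5
        ds = gaussian_blobs(rng, n_per_class=60, K=K, F=F, sep=4.0)
        model = train_classifier(ds, "mahalanobis", hyperparams={"covariance": covariance})
        X = rng.standard_normal((50, F)) * 3

        classes = model.classes
        means, covs = [], []
        for name in classes:
            rows = ds.features[ds.labels == name]
            means.append(rows.mean(axis=0))
            covs.append(np.cov(rows, rowvar=False, ddof=1))
        if covariance == "pooled":
            n_k = [int((ds.labels == name).sum()) for name in classes]
            pooled = sum((n - 1) * c for n, c in zip(n_k, covs)) / (sum(n_k) - K)
            covs = [pooled] * K
        expected = []
        for x in X:
            dists = []
            for mu, sigma in zip(means, covs):
                eps = 1e-6 * np.trace(sigma) / F
                d = x - mu
                dists.append(float(d @ np.linalg.solve(sigma + eps * np.eye(F), d)))
            expected.append(classes[int(np.argmin(dists))])
        np.testing.assert_array_equal(model.predict(X), np.array(expected, dtype=object))

    def test_unknown_algorithm_rejected(self, rng):
        with pytest.raises(ValueError, match="unknown algorithm"):
            train_classifier(gaussian_blobs(rng), "forest")

    def test_single_class_rejected(self, rng):
        ds = gaussian_blobs(rng, K=1)
        with pytest.raises(ValueError, match="2 classes"):
            train_classifier(ds)

    def test_hyperparams_recorded(self, rng):
        model = train_classifier(gaussian_blobs(rng), "svm_linear", hyperparams={"C": 0.5})
        assert model.hyperparams["C"] == 0.5


class TestPredictMap:
    @pytest.mark.parametrize("algorithm", ["perceptron", "mahalanobis", "svm_linear"])
    def test_noiseless_scene_maps_to_ground_truth(self, noiseless_scene, algorithm):
        scene = noiseless_scene
        from benthoscan.synthetic_scene import sparse_annotations

        ann = sparse_annotations(scene.truth, 0.05, seed=2, min_pixels_per_class=20)
        lm = rasterize_annotations(ann, scene.truth.shape)
        ds = extract_dataset(scene.cube, lm, mode="hsi")
        model = train_classifier(ds, algorithm, seed=0)
        label_map, qc = predict_map(model, scene.cube)
        assert qc["n_fallback_pixels"] == 0
        # legends share sorted-name indexing, so indices are comparable
        assert (label_map.indices == scene.truth.indices).mean() == 1.0

    def test_training_pixels_reproduced_at_least_at_training_accuracy(self, noisy_scene):
        scene = noisy_scene
        from benthoscan.synthetic_scene import sparse_annotations

        ann = sparse_annotations(scene.truth, 0.05, seed=3, min_pixels_per_class=20)
        lm = rasterize_annotations(ann, scene.truth.shape)
        ds = extract_dataset(scene.cube, lm, mode="hsi")
        model = train_classifier(ds, "mahalanobis", seed=0)
        train_acc = (model.predict(ds.features) == ds.labels).mean()
        label_map, _ = predict_map(model, scene.cube)
        mask = lm.indices != UNLABELED
        names = np.array([label_map.legend[i] for i in label_map.indices[mask]], dtype=object)
        truth_names = np.array([lm.legend[i] for i in lm.indices[mask]], dtype=object)
        assert (names == truth_names).mean() >= train_acc - 1e-12

    def test_uniform_cube_single_class_via_fallback(self, rng):
        ds = gaussian_blobs(rng, F=5)
        ds = PixelDataset(ds.features, ds.labels, ds.provenance, mode="hsi",
                          band_range=(400.0, 750.0))
        model = train_classifier(ds, "mahalanobis", seed=0)
        wl = np.array([380.0, 420.0, 500.0, 580.0, 660.0, 740.0, 770.0, 800.0])
        sel = (wl >= 400) & (wl <= 750)
        assert sel.sum() == 5  # model F matches in-range band count
        cube = SpectralCube(np.full((4, 6, 8), 0.3), wl)
        m1, qc = predict_map(model, cube)
        assert qc["n_fallback_pixels"] == 24
        assert len(np.unique(m1.indices)) == 1
        m2, _ = predict_map(model, cube)
        np.testing.assert_array_equal(m1.indices, m2.indices)

    def test_band_coverage_checked(self, rng):
        ds = gaussian_blobs(rng, F=5)
        ds = PixelDataset(ds.features, ds.labels, ds.provenance, mode="hsi")
        model = train_classifier(ds, "mahalanobis")
        cube = SpectralCube(np.ones((2, 2, 6)), np.linspace(500, 700, 6))
        with pytest.raises(ValueError, match="cover"):
            predict_map(model, cube)


class TestEvaluate:
    def test_perfect_predictions(self, rng):
        ds = gaussian_blobs(rng, sep=20.0)
        model = train_classifier(ds, "mahalanobis")
        report = evaluate(model, ds)
        assert report.accuracy == 1.0
        np.testing.assert_allclose(report.precision, 1.0)
        np.testing.assert_allclose(report.recall, 1.0)

    def test_hand_confusion_matrix(self):
        report = metrics_from_confusion(np.array([[8, 2], [1, 9]]), ["a", "b"])
        assert report.accuracy == pytest.approx(0.85)
        np.testing.assert_allclose(report.precision, [8 / 9, 9 / 11])
        np.testing.assert_allclose(report.recall, [0.8, 0.9])
        np.testing.assert_array_equal(report.support, [10, 10])

    def test_matches_sklearn_on_random_labels(self, rng):
        from sklearn.metrics import accuracy_score, confusion_matrix, precision_score, recall_score

        classes = ["a", "b", "c", "d"]
        y_true = rng.choice(classes, 1000)
        y_pred = rng.choice(classes, 1000)
        conf = confusion_matrix(y_true, y_pred, labels=classes)
        report = metrics_from_confusion(conf, classes)
        assert report.accuracy == pytest.approx(accuracy_score(y_true, y_pred))
        np.testing.assert_allclose(
            report.precision, precision_score(y_true, y_pred, labels=classes, average=None)
        )
        np.testing.assert_allclose(
            report.recall, recall_score(y_true, y_pred, labels=classes, average=None)
        )

    def test_absent_class_gets_nan_not_dropped(self, rng):
        ds = gaussian_blobs(rng, K=3, F=4, sep=8.0)
        model = train_classifier(ds, "mahalanobis")
        subset = ds.labels != "class_2"
        val = PixelDataset(ds.features[subset], ds.labels[subset],
                           [p for p, keep in zip(ds.provenance, subset) if keep])
        report = evaluate(model, val)
        k = model.classes.index("class_2")
        assert len(report.classes) == 3
        assert report.support[k] == 0
        assert np.isnan(report.recall[k])

    def test_unknown_validation_class_rejected(self, rng):
        ds = gaussian_blobs(rng, K=2)
        model = train_classifier(ds, "mahalanobis")
        bad = PixelDataset(ds.features, np.array(["zzz"] * ds.n, dtype=object), ds.provenance)
        with pytest.raises(ValueError, match="zzz"):
            evaluate(model, bad)


class TestPoolDatasets:
    def test_counts_and_provenance_preserved(self, rng):
        a = gaussian_blobs(rng, n_per_class=30)
        b = PixelDataset(a.features + 1.0, a.labels,
                         [("other", l, s) for _, l, s in a.provenance])
        pooled = pool_datasets([a, b])
        assert pooled.n == a.n + b.n
        assert pooled.provenance == a.provenance + b.provenance

    def test_single_dataset_identity(self, rng):
        a = gaussian_blobs(rng, n_per_class=10)
        pooled = pool_datasets([a])
        np.testing.assert_array_equal(pooled.features, a.features)

    def test_feature_dim_mismatch_rejected(self, rng):
        a = gaussian_blobs(rng, F=3)
        b = gaussian_blobs(rng, F=4)
        b = PixelDataset(b.features, b.labels, [("o", l, s) for _, l, s in b.provenance])
        with pytest.raises(ValueError, match="differ"):
            pool_datasets([a, b])

    def test_duplicate_provenance_rejected(self, rng):
        a = gaussian_blobs(rng)
        with pytest.raises(ValueError, match="overlap"):
            pool_datasets([a, a])
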