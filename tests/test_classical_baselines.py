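import numpy as np
import pytest

from cycleseg import classical_baselines as cb


class TestKMeans:
    def test_k_equals_one_whole_volume(self):
        vol = np.random.default_rng(0).random((4, 8, 8))
        res = cb.kmeans_segment(vol, k=1)
        assert res.nuclei_mask.all()
        assert res.counts[0] == vol.size

    def test_three_block_volume_pure_assignment(self):
        vol = np.zeros((3, 6, 6))
        vol[1] = 100.0
        vol[2] = 200.0
        res = cb.kmeans_segment(vol, k=3)
        # each constant block lands in exactly one cluster
        for z in range(3):
            assert len(np.unique(res.labels[z])) == 1
        assert len({res.labels[z, 0, 0] for z in range(3)}) == 3
        # nuclei mask is the brightest block
        assert res.nuclei_mask[2].all() and not res.nuclei_mask[0].any()

    def test_nuclei_cluster_has_highest_centroid(self):
        vol = np.random.default_rng(1).gamma(2.0, 10.0, size=(4, 16, 16))
        res = cb.kmeans_segment(vol, k=3)
        nuclei_centroid = res.centroids[np.argmax(res.centroids)]
        assert (nuclei_centroid >= res.centroids).all()
        assert res.nuclei_mask.sum() == res.counts[np.argmax(res.centroids)]

    def test_objective_nonincreasing(self):
        rng = np.random.default_rng(2)
        vol = rng.normal(50, 20, size=(4, 12, 12))
        flat = vol.ravel()

        def wcss(centroids):
            return (np.min(np.abs(flat[:, None] - centroids[None, :]), axis=1) ** 2).sum()

        # run with decreasing eps: tighter convergence never raises the objective
        loose = cb.kmeans_segment(vol, k=3, eps=5.0)
        tight = cb.kmeans_segment(vol, k=3, eps=0.01)
        assert wcss(tight.centroids) <= wcss(loose.centroids) + 1e-6

    def test_degenerate_k_warns(self):
        with pytest.warns(UserWarning, match="distinct"):
            cb.kmeans_segment(np.zeros((2, 2, 2)), k=3)

    def test_matches_sklearn_on_small_volume(self):
        from sklearn.cluster import KMeans

        rng = np.random.default_rng(3)
        vol = np.concatenate([rng.normal(0, 1, 200), rng.normal(50, 1, 200), rng.normal(200, 1, 100)])
        vol = vol.reshape(5, 10, 10)
        ours = cb.kmeans_segment(vol, k=3, eps=1e-6)
        ref = KMeans(n_clusters=3, n_init=10, random_state=0).fit(vol.reshape(-1, 1))
        np.testing.assert_allclose(np.sort(ours.centroids), np.sort(ref.cluster_centers_.ravel()), rtol=1e-3)


class TestSubsampling:
    def test_cap_respected_and_small_slices_kept_whole(self):
        rng = np.random.default_rng(0)
        feats = [rng.random((524288 // 64, 3)), rng.random((100, 3))]
        labels = [rng.integers(0, 2, len(f)) for f in feats]
        subset = cb.subsample_pixel_features(feats, labels, n_per_slice=5000, seed=1)
        per_slice = subset.provenance.groupby("slice").size()
        assert per_slice[0] == 5000
        assert per_slice[1] == 100

    def test_draw_without_replacement(self):
        feats = [np.arange(50, dtype=float).reshape(-1, 1)]
        labels = [np.zeros(50)]
        subset = cb.subsample_pixel_features(feats, labels, n_per_slice=40, seed=0)
        assert len(np.unique(subset.features)) == 40

    def test_foreground_fraction_unbiased(self):
        """Random pixel selection preserves the ~1:1500 class ratio in expectation."""
        rng = np.random.default_rng(42)
        n_pixels, p_fg = 30000, 1 / 1500
        labels = (rng.random(n_pixels) < p_fg).astype(int)
        feats = np.zeros((n_pixels, 1))
        true_frac = labels.mean()
        fracs = []
        for seed in range(50):
            subset = cb.subsample_pixel_features([feats], [labels], n_per_slice=5000, seed=seed)
            fracs.append(subset.labels.mean())
        se = np.std(fracs, ddof=1) / np.sqrt(len(fracs))
        assert abs(np.mean(fracs) - true_frac) <= 3 * max(se, 1e-12)

    def test_deterministic_under_seed(self):
        rng = np.random.default_rng(0)
        feats = [rng.random((500, 2))]
        labels = [rng.integers(0, 2, 500)]
        a = cb.subsample_pixel_features(feats, labels, 100, seed=7)
        b = cb.subsample_pixel_features(feats, labels, 100, seed=7)
        np.testing.assert_array_equal(a.features, b.features)


class TestClassifiers:
    def test_config_defaults_match_tuned_values(self):
        cfg = cb.PixelClassifierConfig()
        assert (cfg.svm_c, cfg.svm_kernel) == (0.7, "rbf")
        assert (cfg.rf_trees, cfg.rf_max_depth, cfg.rf_min_split, cfg.rf_min_leaf, cfg.rf_criterion) == (
            35, 17, 9, 24, "gini")
        assert (cfg.gbc_trees, cfg.gbc_max_depth, cfg.gbc_min_leaf_fraction,
                cfg.gbc_min_split_fraction, cfg.gbc_criterion) == (100, 1, 0.2, 0.3, "friedman_mse")

    def test_minority_class_weighted_higher(self):
        labels = np.array([0] * 90 + [1] * 10)
        weights = cb._inverse_frequency_weights(labels)
        assert weights[1] > weights[0]

    def test_rf_separable_toy_perfect_training_f(self):
        from cycleseg.evaluation import metrics_from_counts

        rng = np.random.default_rng(0)
        x0 = rng.normal(0, 0.3, size=(200, 2))
        x1 = rng.normal(5, 0.3, size=(40, 2))
        subset = cb.TrainingSubset(np.vstack([x0, x1]), np.array([0] * 200 + [1] * 40))
        clf = cb.train_pixel_classifier(subset, cb.PixelClassifierConfig(model="rf", rf_min_leaf=1, rf_min_split=2))
        pred = clf.predict(subset.features)
        tp = int(((pred == 1) & (subset.labels == 1)).sum())
        fp = int(((pred == 1) & (subset.labels == 0)).sum())
        fn = int(((pred == 0) & (subset.labels == 1)).sum())
        assert metrics_from_counts(tp, fp, fn).f_measure == 1.0

    def test_single_class_subset_rejected(self):
        subset = cb.TrainingSubset(np.zeros((10, 2)), np.zeros(10))
        with pytest.raises(ValueError, match="single class"):
            cb.train_pixel_classifier(subset)

    def test_gbc_and_svm_train(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=(300, 3))
        y = (x[:, 0] > 0.5).astype(int)
        for model in ("gbc", "svm"):
            clf = cb.train_pixel_classifier(
                cb.TrainingSubset(x, y), cb.PixelClassifierConfig(model=model))
            assert clf.predict(x[:5]).shape == (5,)


class TestSlicewisePrediction:
    def _fitted(self):
        rng = np.random.default_rng(0)
        x = np.vstack([rng.normal(0, 1, (100, 2)), rng.normal(10, 1, (100, 2))])
        y = np.array([0] * 100 + [1] * 100)
        return cb.train_pixel_classifier(cb.TrainingSubset(x, y), cb.PixelClassifierConfig(model="rf", rf_min_leaf=1))

    def test_output_shape_and_slice_independence(self):
        clf = self._fitted()
        rng = np.random.default_rng(2)
        feats = rng.normal(0, 1, size=(2, 3, 6, 6))
        out = cb.predict_volume_slicewise(clf, feats)
        assert out.shape == (3, 6, 6)
        # changing slice 2 leaves slices 0-1 untouched
        feats2 = feats.copy()
        feats2[:, 2] += 10
        out2 = cb.predict_volume_slicewise(clf, feats2)
        np.testing.assert_array_equal(out[:2], out2[:2])

    def test_constant_features_constant_prediction(self):
        clf = self._fitted()
        out = cb.predict_volume_slicewise(clf, np.zeros((2, 2, 4, 4)))
        assert len(np.unique(out)) == 1

    def test_channel_mismatch_rejected(self):
        clf = self._fitted()
        with pytest.raises(ValueError, match="feature channels"):
            cb.predict_volume_slicewise(clf, np.zeros((5, 2, 4, 4)))
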