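"""Time-binned pairwise classification of encoding epochs."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import wmreplay as w
from wmreplay.containers import ValidationError
from wmreplay.encoding import PAIRS


class TestTimeBinGrid:
    def test_canonical_grid(self):
        grid = w.make_time_bins()
        assert grid.n_bins == 26
        assert grid.centers_ms[0] == -10.0
        assert grid.centers_ms[-1] == 490.0
        assert np.allclose(np.diff(grid.centers_ms), 20.0)
        assert grid.samples_per_bin == 13

    def test_degenerate_window_rejected(self):
        with pytest.raises(ValidationError):
            w.make_time_bins(t_start=0, t_end=10, width=20)


class TestFeatureExtraction:
    def test_full_sensor_array_gives_3562_features(self):
        n_ch, n_samp = 274, 361
        t = -100 + np.arange(n_samp) * (1000 / 600)
        ep = w.SensorEpochs(
            data=np.zeros((2, n_ch, n_samp)), time_ms=t, fs=600.0,
            alignment="stimulus_onset",
            events=pd.DataFrame({"trial_id": [0, 1]}),
        )
        grid = w.make_time_bins()
        X = w.extract_bin_features(ep, grid, 170.0)
        assert X.shape == (2, 3562)

    def test_zero_epochs_give_zero_vectors(self, small_design, small_params):
        ep = w.simulate_encoding_epochs(small_design[:2], small_params)
        ep = ep.copy_with(data=np.zeros_like(ep.data))
        X = w.extract_bin_features(ep, w.make_time_bins(), 170.0)
        assert np.all(X == 0)

    def test_channel_major_ordering(self, small_design, small_params):
        ep = w.simulate_encoding_epochs(small_design[:2], small_params)
        grid = w.make_time_bins()
        X = w.extract_bin_features(ep, grid, 170.0)
        spb = grid.samples_per_bin
        i0 = ep.sample_index(160.0)
        # features of channel 5 are contiguous
        assert np.array_equal(
            X[0, 5 * spb : 6 * spb], ep.data[0, 5, i0 : i0 + spb]
        )

    def test_bin_outside_epoch_rejected(self, small_design, small_params):
        ep = w.simulate_encoding_epochs(small_design[:2], small_params)
        with pytest.raises(ValidationError):
            w.extract_bin_features(ep, w.make_time_bins(), 700.0)


class TestFeatureReduction:
    def test_null_features_kept_at_alpha_rate(self):
        rng = np.random.default_rng(1)
        X = rng.standard_normal((100, 1000))
        y = np.array(["F"] * 50 + ["B"] * 50)
        mask = w.reduce_features(X, y, alpha=0.05)
        # binomial 99% interval around 5% of 1000
        lo, hi = stats.binom.interval(0.99, 1000, 0.05)
        assert lo <= mask.sum() <= hi

    def test_separated_feature_always_kept(self):
        rng = np.random.default_rng(2)
        X = rng.standard_normal((100, 20))
        y = np.array(["F"] * 50 + ["B"] * 50)
        X[:50, 7] += 10.0  # 10 SD separation
        mask = w.reduce_features(X, y)
        assert mask[7]

    def test_alpha_one_keeps_everything(self):
        rng = np.random.default_rng(3)
        X = rng.standard_normal((20, 15))
        y = np.array(["F"] * 10 + ["B"] * 10)
        assert w.reduce_features(X, y, alpha=1.0 + 1e-9).all()

    def test_single_class_rejected(self):
        X = np.zeros((10, 5))
        with pytest.raises(ValidationError):
            w.reduce_features(X, np.array(["F"] * 10))


class TestPairwiseClassifier:
    def _separable(self, n=40, d=6, gap=5.0, seed=0):
        rng = np.random.default_rng(seed)
        X = rng.standard_normal((n, d)) * 0.1
        y = np.array(["F"] * (n // 2) + ["B"] * (n // 2))
        X[: n // 2, 0] += gap
        return X, y

    def test_separable_data_fits_perfectly(self):
        X, y = self._separable()
        clf = w.train_pairwise_classifier(X, y, 170.0, ("F", "B"))
        assert (clf.predict(X) == y).all()

    def test_positive_margin_favors_first_category(self):
        X, y = self._separable()
        clf = w.train_pairwise_classifier(X, y, 170.0, ("F", "B"))
        dv = clf.decision_values(X)
        assert (dv[y == "F"] > 0).all() and (dv[y == "B"] < 0).all()

    def test_unbalanced_classes_rejected(self):
        X, y = self._separable()
        with pytest.raises(ValidationError):
            w.train_pairwise_classifier(X[:-3], y[:-3], 170.0, ("F", "B"))

    def test_training_is_deterministic(self):
        X, y = self._separable()
        a = w.train_pairwise_classifier(X, y, 170.0, ("F", "B"))
        b = w.train_pairwise_classifier(X, y, 170.0, ("F", "B"))
        assert np.array_equal(a.weights, b.weights) and a.bias == b.bias

    def test_channel_permutation_invariance(self):
        # permuting features with matching mask remap leaves decisions intact
        X, y = self._separable()
        clf = w.train_pairwise_classifier(X, y, 170.0, ("F", "B"))
        perm = np.random.default_rng(4).permutation(X.shape[1])
        Xp = X[:, perm]
        clf_p = w.train_pairwise_classifier(Xp, y, 170.0, ("F", "B"))
        assert np.allclose(
            clf.decision_values(X), clf_p.decision_values(Xp), atol=1e-8
        )


class TestCrossValidation:
    def test_label_permutation_is_at_chance(self, small_params):
        p = small_params.replace(snr_encoding=5.0)
        design = w.assign_predominant(w.enumerate_design(5)[:40], p)
        ep = w.simulate_encoding_epochs(design, p)
        rng = np.random.default_rng(6)
        ev = ep.events.copy()
        ev["category"] = rng.permutation(ev["category"].to_numpy())
        ep = ep.copy_with(events=ev)
        grid = w.make_time_bins(t_start=140, t_end=200)  # 3 bins suffice
        curve = w.crossvalidate_bins(ep, grid, folds=10, seed=0)
        n = 40  # trials per category
        lo, hi = stats.binom.interval(0.999, n * 2, 0.5)
        assert lo / (n * 2) <= curve.mean_accuracy.mean() <= hi / (n * 2)

    def test_prestimulus_bin_at_chance(self, clf_bundle):
        _, _, grid, curve, _, _ = clf_bundle
        i = grid.centers_ms.index(-10.0)
        assert abs(curve.mean_accuracy[i] - 0.5) < 0.2  # 30 trials, wide CI

    def test_reproducible_given_seed(self, small_params):
        p = small_params.replace(snr_encoding=2.0)
        design = w.assign_predominant(w.enumerate_design(5)[:25], p)
        ep = w.simulate_encoding_epochs(design, p)
        grid = w.make_time_bins(t_start=160, t_end=180)
        a = w.crossvalidate_bins(ep, grid, folds=5, seed=3)
        b = w.crossvalidate_bins(ep, grid, folds=5, seed=3)
        assert np.array_equal(a.accuracy, b.accuracy)

    def test_too_few_trials_rejected(self, small_design, small_params):
        ep = w.simulate_encoding_epochs(small_design[:4], small_params)
        with pytest.raises(ValidationError):
            w.crossvalidate_bins(ep, w.make_time_bins(t_start=160, t_end=180))

    def test_high_snr_peaks_at_evoked_latency(self, clf_bundle):
        _, _, grid, curve, center, _ = clf_bundle
        i170 = grid.centers_ms.index(170.0)
        assert curve.mean_accuracy[i170] > 0.95
        assert curve.mean_accuracy[i170] >= curve.mean_accuracy.max() - 1e-12


class TestGroupSignificance:
    def test_exact_chance_everywhere_is_silent(self):
        curves = [
            w.AccuracyCurve(tuple(range(10)), PAIRS, np.full((3, 10), 0.5))
            for _ in range(8)
        ]
        sig = w.group_accuracy_significance(curves, n_permutations=200, seed=0)
        assert not sig.significant.any()

    def test_known_effect_found_as_contiguous_cluster(self):
        rng = np.random.default_rng(0)
        centers = tuple(float(c) for c in range(-10, 500, 20))
        curves = []
        for _ in range(14):
            acc = np.full((3, 26), 0.5) + rng.normal(0, 0.05, (3, 26))
            acc[:, 5:] += 0.25  # effect from 90 ms on
            curves.append(w.AccuracyCurve(centers, PAIRS, acc))
        sig = w.group_accuracy_significance(curves, n_permutations=500, seed=1)
        assert sig.significant[5:].all()
        assert not sig.significant[:3].any()
        assert all(
            1 / (500 + 1) <= p <= 1 for p in sig.cluster_p_values
        )

    def test_needs_two_subjects(self):
        c = w.AccuracyCurve((0.0,), PAIRS, np.full((3, 1), 0.6))
        with pytest.raises(ValidationError):
            w.group_accuracy_significance([c])


class TestBestBin:
    def test_unique_maximum_selected(self):
        acc = np.full((3, 5), 0.6)
        acc[:, 3] = 0.8
        curve = w.AccuracyCurve((10.0, 30.0, 50.0, 70.0, 90.0), PAIRS, acc)
        center, clfs = w.select_best_bin(curve)
        assert center == 70.0 and clfs is None

    def test_tie_goes_to_earliest_bin(self):
        curve = w.AccuracyCurve((10.0, 30.0, 50.0), PAIRS, np.full((3, 3), 0.7))
        center, _ = w.select_best_bin(curve)
        assert center == 10.0

    def test_refit_returns_three_classifiers(self, clf_bundle):
        *_, center, classifiers = clf_bundle
        assert set(classifiers) == set(PAIRS)
        assert all(c.bin_center_ms == center for c in classifiers.values())
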