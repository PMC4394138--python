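import numpy as np
import pytest

from conftest import make_trace
from neoseize.detector import (
    binarize,
    fit_normalizer,
    load_model,
    moving_average,
    predict_probabilities,
    save_model,
    train_model,
)
from neoseize.features import FeatureMatrix, default_registry


def feature_matrix(X, n_channels=1, fingerprint="test"):
    """Wrap an (epochs x features) array as a single-channel FeatureMatrix."""
    X = np.asarray(X, dtype=float)
    values = np.repeat(X[:, None, :], n_channels, axis=1)
    return FeatureMatrix(
        values=values,
        feature_names=[f"f{i}" for i in range(X.shape[1])],
        epoch_start_s=np.arange(X.shape[0]) * 4.0,
        registry_fingerprint=fingerprint,
        channel_labels=[f"ch{i}" for i in range(n_channels)],
    )


def separable_data(n=120, d=5, gap=6.0, seed=0):
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n, d))
    y = np.zeros(n, dtype=int)
    y[n // 2 :] = 1
    X[y == 1, 0] += gap
    return X, y


class TestNormalizer:
    def test_training_columns_become_zero_mean_unit_sd(self):
        X = np.random.default_rng(0).standard_normal((200, 7)) * 5 + 3
        norm = fit_normalizer(X)
        Z = norm.transform(X)
        assert np.max(np.abs(Z.mean(axis=0))) < 1e-9
        assert np.max(np.abs(Z.std(axis=0) - 1)) < 1e-9

    def test_constant_feature_flagged_and_zeroed(self):
        X = np.random.default_rng(0).standard_normal((50, 3))
        X[:, 1] = 4.2
        with pytest.warns(UserWarning, match="zero-variance"):
            norm = fit_normalizer(X)
        assert norm.zero_variance.tolist() == [False, True, False]
        assert np.all(norm.transform(X)[:, 1] == 0)

    def test_template_is_frozen_not_refit(self):
        rng = np.random.default_rng(1)
        A = rng.standard_normal((100, 4))
        B = rng.standard_normal((100, 4)) + 2.5  # shifted population
        norm = fit_normalizer(A)
        assert np.all(np.abs(norm.transform(B).mean(axis=0)) > 0.5)


class TestTraining:
    def test_single_class_rejected(self):
        fm = feature_matrix(np.random.default_rng(0).standard_normal((20, 3)))
        with pytest.raises(ValueError, match="single class"):
            train_model(fm, np.zeros(20))

    def test_separable_features_reach_auc_1(self):
        from sklearn.metrics import roc_auc_score

        X, y = separable_data()
        fm = feature_matrix(X)
        model = train_model(fm, y, seed=0)
        trace = predict_probabilities(model, fm, smoothing_window_epochs=1)
        assert roc_auc_score(y, trace.fused) == 1.0

    def test_permuted_labels_give_chance_auc(self):
        from sklearn.metrics import roc_auc_score

        X, y = separable_data(n=300, seed=2)
        rng = np.random.default_rng(0)
        y_perm = rng.permutation(y)
        half = 150
        model = train_model(feature_matrix(X[:half]), y_perm[:half], seed=0)
        trace = predict_probabilities(model, feature_matrix(X[half:]), smoothing_window_epochs=1)
        assert roc_auc_score(y_perm[half:], trace.fused) == pytest.approx(0.5, abs=0.1)

    def test_deterministic_given_seed(self):
        X, y = separable_data()
        fm = feature_matrix(X)
        t1 = predict_probabilities(train_model(fm, y, seed=3), fm)
        t2 = predict_probabilities(train_model(fm, y, seed=3), fm)
        np.testing.assert_array_equal(t1.fused, t2.fused)

    def test_save_load_round_trip(self, tmp_path, tiny_model, seizure_features):
        path = tmp_path / "model.joblib"
        save_model(tiny_model, path)
        back = load_model(path)
        t1 = predict_probabilities(tiny_model, seizure_features)
        t2 = predict_probabilities(back, seizure_features)
        np.testing.assert_array_equal(t1.fused, t2.fused)


class TestMovingAverage:
    def test_constant_input_is_fixed_point(self):
        np.testing.assert_allclose(moving_average(np.full(50, 0.3), 15), 0.3)

    def test_window_one_is_identity(self):
        x = np.random.default_rng(0).random(30)
        np.testing.assert_array_equal(moving_average(x, 1), x)

    def test_unit_spike_spreads_to_window(self):
        x = np.zeros(61)
        x[30] = 1.0
        sm = moving_average(x, 15)
        np.testing.assert_allclose(sm[30 - 7 : 30 + 8], 1 / 15)
        assert sm[30 - 8] == 0.0 and sm[30 + 8] == 0.0


class TestPrediction:
    def test_registry_mismatch_rejected(self, tiny_model):
        fm = feature_matrix(np.zeros((10, 55)), fingerprint="other")
        with pytest.raises(ValueError, match="fingerprint"):
            predict_probabilities(tiny_model, fm)

    def test_fused_is_max_across_channels(self, tiny_trace):
        np.testing.assert_array_equal(
            tiny_trace.fused, tiny_trace.per_channel.max(axis=0)
        )

    def test_fused_invariant_under_channel_permutation(self, tiny_model, seizure_features):
        import dataclasses

        perm = np.random.default_rng(0).permutation(seizure_features.n_channels)
        fm_p = dataclasses.replace(
            seizure_features,
            values=seizure_features.values[:, perm, :],
            channel_labels=[seizure_features.channel_labels[i] for i in perm],
        )
        t1 = predict_probabilities(tiny_model, seizure_features)
        t2 = predict_probabilities(tiny_model, fm_p)
        np.testing.assert_allclose(t1.fused, t2.fused, atol=1e-12)

    def test_probabilities_bounded(self, tiny_trace):
        assert np.all(tiny_trace.per_channel >= 0) and np.all(tiny_trace.per_channel <= 1)


class TestBinarize:
    def test_all_below_threshold_gives_empty_track(self):
        trace = make_trace(np.full(20, 0.2))
        assert binarize(trace, 0.5, 32.0).events.events == []

    def test_single_epoch_with_collar(self):
        fused = np.zeros(60)
        times = 4.0 + 4.0 * np.arange(60)
        fused[np.where(times == 100.0)[0][0]] = 0.9
        trace = make_trace(fused, times_s=times, duration_s=400.0)
        dec = binarize(trace, 0.5, 8.0)
        assert dec.events.events == [(92.0, 112.0)]

    def test_zero_collar_matches_suprathreshold_runs(self):
        fused = np.array([0.1, 0.8, 0.9, 0.2, 0.7, 0.1])
        trace = make_trace(fused, duration_s=32.0)
        dec = binarize(trace, 0.5, 0.0)
        # runs at epochs 1-2 (t=8..16) and 4 (t=20..24)
        assert dec.events.events == [(8.0, 16.0), (20.0, 24.0)]
        np.testing.assert_array_equal(dec.binary, fused >= 0.5)

    def test_collar_merges_touching_runs(self):
        fused = np.array([0.9, 0.0, 0.0, 0.9, 0.0])
        trace = make_trace(fused, duration_s=100.0)
        dec = binarize(trace, 0.5, 6.0)
        assert len(dec.events.events) == 1

    def test_threshold_monotonicity(self):
        rng = np.random.default_rng(0)
        trace = make_trace(rng.random(100))
        prev = None
        for th in np.linspace(0.1, 0.9, 9):
            cur = set(np.nonzero(binarize(trace, th, 0.0).binary)[0])
            if prev is not None:
                assert cur.issubset(prev)
            prev = cur

    def test_collar_monotonicity(self):
        rng = np.random.default_rng(1)
        trace = make_trace(rng.random(100), duration_s=500.0)
        small = binarize(trace, 0.5, 4.0).events.events
        big = binarize(trace, 0.5, 16.0).events.events
        from neoseize.core import total_overlap

        assert total_overlap(small, big) == pytest.approx(
            sum(b - a for a, b in small), abs=1e-9
        )


def test_end_to_end_detector_finds_strong_discharges(tiny_trace, seizure_recording):
    """Events trained and predicted on the same record must light up clearly."""
    _, ann = seizure_recording
    from neoseize.detector import binarize

    dec = binarize(tiny_trace, 0.5, 32.0)
    from neoseize.metrics import event_metrics

    assert event_metrics(dec, ann).gdr_pct == 100.0
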