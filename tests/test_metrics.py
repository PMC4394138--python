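import numpy as np
import pytest

from conftest import make_trace
from neoseize.core import AnnotationTrack
from neoseize.detector import DecisionTrace, binarize
from neoseize.metrics import (
    MetricsTable,
    ThresholdGrid,
    auc_per_patient_mean,
    auc_pooled_thresholds,
    bootstrap_upper95,
    compute_metrics_table,
    epoch_confusion,
    event_metrics,
    threshold_guide,
)


def decisions_from(events, duration_s, threshold=0.5, collar_s=0.0):
    return DecisionTrace(
        binary=np.array([]),
        threshold=threshold,
        collar_s=collar_s,
        events=AnnotationTrack(events),
        times_s=np.array([]),
        duration_s=duration_s,
    )


def two_level_cohort(shift, low=0.1, high=0.4, n_epochs=100, seiz=range(20, 40)):
    """Two patients whose traces separate seizure from background perfectly
    but at shifted operating levels."""
    traces, truths = [], []
    for delta in (0.0, shift):
        fused = np.full(n_epochs, low + delta)
        fused[list(seiz)] = high + delta
        trace = make_trace(fused)
        t = trace.times_s
        truths.append(AnnotationTrack([(t[seiz[0]], t[seiz[-1]] + 4.0)]))
        traces.append(trace)
    return traces, truths


class TestEpochConfusion:
    def test_perfect_agreement(self):
        truth = AnnotationTrack([(100.0, 200.0)])
        dec = decisions_from([(100.0, 200.0)], 400.0)
        assert epoch_confusion(dec, truth) == (1.0, 1.0)

    def test_all_positive_decisions(self):
        truth = AnnotationTrack([(100.0, 200.0)])
        dec = decisions_from([(0.0, 400.0)], 400.0)
        se, sp = epoch_confusion(dec, truth)
        assert se == 1.0 and sp == 0.0

    def test_partial_overlap_matches_interval_oracle(self):
        truth = AnnotationTrack([(100.0, 200.0)])
        dec = decisions_from([(150.0, 250.0)], 400.0)
        se, sp = epoch_confusion(dec, truth)
        assert se == pytest.approx(50.0 / 100.0, abs=1e-12)
        assert sp == pytest.approx(250.0 / 300.0, abs=1e-12)

    def test_undefined_metrics_reported_as_missing(self):
        dec = decisions_from([], 100.0)
        se, sp = epoch_confusion(dec, AnnotationTrack([]))
        assert se is None and sp == 1.0


class TestEventMetrics:
    def test_no_detections(self):
        truth = AnnotationTrack([(10.0, 20.0), (50.0, 60.0)])
        s = event_metrics(decisions_from([], 3600.0), truth)
        assert s.gdr_pct == 0.0 and s.fd_per_h == 0.0

    def test_one_detection_covering_two_adjoining_seizures(self):
        truth = AnnotationTrack([(10.0, 20.0), (20.0, 30.0)])
        s = event_metrics(decisions_from([(15.0, 25.0)], 3600.0), truth)
        assert s.gdr_pct == 100.0 and s.n_false == 0

    def test_false_detection_rate_per_hour(self):
        truth = AnnotationTrack([])
        dets = [(100.0, 110.0), (200.0, 210.0), (300.0, 310.0)]
        s = event_metrics(decisions_from(dets, 10 * 3600.0), truth)
        assert s.fd_per_h == pytest.approx(0.3)

    def test_zero_duration_rejected(self):
        with pytest.raises(ValueError):
            event_metrics(decisions_from([], 0.0), AnnotationTrack([]))


class TestThresholdGridValidation:
    def test_rejects_non_increasing(self):
        with pytest.raises(ValueError):
            ThresholdGrid(np.array([0.1, 0.1, 0.2]))

    def test_rejects_single_value(self):
        with pytest.raises(ValueError):
            ThresholdGrid(np.array([0.5]))


class TestAucOrders:
    def hand_table(self):
        # thresholds ascending; SE falls, SP rises
        SE = np.array([[1.0, 0.9], [0.8, 0.6], [0.2, 0.3]])
        SP = np.array([[0.1, 0.2], [0.5, 0.7], [0.9, 0.8]])
        return MetricsTable(np.array([0.2, 0.5, 0.8]), SE, SP, [0, 1])

    def test_per_patient_matches_hand_trapezoid(self):
        table = self.hand_table()

        def trap(se, sp):
            se = [1.0] + list(se) + [0.0]
            sp = [0.0] + list(sp) + [1.0]
            return sum(
                (sp[i] - sp[i - 1]) * (se[i] + se[i - 1]) / 2 for i in range(1, len(sp))
            )

        expected = (trap(table.SE[:, 0], table.SP[:, 0]) + trap(table.SE[:, 1], table.SP[:, 1])) / 2
        assert auc_per_patient_mean(table) == pytest.approx(expected, abs=1e-12)

    def test_pooled_matches_hand_trapezoid_on_averaged_curve(self):
        table = self.hand_table()
        se = table.SE.mean(axis=1)
        sp = table.SP.mean(axis=1)
        se_a = np.concatenate(([1.0], se, [0.0]))
        sp_a = np.concatenate(([0.0], sp, [1.0]))
        expected = np.sum((sp_a[1:] - sp_a[:-1]) * (se_a[1:] + se_a[:-1]) / 2)
        assert auc_pooled_thresholds(table) == pytest.approx(expected, abs=1e-12)

    def test_single_patient_orders_agree_to_1e12(self):
        table = self.hand_table()
        one = MetricsTable(table.thresholds, table.SE[:, :1], table.SP[:, :1], [0])
        assert abs(auc_per_patient_mean(one) - auc_pooled_thresholds(one)) < 1e-12

    def test_identical_patients_orders_agree(self):
        table = self.hand_table()
        dup = MetricsTable(
            table.thresholds,
            np.repeat(table.SE[:, :1], 3, axis=1),
            np.repeat(table.SP[:, :1], 3, axis=1),
            [0, 1, 2],
        )
        assert auc_per_patient_mean(dup) == pytest.approx(auc_pooled_thresholds(dup), abs=1e-12)

    def test_perfect_separation_gives_auc_1(self):
        traces, truths = two_level_cohort(shift=0.0)
        table = compute_metrics_table(traces, truths)
        assert auc_per_patient_mean(table) == pytest.approx(1.0, abs=1e-9)

    def test_constant_probabilities_give_chance_auc(self):
        trace = make_trace(np.full(100, 0.4))
        t = trace.times_s
        truth = AnnotationTrack([(t[10], t[30])])
        table = compute_metrics_table([trace], [truth])
        assert auc_per_patient_mean(table) == pytest.approx(0.5, abs=1e-9)

    def test_incomplete_table_rejected(self):
        table = self.hand_table()
        table.SE[0, 0] = np.nan
        with pytest.raises(ValueError, match="undefined"):
            auc_per_patient_mean(table)

    def test_calibration_shift_makes_pooled_auc_strictly_lower(self):
        traces, truths = two_level_cohort(shift=0.45)
        table = compute_metrics_table(traces, truths)
        per_patient = auc_per_patient_mean(table)
        pooled = auc_pooled_thresholds(table)
        assert per_patient == pytest.approx(1.0, abs=1e-9)
        assert pooled < per_patient - 1e-6

    def test_epoch_level_se_sp_monotone_in_threshold(self):
        rng = np.random.default_rng(4)
        trace = make_trace(rng.random(200))
        t = trace.times_s
        truth = AnnotationTrack([(t[20], t[60]), (t[120], t[150])])
        table = compute_metrics_table([trace], [truth])
        assert np.all(np.diff(table.SE[:, 0]) <= 1e-12)
        assert np.all(np.diff(table.SP[:, 0]) >= -1e-12)


class TestThresholdGuide:
    def test_identical_patients_give_degenerate_ci(self):
        traces, truths = two_level_cohort(shift=0.0)
        guide = threshold_guide(traces, truths, np.array([0.2, 0.6]), collar_s=0.0, seed=0)
        row = guide[guide.threshold == 0.2].iloc[0]
        assert row.fd_per_h_upper95 == pytest.approx(row.fd_per_h_mean, abs=1e-12)

    def test_threshold_beyond_max_probability(self):
        traces, truths = two_level_cohort(shift=0.0)
        guide = threshold_guide(traces, truths, np.array([0.5, 1.0]), collar_s=0.0, seed=0)
        row = guide[guide.threshold == 1.0].iloc[0]
        assert row.gdr_mean_pct == 0.0
        assert row.fd_per_h_upper95 == 0.0

    def test_single_patient_ci_missing(self):
        traces, truths = two_level_cohort(shift=0.0)
        guide = threshold_guide(traces[:1], truths[:1], np.array([0.2, 0.6]), seed=0)
        assert np.isnan(guide.fd_per_h_upper95).all()

    def test_gdr_non_increasing_in_threshold(self):
        rng = np.random.default_rng(2)
        trace = make_trace(np.sort(rng.random((4, 150)), axis=0))
        t = trace.times_s
        truth = AnnotationTrack([(t[30], t[60])])
        guide = threshold_guide([trace, trace], [truth, truth], collar_s=0.0, seed=0)
        assert np.all(np.diff(guide.gdr_mean_pct) <= 1e-9)


class TestBootstrapUpperBound:
    def test_matches_exact_quantile_by_enumeration(self):
        values = np.array([0.1, 0.3, 0.9])
        # enumerate all 27 equally likely resample means
        means = sorted(
            np.mean([values[i], values[j], values[k]])
            for i in range(3)
            for j in range(3)
            for k in range(3)
        )
        cdf = np.arange(1, 28) / 27.0
        exact = next(m for m, c in zip(means, cdf) if c >= 0.975)
        boot = bootstrap_upper95(values, n_boot=20000, rng=0)
        assert boot == pytest.approx(exact, rel=0.05)

    def test_seeded_and_deterministic(self):
        values = np.array([0.2, 0.5, 0.7, 1.1])
        assert bootstrap_upper95(values, rng=3) == bootstrap_upper95(values, rng=3)


def test_binarize_feeds_confusion_consistently(tiny_trace, seizure_recording):
    """Epoch confusion of a real decision trace lies in [0, 1]."""
    _, ann = seizure_recording
    se, sp = epoch_confusion(binarize(tiny_trace, 0.5, 32.0), ann)
    assert 0.0 <= se <= 1.0 and 0.0 <= sp <= 1.0
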