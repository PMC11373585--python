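"""Event windows, windowed scoring, ROC sweep and threshold optimum."""

import numpy as np
import pytest

import mislfp as m
from mislfp.detection import Detection
from mislfp.synthetic import event_template
from conftest import make_per_cycle_series


def det(t):
    return Detection(t_flag=t, batch_index=int(round(t / 0.14)) - 1, strategy="batch",
                     value=1e3, r_init=40e3)


class TestEventWindows:
    def test_flat_trace_yields_no_windows(self):
        trace = m.LfpTrace(np.zeros(10_000), 2000.0, cue_times=np.array([1.0]))
        assert m.extract_event_windows(trace) == []

    def test_window_matches_continuous_template_oracle(self):
        fs, onset, dur, freq = 2000.0, 2.0, 1.68, 7.0
        t = np.arange(int(10 * fs)) / fs
        x = event_template(t, onset, dur, 1.0, freq)
        trace = m.LfpTrace(x, fs, cue_times=np.array([1.5]))
        (w,) = m.extract_event_windows(trace, search_horizon=2.5)
        # independent oracle: evaluate the continuous template on a 100x
        # finer grid, locate first/last peaks of |x| and their half-height
        # crossings
        tf = np.arange(1.5, 4.01, 1.0 / (100 * fs))
        xf = np.abs(event_template(tf, onset, dur, 1.0, freq))
        pk = np.flatnonzero((xf[1:-1] > xf[:-2]) & (xf[1:-1] >= xf[2:])) + 1
        pk = pk[xf[pk] > 1e-9]
        first, last = pk[0], pk[-1]
        i = first
        while xf[i] >= xf[first] / 2:
            i -= 1
        start_oracle = tf[i]
        j = last
        while xf[j] >= xf[last] / 2:
            j += 1
        end_oracle = tf[j]
        assert w.start == pytest.approx(start_oracle, abs=1.0 / fs)
        assert w.end == pytest.approx(end_oracle, abs=1.0 / fs)
        assert w.source_cue == 1.5

    def test_extracted_windows_overlap_ground_truth(self, noiseless_session):
        trace, amplified, _series, windows = noiseless_session
        spans = trace.ground_truth_event_spans
        assert len(windows) == len(spans)
        for w, (s0, e0) in zip(windows, spans):
            assert w.start < e0 and w.end > s0  # overlap

    def test_overlapping_windows_are_merged(self):
        fs = 2000.0
        t = np.arange(int(8 * fs)) / fs
        x = event_template(t, 2.0, 1.68, 1.0, 7.0) + event_template(t, 3.0, 1.68, 1.0, 7.0)
        trace = m.LfpTrace(x, fs, cue_times=np.array([1.5, 2.6]))
        with pytest.warns(UserWarning, match="merged"):
            windows = m.extract_event_windows(trace, search_horizon=2.5)
        assert len(windows) == 1
        assert windows[0].source_cue == 1.5

    def test_windows_from_ground_truth(self, noiseless_session):
        trace, *_ = noiseless_session
        gt = m.windows_from_ground_truth(trace)
        assert len(gt) == len(trace.ground_truth_event_spans)
        for w in gt:
            assert w.start > w.source_cue


class TestScoring:
    windows = [
        m.EventWindow(1.0, 2.0, 0.5),
        m.EventWindow(4.0, 5.0, 3.5),
        m.EventWindow(7.0, 8.0, 6.5),
    ]
    batch_times = 0.14 * (1 + np.arange(100))

    def in_window_batches(self):
        return sum(
            1 for t in self.batch_times if any(w.contains(t) for w in self.windows)
        )

    def test_toy_layout(self):
        dets = [det(1.54), det(4.2), det(9.8)]  # 2 windows hit + 1 stray
        c = m.score_detections(dets, self.windows, 100, self.batch_times)
        assert (c.tp, c.fn, c.fp) == (2, 1, 1)
        assert c.tn == 100 - self.in_window_batches() - 1

    def test_no_detections(self):
        c = m.score_detections([], self.windows, 100, self.batch_times)
        assert (c.tp, c.fn, c.fp) == (0, 3, 0)
        assert c.tn == 100 - self.in_window_batches()

    def test_every_batch_detects(self):
        dets = [det(t) for t in self.batch_times]
        c = m.score_detections(dets, self.windows, 100, self.batch_times)
        assert (c.tp, c.fn, c.tn) == (3, 0, 0)
        assert c.fp == 100 - self.in_window_batches()

    def test_count_conservation(self):
        rng = np.random.default_rng(7)
        dets = [det(t) for t in rng.choice(self.batch_times, 20, replace=False)]
        c = m.score_detections(dets, self.windows, 100, self.batch_times)
        assert c.tp + c.fn == len(self.windows)
        assert c.tn + c.fp + sum(
            1
            for t in self.batch_times
            if any(w.contains(t) for w in self.windows)
            and t not in {d.t_flag for d in dets}
        ) + sum(
            1
            for d in dets
            if any(w.contains(d.t_flag) for w in self.windows)
        ) == 100

    def test_off_grid_detection_rejected(self):
        with pytest.raises(ValueError):
            m.score_detections([det(1.5)], self.windows, 100, self.batch_times)


class TestMetrics:
    def test_arithmetic(self):
        mm = m.metrics(m.ConfusionCounts(tp=2, fp=2, fn=1, tn=95))
        assert mm.sensitivity == pytest.approx(2 / 3)
        assert mm.specificity == pytest.approx(95 / 97)
        assert mm.accuracy == pytest.approx(97 / 100)
        assert mm.tpr == mm.sensitivity
        assert mm.fpr == pytest.approx(2 / 97)

    def test_undefined_marked_not_zeroed(self):
        mm = m.metrics(m.ConfusionCounts(tp=0, fp=1, fn=0, tn=5))
        assert mm.sensitivity is None

    def test_perfect_detector(self):
        mm = m.metrics(m.ConfusionCounts(tp=3, fp=0, fn=0, tn=97))
        assert mm.sensitivity == mm.specificity == mm.accuracy == 1.0


class TestRocSweep:
    def make_inputs(self):
        rng = np.random.default_rng(8)
        series = make_per_cycle_series(
            np.cumsum(rng.normal(0, 50, 7000)) + 30e3
        )
        windows = [m.EventWindow(2.0, 3.5, 1.5), m.EventWindow(8.0, 9.5, 7.5)]
        return series, windows

    def test_extreme_thresholds_hit_corners(self):
        series, windows = self.make_inputs()
        config = m.DetectionConfig(strategy="maxdrop")
        search = m.ThresholdSearchConfig(a_grid=np.array([1e-9, 10.0]))
        roc = m.roc_sweep(series, windows, config, search)
        assert (roc.fpr[0], roc.tpr[0]) == (1.0, 1.0)  # everything detects
        assert (roc.fpr[-1], roc.tpr[-1]) == (0.0, 0.0)  # nothing detects

    def test_roc_coordinates_non_increasing_in_a(self):
        series, windows = self.make_inputs()
        for strategy in ("maxdiff", "maxdrop", "batch"):
            roc = m.roc_sweep(series, windows, m.DetectionConfig(strategy=strategy))
            assert np.all(np.diff(roc.fpr) <= 1e-12)
            assert np.all(np.diff(roc.tpr) <= 1e-12)

    def test_matches_sklearn_on_batch_aligned_windows(self):
        """One batch end per window: windowed scoring reduces to plain
        per-sample binary classification, cross-checked against sklearn."""
        from sklearn.metrics import roc_curve as sk_roc

        rng = np.random.default_rng(9)
        n = 40
        labels = rng.random(n) < 0.3
        scores = np.where(labels, rng.uniform(0.005, 0.03, n), rng.uniform(0.001, 0.015, n))
        # chain readouts so each per-batch biomarker normalizes to scores[k]
        r = [40e3]
        for s in scores:
            r.append(r[-1] * (1 - s))
        series = m.ResistanceSeries(
            times=0.14 * (1 + np.arange(n)),
            readouts=np.array(r[1:]),
            cycle_period=2e-3,
            cycles_per_readout=70,
            initial_resistance=40e3,
        )
        windows = [
            m.EventWindow(t - 0.01, t + 0.01, t - 0.02)
            for t, lab in zip(series.times, labels)
            if lab
        ]
        grid = np.sort(np.concatenate([scores * (1 - 1e-9), [scores.max() * 2]]))
        roc = m.roc_sweep(
            series, windows, m.DetectionConfig(strategy="batch"),
            m.ThresholdSearchConfig(a_grid=grid),
        )
        fpr_sk, tpr_sk, _ = sk_roc(labels.astype(int), scores)
        ours = {(round(f, 12), round(t, 12)) for f, t in zip(roc.fpr, roc.tpr)}
        theirs = {(round(f, 12), round(t, 12)) for f, t in zip(fpr_sk, tpr_sk)}
        assert theirs <= ours | {(0.0, 0.0)}


class TestOptimalThreshold:
    def test_three_point_example(self):
        roc = m.RocCurve(
            a_values=np.array([0.01, 0.02, 0.03]),
            fpr=np.array([1.0, 0.1, 0.0]),
            tpr=np.array([1.0, 0.9, 0.0]),
            strategy="batch",
            batch_size=70,
        )
        a_opt, point = m.optimal_threshold(roc, 45.0)
        assert a_opt == 0.02
        assert point == (0.1, 0.9)

    def test_diagonal_ties_break_to_smallest_a(self):
        roc = m.RocCurve(
            a_values=np.array([0.01, 0.02, 0.03]),
            fpr=np.array([0.9, 0.5, 0.1]),
            tpr=np.array([0.9, 0.5, 0.1]),
            strategy="batch",
            batch_size=70,
        )
        a_opt, _ = m.optimal_threshold(roc, 45.0)
        assert a_opt == 0.01

    @pytest.mark.parametrize("angle", [30.0, 45.0, 60.0])
    def test_matches_geometric_distance_oracle(self, angle):
        rng = np.random.default_rng(10)
        fpr = np.sort(rng.random(50))[::-1]
        tpr = np.sort(rng.random(50))[::-1]
        roc = m.RocCurve(
            a_values=np.linspace(0.01, 0.5, 50), fpr=fpr, tpr=tpr,
            strategy="batch", batch_size=70,
        )
        a_opt, _ = m.optimal_threshold(roc, angle)
        # perpendicular distance from each point to the secant through the
        # ideal classifier (0, 1) at angle alpha; minimal distance wins
        al = np.deg2rad(angle)
        d = np.abs(np.sin(al) * fpr - np.cos(al) * tpr + np.cos(al))
        assert a_opt == roc.a_values[int(np.argmin(d))]

    def test_45_deg_equals_youden_argmax(self):
        rng = np.random.default_rng(11)
        fpr = np.sort(rng.random(30))[::-1]
        tpr = np.clip(fpr + rng.normal(0, 0.2, 30), 0, 1)
        roc = m.RocCurve(
            a_values=np.linspace(0.01, 0.3, 30), fpr=fpr, tpr=tpr,
            strategy="batch", batch_size=70,
        )
        a_opt, _ = m.optimal_threshold(roc, 45.0)
        assert a_opt == roc.a_values[int(np.argmax(tpr - fpr))]


class TestLatency:
    def test_single_window_example(self):
        windows = [m.EventWindow(10.45, 12.2, 10.0)]
        d = Detection(t_flag=10.71, batch_index=0, strategy="batch", value=1e3, r_init=40e3)
        lat = m.detection_latency([d], windows)
        assert lat.size == 1
        assert lat[0] == pytest.approx(0.71)

    def test_no_true_positives_empty(self):
        assert m.detection_latency([], [m.EventWindow(1.0, 2.0, 0.5)]).size == 0

    def test_first_in_window_detection_counts(self):
        windows = [m.EventWindow(1.0, 3.0, 0.5)]
        dets = [det(2.80), det(1.54)]
        lat = m.detection_latency(dets, windows)
        assert lat[0] == pytest.approx(1.54 - 0.5)


class TestBaseline:
    def test_flat_trace_no_peaks(self):
        trace = m.LfpTrace(np.zeros(5000), 2000.0)
        assert m.baseline_detect(trace).size == 0

    def test_gaussian_bump_peak_at_center(self):
        fs = 2000.0
        t = np.arange(int(4 * fs)) / fs
        x = np.exp(-0.5 * ((t - 2.0) / 0.05) ** 2)
        trace = m.LfpTrace(x, fs)
        peaks = m.baseline_detect(trace, prominence=0.5)
        assert peaks.size == 1
        assert peaks[0] == pytest.approx(2.0, abs=1.0 / fs)

    def test_white_noise_below_prominence_silent(self):
        rng = np.random.default_rng(12)
        trace = m.LfpTrace(rng.normal(0, 1e-3, 10_000), 2000.0)
        assert m.baseline_detect(trace, prominence=0.5).size == 0

    def test_cue_gated_detection_times(self):
        fs = 2000.0
        t = np.arange(int(6 * fs)) / fs
        x = np.exp(-0.5 * ((t - 2.5) / 0.05) ** 2)
        trace = m.LfpTrace(x, fs)
        out = m.baseline_detect(trace, cues=np.array([2.0]), prominence=0.5)
        assert out.size == 1 and out[0] == pytest.approx(2.5, abs=2 / fs)

    def test_invalid_savgol_params_rejected(self):
        trace = m.LfpTrace(np.zeros(100), 2000.0)
        with pytest.raises(ValueError):
            m.baseline_detect(trace, sg_window=50)
        with pytest.raises(ValueError):
            m.baseline_detect(trace, sg_window=3, sg_order=5)
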