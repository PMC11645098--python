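"""Streaming fusion detector: thresholds, sweep mechanics, event scoring."""

import numpy as np
import pytest

from pepdetect import (
    ClassifierConfig,
    CohortConfig,
    DetectorConfig,
    compute_threshold,
    detect_stream,
    evaluate_realtime,
    generate_cohort,
    train_detector,
)
from pepdetect.realtime import EXPECTED, UNEXPECTED, truth_windows
from pepdetect.synthetic import Recording


@pytest.fixture(scope="module")
def rt_cohort():
    """Strong-effect cohort for detector training/validation tests."""
    cfg = CohortConfig(
        n_subjects=5, events_per_subject=8, n_dropped_total=0,
        unpredicted_fraction=0.4, effect_size=3.0,
        inter_event_interval_s=(3.0, 4.0), seed=21,
    )
    return generate_cohort(cfg)


@pytest.fixture(scope="module")
def trained(rt_cohort):
    subs = sorted(rt_cohort.recordings)
    det = train_detector(
        rt_cohort, subs[:4], DetectorConfig(), ClassifierConfig(n_trees=60, seed=3)
    )
    return det, subs[4:]


class TestThreshold:
    def test_min_of_max_definition(self):
        windows = {"eeg": [np.array([0.1, -0.8]), np.array([1.2]), np.array([0.9])]}
        assert compute_threshold(windows)["eeg"] == pytest.approx(0.8)

    def test_single_event_is_its_own_maximum(self):
        assert compute_threshold({"accel": [np.array([-0.4, 0.3])]})["accel"] == 0.4

    def test_empty_unexpected_set_rejected(self):
        with pytest.raises(ValueError, match="eeg"):
            compute_threshold({"eeg": []})

    def test_every_training_event_max_at_least_threshold(self, rng):
        windows = {"eeg": [rng.standard_normal(50) for _ in range(10)]}
        thr = compute_threshold(windows)["eeg"]
        assert all(np.max(np.abs(w)) >= thr for w in windows["eeg"])


class TestConfigInvariants:
    def test_step_larger_than_window_rejected(self):
        with pytest.raises(ValueError):
            DetectorConfig(window_ms=100.0, step_ms=200.0)

    def test_skip_smaller_than_window_rejected(self):
        with pytest.raises(ValueError):
            DetectorConfig(skip_after_detection_ms=100.0)


class TestSweepMechanics:
    def test_subthreshold_stream_zero_detections_iteration_count(self, trained):
        det, _ = trained
        n = 5000
        rec = Recording(
            subject_id="flat",
            eeg=np.sin(np.arange(n) * 0.05) * 1e-3,
            accel=np.zeros(750),
            eeg_rate=1000.0,
            accel_rate=150.0,
            onsets=np.array([1000]),
        )
        refs = {"eeg": 1.0, "accel": 1.0}
        res = detect_stream(rec, det, refs=refs)
        assert res.events == []
        # sweep arithmetic: floor((n - delay - window) / step) + 1
        assert res.n_iterations == (n - 80 - 256) // 30 + 1

    def test_stream_shorter_than_window_warns_empty(self, trained, caplog):
        import logging

        det, _ = trained
        rec = Recording("tiny", np.zeros(100), np.zeros(15), 1000.0, 150.0, np.array([10]))
        with caplog.at_level(logging.WARNING, logger="pepdetect.realtime"):
            res = detect_stream(rec, det, refs={"eeg": 1.0, "accel": 1.0})
        assert res.events == [] and res.n_iterations == 0
        assert any("shorter" in r.message for r in caplog.records)

    def test_skip_rule_no_two_detections_within_1s(self, rt_cohort, trained):
        det, val = trained
        for sid in val:
            res = detect_stream(rt_cohort.recordings[sid], det)
            times = [d.trigger_time_ms for d in res.events]
            assert all(b - a >= det.config.skip_after_detection_ms
                       for a, b in zip(times, times[1:]))


class TestDetection:
    def test_planted_events_detected_with_latency_bound(self, rt_cohort, trained):
        det, val = trained
        for sid in val:
            res = detect_stream(rt_cohort.recordings[sid], det)
            ev = rt_cohort.events[rt_cohort.events["subject"] == sid]
            tw = truth_windows(ev[ev["label"] == "Unpredicted"], det.config, 1000.0)
            for _, t in tw.iterrows():
                overlapping = [
                    d for d in res.events
                    if d.window_start_ms < t["win_end_ms"]
                    and t["win_start_ms"] < d.window_end_ms
                ]
                assert overlapping, f"event at {t['onset_sample']} not detected"
                lat = overlapping[0].trigger_time_ms - t["onset_sample"]
                assert lat < 400.0

    def test_threshold_monotonicity_fp_never_increase(self, rt_cohort, trained):
        from dataclasses import replace

        det, val = trained
        fp_counts = []
        for factor in (1.0, 1.5):
            thr = {k: v * factor for k, v in det.config.thresholds.items()}
            d2 = replace(det, config=replace(det.config, thresholds=thr))
            results = {s: detect_stream(rt_cohort.recordings[s], d2) for s in val}
            events = rt_cohort.events[rt_cohort.events["subject"].isin(val)]
            counts, _ = evaluate_realtime(results, events, d2.config, 1000.0)
            fp_counts.append(counts.FP)
        assert fp_counts[1] <= fp_counts[0]


class TestEvaluation:
    def test_perfect_and_silent_detectors(self, rt_cohort, trained):
        from pepdetect.realtime import DetectionEvent, DetectionResult

        det, val = trained
        events = rt_cohort.events[rt_cohort.events["subject"].isin(val)]
        # silent detector: FN = number of true Unpredicted events
        silent = {s: DetectionResult([], [], 0, 0.0) for s in val}
        counts, m = evaluate_realtime(silent, events, det.config, 1000.0)
        assert counts.TP == 0 and counts.FN == (events["label"] == "Unpredicted").sum()
        # oracle detector: one perfectly aligned detection per true event
        oracle = {}
        for s in val:
            ev = truth_windows(
                events[(events["subject"] == s) & (events["label"] == "Unpredicted")],
                det.config, 1000.0,
            )
            dets = [
                DetectionEvent(s, r["win_end_ms"], r["win_start_ms"], r["win_end_ms"],
                               UNEXPECTED, 1.0, 1.0)
                for _, r in ev.iterrows()
            ]
            oracle[s] = DetectionResult(dets, [], 0, 0.0)
        counts, m = evaluate_realtime(oracle, events, det.config, 1000.0)
        assert m.sensitivity == 1.0 and counts.FP == 0

    def test_matches_brute_force_interval_scoring(self, rt_cohort, trained):
        det, val = trained
        results = {s: detect_stream(rt_cohort.recordings[s], det) for s in val}
        events = rt_cohort.events[rt_cohort.events["subject"].isin(val)]
        counts, _ = evaluate_realtime(results, events, det.config, 1000.0)
        # independent re-scoring of detection/truth interval overlap
        tp = fp = fn = tn = 0
        for s in val:
            ev = truth_windows(
                events[(events["subject"] == s) & (events["label"] == "Unpredicted")],
                det.config, 1000.0,
            )
            spans = [(r["win_start_ms"], r["win_end_ms"]) for _, r in ev.iterrows()]
            hit = [False] * len(spans)
            for d in results[s].events:
                ov = [i for i, (b0, b1) in enumerate(spans)
                      if max(d.window_start_ms, b0) < min(d.window_end_ms, b1)]
                if ov:
                    tp += 1
                    for i in ov:
                        hit[i] = True
                else:
                    fp += 1
            fn += hit.count(False)
            for inv in results[s].invocations:
                if inv.result == EXPECTED and not any(
                    max(inv.window_start_ms, b0) < min(inv.window_end_ms, b1)
                    for b0, b1 in spans
                ):
                    tn += 1
        assert (counts.TP, counts.FP, counts.FN, counts.TN) == (tp, fp, fn, tn)
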