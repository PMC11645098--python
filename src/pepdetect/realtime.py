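"""Streaming EEG + acceleration fusion detector and its event-level scoring.

A 256 ms analysis window sweeps the synchronized, causally filtered streams
in 30 ms steps, offset 80 ms from the sweep position.  Each window is
normalized by the subject's stored reference scalars and compared against
per-signal thresholds (the minimum over Unexpected training events of the
event-window maxima).  Sub-threshold windows advance by one step;
supra-threshold windows are classified from order-3 state-space features —
an "Expected" verdict advances one step, an "Unexpected" verdict records a
detection and advances 1 s so the same fall is never counted twice.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .classify import (
    ClassifierConfig,
    ConfusionCounts,
    Metrics,
    TrainedEnsemble,
    compute_metrics,
    train_bagged_trees,
)
from .features import state_space_features
from .preprocess import PreprocessSpec, bandpass_notch, resample_accel, savgol_smooth
from .synthetic import UNPREDICTED, Recording, SyntheticCohort

logger = logging.getLogger(__name__)

EXPECTED = "Expected"
UNEXPECTED = "Unexpected"


@dataclass(frozen=True)
class DetectorConfig:
    window_ms: float = 256.0
    onset_delay_ms: float = 80.0
    step_ms: float = 30.0
    skip_after_detection_ms: float = 1000.0
    order: int = 3
    horizon: int = 10
    decimate: int = 4
    trigger_rule: str = "any"          # "any": either signal over threshold
    feature_mode: str = "fusion"       # "fusion" (EEG+accel) or "eeg"
    thresholds: dict = field(default_factory=dict)  # {"eeg": x, "accel": y}
    preprocess: PreprocessSpec = field(default_factory=PreprocessSpec)

    def __post_init__(self) -> None:
        if self.window_ms <= 0:
            raise ValueError("window_ms must be > 0")
        if self.step_ms > self.window_ms:
            raise ValueError("step_ms must be <= window_ms")
        if self.skip_after_detection_ms < self.window_ms:
            raise ValueError("skip_after_detection_ms must be >= window_ms")


@dataclass
class DetectionEvent:
    subject_id: str
    trigger_time_ms: float
    window_start_ms: float
    window_end_ms: float
    predicted_class: str
    max_eeg: float
    max_accel: float


@dataclass
class Invocation:
    """One supra-threshold classifier call (for window-level TN accounting)."""

    subject_id: str
    window_start_ms: float
    window_end_ms: float
    result: str


@dataclass
class DetectionResult:
    events: list[DetectionEvent]
    invocations: list[Invocation]
    n_iterations: int
    mean_iteration_ms: float


@dataclass
class TrainedDetector:
    config: DetectorConfig
    classifier: TrainedEnsemble
    training_subjects: list[str]


# ---------------------------------------------------------------------------
# Stream preparation and references
# ---------------------------------------------------------------------------

def prepare_streams(rec: Recording, spec: PreprocessSpec) -> tuple[np.ndarray, np.ndarray]:
    """Causally filter the EEG, smooth both channels, and resample the
    acceleration to the EEG rate. Returns (eeg, accel) at eeg_rate."""
    eeg = bandpass_notch(rec.eeg, rec.eeg_rate, spec, zero_phase=False)
    eeg = savgol_smooth(eeg, spec)
    acc = savgol_smooth(rec.accel, spec)
    acc = resample_accel(acc, rec.accel_rate, rec.eeg_rate)
    n = len(eeg)
    if len(acc) < n:
        acc = np.pad(acc, (0, n - len(acc)))
    return eeg, acc[:n]


def _event_window(onset: int, config: DetectorConfig, rate: float) -> slice:
    i0 = onset + int(round(config.onset_delay_ms * rate / 1000.0))
    n = int(round(config.window_ms * rate / 1000.0))
    return slice(i0, i0 + n)


def subject_references(
    rec: Recording, config: DetectorConfig
) -> dict[str, float]:
    """Per-subject normalization scalars: max |signal| within the first
    event's analysis window, per channel."""
    if len(rec.onsets) == 0:
        raise ValueError(f"subject {rec.subject_id}: no events for reference")
    eeg, acc = prepare_streams(rec, config.preprocess)
    sl = _event_window(int(rec.onsets[0]), config, rec.eeg_rate)
    refs = {
        "eeg": float(np.max(np.abs(eeg[sl]))),
        "accel": float(np.max(np.abs(acc[sl]))),
    }
    for name, v in refs.items():
        if v == 0.0:
            raise ValueError(
                f"subject {rec.subject_id}: zero {name} reference window"
            )
    return refs


# ---------------------------------------------------------------------------
# Training: thresholds + classifier
# ---------------------------------------------------------------------------

def compute_threshold(unexpected_windows: dict[str, list[np.ndarray]]) -> dict[str, float]:
    """Per-signal threshold: the minimum over Unexpected training events of
    the maximum |normalized signal| within the event window."""
    thresholds = {}
    for name, windows in unexpected_windows.items():
        if not windows:
            raise ValueError(f"no Unexpected training events for signal {name!r}")
        thresholds[name] = float(min(np.max(np.abs(w)) for w in windows))
    return thresholds


def _window_features(
    eeg_w: np.ndarray, acc_w: np.ndarray, config: DetectorConfig
) -> np.ndarray:
    f_eeg = state_space_features(eeg_w, config.order, config.horizon, config.decimate)
    if config.feature_mode == "eeg":
        return f_eeg
    f_acc = state_space_features(acc_w, config.order, config.horizon, config.decimate)
    return np.concatenate([f_eeg, f_acc])


def train_detector(
    cohort: SyntheticCohort,
    training_subjects: list[str],
    config: DetectorConfig = DetectorConfig(),
    classifier_config: ClassifierConfig = ClassifierConfig(),
) -> TrainedDetector:
    """Fit thresholds and the window classifier on the training subjects.

    Each completed event contributes its response window ([onset+80,
    onset+336] ms) plus jittered copies (offsets up to +/-120 ms), all
    labeled Unexpected/Expected by the event's predictability class, and
    Expected-labeled context windows (a quiet pre-event no-fall window, an
    onset-straddling window, a post-response window).  The sliding
    detector classifies windows at arbitrary offsets from the onset, so
    the classifier must see both off-alignment responses (positives) and
    non-response context (negatives), or it guesses on them.  Thresholds
    use only the aligned Unexpected windows.
    """
    rows, labels = [], []
    unexpected = {"eeg": [], "accel": []}
    rate = None
    for sid in training_subjects:
        rec = cohort.recordings[sid]
        rate = rec.eeg_rate
        refs = subject_references(rec, config)
        eeg, acc = prepare_streams(rec, config.preprocess)
        eeg, acc = eeg / refs["eeg"], acc / refs["accel"]
        sub = cohort.events[cohort.events["subject"] == sid]
        quiet_off = int(round((config.skip_after_detection_ms + config.window_ms)
                              * rate / 1000.0))
        jitter = [int(round(d * rate / 1000.0)) for d in (-60, -30, 0, 30, 60)]
        for onset, label in zip(sub["onset_sample"], sub["label"]):
            sl = _event_window(int(onset), config, rate)
            if sl.stop > len(eeg):
                logger.warning("skipping training event at %d: stream too short", onset)
                continue
            win = sl.stop - sl.start
            cls = UNEXPECTED if label == UNPREDICTED else EXPECTED
            if cls == UNEXPECTED:
                unexpected["eeg"].append(eeg[sl])
                unexpected["accel"].append(acc[sl])
            for off in jitter:
                osl = slice(sl.start + off, sl.stop + off)
                if osl.start >= 0 and osl.stop <= len(eeg):
                    rows.append(_window_features(eeg[osl], acc[osl], config))
                    labels.append(cls)
            delay = int(sl.start - onset)
            straddles = [-win - delay + k for k in (0, int(0.4 * delay), int(0.8 * delay))]
            for off in (-quiet_off, *straddles, win):
                osl = slice(sl.start + off, sl.stop + off)
                if osl.start >= 0 and osl.stop <= len(eeg):
                    rows.append(_window_features(eeg[osl], acc[osl], config))
                    labels.append(EXPECTED)
    thresholds = compute_threshold(unexpected)
    ens = train_bagged_trees(
        np.vstack(rows), classifier_config, labels=np.array(labels, dtype=object)
    )
    return TrainedDetector(
        config=replace(config, thresholds=thresholds),
        classifier=ens,
        training_subjects=list(training_subjects),
    )


# ---------------------------------------------------------------------------
# Detection loop
# ---------------------------------------------------------------------------

def detect_stream(
    rec: Recording,
    detector: TrainedDetector,
    refs: dict[str, float] | None = None,
) -> DetectionResult:
    """Run the sliding-window fusion detector over one subject's streams."""
    config = detector.config
    rate = rec.eeg_rate
    refs = refs or subject_references(rec, config)
    eeg, acc = prepare_streams(rec, config.preprocess)
    eeg, acc = eeg / refs["eeg"], acc / refs["accel"]

    win = int(round(config.window_ms * rate / 1000.0))
    step = int(round(config.step_ms * rate / 1000.0))
    skip = int(round(config.skip_after_detection_ms * rate / 1000.0))
    delay = int(round(config.onset_delay_ms * rate / 1000.0))
    thr_e = config.thresholds.get("eeg", np.inf)
    thr_a = config.thresholds.get("accel", np.inf)

    events: list[DetectionEvent] = []
    invocations: list[Invocation] = []
    n = len(eeg)
    if n < delay + win:
        logger.warning(
            "stream for %s shorter than one analysis window", rec.subject_id
        )
        return DetectionResult([], [], 0, 0.0)

    p = 0
    iters = 0
    t0 = time.perf_counter()
    while p + delay + win <= n:
        iters += 1
        s = p + delay
        eeg_w = eeg[s : s + win]
        acc_w = acc[s : s + win]
        max_e = float(np.max(np.abs(eeg_w)))
        max_a = float(np.max(np.abs(acc_w)))
        if config.trigger_rule == "any":
            supra = max_e > thr_e or max_a > thr_a
        else:
            supra = max_e > thr_e and max_a > thr_a
        if not supra:
            p += step
            continue
        feats = _window_features(eeg_w, acc_w, config)
        verdict = str(detector.classifier.predict(feats[None, :])[0])
        start_ms = s * 1000.0 / rate
        end_ms = (s + win) * 1000.0 / rate
        invocations.append(Invocation(rec.subject_id, start_ms, end_ms, verdict))
        if verdict == EXPECTED:
            p += step
        else:
            events.append(
                DetectionEvent(
                    subject_id=rec.subject_id,
                    trigger_time_ms=end_ms,
                    window_start_ms=start_ms,
                    window_end_ms=end_ms,
                    predicted_class=verdict,
                    max_eeg=max_e,
                    max_accel=max_a,
                )
            )
            p += skip
    elapsed_ms = (time.perf_counter() - t0) * 1000.0
    mean_iter = elapsed_ms / iters if iters else 0.0
    logger.info(
        "%s: %d iterations, %.2f ms/iteration (step budget %.0f ms)",
        rec.subject_id, iters, mean_iter, config.step_ms,
    )
    return DetectionResult(events, invocations, iters, mean_iter)


# ---------------------------------------------------------------------------
# Event-level evaluation
# ---------------------------------------------------------------------------

def _overlaps(a0: float, a1: float, b0: float, b1: float) -> bool:
    return a0 < b1 and b0 < a1


def truth_windows(
    events: pd.DataFrame, config: DetectorConfig, rate: float
) -> pd.DataFrame:
    """Per-event scoring windows [onset+delay, onset+delay+window] in ms."""
    onset_ms = events["onset_sample"] * 1000.0 / rate
    out = events.copy()
    out["win_start_ms"] = onset_ms + config.onset_delay_ms
    out["win_end_ms"] = out["win_start_ms"] + config.window_ms
    return out


def evaluate_realtime(
    results: dict[str, DetectionResult],
    events: pd.DataFrame,
    config: DetectorConfig,
    rate: float,
) -> tuple[ConfusionCounts, Metrics]:
    """Score detections against labeled events by window overlap.

    TP: an Unexpected detection whose window overlaps a true Unpredicted
    event's window.  FP: an Unexpected detection with no such overlap.
    FN: a true Unpredicted event with no overlapping detection.  TN: each
    supra-threshold classifier invocation resolved Expected whose window
    does not overlap a true Unpredicted event (window-level negatives).
    """
    tp = fp = fn = tn = 0
    for sid, res in results.items():
        sub = truth_windows(
            events[events["subject"] == sid], config, rate
        )
        unpred = sub[sub["label"] == UNPREDICTED]
        spans = list(zip(unpred["win_start_ms"], unpred["win_end_ms"]))
        if unpred.duplicated("onset_sample").any():
            raise ValueError("overlapping truth events")
        matched = np.zeros(len(spans), dtype=bool)
        for det in res.events:
            hit = False
            for i, (b0, b1) in enumerate(spans):
                if _overlaps(det.window_start_ms, det.window_end_ms, b0, b1):
                    matched[i] = True
                    hit = True
            if hit:
                tp += 1
            else:
                fp += 1
        fn += int((~matched).sum())
        for inv in res.invocations:
            if inv.result != EXPECTED:
                continue
            if not any(
                _overlaps(inv.window_start_ms, inv.window_end_ms, b0, b1)
                for b0, b1 in spans
            ):
                tn += 1
    counts = ConfusionCounts(TP=tp, TN=tn, FP=fp, FN=fn)
    return counts, compute_metrics(counts)
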