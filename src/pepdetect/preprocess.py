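"""Filtering, baseline correction, normalization, and epoch extraction.

EEG streams are bandpassed 2.5-30 Hz (2nd-order Butterworth) with a 60 Hz
notch, smoothed with a Savitzky-Golay filter, epoched around event onsets,
detrended on the -300..-100 ms pre-onset baseline, and normalized per
subject to the maximum magnitude of that subject's first event epoch.
Offline analysis uses zero-phase (forward-backward) filtering; the streaming
detector uses the causal variant of the same filters.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from fractions import Fraction

import numpy as np
from scipy import signal

logger = logging.getLogger(__name__)


class ParameterError(ValueError):
    """Invalid filter/epoching parameters."""


class DegenerateInputError(ValueError):
    """Input carries no usable signal (constant, zero reference, ...)."""


@dataclass(frozen=True)
class PreprocessSpec:
    """Filter chain and baseline parameters.

    bandpass is (low Hz, high Hz, order) of the Butterworth design; the
    notch is a 2nd-order IIR notch at notch_hz with quality factor notch_q.
    sg_filter is the (window length, polynomial order) of the
    Savitzky-Golay smoother.  baseline_window is in ms relative to onset
    and must be strictly pre-onset.
    """

    bandpass: tuple[float, float, int] = (2.5, 30.0, 2)
    notch_hz: float = 60.0
    notch_q: float = 30.0
    sg_filter: tuple[int, int] = (51, 3)
    baseline_window: tuple[float, float] = (-300.0, -100.0)
    zero_phase: bool = True


@dataclass
class Epoch:
    """One channel's fixed-length window around an event onset.

    window is (start_ms, end_ms) relative to onset; length(samples) must
    equal round((end_ms - start_ms) * rate / 1000).
    """

    samples: np.ndarray
    rate: float
    channel_id: str = "eeg"
    subject_id: str = ""
    onset_index: int = 0
    label: str | None = None
    window: tuple[float, float] = (0.0, 1000.0)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        start, end = self.window
        if not start < end:
            raise ParameterError(f"epoch window must have start < end, got {self.window}")
        expect = int(round((end - start) * self.rate / 1000.0))
        if len(self.samples) != expect:
            raise ParameterError(
                f"epoch has {len(self.samples)} samples, window {self.window} at "
                f"{self.rate} Hz requires {expect}"
            )

    def time_ms(self) -> np.ndarray:
        """Sample times in ms relative to onset."""
        return self.window[0] + np.arange(len(self.samples)) * 1000.0 / self.rate

    def crop(self, start_ms: float, end_ms: float) -> "Epoch":
        """Sub-window of this epoch (ms relative to onset)."""
        if start_ms < self.window[0] or end_ms > self.window[1] + 1e-9:
            raise ParameterError(
                f"crop ({start_ms}, {end_ms}) outside epoch window {self.window}"
            )
        i0 = int(round((start_ms - self.window[0]) * self.rate / 1000.0))
        n = int(round((end_ms - start_ms) * self.rate / 1000.0))
        return replace(
            self,
            samples=self.samples[i0 : i0 + n].copy(),
            window=(start_ms, end_ms),
            meta=dict(self.meta),
        )


# ---------------------------------------------------------------------------
# Filters
# ---------------------------------------------------------------------------

def _design_filters(rate: float, spec: PreprocessSpec):
    low, high, order = spec.bandpass
    if not 0 < low < high:
        raise ParameterError(f"need 0 < low < high, got {spec.bandpass}")
    if rate <= 2 * high:
        raise ParameterError(
            f"sampling rate {rate} Hz too low for bandpass upper edge {high} Hz"
        )
    sos_bp = signal.butter(order, [low, high], btype="bandpass", fs=rate, output="sos")
    sos_notch = None
    if spec.notch_hz and spec.notch_hz < rate / 2:
        b, a = signal.iirnotch(spec.notch_hz, spec.notch_q, fs=rate)
        sos_notch = signal.tf2sos(b, a)
    return sos_bp, sos_notch


def bandpass_notch(
    samples: np.ndarray,
    rate: float,
    spec: PreprocessSpec = PreprocessSpec(),
    zero_phase: bool | None = None,
) -> np.ndarray:
    """Butterworth bandpass + IIR notch; length-preserving.

    zero_phase=True applies the filters forward-backward (offline mode);
    False applies them causally (streaming mode).  Defaults to the spec's
    zero_phase flag.
    """
    samples = np.asarray(samples, dtype=float)
    sos_bp, sos_notch = _design_filters(rate, spec)
    zp = spec.zero_phase if zero_phase is None else zero_phase
    apply = signal.sosfiltfilt if zp else signal.sosfilt
    out = apply(sos_bp, samples)
    if sos_notch is not None:
        out = apply(sos_notch, out)
    return np.asarray(out)


def savgol_smooth(samples: np.ndarray, spec: PreprocessSpec = PreprocessSpec()) -> np.ndarray:
    """Savitzky-Golay smoothing (window clipped to the signal length)."""
    window, poly = spec.sg_filter
    n = len(samples)
    if window > n:
        window = n if n % 2 == 1 else n - 1
    if window <= poly:
        return np.asarray(samples, dtype=float)
    return signal.savgol_filter(np.asarray(samples, dtype=float), window, poly)


# ---------------------------------------------------------------------------
# Baseline correction and normalization
# ---------------------------------------------------------------------------

def detrend_baseline(
    epoch: Epoch, baseline_window: tuple[float, float] = (-300.0, -100.0)
) -> Epoch:
    """Subtract the OLS line fitted on the pre-onset baseline window.

    The line (DC + linear trend) is estimated from samples in
    [baseline_window[0], baseline_window[1]) ms and subtracted from the
    whole epoch, so the baseline mean becomes 0.  The baseline standard
    deviation (after correction) is stored in epoch.meta["baseline_sd"].
    """
    b0, b1 = baseline_window
    if not b0 < b1 <= 0:
        raise ParameterError("baseline window must be strictly pre-onset with start < end")
    if b0 < epoch.window[0] - 1e-9:
        raise ParameterError(
            f"epoch window {epoch.window} does not contain baseline window {baseline_window}"
        )
    t = epoch.time_ms()
    mask = (t >= b0) & (t < b1)
    if mask.sum() < 2:
        raise ParameterError("baseline window contains fewer than 2 samples")
    coef = np.polynomial.polynomial.polyfit(t[mask], epoch.samples[mask], 1)
    corrected = epoch.samples - np.polynomial.polynomial.polyval(t, coef)
    meta = dict(epoch.meta)
    meta["baseline_sd"] = float(np.std(corrected[mask]))
    return replace(epoch, samples=corrected, meta=meta)


def normalize_subject(epochs: list[Epoch]) -> list[Epoch]:
    """Scale each subject's epochs by that subject's reference magnitude.

    The reference is the maximum absolute value of the subject's first
    epoch (in the order given), so the first epoch's max |value| becomes 1.
    """
    by_subject: dict[str, float] = {}
    out: list[Epoch] = []
    for ep in epochs:
        if ep.subject_id not in by_subject:
            ref = float(np.max(np.abs(ep.samples)))
            if ref == 0.0:
                raise DegenerateInputError(
                    f"subject {ep.subject_id!r}: first epoch is all-zero, "
                    "normalization reference undefined"
                )
            by_subject[ep.subject_id] = ref
        ref = by_subject[ep.subject_id]
        meta = dict(ep.meta)
        meta["normalization_reference"] = ref
        out.append(replace(ep, samples=ep.samples / ref, meta=meta))
    return out


# ---------------------------------------------------------------------------
# Epoching and resampling
# ---------------------------------------------------------------------------

def extract_epochs(
    recording: np.ndarray,
    rate: float,
    onsets: np.ndarray,
    window: tuple[float, float],
    subject_id: str = "",
    channel_id: str = "eeg",
    labels: list[str] | None = None,
) -> list[Epoch]:
    """Cut one epoch per onset; onsets too close to the edges are skipped
    with a logged warning."""
    recording = np.asarray(recording, dtype=float)
    start_ms, end_ms = window
    n = int(round((end_ms - start_ms) * rate / 1000.0))
    out: list[Epoch] = []
    for j, onset in enumerate(np.asarray(onsets, dtype=int)):
        i0 = onset + int(round(start_ms * rate / 1000.0))
        if i0 < 0 or i0 + n > len(recording):
            logger.warning(
                "skipping onset %d (%s): window %s falls outside the recording",
                onset, subject_id, window,
            )
            continue
        out.append(
            Epoch(
                samples=recording[i0 : i0 + n].copy(),
                rate=rate,
                channel_id=channel_id,
                subject_id=subject_id,
                onset_index=int(onset),
                label=None if labels is None else labels[j],
                window=(start_ms, end_ms),
            )
        )
    return out


def resample_accel(samples: np.ndarray, from_rate: float, to_rate: float) -> np.ndarray:
    """Band-limited (polyphase) resampling between the two stream rates."""
    if from_rate <= 0 or to_rate <= 0:
        raise ParameterError("sampling rates must be > 0")
    samples = np.asarray(samples, dtype=float)
    if from_rate == to_rate:
        return samples.copy()
    frac = Fraction(to_rate / from_rate).limit_denominator(1000)
    return signal.resample_poly(samples, frac.numerator, frac.denominator)


WINDOW_GRID: tuple[tuple[float, float], ...] = tuple(
    (start, end) for start in (0.0, 80.0) for end in (350.0, 500.0, 750.0, 1000.0)
)
"""The epoch-window grid: {0, 80} ms starts x {350, 500, 750, 1000} ms ends."""


def preprocess_cohort(
    cohort,
    window: tuple[float, float],
    spec: PreprocessSpec = PreprocessSpec(),
) -> list[Epoch]:
    """Full offline chain for one analysis window over a synthetic cohort.

    Per subject: zero-phase filter + smooth the EEG stream, extract padded
    epochs covering the baseline, detrend on the pre-onset baseline, crop
    to the analysis window, then normalize by the subject's first epoch.
    """
    start_ms, end_ms = window
    pad_start = min(start_ms, spec.baseline_window[0])
    epochs: list[Epoch] = []
    for sid, rec in cohort.recordings.items():
        filtered = bandpass_notch(rec.eeg, rec.eeg_rate, spec, zero_phase=True)
        filtered = savgol_smooth(filtered, spec)
        sub = cohort.events[cohort.events["subject"] == sid]
        padded = extract_epochs(
            filtered,
            rec.eeg_rate,
            sub["onset_sample"].to_numpy(),
            (pad_start, end_ms),
            subject_id=sid,
            labels=sub["label"].tolist(),
        )
        cropped = [
            detrend_baseline(ep, spec.baseline_window).crop(start_ms, end_ms)
            for ep in padded
        ]
        epochs.extend(normalize_subject(cropped))
    return epochs
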