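"""Synthetic perturbation-cohort generator.

Emulates the statistical structure of a platform-translation balance study:
per-subject continuous mastoid-EEG (1000 Hz) and platform-acceleration
(150 Hz) streams with scheduled perturbation onsets, perturbation-evoked
potentials (PEPs) whose morphology depends on whether the perturbation was
Predicted or Unpredicted, and 1/f-plus-alpha background EEG.  Real cohorts
of this kind are rarely shareable, so every downstream stage is exercised
on cohorts drawn from this generator.

The evoked component is gated to zero before 80 ms post-onset: single-trial
EEG is indistinguishable between classes until the long-latency cortical
response begins, which is the property the epoch-window grid probes.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

PREDICTED = "Predicted"
UNPREDICTED = "Unpredicted"

G_CM_S2 = 981.0  # 1 g in cm/s^2


class CohortConfigError(ValueError):
    """Raised when a cohort configuration violates an invariant."""


class CohortIOError(IOError):
    """Raised when a cohort directory is missing or corrupt."""


@dataclass(frozen=True)
class NoiseProfile:
    """Background-EEG spectrum: 1/f^alpha colored noise plus a 10 Hz line.

    amplitude_uv is the RMS of the colored-noise component in microvolts;
    alpha_power is the RMS of the 10 Hz oscillation relative to amplitude_uv.
    """

    one_over_f_exponent: float = 1.0
    alpha_hz: float = 10.0
    alpha_power: float = 0.3
    amplitude_uv: float = 10.0


@dataclass(frozen=True)
class PlatformProfile:
    """Platform translation kinematics (trapezoidal velocity profile)."""

    displacement_cm: float = 20.0
    peak_velocity_cm_s: float = 100.0
    peak_accel_g: float = 0.2
    noise_g: float = 0.005


@dataclass(frozen=True)
class CohortConfig:
    n_subjects: int = 40
    events_per_subject: int = 34
    n_dropped_total: int = 40
    unpredicted_fraction: float = 435.0 / 1320.0
    eeg_rate: float = 1000.0
    accel_rate: float = 150.0
    effect_size: float = 1.0
    pep_amplitude_uv: float = 20.0
    artifact_amplitude_uv: float = 30.0
    latency_jitter_ms: float = 10.0
    inter_event_interval_s: tuple[float, float] = (4.0, 6.0)
    noise_profile: NoiseProfile = field(default_factory=NoiseProfile)
    platform_profile: PlatformProfile = field(default_factory=PlatformProfile)
    seed: int = 0

    def validate(self) -> None:
        if self.n_subjects < 1 or self.events_per_subject < 1:
            raise CohortConfigError("n_subjects and events_per_subject must be >= 1")
        if not (0 <= self.n_dropped_total < self.n_subjects * self.events_per_subject):
            raise CohortConfigError(
                "invariant violated: n_dropped_total < n_subjects * events_per_subject"
            )
        if not (0.0 <= self.unpredicted_fraction <= 1.0):
            raise CohortConfigError("invariant violated: unpredicted_fraction in [0, 1]")
        if self.eeg_rate <= 0 or self.accel_rate <= 0:
            raise CohortConfigError("invariant violated: sampling rates must be > 0")
        if self.effect_size < 0:
            raise CohortConfigError("invariant violated: effect_size >= 0")
        lo, hi = self.inter_event_interval_s
        if not (0 < lo <= hi):
            raise CohortConfigError("inter_event_interval_s must satisfy 0 < lo <= hi")

    @property
    def n_completed(self) -> int:
        return self.n_subjects * self.events_per_subject - self.n_dropped_total


@dataclass
class Recording:
    """One subject's synchronized continuous streams."""

    subject_id: str
    eeg: np.ndarray          # microvolts, at eeg_rate
    accel: np.ndarray        # g, at accel_rate
    eeg_rate: float
    accel_rate: float
    onsets: np.ndarray       # event-onset sample indices into `eeg`


@dataclass
class SyntheticCohort:
    config: CohortConfig
    recordings: dict[str, Recording]
    events: pd.DataFrame     # columns: subject, onset_sample, label
    truth_log: list[dict]

    @property
    def n_events(self) -> int:
        return len(self.events)


# ---------------------------------------------------------------------------
# Waveform primitives
# ---------------------------------------------------------------------------

def _gate(t_ms: np.ndarray, start_ms: float = 80.0, ramp_ms: float = 15.0) -> np.ndarray:
    """Smoothstep gate: exactly 0 before start_ms, 1 after start_ms + ramp_ms."""
    u = np.clip((t_ms - start_ms) / ramp_ms, 0.0, 1.0)
    return u * u * (3.0 - 2.0 * u)


def pep_template(
    t_ms: np.ndarray,
    class_label: str,
    effect_size: float,
    amplitude_uv: float = 20.0,
    latency_shift_ms: float = 0.0,
) -> np.ndarray:
    """Perturbation-evoked potential template on a post-onset time axis (ms).

    Two Gaussian-windowed deflections — a negativity (N1) near 130 ms and a
    broader positivity (P2) near 240 ms — gated to zero before 80 ms
    post-onset.  The Unpredicted class scales peak amplitude by
    (1 + effect_size), delays both peaks by effect_size * 20 ms, widens the
    N1 by a factor (1 + effect_size / 4), and adds a phase-locked evoked
    low-beta burst (18 Hz, Gaussian envelope around 200 ms) whose amplitude
    grows with effect_size — so the class difference is morphological and
    dynamical (waveform shape and spectral content), not just a gain
    change.  The burst band is chosen away from the deflections' own 3-8 Hz
    energy and the 10 Hz background rhythm so that the predictability
    signature is an oscillatory mode, as balance-cortex beta responses are.
    The latency delay saturates at 30 ms — empirical PEP latency
    differences are tens of ms regardless of how strong the amplitude
    effect is.  effect_size = 0 makes the classes generatively identical.
    """
    if class_label not in (PREDICTED, UNPREDICTED):
        raise ValueError(f"unknown class label: {class_label!r}")
    amp = amplitude_uv
    shift = latency_shift_ms
    n1_width = 20.0
    burst = np.zeros_like(t_ms)
    if class_label == UNPREDICTED:
        amp = amp * (1.0 + effect_size)
        shift = shift + 20.0 * min(effect_size, 1.5)
        n1_width = n1_width * (1.0 + effect_size / 4.0)
        burst_amp = amplitude_uv * 1.2 * effect_size
        envelope = np.exp(-0.5 * ((t_ms - (200.0 + shift)) / 150.0) ** 2)
        burst = burst_amp * envelope * np.sin(2 * np.pi * 18.0 * (t_ms - shift) / 1000.0)
    neg = -amp * np.exp(-0.5 * ((t_ms - (130.0 + shift)) / n1_width) ** 2)
    pos = 0.8 * amp * np.exp(-0.5 * ((t_ms - (240.0 + shift)) / 35.0) ** 2)
    return _gate(t_ms) * (neg + pos + burst)


def onset_artifact(
    t_ms: np.ndarray, amplitude_uv: float, rng: np.random.Generator
) -> np.ndarray:
    """Class-independent early artifact: a damped ~8 Hz oscillation in the
    first tens of ms after onset (platform jerk / short-latency EMG).

    Its amplitude varies event to event, adding variance to the 0-80 ms
    segment that carries no class information — the reason analyses cut
    epochs at 80 ms.
    """
    if amplitude_uv <= 0:
        return np.zeros_like(t_ms)
    amp = amplitude_uv * abs(rng.normal(1.0, 0.3))
    phase = rng.uniform(0, 2 * np.pi)
    x = amp * np.exp(-t_ms / 25.0) * np.sin(2 * np.pi * 8.0 * t_ms / 1000.0 + phase)
    return np.where(t_ms >= 0, x, 0.0)


def colored_noise(
    n: int, rate: float, profile: NoiseProfile, rng: np.random.Generator
) -> np.ndarray:
    """1/f^alpha Gaussian noise (RMS = amplitude_uv) plus a 10 Hz sinusoid."""
    if n == 0:
        return np.zeros(0)
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, d=1.0 / rate)
    scale = np.ones_like(f)
    nz = f > 0
    scale[nz] = f[nz] ** (-profile.one_over_f_exponent / 2.0)
    scale[0] = 0.0
    x = np.fft.irfft(spec * scale, n=n)
    rms = np.sqrt(np.mean(x**2))
    if rms > 0:
        x = x * (profile.amplitude_uv / rms)
    phase = rng.uniform(0, 2 * np.pi)
    t = np.arange(n) / rate
    alpha_rms = profile.alpha_power * profile.amplitude_uv
    x = x + np.sqrt(2.0) * alpha_rms * np.sin(2 * np.pi * profile.alpha_hz * t + phase)
    return x


def generate_event_waveform(
    class_label: str,
    effect_size: float,
    noise_profile: NoiseProfile,
    rng: np.random.Generator,
    length_ms: float = 1000.0,
    rate: float = 1000.0,
    amplitude_uv: float = 20.0,
    latency_jitter_ms: float = 0.0,
) -> np.ndarray:
    """One post-onset EEG epoch: gated PEP plus background noise."""
    n = int(round(length_ms * rate / 1000.0))
    t_ms = np.arange(n) * 1000.0 / rate
    jitter = rng.uniform(-latency_jitter_ms, latency_jitter_ms) if latency_jitter_ms else 0.0
    pep = pep_template(t_ms, class_label, effect_size, amplitude_uv, jitter)
    return pep + colored_noise(n, rate, noise_profile, rng)


def accel_pulse(profile: PlatformProfile, rate: float) -> np.ndarray:
    """Platform acceleration trace (g) for one translation.

    Trapezoidal velocity profile: ramp at peak_accel_g up to the peak
    velocity, optional cruise, ramp down, with total area equal to the
    stroke displacement.  If the commanded peak velocity is not reachable
    within the stroke at the given ramp acceleration, the profile degrades
    to the triangular one that is (velocity capped at sqrt(a * d)).
    """
    a = profile.peak_accel_g * G_CM_S2            # cm/s^2
    d = profile.displacement_cm
    v = min(profile.peak_velocity_cm_s, np.sqrt(a * d))
    t_ramp = v / a
    t_cruise = max(0.0, (d - v * t_ramp) / v)     # area: v*t_ramp (two half ramps) + v*t_cruise
    total = 2 * t_ramp + t_cruise
    n = int(np.ceil(total * rate)) + 1
    t = np.arange(n) / rate
    acc = np.zeros(n)
    acc[t < t_ramp] = profile.peak_accel_g
    acc[(t >= t_ramp + t_cruise) & (t < total)] = -profile.peak_accel_g
    return acc


# ---------------------------------------------------------------------------
# Cohort generation
# ---------------------------------------------------------------------------

def _subject_id(i: int) -> str:
    return f"sub-{i + 1:02d}"


def generate_cohort(config: CohortConfig) -> SyntheticCohort:
    """Draw a full cohort. Deterministic given config.seed."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n_total = config.n_subjects * config.events_per_subject

    dropped = set(rng.choice(n_total, size=config.n_dropped_total, replace=False).tolist())
    completed_idx = [i for i in range(n_total) if i not in dropped]
    n_unpred = int(round(config.unpredicted_fraction * len(completed_idx)))
    unpred_slots = set(
        rng.choice(len(completed_idx), size=n_unpred, replace=False).tolist()
    )
    labels_by_slot = {
        gi: (UNPREDICTED if si in unpred_slots else PREDICTED)
        for si, gi in enumerate(completed_idx)
    }

    pulse = accel_pulse(config.platform_profile, config.accel_rate)
    lo, hi = config.inter_event_interval_s
    pre_s, post_s = 2.0, 2.0

    recordings: dict[str, Recording] = {}
    rows: list[dict] = []
    truth: list[dict] = []
    for s in range(config.n_subjects):
        sid = _subject_id(s)
        gaps = rng.uniform(lo, hi, size=config.events_per_subject)
        onset_times = pre_s + np.cumsum(gaps) - gaps[0]
        dur_s = onset_times[-1] + post_s
        n_eeg = int(round(dur_s * config.eeg_rate))
        n_acc = int(round(dur_s * config.accel_rate))
        eeg = colored_noise(n_eeg, config.eeg_rate, config.noise_profile, rng)
        acc = rng.standard_normal(n_acc) * config.platform_profile.noise_g

        onsets = []
        for k in range(config.events_per_subject):
            gi = s * config.events_per_subject + k
            onset = int(round(onset_times[k] * config.eeg_rate))
            completed = gi not in dropped
            # draw per-event randomness unconditionally so stream noise stays
            # aligned across configs differing only in dropout placement
            jitter = (
                rng.uniform(-config.latency_jitter_ms, config.latency_jitter_ms)
                if config.latency_jitter_ms
                else 0.0
            )
            if not completed:
                truth.append(
                    {"subject": sid, "onset_sample": onset, "dropped": True}
                )
                continue
            label = labels_by_slot[gi]
            n_pep = int(round(1.0 * config.eeg_rate))  # 1 s of evoked response
            t_ms = np.arange(n_pep) * 1000.0 / config.eeg_rate
            pep = pep_template(
                t_ms, label, config.effect_size, config.pep_amplitude_uv, jitter
            )
            pep = pep + onset_artifact(t_ms, config.artifact_amplitude_uv, rng)
            stop = min(onset + n_pep, n_eeg)
            eeg[onset:stop] += pep[: stop - onset]
            a_on = int(round(onset_times[k] * config.accel_rate))
            a_stop = min(a_on + len(pulse), n_acc)
            acc[a_on:a_stop] += pulse[: a_stop - a_on]
            onsets.append(onset)
            rows.append({"subject": sid, "onset_sample": onset, "label": label})
            truth.append(
                {
                    "subject": sid,
                    "onset_sample": onset,
                    "dropped": False,
                    "label": label,
                    "latency_jitter_ms": float(jitter),
                    "amplitude_uv": float(
                        config.pep_amplitude_uv
                        * (1.0 + config.effect_size if label == UNPREDICTED else 1.0)
                    ),
                }
            )
        recordings[sid] = Recording(
            subject_id=sid,
            eeg=eeg,
            accel=acc,
            eeg_rate=config.eeg_rate,
            accel_rate=config.accel_rate,
            onsets=np.asarray(onsets, dtype=int),
        )

    events = pd.DataFrame(rows, columns=["subject", "onset_sample", "label"])
    cohort = SyntheticCohort(
        config=config, recordings=recordings, events=events, truth_log=truth
    )
    assert cohort.n_events == config.n_completed
    return cohort


# ---------------------------------------------------------------------------
# Persistence (plain-text cohort directory)
# ---------------------------------------------------------------------------

def write_cohort(cohort: SyntheticCohort, directory: str | Path) -> None:
    """Write the cohort directory: per-subject CSV streams, events.csv,
    truth.json, config.yaml."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for sid, rec in cohort.recordings.items():
        for channel, data in (("eeg", rec.eeg), ("accel", rec.accel)):
            df = pd.DataFrame(
                {"sample_index": np.arange(len(data)), "value": data}
            )
            df.to_csv(directory / f"{sid}_{channel}.csv", index=False, float_format="%.6g")
    cohort.events.to_csv(directory / "events.csv", index=False)
    with open(directory / "truth.json", "w") as fh:
        json.dump(cohort.truth_log, fh, indent=1)
    with open(directory / "config.yaml", "w") as fh:
        yaml.safe_dump(_config_to_dict(cohort.config), fh)


def read_cohort(directory: str | Path) -> SyntheticCohort:
    """Read a cohort directory written by :func:`write_cohort`."""
    directory = Path(directory)
    for required in ("config.yaml", "events.csv", "truth.json"):
        if not (directory / required).exists():
            raise CohortIOError(f"cohort directory {directory} is missing {required}")
    with open(directory / "config.yaml") as fh:
        config = _config_from_dict(yaml.safe_load(fh))
    events = pd.read_csv(directory / "events.csv")
    with open(directory / "truth.json") as fh:
        truth = json.load(fh)
    recordings: dict[str, Recording] = {}
    for s in range(config.n_subjects):
        sid = _subject_id(s)
        streams = {}
        for channel in ("eeg", "accel"):
            path = directory / f"{sid}_{channel}.csv"
            if not path.exists():
                raise CohortIOError(f"cohort directory {directory} is missing {path.name}")
            streams[channel] = pd.read_csv(path)["value"].to_numpy()
        sub_events = events[events["subject"] == sid]
        recordings[sid] = Recording(
            subject_id=sid,
            eeg=streams["eeg"],
            accel=streams["accel"],
            eeg_rate=config.eeg_rate,
            accel_rate=config.accel_rate,
            onsets=sub_events["onset_sample"].to_numpy(dtype=int),
        )
    return SyntheticCohort(
        config=config, recordings=recordings, events=events, truth_log=truth
    )


def _config_to_dict(config: CohortConfig) -> dict:
    d = dataclasses.asdict(config)
    d["inter_event_interval_s"] = list(config.inter_event_interval_s)
    return d


def _config_from_dict(d: dict) -> CohortConfig:
    d = dict(d)
    d["noise_profile"] = NoiseProfile(**d["noise_profile"])
    d["platform_profile"] = PlatformProfile(**d["platform_profile"])
    d["inter_event_interval_s"] = tuple(d["inter_event_interval_s"])
    return CohortConfig(**d)
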