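"""Filtering, baseline correction, normalization, epoching, resampling."""

import numpy as np
import pytest
from scipy import signal

from pepdetect import (
    DegenerateInputError,
    Epoch,
    ParameterError,
    PreprocessSpec,
    bandpass_notch,
    detrend_baseline,
    extract_epochs,
    normalize_subject,
    resample_accel,
)
from pepdetect.preprocess import WINDOW_GRID


def steady_state_gain(freq, rate=1000.0, dur=4.0):
    t = np.arange(int(dur * rate)) / rate
    x = np.sin(2 * np.pi * freq * t)
    y = bandpass_notch(x, rate)
    mid = y[len(y) // 4 : -len(y) // 4]
    return np.max(np.abs(mid))


class TestFilters:
    def test_zero_in_zero_out(self):
        assert np.allclose(bandpass_notch(np.zeros(1000), 1000.0), 0.0)

    def test_length_preserved(self, rng):
        x = rng.standard_normal(777)
        assert len(bandpass_notch(x, 1000.0)) == 777

    def test_notch_attenuates_60hz_at_least_20db(self):
        # steady-state amplitude of a 60 Hz unit sinusoid
        assert steady_state_gain(60.0) < 10 ** (-20 / 20)

    def test_passband_10hz_within_1db(self):
        g = steady_state_gain(10.0)
        assert 10 ** (-1 / 20) < g < 10 ** (1 / 20)

    def test_frequency_response_oracle(self):
        # designed-filter frequency response agrees with the measured gains
        # (compared away from the notch null, where leakage dominates)
        sos = signal.butter(2, [2.5, 30.0], btype="bandpass", fs=1000.0, output="sos")
        b, a = signal.iirnotch(60.0, 30.0, fs=1000.0)
        for freq in (5.0, 10.0, 25.0, 45.0):
            _, h_bp = signal.sosfreqz(sos, worN=[freq], fs=1000.0)
            _, h_n = signal.freqz(b, a, worN=[freq], fs=1000.0)
            # zero-phase application squares the magnitude response
            expected = (np.abs(h_bp[0]) * np.abs(h_n[0])) ** 2
            assert steady_state_gain(freq) == pytest.approx(expected, rel=0.05)

    def test_rate_too_low_for_band(self):
        with pytest.raises(ParameterError, match="rate"):
            bandpass_notch(np.ones(100), 50.0)


class TestDetrendBaseline:
    def _epoch(self, samples):
        return Epoch(samples=samples, rate=1000.0, window=(-300.0, 700.0))

    def test_constant_removed(self):
        out = detrend_baseline(self._epoch(np.full(1000, 7.0)))
        assert np.allclose(out.samples, 0.0, atol=1e-9)

    def test_exact_line_removed(self):
        t = np.arange(1000)
        out = detrend_baseline(self._epoch(3.0 + 0.01 * t))
        assert np.allclose(out.samples, 0.0, atol=1e-9)

    def test_line_plus_sinusoid_recovers_sinusoid(self):
        t_ms = np.arange(1000) - 300.0
        sine = np.sin(2 * np.pi * 40.0 * t_ms / 1000.0)  # zero-mean on baseline
        out = detrend_baseline(self._epoch(5.0 - 0.02 * t_ms + sine))
        # OLS oracle on the baseline window
        mask = (t_ms >= -300) & (t_ms < -100)
        coef = np.polynomial.polynomial.polyfit(t_ms[mask], (5.0 - 0.02 * t_ms + sine)[mask], 1)
        oracle = (5.0 - 0.02 * t_ms + sine) - np.polynomial.polynomial.polyval(t_ms, coef)
        assert np.allclose(out.samples, oracle, atol=1e-9)
        assert abs(np.mean(out.samples[mask])) < 1e-6

    def test_idempotent(self, rng):
        ep = self._epoch(rng.standard_normal(1000))
        once = detrend_baseline(ep)
        twice = detrend_baseline(once)
        assert np.allclose(once.samples, twice.samples, atol=1e-9)

    def test_baseline_sd_recorded(self, rng):
        out = detrend_baseline(self._epoch(rng.standard_normal(1000)))
        assert out.meta["baseline_sd"] > 0

    def test_epoch_missing_baseline_rejected(self):
        ep = Epoch(samples=np.zeros(500), rate=1000.0, window=(0.0, 500.0))
        with pytest.raises(ParameterError, match="baseline"):
            detrend_baseline(ep)


class TestNormalizeSubject:
    def _epoch(self, samples, subject):
        return Epoch(
            samples=samples, rate=1000.0, subject_id=subject, window=(0.0, len(samples))
        )

    def test_first_epoch_max_becomes_one(self):
        eps = normalize_subject([self._epoch(np.array([1.0, -5.0, 2.0]), "s1")])
        assert np.max(np.abs(eps[0].samples)) == pytest.approx(1.0)
        assert np.allclose(eps[0].samples, [0.2, -1.0, 0.4])

    def test_subjects_scaled_independently(self):
        eps = normalize_subject(
            [
                self._epoch(np.array([2.0, 1.0]), "s1"),
                self._epoch(np.array([8.0, 4.0]), "s2"),
            ]
        )
        # raw cross-subject ratio (4x) is not preserved after scaling
        assert np.allclose(eps[0].samples, eps[1].samples)

    def test_gain_invariance(self, rng):
        raw = [rng.standard_normal(50) for _ in range(3)]
        a = normalize_subject([self._epoch(x, "s") for x in raw])
        b = normalize_subject([self._epoch(2.5 * x, "s") for x in raw])
        for ea, eb in zip(a, b):
            assert np.allclose(ea.samples, eb.samples, atol=1e-12)

    def test_zero_reference_rejected(self):
        with pytest.raises(DegenerateInputError, match="reference"):
            normalize_subject([self._epoch(np.zeros(10), "s")])


class TestExtractEpochs:
    def test_sample_counts_across_grid(self, rng):
        recording = rng.standard_normal(5000)
        for start, end in WINDOW_GRID:
            eps = extract_epochs(recording, 1000.0, [2000], (start, end))
            assert len(eps) == 1
            assert len(eps[0].samples) == round((end - start))

    def test_920_samples_for_80_to_1000(self, rng):
        eps = extract_epochs(rng.standard_normal(3000), 1000.0, [1000], (80.0, 1000.0))
        assert len(eps[0].samples) == 920

    def test_150hz_sample_counts(self, rng):
        eps = extract_epochs(rng.standard_normal(600), 150.0, [200], (0.0, 1000.0))
        assert len(eps[0].samples) == 150

    def test_edge_onset_skipped_with_warning(self, rng, caplog):
        import logging

        with caplog.at_level(logging.WARNING, logger="pepdetect.preprocess"):
            eps = extract_epochs(
                rng.standard_normal(500), 1000.0, [0], (-300.0, 350.0)
            )
        assert eps == []
        assert any("skipping onset" in r.message for r in caplog.records)


class TestResample:
    def test_constant_preserved(self):
        out = resample_accel(np.full(300, 4.2), 150.0, 1000.0)
        assert len(out) == 2000
        mid = out[200:-200]
        assert np.allclose(mid, 4.2, rtol=1e-3)

    def test_sinusoid_amplitude_within_1pct(self):
        t = np.arange(600) / 150.0
        x = np.sin(2 * np.pi * 5.0 * t)
        y = resample_accel(x, 150.0, 1000.0)
        mid = y[len(y) // 4 : -len(y) // 4]
        assert np.max(np.abs(mid)) == pytest.approx(1.0, rel=0.01)

    def test_round_trip_rms_within_1pct(self, rng):
        x = signal.sosfiltfilt(
            signal.butter(4, 30.0, fs=150.0, output="sos"), rng.standard_normal(1500)
        )
        back = resample_accel(resample_accel(x, 150.0, 1000.0), 1000.0, 150.0)
        n = min(len(x), len(back))
        err = np.sqrt(np.mean((x[100 : n - 100] - back[100 : n - 100]) ** 2))
        assert err < 0.01 * np.sqrt(np.mean(x**2))

    def test_invalid_rates(self):
        with pytest.raises(ParameterError):
            resample_accel(np.ones(10), -1.0, 100.0)
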