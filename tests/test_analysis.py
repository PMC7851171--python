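"""Wavelet denoising, spectral amplitude/phase, beat-spectrum estimation."""

import numpy as np
import pytest

from ionobeat.acoustics import PressureTrace
from ionobeat.analysis import (
    amplitude_at_frequency,
    beat_distance,
    phase_shift,
    wavelet_denoise,
)


class TestWaveletDenoise:
    def test_zero_in_zero_out(self, fs):
        tr = wavelet_denoise(PressureTrace(np.zeros(30000), fs))
        assert np.all(tr.p == 0)

    def test_band_limited_signal_energy_preserved(self, fs):
        t = np.arange(40000) / fs
        sig = np.sin(2 * np.pi * 2e6 * t) * np.exp(-0.5 * ((t - 128e-6) / 20e-6) ** 2)
        out = wavelet_denoise(PressureTrace(sig, fs))
        ratio = np.linalg.norm(out.p) / np.linalg.norm(sig)
        assert ratio == pytest.approx(1.0, abs=0.05)

    def test_12mhz_component_suppressed_20db(self, fs):
        t = np.arange(40000) / fs
        sig = np.sin(2 * np.pi * 12e6 * t)
        out = wavelet_denoise(PressureTrace(sig, fs))
        att = 20 * np.log10(np.linalg.norm(sig) / max(np.linalg.norm(out.p), 1e-300))
        assert att >= 20.0

    def test_idempotent_within_one_percent(self, fs):
        rng = np.random.default_rng(4)
        t = np.arange(40000) / fs
        sig = np.sin(2 * np.pi * 1.5e6 * t) + 0.3 * rng.normal(size=t.size)
        once = wavelet_denoise(PressureTrace(sig, fs))
        twice = wavelet_denoise(once)
        rel = np.linalg.norm(twice.p - once.p) / np.linalg.norm(once.p)
        assert rel < 0.01

    def test_too_short_trace_rejected(self, fs):
        with pytest.raises(ValueError):
            wavelet_denoise(PressureTrace(np.zeros(16), fs))


class TestAmplitudeAtFrequency:
    def test_unit_sinusoid_reads_one(self, sinusoid_trace):
        tr = sinusoid_trace(2.5e6)
        res = amplitude_at_frequency(tr, 2.5e6, window=(21e-6, 22.5e-6))
        assert res.amplitude == pytest.approx(1.0, rel=0.02)

    def test_frequency_resolution_is_5khz(self, sinusoid_trace):
        res = amplitude_at_frequency(sinusoid_trace(2.5e6), 2.5e6, window=(21e-6, 22.5e-6))
        assert res.df_hz == pytest.approx(5e3)

    def test_window_excludes_second_pulse(self, fs):
        """Second burst outside the analysis window does not contribute."""
        t = np.arange(int(40e-6 * fs)) / fs
        f0 = 2.0e6
        tone = np.sin(2 * np.pi * f0 * t)
        first = tone * ((t >= 21e-6) & (t < 22.5e-6))
        both = first + 3.0 * tone * ((t >= 30e-6) & (t < 33e-6))
        a1 = amplitude_at_frequency(PressureTrace(first, fs), f0, window=(21e-6, 22.5e-6))
        a2 = amplitude_at_frequency(PressureTrace(both, fs), f0, window=(21e-6, 22.5e-6))
        assert a2.amplitude == pytest.approx(a1.amplitude, rel=1e-6)

    def test_amplitude_insensitive_to_dc_offset_after_detector(self, sinusoid_trace):
        """With DC removed upstream by the detector band-pass, a constant
        offset does not move the extracted amplitude."""
        from ionobeat.acoustics import detector_response
        tr = sinusoid_trace(2.5e6)
        shifted = PressureTrace(tr.p + 5.0, tr.fs)
        a0 = amplitude_at_frequency(detector_response(tr), 2.5e6, window=(21e-6, 22.5e-6)).amplitude
        a1 = amplitude_at_frequency(detector_response(shifted), 2.5e6, window=(21e-6, 22.5e-6)).amplitude
        assert a1 == pytest.approx(a0, rel=0.01)

    def test_f0_above_nyquist_rejected(self, sinusoid_trace):
        with pytest.raises(ValueError):
            amplitude_at_frequency(sinusoid_trace(1e6), 90e6)

    def test_window_outside_trace_rejected(self, sinusoid_trace):
        with pytest.raises(ValueError):
            amplitude_at_frequency(sinusoid_trace(1e6, duration=10e-6), 1e6,
                                   window=(21e-6, 22.5e-6))


class TestPhaseShift:
    def test_identical_traces_zero_phase(self, sinusoid_trace):
        tr = sinusoid_trace(2.5e6)
        assert phase_shift(tr, tr, 2.5e6) == pytest.approx(0.0, abs=1e-6)

    def test_quarter_period_delay_minus_90(self, fs):
        f0 = 2.5e6
        t = np.arange(int(30e-6 * fs)) / fs
        ref = PressureTrace(np.sin(2 * np.pi * f0 * t), fs)
        delayed = PressureTrace(np.sin(2 * np.pi * f0 * (t - 1 / (4 * f0))), fs)
        assert phase_shift(ref, delayed, f0) == pytest.approx(-90.0, abs=1.0)

    def test_sign_flip_is_180(self, sinusoid_trace):
        tr = sinusoid_trace(2.5e6)
        flipped = PressureTrace(-tr.p, tr.fs)
        assert abs(phase_shift(tr, flipped, 2.5e6)) == pytest.approx(180.0, abs=1.0)

    def test_antisymmetry(self, fs):
        f0 = 2.0e6
        t = np.arange(int(30e-6 * fs)) / fs
        a = PressureTrace(np.sin(2 * np.pi * f0 * t), fs)
        b = PressureTrace(np.sin(2 * np.pi * f0 * t - 0.7), fs)
        assert phase_shift(a, b, f0) == pytest.approx(-phase_shift(b, a, f0), abs=1e-6)

    def test_vanishing_reference_rejected(self, fs):
        ref = PressureTrace(np.zeros(int(30e-6 * fs)), fs)
        tst = PressureTrace(np.ones(int(30e-6 * fs)), fs)
        with pytest.raises(ValueError):
            phase_shift(ref, tst, 2.5e6)


class TestBeatDistance:
    @pytest.mark.parametrize("dt_sep_us,c", [
        (2.0, 1400.0), (5.0, 1500.0), (9.557, 1556.9), (14.0, 1450.0), (20.0, 1600.0),
    ])
    def test_two_impulse_oracle_grid(self, two_impulse_trace, dt_sep_us, c):
        """Exact (±1 quefrency bin) on noiseless two-impulse fixtures."""
        tr, dt_actual = two_impulse_trace(dt_sep_us * 1e-6)
        res = beat_distance(tr, c=c, tof_cutoff=60e-6)
        assert res.detected
        bin_m = c * (res.quefrency_s[1] - res.quefrency_s[0])
        assert abs(res.peak_distance_m - c * dt_actual) <= bin_m + 1e-12

    def test_single_pulse_reports_no_beat(self, fs):
        p = np.zeros(int(400e-6 * fs))
        p[1000] = 1.0
        res = beat_distance(PressureTrace(p, fs), c=1500.0, tof_cutoff=60e-6)
        assert not res.detected
        assert res.peak_distance_m is None

    def test_truth_errors_computed(self, two_impulse_trace):
        tr, dt_actual = two_impulse_trace(9.557e-6)
        c = 1556.9
        res = beat_distance(tr, c=c, tof_cutoff=60e-6,
                            truth={"distance": c * dt_actual, "range": 0.114})
        assert res.relative_error_distance_pct < 0.2
        assert res.relative_error_range_pct < 0.02

    def test_band_restriction_still_finds_beat(self, two_impulse_trace):
        tr, dt_actual = two_impulse_trace(9.557e-6)
        c = 1556.9
        res = beat_distance(tr, c=c, tof_cutoff=60e-6, band_hz=(60e3, 500e3),
                            max_distance=25e-3)
        assert res.detected
        assert res.peak_distance_m == pytest.approx(c * dt_actual, rel=0.03)

    def test_cutoff_beyond_resolution_rejected(self, fs):
        short = PressureTrace(np.zeros(1000), fs)
        with pytest.raises(ValueError):
            beat_distance(short, c=1500.0, tof_cutoff=120e-6)
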