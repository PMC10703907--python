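import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import gutflow as gf
from gutflow.errors import ParameterError

from conftest import make_channel, sine_channel
from oracles import brute_force_strength, brute_force_waves, dft_peak


class TestDetectWaves:
    def test_pure_sine_count_and_amplitude(self):
        # 0.7 Hz for 60 s -> 42 full waves, crest-to-trough 2A = 1.0
        ch = sine_channel(freq=0.7, amp=0.5, duration=60.0)
        waves = gf.detect_waves(ch, min_amplitude=0.02)
        assert len(waves) == 42
        assert all(w.amplitude == pytest.approx(1.0, abs=0.01) for w in waves)
        wl = [w.wavelength for w in waves if w.wavelength is not None]
        assert np.mean(wl) == pytest.approx(1 / 0.7, abs=0.01)

    def test_constant_trace_has_no_waves(self):
        ch = make_channel("pressure", np.full(5000, 1.5), dt=0.002)
        assert gf.detect_waves(ch) == []

    def test_empty_window_is_an_error(self):
        ch = sine_channel()
        with pytest.raises(ParameterError):
            gf.detect_waves(ch, window=(10.0, 10.0))

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        t = np.arange(0, 60, 0.05)
        y = 5 + 0.5 * np.sin(2 * np.pi * 0.7 * t) + rng.normal(0, 0.05, t.size)
        ch = make_channel("longitudinal", y)
        waves = gf.detect_waves(ch, min_amplitude=0.3, smooth_window=0)
        oracle = brute_force_waves(t, y, 0.3)
        assert len(waves) == len(oracle)
        for w, (ct, cv, tt, tv) in zip(waves, oracle):
            assert w.crest_time == pytest.approx(ct, abs=1e-12)
            assert w.crest_value == pytest.approx(cv, abs=1e-12)
            assert w.trough_value == pytest.approx(tv, abs=1e-12)

    def test_amplitude_classification_bounds(self):
        classes = gf.AmplitudeClass()
        assert classes.label(0.03) == "low"
        assert classes.label(0.19) == "low"
        assert classes.label(0.2) == "high"
        assert classes.label(0.02) == "sub"


class TestStrength:
    def test_mean_of_two_known_amplitudes(self):
        # two waves with crest-to-trough swings 0.4 and 0.6 -> S = 0.5
        y = [1.5, 1.9, 1.5, 2.1, 1.5, 1.7]
        ch = make_channel("pressure", y, dt=0.5)
        sm = gf.strength(ch, min_amplitude=0.03, smooth_window=0)
        assert sm.n_waves == 2
        assert sm.S == pytest.approx(0.5 * (0.4 + 0.6), abs=1e-12)

    def test_counting_frequency_of_sine(self):
        sm = gf.strength(sine_channel(freq=0.7, duration=60.0))
        assert sm.frequency_hz == pytest.approx(0.7, abs=0.017)
        assert sm.n_waves == 42

    def test_no_waves_gives_zero(self):
        sm = gf.strength(make_channel("pressure", np.full(5000, 1.5), dt=0.002))
        assert sm.S == 0.0 and sm.frequency_hz == 0.0

    @pytest.mark.parametrize("seed", range(5))
    def test_equals_oracle_on_noisy_traces(self, seed):
        rng = np.random.default_rng(100 + seed)
        t = np.arange(0, 45, 0.05)
        y = 3 - 0.3 * np.sin(2 * np.pi * 0.7 * t) + rng.normal(0, 0.04, t.size)
        ch = make_channel("ew1", y)
        sm = gf.strength(ch, min_amplitude=0.25, smooth_window=0)
        s_oracle, n_oracle = brute_force_strength(t, y, 0.25)
        assert sm.S == pytest.approx(s_oracle, abs=1e-9)
        assert sm.n_waves == n_oracle

    @given(st.floats(0.1, 10.0))
    @settings(max_examples=20, deadline=None)
    def test_homogeneity_under_scaling(self, k):
        rng = np.random.default_rng(7)
        t = np.arange(0, 30, 0.05)
        y = 0.5 * np.sin(2 * np.pi * 0.7 * t) + rng.normal(0, 0.03, t.size)
        base = gf.strength(make_channel("longitudinal", 5 + y),
                           min_amplitude=0.2, smooth_window=0)
        scaled = gf.strength(make_channel("longitudinal", 5 + k * y),
                             min_amplitude=0.2 * k, smooth_window=0)
        assert scaled.S == pytest.approx(k * base.S, rel=1e-9)
        assert scaled.n_waves == base.n_waves


class TestGross:
    def test_constant_level(self):
        ch = make_channel("pressure", np.full(5000, 1.5), dt=0.002)
        g = gf.gross(ch, (0, 5), None)
        assert g.G_mean == pytest.approx(1.5)

    def test_step_delta(self):
        y = np.concatenate([np.full(1000, 1.0), np.full(1000, 1.27)])
        ch = make_channel("pressure", y, dt=0.002)
        g = gf.gross(ch, (2.0, 4.0), (0.0, 2.0))
        assert g.G_delta == pytest.approx(0.27, abs=1e-9)

    def test_linear_ramp_mean_is_midpoint(self):
        t = np.arange(0, 10, 0.05)
        ch = make_channel("longitudinal", 1.0 + 0.2 * t)
        g = gf.gross(ch, (0, 10))
        assert g.G_mean == pytest.approx(1.0 + 0.2 * 5.0, abs=0.01)

    def test_delta_antisymmetry(self):
        rng = np.random.default_rng(3)
        ch = make_channel("longitudinal", 5 + rng.normal(0, 1, 400))
        fwd = gf.gross(ch, (10, 20), (0, 10)).G_delta
        # swapping the interval roles negates the delta
        rev_mean = gf.gross(ch, (0, 10)).G_mean - gf.gross(ch, (10, 20)).G_mean
        assert fwd == pytest.approx(-rev_mean, abs=1e-12)

    def test_zero_length_interval_rejected(self):
        ch = sine_channel()
        with pytest.raises(ParameterError):
            gf.gross(ch, (5.0, 5.0))


class TestNormalizeLongitudinal:
    def test_subtracts_minimum(self):
        ch = make_channel("longitudinal", [2.1, 2.4, 2.0])
        out = gf.normalize_longitudinal(ch)
        np.testing.assert_allclose(out.values, [0.1, 0.4, 0.0], atol=1e-12)

    def test_idempotent_and_range_preserving(self):
        rng = np.random.default_rng(0)
        ch = make_channel("longitudinal", 5 + rng.normal(0, 1, 100))
        once = gf.normalize_longitudinal(ch)
        twice = gf.normalize_longitudinal(once)
        np.testing.assert_allclose(once.values, twice.values, atol=1e-15)
        assert np.ptp(once.values) == pytest.approx(np.ptp(ch.values))

    def test_rejects_other_channels(self):
        with pytest.raises(ParameterError):
            gf.normalize_longitudinal(sine_channel("ew1", baseline=3.0))


class TestSpectrum:
    def test_single_tone_peak(self):
        sp = gf.fft_spectrum(sine_channel(freq=0.7, amp=0.5, duration=120.0))
        assert sp.peak_frequency == pytest.approx(0.7, abs=0.01)
        assert sp.amplitudes.max() == pytest.approx(0.5, rel=0.05)

    def test_highpass_removes_slow_drift(self):
        t = np.arange(0, 120, 0.05)
        y = 5 + 0.5 * np.sin(2 * np.pi * 0.7 * t) + 2 * np.sin(2 * np.pi * 0.05 * t)
        sp = gf.fft_spectrum(make_channel("longitudinal", y))
        assert np.all(sp.frequencies >= 0.2)
        assert sp.peak_frequency == pytest.approx(0.7, abs=0.01)

    def test_fft_peak_matches_direct_dft_oracle(self):
        rng = np.random.default_rng(2)
        t = np.arange(0, 40, 0.05)
        y = 5 + 0.4 * np.sin(2 * np.pi * 0.75 * t) + rng.normal(0, 0.05, t.size)
        sp = gf.fft_spectrum(make_channel("longitudinal", y))
        oracle = dft_peak(list(y[::4]), 0.2, 0.2)  # decimated to keep it fast
        assert sp.peak_frequency == pytest.approx(oracle, abs=0.05)

    def test_envelope_shifts_left_for_slower_weaker_group(self):
        rng = np.random.default_rng(5)
        t = np.arange(0, 120, 0.05)

        def fit_peak(f0, a):
            y = 5 + a * np.sin(2 * np.pi * f0 * t) + rng.normal(0, 0.02, t.size)
            return gf.fft_spectrum(make_channel("longitudinal", y)).fit_peak_frequency

        assert fit_peak(0.66, 0.3) < fit_peak(0.74, 0.5)

    def test_too_few_points_flags_fit_unavailable(self):
        rng = np.random.default_rng(1)
        ch = make_channel("longitudinal", 5 + rng.normal(0, 0.001, 600))
        sp = gf.fft_spectrum(ch)
        assert not sp.fit_available
        with pytest.raises(ParameterError):
            sp.envelope(np.array([0.7]))

    def test_short_window_rejected(self):
        with pytest.raises(ParameterError):
            gf.fft_spectrum(sine_channel(duration=30.0), window=(0, 10))

    def test_counting_and_fft_agree_for_single_tone(self):
        ch = sine_channel(freq=0.7, amp=0.5, duration=120.0)
        sm = gf.strength(ch)
        sp = gf.fft_spectrum(ch)
        assert sm.frequency_hz == pytest.approx(sp.peak_frequency, abs=0.01)
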