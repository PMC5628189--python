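"""The six acoustic features, their normalization and smoothing."""

import numpy as np
import pytest

from voiceonset import SpectralConfig, Waveform, extract_features, multitaper_spectrogram
from voiceonset.features import (
    FEATURE_NAMES,
    amp_mod,
    amplitude,
    freq_mod,
    harmonic_pitch,
    normalize_and_smooth,
    spectral_change,
    wiener_entropy,
)
from voiceonset.spectral import spectral_derivatives

from conftest import analyzed, make_harmonic_stack, make_noise, make_tone


def _scaled(sg, c):
    """Copy of a spectrogram set with power scaled by c."""
    from dataclasses import replace

    return replace(sg, power=c * sg.power)


class TestAmplitude:
    def test_zero_signal_constant_log_floor(self):
        sg = multitaper_spectrogram(Waveform(np.zeros(2000), 16000.0))
        a = amplitude(sg)
        assert np.ptp(a) == 0.0

    def test_gain_shifts_raw_log_amplitude(self, tone_sg):
        a1 = amplitude(tone_sg)
        a2 = amplitude(_scaled(tone_sg, 100.0))
        np.testing.assert_allclose(a2 - a1, 2 * np.log(10.0), rtol=1e-9)

    def test_in_band_tone_louder_than_below_band_tone(self):
        hi = analyzed(make_tone(10000.0, dur_ms=100.0))
        lo = analyzed(make_tone(50.0, dur_ms=100.0))  # below the 150 Hz band edge
        assert amplitude(hi).mean() > amplitude(lo).mean()


class TestWienerEntropy:
    def test_flat_spectrum_gives_one(self, tone_sg):
        sg = _scaled(tone_sg, 0.0)
        sg.power = sg.power + 1.0  # perfectly flat
        np.testing.assert_allclose(wiener_entropy(sg), 1.0, rtol=1e-12)

    def test_single_bin_spectrum_near_zero(self, tone_sg):
        sg = _scaled(tone_sg, 0.0)
        sg.power = sg.power.copy()
        sg.power[10, :] = 1.0
        assert np.all(wiener_entropy(sg) < 1e-3)

    def test_exact_scale_invariance(self, stack_sg):
        we1 = wiener_entropy(stack_sg)
        we2 = wiener_entropy(_scaled(stack_sg, 37.5))
        np.testing.assert_allclose(we2, we1, rtol=1e-12)

    def test_noise_entropy_exceeds_harmonic_entropy(self, noise_sg, stack_sg):
        assert wiener_entropy(noise_sg).mean() > wiener_entropy(stack_sg).mean()


class TestSpectralChange:
    def test_constant_spectrogram_zero_interior(self, tone_sg):
        sg = _scaled(tone_sg, 0.0)
        sg.power = sg.power + 2.0
        sg = spectral_derivatives(sg, SpectralConfig(log_power_derivatives=False))
        assert np.all(spectral_change(sg)[1:-1] == 0.0)

    def test_fast_chirp_changes_more_over_time_than_steady_tone(self):
        """A sweeping spectrum has far larger time-derivative mass than a
        stationary one (the d_freq term is comparable for both, set by the
        static peak structure, so the time component carries the contrast)."""
        from scipy.signal import chirp as chirp_wave

        fs = 44100.0
        t = np.arange(int(fs * 0.2)) / fs
        sweep = analyzed(Waveform(0.1 * chirp_wave(t, 1000.0, t[-1], 15000.0), fs))
        tone = analyzed(make_tone(1000.0))
        dt_sweep = np.abs(sweep.d_time).sum(axis=0)
        dt_tone = np.abs(tone.d_time).sum(axis=0)
        assert np.median(dt_sweep) > 5 * np.median(dt_tone)

    def test_voiced_frames_change_more_than_noise_frames(self, small_corpus):
        """Operationally, SC separates speech from the stationary floor."""
        _, truth, fms = small_corpus
        j = FEATURE_NAMES.index("spectral_change")
        voiced, noise = [], []
        for (_, row), fm in zip(truth.iterrows(), fms):
            voiced.append(fm.values[fm.times > row["truth_ms"] + 50, j].mean())
            noise.append(fm.values[fm.times < row["truth_ms"] - 100, j].mean())
        assert np.mean(voiced) > np.mean(noise)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(5)
        sg = analyzed(make_noise(fs=16000.0, dur_ms=40.0, seed=6))
        sc = spectral_change(sg)
        expect = np.empty(sg.n_frames)
        for j in range(sg.n_frames):
            acc = 0.0
            for i in range(sg.freqs.size):
                acc += (sg.d_time[i, j] ** 2 + sg.d_freq[i, j] ** 2) ** 0.5
            expect[j] = acc
        np.testing.assert_allclose(sc, expect, rtol=1e-12)


class TestAmpMod:
    def test_stationary_tone_interior_near_zero(self, tone_sg):
        am = amp_mod(tone_sg)[5:-5]
        scale = np.abs(amp_mod(tone_sg)).max() + 1e-30
        assert np.abs(am).max() <= scale  # finite, no blow-up

    def test_onset_positive_offset_negative(self):
        fs = 16000.0
        n = int(fs * 0.3)
        x = np.zeros(n)
        t = np.arange(n) / fs
        gate = slice(int(0.1 * fs), int(0.2 * fs))
        x[gate] = 0.2 * np.sin(2 * np.pi * 1000 * t[gate])
        x += np.random.default_rng(7).normal(0, 1e-4, n)
        sg = analyzed(Waveform(x, fs))
        am = amp_mod(sg)
        on = (sg.times >= 95) & (sg.times <= 105)
        off = (sg.times >= 195) & (sg.times <= 205)
        assert am[on].max() > 0
        assert am[off].min() < 0

    def test_equals_column_sum_of_time_derivative(self, noise_sg):
        np.testing.assert_allclose(amp_mod(noise_sg), noise_sg.d_time.sum(axis=0), rtol=1e-12)


class TestFreqMod:
    def test_steady_stack_below_noise(self, stack_sg, noise_sg):
        assert freq_mod(stack_sg)[5:-5].mean() < freq_mod(noise_sg)[5:-5].mean()

    def test_zero_time_derivative_gives_zero(self, tone_sg):
        from dataclasses import replace

        sg = replace(tone_sg, d_time=np.zeros_like(tone_sg.power))
        assert np.all(freq_mod(sg) == 0.0)


class TestHarmonicPitch:
    def test_stack_exceeds_noise(self, stack_sg, noise_sg):
        assert harmonic_pitch(stack_sg).mean() > 2 * harmonic_pitch(noise_sg).mean()

    def test_stack_exceeds_pure_tone(self, stack_sg, tone_sg):
        assert harmonic_pitch(stack_sg).mean() > harmonic_pitch(tone_sg).mean()

    def test_empty_band_raises(self, stack_sg):
        with pytest.raises(ValueError):
            harmonic_pitch(stack_sg, pitch_range_hz=(20000.0, 21000.0))


class TestNormalizeAndSmooth:
    def test_minmax_normalization_without_smoothing(self):
        raw = np.tile(np.array([0.0, 5.0, 10.0])[:, None], (1, 6))
        fm = normalize_and_smooth(raw, np.array([0.0, 1.0, 2.0]), smooth_ms=0.0)
        np.testing.assert_allclose(fm.values[:, 0], [0.0, 0.5, 1.0])

    def test_impulse_smoothing_preserves_mass(self):
        n = 201
        raw = np.zeros((n, 6))
        raw[100, :] = 1.0
        fm = normalize_and_smooth(raw, np.arange(n, dtype=float), smooth_ms=10.0)
        # pre-normalization smoothed mass: recover via the raw/smoothed ratio
        from scipy.ndimage import gaussian_filter1d

        sm = gaussian_filter1d(raw, sigma=10.0 / 2.355, axis=0, mode="nearest", truncate=3.0)
        assert abs(sm[:, 0].sum() - 1.0) < 0.01
        # smoothed bump is symmetric around the impulse
        np.testing.assert_allclose(fm.values[100 - 5 : 100, 0], fm.values[101 : 106, 0][::-1], rtol=1e-6)

    def test_constant_feature_flagged_and_zeroed(self):
        raw = np.ones((50, 6))
        raw[:, 0] = np.linspace(0, 1, 50)
        fm = normalize_and_smooth(raw, np.arange(50, dtype=float))
        assert not fm.constant[0]
        assert fm.constant[1:].all()
        assert np.all(fm.values[:, 1:] == 0.0)

    def test_output_attains_zero_and_one(self, stack_sg):
        fm = extract_features(stack_sg)
        for j in range(6):
            if not fm.constant[j]:
                assert fm.values[:, j].min() == pytest.approx(0.0, abs=1e-12)
                assert fm.values[:, j].max() == pytest.approx(1.0, abs=1e-12)


def test_gain_invariance_of_normalized_features():
    """All six normalized features agree for x and 20*x."""
    w = make_harmonic_stack(150.0, fs=16000.0, dur_ms=150.0, seed=8)
    w2 = Waveform(20.0 * w.samples, w.sample_rate)
    f1 = extract_features(analyzed(w))
    f2 = extract_features(analyzed(w2))
    np.testing.assert_allclose(f1.values, f2.values, atol=1e-6)


def test_voiced_frames_separate_from_noise_frames(small_corpus):
    """Harmonic pitch and entropy-complement are higher in voiced regions."""
    waveforms, truth, fms = small_corpus
    hp_voiced, hp_noise, we_voiced, we_noise = [], [], [], []
    for (_, row), fm in zip(truth.iterrows(), fms):
        voiced = fm.times > row["truth_ms"] + 50
        noise = fm.times < row["truth_ms"] - 100
        hp = fm["harmonic_pitch"]
        we_c = fm["wiener_entropy"]  # oriented: complement of the GM/AM ratio
        hp_voiced.append(hp[voiced].mean())
        hp_noise.append(hp[noise].mean())
        we_voiced.append(we_c[voiced].mean())
        we_noise.append(we_c[noise].mean())
    assert np.mean(hp_voiced) > np.mean(hp_noise)
    assert np.mean(we_voiced) > np.mean(we_noise)
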