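"""Shared fixtures: synthetic signals and a small pre-analyzed corpus."""

from __future__ import annotations

import numpy as np
import pytest

from voiceonset import (
    CorpusConfig,
    SpectralConfig,
    Waveform,
    generate_corpus,
    multitaper_spectrogram,
    spectral_derivatives,
)
from voiceonset.pipeline import compute_features


def make_tone(freq_hz: float, fs: float = 44100.0, dur_ms: float = 200.0, rms: float = 0.1) -> Waveform:
    t = np.arange(int(fs * dur_ms / 1000.0)) / fs
    x = np.sqrt(2.0) * rms * np.sin(2 * np.pi * freq_hz * t)
    return Waveform(samples=x, sample_rate=fs, trial_id=f"tone{freq_hz:g}")


def make_noise(fs: float = 44100.0, dur_ms: float = 200.0, rms: float = 0.1, seed: int = 0) -> Waveform:
    rng = np.random.default_rng(seed)
    n = int(fs * dur_ms / 1000.0)
    return Waveform(samples=rng.normal(0.0, rms, n), sample_rate=fs, trial_id="noise")


def make_harmonic_stack(
    f0_hz: float = 200.0,
    n_harmonics: int = 10,
    fs: float = 44100.0,
    dur_ms: float = 200.0,
    rms: float = 0.1,
    seed: int = 0,
) -> Waveform:
    rng = np.random.default_rng(seed)
    t = np.arange(int(fs * dur_ms / 1000.0)) / fs
    x = np.zeros_like(t)
    for k in range(1, n_harmonics + 1):
        if k * f0_hz < 0.45 * fs:
            x += np.sin(2 * np.pi * k * f0_hz * t + rng.uniform(0, 2 * np.pi)) / k
    x *= rms / np.sqrt(np.mean(x**2))
    return Waveform(samples=x, sample_rate=fs, trial_id=f"stack{f0_hz:g}")


def analyzed(w: Waveform, cfg: SpectralConfig | None = None):
    return spectral_derivatives(multitaper_spectrogram(w, cfg))


@pytest.fixture(scope="session")
def tone_sg():
    """Spectrogram of a steady 1 kHz tone at 44.1 kHz."""
    return analyzed(make_tone(1000.0))


@pytest.fixture(scope="session")
def noise_sg():
    """Spectrogram of stationary white noise at 44.1 kHz."""
    return analyzed(make_noise(dur_ms=300.0))


@pytest.fixture(scope="session")
def stack_sg():
    """Spectrogram of a 200 Hz harmonic stack."""
    return analyzed(make_harmonic_stack())


@pytest.fixture(scope="session")
def small_corpus():
    """30 synthetic trials with truth table and precomputed features."""
    waveforms, truth = generate_corpus(
        30, CorpusConfig(snr_range_db=(10.0, 30.0), transient_prob=0.4), seed=11
    )
    fms = [compute_features(w) for w in waveforms]
    return waveforms, truth, fms
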