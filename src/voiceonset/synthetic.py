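"""Seeded generator of trial waveforms with known ground-truth onsets.

Emulates the acoustics of a single naming-task trial: a stationary Gaussian
noise floor, optionally a loud but brief broadband pre-vocal transient
(a lip-smack-like burst the detector must ignore), optionally a
low-amplitude unvoiced prefix (band-limited noise, like [s] before a
vowel), and a voiced segment modeled as a harmonic stack with 1/k spectral
tilt, random phases, and a linear amplitude ramp at onset.

The ground-truth onset is the start of the first speech sound: the
unvoiced prefix when present, otherwise the voiced onset. Also provided:
a corpus generator drawing trial parameters from realistic ranges, and a
simulator of human raters (per-rater constant bias plus Gaussian jitter)
for exercising the optimization and evaluation machinery.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import butter, sosfilt

from .audio_io import Waveform


class TrialSpecError(ValueError):
    """Raised for inconsistent trial specifications."""


@dataclass(frozen=True)
class TrialSpec:
    """Acoustic blueprint of one synthetic trial.

    RMS levels are linear amplitudes relative to full scale; the noise
    floor defines the reference against which SNRs are set. A transient,
    when present, must end before the speech onset and be shorter than the
    detector's 35 ms sustain window.
    """

    duration_ms: float = 1800.0
    sample_rate: float = 16000.0
    noise_floor_rms: float = 0.01
    voiced_onset_ms: float = 700.0
    f0_hz: float = 150.0
    n_harmonics: int = 10
    voiced_rms: float = 0.1
    ramp_ms: float = 20.0
    unvoiced_prefix_ms: float = 0.0
    prefix_rms: float = 0.0
    prefix_band_hz: tuple[float, float] = (3000.0, 7000.0)
    transient_at_ms: float | None = None
    transient_dur_ms: float = 20.0
    transient_rms: float = 0.0

    def __post_init__(self) -> None:
        if self.voiced_onset_ms + self.ramp_ms >= self.duration_ms:
            raise TrialSpecError("voiced onset + ramp must end before the recording does")
        if self.unvoiced_prefix_ms < 0 or self.unvoiced_prefix_ms > self.voiced_onset_ms:
            raise TrialSpecError("unvoiced prefix must fit before the voiced onset")
        if self.transient_at_ms is not None:
            if self.transient_dur_ms >= 35.0:
                raise TrialSpecError("transient must be shorter than the 35 ms sustain window")
            if self.transient_at_ms + self.transient_dur_ms >= self.truth_ms - 35.0:
                raise TrialSpecError("transient must precede speech onset by more than 35 ms")
        if self.f0_hz <= 0 or self.n_harmonics < 1:
            raise TrialSpecError("need positive f0 and at least one harmonic")

    @property
    def truth_ms(self) -> float:
        """Acoustic ground-truth onset: first speech sound in the trial."""
        if self.unvoiced_prefix_ms > 0 and self.prefix_rms > 0:
            return self.voiced_onset_ms - self.unvoiced_prefix_ms
        return self.voiced_onset_ms

    @property
    def detectable(self) -> bool:
        return self.voiced_rms > 0 or (self.unvoiced_prefix_ms > 0 and self.prefix_rms > 0)


def generate_trial(
    spec: TrialSpec, seed: int | np.random.Generator, trial_id: str = "trial"
) -> tuple[Waveform, float]:
    """Render one trial; returns the waveform and its ground-truth onset (ms).

    Deterministic given the seed: the same seed reproduces the samples
    bit for bit.
    """
    rng = np.random.default_rng(seed)
    fs = spec.sample_rate
    n = int(round(spec.duration_ms * fs / 1000.0))
    t = np.arange(n) / fs
    x = rng.normal(0.0, spec.noise_floor_rms, size=n)

    if spec.transient_at_ms is not None and spec.transient_rms > 0:
        i0 = int(round(spec.transient_at_ms * fs / 1000.0))
        i1 = min(n, i0 + int(round(spec.transient_dur_ms * fs / 1000.0)))
        burst = rng.normal(0.0, spec.transient_rms, size=i1 - i0)
        # Hann envelope: abrupt clicks still have smooth attack/decay at this scale
        burst *= np.hanning(burst.size)
        x[i0:i1] += burst

    if spec.unvoiced_prefix_ms > 0 and spec.prefix_rms > 0:
        p0 = int(round((spec.voiced_onset_ms - spec.unvoiced_prefix_ms) * fs / 1000.0))
        p1 = int(round(spec.voiced_onset_ms * fs / 1000.0))
        lo, hi = spec.prefix_band_hz
        hi = min(hi, 0.45 * fs)
        sos = butter(4, [lo, hi], btype="bandpass", fs=fs, output="sos")
        noise = sosfilt(sos, rng.normal(0.0, 1.0, size=p1 - p0))
        rms = np.sqrt(np.mean(noise**2)) or 1.0
        x[p0:p1] += noise / rms * spec.prefix_rms

    if spec.voiced_rms > 0:
        v0 = int(round(spec.voiced_onset_ms * fs / 1000.0))
        seg = np.zeros(n - v0)
        tseg = t[v0:] - t[v0]
        nyq = 0.45 * fs
        amps = np.array(
            [1.0 / k for k in range(1, spec.n_harmonics + 1) if k * spec.f0_hz < nyq]
        )
        phases = rng.uniform(0.0, 2 * np.pi, size=amps.size)
        for k, (a, ph) in enumerate(zip(amps, phases), start=1):
            seg += a * np.sin(2 * np.pi * k * spec.f0_hz * tseg + ph)
        rms = np.sqrt(np.mean(seg**2)) or 1.0
        seg *= spec.voiced_rms / rms
        ramp_n = int(round(spec.ramp_ms * fs / 1000.0))
        if ramp_n > 0:
            env = np.ones(seg.size)
            env[:ramp_n] = np.linspace(0.0, 1.0, ramp_n, endpoint=False)
            seg *= env
        x[v0:] += seg

    w = Waveform(samples=x, sample_rate=fs, trial_id=trial_id)
    return w, spec.truth_ms


@dataclass(frozen=True)
class CorpusConfig:
    """Parameter ranges for a random corpus of synthetic trials.

    Defaults emulate adult-voice naming trials: f0 uniform in 100-250 Hz,
    speech onsets uniform in 300-1200 ms, voiced SNR uniform in 5-30 dB
    over the noise floor. A fraction of trials carries a loud pre-vocal
    transient; unvoiced prefixes are off by default (their onsets probe a
    separate detector behavior and are opted into explicitly).
    """

    duration_ms: float = 1800.0
    sample_rate: float = 16000.0
    noise_floor_rms: float = 0.01
    f0_range_hz: tuple[float, float] = (100.0, 250.0)
    onset_range_ms: tuple[float, float] = (300.0, 1200.0)
    snr_range_db: tuple[float, float] = (5.0, 30.0)
    transient_prob: float = 0.3
    transient_snr_db: float = 20.0
    prefix_prob: float = 0.0
    prefix_snr_db: float = 10.0
    prefix_dur_ms: float = 60.0


def generate_corpus(
    n_trials: int,
    config: CorpusConfig | None = None,
    seed: int | np.random.Generator = 0,
) -> tuple[list[Waveform], pd.DataFrame]:
    """Draw ``n_trials`` random trials; returns waveforms and a truth table.

    The truth table has columns ``trial_id``, ``truth_ms``, ``f0_hz``,
    ``snr_db``, ``has_transient``.
    """
    config = config or CorpusConfig()
    rng = np.random.default_rng(seed)
    waveforms: list[Waveform] = []
    rows = []
    for i in range(n_trials):
        f0 = rng.uniform(*config.f0_range_hz)
        onset = rng.uniform(*config.onset_range_ms)
        snr_db = rng.uniform(*config.snr_range_db)
        voiced_rms = config.noise_floor_rms * 10 ** (snr_db / 20.0)
        has_transient = rng.random() < config.transient_prob
        has_prefix = rng.random() < config.prefix_prob
        prefix_ms = config.prefix_dur_ms if has_prefix else 0.0
        transient_at = None
        if has_transient:
            earliest = 50.0
            latest = onset - prefix_ms - 90.0
            if latest > earliest:
                transient_at = rng.uniform(earliest, latest)
        spec = TrialSpec(
            duration_ms=config.duration_ms,
            sample_rate=config.sample_rate,
            noise_floor_rms=config.noise_floor_rms,
            voiced_onset_ms=onset,
            f0_hz=f0,
            voiced_rms=voiced_rms,
            unvoiced_prefix_ms=prefix_ms,
            prefix_rms=(
                config.noise_floor_rms * 10 ** (config.prefix_snr_db / 20.0) if has_prefix else 0.0
            ),
            transient_at_ms=transient_at,
            transient_rms=(
                config.noise_floor_rms * 10 ** (config.transient_snr_db / 20.0)
                if transient_at is not None
                else 0.0
            ),
        )
        trial_id = f"trial_{i:04d}"
        w, truth = generate_trial(spec, rng, trial_id=trial_id)
        waveforms.append(w)
        rows.append(
            {
                "trial_id": trial_id,
                "truth_ms": truth,
                "f0_hz": f0,
                "snr_db": snr_db,
                "has_transient": transient_at is not None,
            }
        )
    columns = ["trial_id", "truth_ms", "f0_hz", "snr_db", "has_transient"]
    return waveforms, pd.DataFrame(rows, columns=columns)


def simulate_raters(
    truth_ms,
    bias_ms,
    jitter_sd_ms,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Simulate manual ratings: truth + per-rater constant bias + jitter.

    ``bias_ms`` and ``jitter_sd_ms`` are sequences, one entry per rater.
    Returns a trials x raters DataFrame with columns ``rater_1``, ...
    """
    truth = np.asarray(truth_ms, dtype=np.float64)
    bias = np.asarray(bias_ms, dtype=np.float64)
    jitter = np.asarray(jitter_sd_ms, dtype=np.float64)
    if bias.shape != jitter.shape:
        raise ValueError("bias_ms and jitter_sd_ms must have one entry per rater")
    rng = np.random.default_rng(seed)
    ratings = truth[:, None] + bias[None, :] + rng.normal(
        0.0, jitter[None, :], size=(truth.size, bias.size)
    )
    return pd.DataFrame(ratings, columns=[f"rater_{r + 1}" for r in range(bias.size)])
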