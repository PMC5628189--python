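"""The six per-frame acoustic features.

Voiced speech differs from background noise and from mouth transients
(lip smacks, clicks) in having a rich harmonic structure, a peaked rather
than flat spectrum, and sustained rather than momentary energy. Six
features capture this per 1-ms frame:

amplitude
    log spectral power integrated over 0.15-22.05 kHz (clipped to Nyquist).
wiener_entropy
    geometric mean / arithmetic mean of the spectrum; 1 for a flat
    (noise-like) spectrum, -> 0 for tonal spectra; gain-invariant.
spectral_change
    summed gradient magnitude of the spectrogram over time and frequency.
amp_mod
    overall change of power across all frequencies (column sum of the
    time derivative).
freq_mod
    arctan of the ratio of maximal absolute time- to frequency-derivative;
    high when the concentration of power across bands changes quickly.
harmonic_pitch
    peak of the cepstrum (spectrum of the log power spectrum) inside a
    quefrency band corresponding to plausible voice pitch; high for
    harmonic stacks, low for noise.

Each feature is Gaussian-smoothed over time and min-max normalized to
[0, 1] per recording, so detection thresholds are comparable across
recordings and gains. Because entropy *rises* for noise, detection uses
the complement internally via its threshold semantics; the feature itself
is stored as defined above.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d

from .spectral import SpectrogramSet, spectral_derivatives

FEATURE_NAMES = (
    "amplitude",
    "wiener_entropy",
    "spectral_change",
    "amp_mod",
    "freq_mod",
    "harmonic_pitch",
)

#: relative floor applied to power before logs and ratios
EPS_REL = 1e-12

#: integration band for the amplitude feature, kHz
AMPLITUDE_BAND_KHZ = (0.15, 22.05)

#: default pitch search range for harmonic_pitch, Hz
PITCH_RANGE_HZ = (50.0, 500.0)

#: features whose defined value is high for NOISE; the detection-oriented
#: matrix stores their complement so "elevated" means speech-like for all six
NOISE_HIGH_FEATURES = ("wiener_entropy", "freq_mod")


@dataclass
class FeatureMatrix:
    """Per-frame features on the spectrogram's time base.

    ``values`` holds the normalized features (columns ordered as
    :data:`FEATURE_NAMES`), each in [0, 1] within the recording;
    ``raw`` the un-normalized, un-smoothed values. ``constant`` flags
    features that were constant over the recording (normalized to 0).
    """

    times: np.ndarray
    values: np.ndarray  # (n_frames, 6), normalized
    raw: np.ndarray  # (n_frames, 6)
    constant: np.ndarray  # (6,) bool
    trial_id: str = ""
    step_ms: float = 1.0

    def __getitem__(self, name: str) -> np.ndarray:
        return self.values[:, FEATURE_NAMES.index(name)]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=list(FEATURE_NAMES))
        df.insert(0, "time_ms", self.times)
        return df


def _eps(power: np.ndarray) -> float:
    return EPS_REL * max(float(power.max()), np.finfo(float).tiny)


def amplitude(sg: SpectrogramSet) -> np.ndarray:
    """Log spectral power integrated over the amplitude band."""
    lo_khz, hi_khz = AMPLITUDE_BAND_KHZ
    nyq_khz = sg.sample_rate / 2000.0
    hi_khz = min(hi_khz, nyq_khz)
    band = (sg.freqs >= lo_khz * 1000.0) & (sg.freqs <= hi_khz * 1000.0)
    if not band.any():
        raise ValueError("amplitude integration band is empty at this sample rate")
    return np.log(sg.power[band].sum(axis=0) + _eps(sg.power))


def wiener_entropy(sg: SpectrogramSet) -> np.ndarray:
    """Geometric over arithmetic mean of the spectrum, per frame."""
    s = sg.power + _eps(sg.power)
    gm = np.exp(np.mean(np.log(s), axis=0))
    am = np.mean(s, axis=0)
    return gm / am


def spectral_change(sg: SpectrogramSet) -> np.ndarray:
    """Summed gradient magnitude across frequency, per frame."""
    _require_derivatives(sg)
    return np.sqrt(sg.d_time**2 + sg.d_freq**2).sum(axis=0)


def amp_mod(sg: SpectrogramSet) -> np.ndarray:
    """Overall change in power across all frequencies, per frame."""
    _require_derivatives(sg)
    return sg.d_time.sum(axis=0)


def freq_mod(sg: SpectrogramSet) -> np.ndarray:
    """arctan of max |d_time| / max |d_freq|, per frame."""
    _require_derivatives(sg)
    num = np.abs(sg.d_time).max(axis=0)
    den = np.abs(sg.d_freq).max(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(num == 0.0, 0.0, num / np.where(den == 0.0, np.inf, den))
    out = np.arctan(ratio)
    # both derivatives zero -> no modulation; num>0, den=0 -> ratio inf -> pi/2
    out[(num > 0) & (den == 0)] = np.pi / 2
    return out


def harmonic_pitch(
    sg: SpectrogramSet,
    pitch_range_hz: tuple[float, float] = PITCH_RANGE_HZ,
) -> np.ndarray:
    """Peak cepstral magnitude in the voice-pitch quefrency band, per frame.

    The cepstrum is the (real) spectrum of the log power spectrum of each
    frame; a stack of harmonics at multiples of f0 produces a cepstral
    peak at quefrency 1/f0. The representable quefrency range is bounded
    above by 1/(2*df), df being the spectral bin spacing, so the requested
    band is clipped to what the resolution supports (and must remain
    non-empty). The log spectrum is zero-padded 4x before the cepstral
    transform for denser quefrency sampling.
    """
    f0_min, f0_max = pitch_range_hz
    if not (0 < f0_min < f0_max):
        raise ValueError("invalid pitch range")
    s = np.log(sg.power + _eps(sg.power))
    s = s - s.mean(axis=0, keepdims=True)  # remove DC of the log spectrum
    df = float(sg.freqs[1] - sg.freqs[0])
    n = s.shape[0]
    n_cep = 4 * (1 << (n - 1).bit_length())
    ceps = np.abs(np.fft.rfft(s, n=n_cep, axis=0))
    quef = np.arange(ceps.shape[0]) / (n_cep * df)  # seconds
    band = (quef >= 1.0 / f0_max) & (quef <= 1.0 / f0_min)
    if not band.any():
        raise ValueError(
            f"quefrency band for pitch {pitch_range_hz} Hz is empty at "
            f"frequency resolution {df:.1f} Hz"
        )
    return ceps[band].max(axis=0)


def _require_derivatives(sg: SpectrogramSet) -> None:
    if sg.d_time is None or sg.d_freq is None:
        raise ValueError("spectral derivatives not populated; call spectral_derivatives first")


#: Gaussian FWHM -> sigma conversion
_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


def normalize_and_smooth(
    raw: np.ndarray,
    times: np.ndarray,
    smooth_ms: float = 10.0,
    trial_id: str = "",
) -> FeatureMatrix:
    """Gaussian-smooth raw features over time, then min-max normalize.

    ``smooth_ms`` is the kernel FWHM (10 ms default, sigma ~ 4.25 ms),
    truncated at +/-3 sigma with edge renormalization (nearest-edge
    extension). Smoothing precedes normalization so the [0, 1] range
    holds exactly in the output. Constant features are flagged and set
    to 0 rather than producing a 0/0 normalization.
    """
    raw = np.asarray(raw, dtype=np.float64)
    if raw.ndim != 2 or raw.shape[1] != len(FEATURE_NAMES):
        raise ValueError(f"expected (n_frames, {len(FEATURE_NAMES)}) raw feature array")
    step_ms = float(times[1] - times[0]) if len(times) > 1 else 1.0
    sigma_frames = smooth_ms * _FWHM_TO_SIGMA / step_ms
    if sigma_frames > 0:
        smoothed = gaussian_filter1d(raw, sigma=sigma_frames, axis=0, mode="nearest", truncate=3.0)
    else:
        smoothed = raw.copy()
    lo = smoothed.min(axis=0)
    hi = smoothed.max(axis=0)
    span = hi - lo
    constant = span == 0.0
    span_safe = np.where(constant, 1.0, span)
    values = np.clip((smoothed - lo) / span_safe, 0.0, 1.0)
    values[:, constant] = 0.0
    return FeatureMatrix(
        times=np.asarray(times, dtype=np.float64),
        values=values,
        raw=raw,
        constant=constant,
        trial_id=trial_id,
        step_ms=step_ms,
    )


def extract_features(
    sg: SpectrogramSet,
    smooth_ms: float = 10.0,
    pitch_range_hz: tuple[float, float] = PITCH_RANGE_HZ,
    trial_id: str = "",
    orient_speech_high: bool = True,
) -> FeatureMatrix:
    """Compute all six features from a spectrogram, normalize and orient them.

    With ``orient_speech_high`` (default) the normalized Wiener-entropy and
    frequency-modulation columns are complemented (``1 - v``), because both
    quantities are high for noise and low for voiced speech: after
    orientation "elevated above threshold" means speech-like for every
    feature, which is what the detection rule counts. ``raw`` always keeps
    the quantities as defined.
    """
    if sg.d_time is None:
        sg = spectral_derivatives(sg)
    raw = np.column_stack(
        [
            amplitude(sg),
            wiener_entropy(sg),
            spectral_change(sg),
            amp_mod(sg),
            freq_mod(sg),
            harmonic_pitch(sg, pitch_range_hz),
        ]
    )
    fm = normalize_and_smooth(raw, sg.times, smooth_ms=smooth_ms, trial_id=trial_id)
    if orient_speech_high:
        for name in NOISE_HIGH_FEATURES:
            j = FEATURE_NAMES.index(name)
            if not fm.constant[j]:
                fm.values[:, j] = 1.0 - fm.values[:, j]
    return fm
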