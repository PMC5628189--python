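"""Multitaper time-frequency analysis.

The spectrogram is estimated by averaging periodograms computed with a
sequence of discrete prolate spheroidal (Slepian, DPSS) tapers. With a
10 ms window and a time-bandwidth product NW = 5, energy for each frequency
bin is concentrated within a half-bandwidth of +/-0.5 kHz, and up to
2*NW - 2 = 8 well-concentrated tapers are available — the defaults used
throughout the package.

Derivatives of the (log-)spectrogram over time and frequency feed the
spectral-change, amplitude-modulation and frequency-modulation features.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.signal.windows import dpss

from .audio_io import Waveform


class InputTooShortError(ValueError):
    """Signal shorter than one analysis window."""


@dataclass(frozen=True)
class SpectralConfig:
    """Parameters of the multitaper spectrogram.

    Attributes
    ----------
    n_tapers : int
        Number of DPSS tapers averaged (default 8).
    window_ms : float
        Analysis window length in ms (default 10).
    step_ms : float
        Hop between successive frames in ms (default 1).
    half_bandwidth_khz : float
        Half-bandwidth of spectral concentration in kHz (default 0.5);
        together with ``window_ms`` this fixes the time-bandwidth product
        NW = window_s * half_bandwidth_hz.
    derivative_scheme : str
        ``"finite_difference"`` (central differences, default) — the only
        scheme currently implemented; the field exists so alternative
        directional-derivative estimators can be plugged in.
    log_power_derivatives : bool
        Differentiate log power (default) rather than linear power.
    """

    n_tapers: int = 8
    window_ms: float = 10.0
    step_ms: float = 1.0
    half_bandwidth_khz: float = 0.5
    derivative_scheme: str = "finite_difference"
    log_power_derivatives: bool = True

    def __post_init__(self) -> None:
        if self.n_tapers < 1:
            raise ValueError("n_tapers must be >= 1")
        if not (self.window_ms > self.step_ms > 0):
            raise ValueError("require window_ms > step_ms > 0")
        if 2 * self.nw < self.n_tapers + 1:
            raise ValueError(
                f"time-bandwidth product NW={self.nw} too small for "
                f"{self.n_tapers} tapers (need NW >= (n_tapers+1)/2)"
            )
        if self.derivative_scheme not in ("finite_difference",):
            raise ValueError(f"unknown derivative_scheme {self.derivative_scheme!r}")

    @property
    def nw(self) -> float:
        """Time-bandwidth product."""
        return self.window_ms / 1000.0 * self.half_bandwidth_khz * 1000.0


@dataclass
class SpectrogramSet:
    """Multitaper power spectrogram and its time/frequency derivatives.

    ``power`` is indexed ``(frequency, time)``; ``times`` are frame centers
    in ms, ``freqs`` in Hz. ``d_time`` is in power (or log-power) units per
    ms, ``d_freq`` per kHz; both are ``None`` until
    :func:`spectral_derivatives` populates them.
    """

    times: np.ndarray
    freqs: np.ndarray
    power: np.ndarray
    sample_rate: float
    config: SpectralConfig
    d_time: np.ndarray | None = field(default=None)
    d_freq: np.ndarray | None = field(default=None)

    @property
    def n_frames(self) -> int:
        return self.times.size


def _next_pow2(n: int) -> int:
    return 1 << (int(n) - 1).bit_length()


def multitaper_spectrogram(w: Waveform, cfg: SpectralConfig | None = None) -> SpectrogramSet:
    """Compute the multitaper power spectrogram of a waveform.

    power(f, t) is the mean over tapers of the squared magnitude of the
    tapered FFT of the frame centered at ``t``. The FFT length is the next
    power of two >= the window length in samples (zero-padding only refines
    frequency sampling; resolution is set by the window and NW).
    """
    cfg = cfg or SpectralConfig()
    fs = w.sample_rate
    win = int(round(cfg.window_ms * fs / 1000.0))
    hop = max(1, int(round(cfg.step_ms * fs / 1000.0)))
    x = w.samples
    if x.size < win:
        raise InputTooShortError(
            f"signal of {x.size} samples shorter than the {win}-sample analysis window"
        )
    nfft = _next_pow2(win)
    tapers = dpss(win, cfg.nw, Kmax=cfg.n_tapers)  # (k, win), unit energy
    frames = sliding_window_view(x, win)[::hop]  # (n_frames, win)
    # (n_frames, k, nbins) -> averaged over tapers
    spec = np.fft.rfft(frames[:, np.newaxis, :] * tapers[np.newaxis, :, :], n=nfft, axis=-1)
    power = np.mean(np.abs(spec) ** 2, axis=1).T  # (nbins, n_frames)
    n_frames = frames.shape[0]
    times = (np.arange(n_frames) * hop + (win - 1) / 2.0) / fs * 1000.0
    freqs = np.fft.rfftfreq(nfft, d=1.0 / fs)
    return SpectrogramSet(times=times, freqs=freqs, power=power, sample_rate=fs, config=cfg)


def spectral_derivatives(sg: SpectrogramSet, cfg: SpectralConfig | None = None) -> SpectrogramSet:
    """Populate ``d_time`` and ``d_freq`` by finite differences.

    Central differences at interior points, one-sided at the edges. By
    default the derivative is taken on log power (with a per-recording
    floor at 1e-12 of the maximum, so silence does not produce -inf);
    set ``log_power_derivatives=False`` in the config for linear power.
    Units: per ms along time, per kHz along frequency.
    """
    cfg = cfg or sg.config
    s = sg.power
    if cfg.log_power_derivatives:
        floor = 1e-12 * max(float(s.max()), np.finfo(float).tiny)
        s = np.log(s + floor)
    # scalar spacings keep the central differences exact for constant input
    if sg.n_frames > 1:
        d_time = np.gradient(s, float(sg.times[1] - sg.times[0]), axis=1)
    else:
        d_time = np.zeros_like(s)
    d_freq = np.gradient(s, float(sg.freqs[1] - sg.freqs[0]) / 1000.0, axis=0)
    return replace(sg, d_time=d_time, d_freq=d_freq)
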