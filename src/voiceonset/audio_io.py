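"""Reading, writing and standardizing trial waveforms.

One WAV file holds one trial (one spoken response). Multi-channel files are
averaged to mono; samples are kept on their native scale until
:func:`standardize` converts them to z-scores, which is how every downstream
spectral computation expects them.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, replace

import numpy as np
from scipy.io import wavfile


class AudioFormatError(ValueError):
    """Raised for unreadable, corrupt or zero-length audio files."""


class DegenerateSignalError(ValueError):
    """Raised when an operation requires a non-constant signal."""


@dataclass(frozen=True)
class Waveform:
    """A mono trial recording.

    Parameters
    ----------
    samples : ndarray of float
        Amplitude sequence; dimensionless after standardization.
    sample_rate : float
        Sampling rate in Hz.
    trial_id : str
        Identifier used to pair the trial with manual ratings.
    """

    samples: np.ndarray
    sample_rate: float
    trial_id: str = ""

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=np.float64)
        object.__setattr__(self, "samples", samples)
        if self.sample_rate <= 0:
            raise ValueError(f"sample_rate must be positive, got {self.sample_rate}")
        if samples.ndim != 1:
            raise ValueError("Waveform samples must be one-dimensional")
        if samples.size and not np.all(np.isfinite(samples)):
            raise ValueError("Waveform contains non-finite samples")

    @property
    def duration_ms(self) -> float:
        return 1000.0 * self.samples.size / self.sample_rate


def read_wav(path: str | os.PathLike) -> Waveform:
    """Read a RIFF WAVE file into a mono :class:`Waveform`.

    Integer PCM (16/24/32-bit) and IEEE float encodings are accepted.
    Multi-channel audio is averaged across channels; the sample rate is
    preserved and no resampling is performed.
    """
    try:
        rate, data = wavfile.read(os.fspath(path))
    except (ValueError, OSError) as exc:
        raise AudioFormatError(f"cannot read WAV file {path!r}: {exc}") from exc
    data = np.asarray(data, dtype=np.float64)
    if data.size == 0:
        raise AudioFormatError(f"zero-length audio in {path!r}")
    if data.ndim == 2:
        data = data.mean(axis=1)
    trial_id = os.path.splitext(os.path.basename(os.fspath(path)))[0]
    return Waveform(samples=data, sample_rate=float(rate), trial_id=trial_id)


def write_wav(path: str | os.PathLike, w: Waveform, encoding: str = "float32") -> None:
    """Write a waveform to disk (``float32`` or ``pcm16`` encoding)."""
    if encoding == "float32":
        wavfile.write(os.fspath(path), int(round(w.sample_rate)), w.samples.astype(np.float32))
    elif encoding == "pcm16":
        peak = np.max(np.abs(w.samples)) or 1.0
        scaled = np.round(w.samples / peak * 32767).astype(np.int16)
        wavfile.write(os.fspath(path), int(round(w.sample_rate)), scaled)
    else:
        raise ValueError(f"unknown encoding {encoding!r}")


def standardize(w: Waveform) -> Waveform:
    """Z-score the waveform: output has sample mean 0 and sample SD 1.

    Standardization makes the analysis invariant to recording gain and DC
    offset. Raises :class:`DegenerateSignalError` for constant signals.
    """
    sd = float(np.std(w.samples))
    if sd == 0.0 or np.ptp(w.samples) == 0.0:
        raise DegenerateSignalError(
            f"trial {w.trial_id or '<unnamed>'}: constant signal cannot be standardized"
        )
    return replace(w, samples=(w.samples - np.mean(w.samples)) / sd)
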