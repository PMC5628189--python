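"""End-to-end helpers: waveform -> features -> onset estimate.

Thin glue over the analysis modules, used by the CLI, the examples and
the test suite. Feature extraction is the expensive step, so the batch
helpers compute each trial's :class:`FeatureMatrix` once and reuse it for
any number of detection or optimization passes.
"""

from __future__ import annotations

import json
import os
from importlib import resources

from .audio_io import Waveform, standardize
from .detection import DetectionConfig, OnsetEstimate, ThresholdSet, detect_batch, detect_onset
from .features import FeatureMatrix, extract_features
from .spectral import SpectralConfig, multitaper_spectrogram, spectral_derivatives


def compute_features(
    w: Waveform,
    spectral_cfg: SpectralConfig | None = None,
    smooth_ms: float = 10.0,
    standardize_first: bool = True,
) -> FeatureMatrix:
    """Standardize, compute the multitaper spectrogram, derive the features."""
    if standardize_first:
        w = standardize(w)
    sg = spectral_derivatives(multitaper_spectrogram(w, spectral_cfg))
    return extract_features(sg, smooth_ms=smooth_ms, trial_id=w.trial_id)


def detect_waveform(
    w: Waveform,
    th: ThresholdSet | None = None,
    spectral_cfg: SpectralConfig | None = None,
    det_cfg: DetectionConfig | None = None,
) -> OnsetEstimate:
    """Full single-trial pipeline with the default (or given) thresholds."""
    th = th or default_thresholds()
    return detect_onset(compute_features(w, spectral_cfg), th, det_cfg)


def detect_waveforms(
    waveforms,
    th: ThresholdSet | None = None,
    spectral_cfg: SpectralConfig | None = None,
    det_cfg: DetectionConfig | None = None,
) -> list[OnsetEstimate]:
    th = th or default_thresholds()
    fms = [compute_features(w, spectral_cfg) for w in waveforms]
    return detect_batch(fms, th, det_cfg)


def save_thresholds(th: ThresholdSet, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        json.dump(th.thresholds, fh, indent=2, sort_keys=True)
        fh.write("\n")


def load_thresholds(path: str | os.PathLike) -> ThresholdSet:
    with open(path) as fh:
        return ThresholdSet(json.load(fh))


def default_thresholds() -> ThresholdSet:
    """Thresholds shipped with the package, optimized on a synthetic corpus."""
    text = resources.files("voiceonset").joinpath("data/default_thresholds.json").read_text()
    return ThresholdSet(json.loads(text))
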