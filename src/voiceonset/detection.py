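"""Sustained multi-feature threshold detection of speech onset.

A frame counts toward detection when a feature exceeds its threshold in
the speech-oriented normalized feature matrix. Speech onset is detected at
the earliest run of frames in which at least ``min_features`` of the six
features are simultaneously elevated for at least ``sustain_ms`` (35 ms by
default) — long enough to reject loud but brief pre-vocal transients such
as lip smacks. Within that window the onset is refined to the first frame
at which the amplitude feature is elevated, which catches low-amplitude
unvoiced onsets ([s], [f], [p]) that precede the harmonic region.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .features import FEATURE_NAMES, FeatureMatrix


@dataclass(frozen=True)
class ThresholdSet:
    """One threshold in [0, 1] per feature (the optimized parameter vector).

    A threshold of 1.0 disables its feature: comparison is strict, and
    normalized features never exceed 1.
    """

    thresholds: dict[str, float]

    def __post_init__(self) -> None:
        if set(self.thresholds) != set(FEATURE_NAMES):
            raise ValueError(
                f"thresholds must have exactly the keys {sorted(FEATURE_NAMES)}, "
                f"got {sorted(self.thresholds)}"
            )
        for name, v in self.thresholds.items():
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"threshold for {name} outside [0, 1]: {v}")

    @classmethod
    def uniform(cls, value: float = 0.5) -> "ThresholdSet":
        return cls({name: value for name in FEATURE_NAMES})

    @classmethod
    def from_array(cls, values) -> "ThresholdSet":
        return cls(dict(zip(FEATURE_NAMES, map(float, values))))

    def as_array(self) -> np.ndarray:
        return np.array([self.thresholds[name] for name in FEATURE_NAMES])

    def __getitem__(self, name: str) -> float:
        return self.thresholds[name]


@dataclass(frozen=True)
class DetectionConfig:
    """Parameters of the sustained-threshold rule.

    ``min_features`` of the six must be elevated simultaneously for
    ``sustain_ms``; ``refine_with_amplitude`` moves the onset to the first
    amplitude-elevated frame within the qualifying window. ``edge_ms``
    frames at each end of the recording are excluded (spectral derivative
    edge bias).
    """

    min_features: int = 4
    sustain_ms: float = 35.0
    refine_with_amplitude: bool = True
    edge_ms: float = 10.0

    def __post_init__(self) -> None:
        if not (1 <= self.min_features <= len(FEATURE_NAMES)):
            raise ValueError("min_features must be in 1..6")
        if self.sustain_ms <= 0:
            raise ValueError("sustain_ms must be positive")


@dataclass(frozen=True)
class OnsetEstimate:
    """Detected onset/offset latency for one trial (ms from recording start)."""

    trial_id: str
    detected: bool
    onset_ms: float | None = None
    offset_ms: float | None = None
    n_features_at_onset: int = 0
    error: str | None = field(default=None, compare=False)


def detect_onset(
    fm: FeatureMatrix,
    th: ThresholdSet,
    cfg: DetectionConfig | None = None,
) -> OnsetEstimate:
    """Apply the sustained multi-feature rule to one feature matrix.

    Absence of a qualifying run is a valid result (``detected=False``),
    not an error.
    """
    cfg = cfg or DetectionConfig()
    above = fm.values > th.as_array()[np.newaxis, :]  # strict: th=1 disables
    q = above.sum(axis=1)
    ok = q >= cfg.min_features
    if cfg.edge_ms > 0:
        edge = int(round(cfg.edge_ms / fm.step_ms))
        if edge > 0:
            ok = ok.copy()
            ok[:edge] = False
            if edge < ok.size:
                ok[-edge:] = False
    need = max(1, math.ceil(cfg.sustain_ms / fm.step_ms))
    start, end = _first_run(ok, need)
    if start is None:
        return OnsetEstimate(trial_id=fm.trial_id, detected=False)
    onset_idx = start
    if cfg.refine_with_amplitude:
        amp_above = above[start:end, FEATURE_NAMES.index("amplitude")]
        hits = np.flatnonzero(amp_above)
        if hits.size:
            onset_idx = start + int(hits[0])
    return OnsetEstimate(
        trial_id=fm.trial_id,
        detected=True,
        onset_ms=float(fm.times[onset_idx]),
        offset_ms=float(fm.times[end - 1]),
        n_features_at_onset=int(q[onset_idx]),
    )


def _first_run(ok: np.ndarray, need: int) -> tuple[int | None, int | None]:
    """Start/stop (half-open) of the earliest True-run of length >= need."""
    if not ok.any():
        return None, None
    padded = np.concatenate(([False], ok, [False]))
    diff = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(diff == 1)
    ends = np.flatnonzero(diff == -1)
    long_enough = np.flatnonzero(ends - starts >= need)
    if long_enough.size == 0:
        return None, None
    i = long_enough[0]
    return int(starts[i]), int(ends[i])


def detect_batch(
    feature_matrices,
    th: ThresholdSet,
    cfg: DetectionConfig | None = None,
) -> list[OnsetEstimate]:
    """Detect onsets for many trials; per-trial failures are collected.

    Trials are independent, so results do not depend on processing order.
    """
    out = []
    for fm in feature_matrices:
        try:
            out.append(detect_onset(fm, th, cfg))
        except Exception as exc:  # noqa: BLE001 - per-file errors must not kill the batch
            out.append(OnsetEstimate(trial_id=getattr(fm, "trial_id", ""), detected=False, error=str(exc)))
    return out


def estimates_to_frame(estimates) -> pd.DataFrame:
    """Tabulate onset estimates (trial_id, onset_ms, offset_ms, ...)."""
    return pd.DataFrame(
        {
            "trial_id": [e.trial_id for e in estimates],
            "onset_ms": [e.onset_ms if e.detected else np.nan for e in estimates],
            "offset_ms": [e.offset_ms if e.detected else np.nan for e in estimates],
            "detected": [e.detected for e in estimates],
            "n_features_at_onset": [e.n_features_at_onset for e in estimates],
        }
    )
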