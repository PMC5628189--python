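"""Mixture-of-experts combination of two onset estimators.

Some estimators are extremely precise most of the time but occasionally
fail badly; others are less precise but robust. Per trial, the combined
estimate takes the precise expert unless the two experts disagree by at
least ``cutoff_ms`` (55 ms by default), in which case the disagreement is
taken as evidence of a gross failure and the robust expert's value is
used instead. The cutoff is the crossover of the two experts' cumulative
|AD|-score distributions: the error size beyond which the robust expert
is more often the better one.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class MixtureConfig:
    cutoff_ms: float = 55.0

    def __post_init__(self) -> None:
        if self.cutoff_ms <= 0:
            raise ValueError("cutoff_ms must be positive")


def combine(precise, robust, cfg: MixtureConfig | None = None) -> np.ndarray:
    """Per-trial gating of two paired latency lists.

    out[i] = precise[i] if |precise[i] - robust[i]| < cutoff else robust[i].
    A missing value (NaN) in one input falls back to the other; both
    missing propagates NaN.
    """
    cfg = cfg or MixtureConfig()
    p = np.asarray(precise, dtype=float)
    r = np.asarray(robust, dtype=float)
    if p.shape != r.shape:
        raise ValueError("precise and robust estimates must be paired")
    out = np.where(np.abs(p - r) < cfg.cutoff_ms, p, r)
    out = np.where(np.isnan(p), r, out)
    out = np.where(np.isnan(r), np.where(np.isnan(p), np.nan, p), out)
    return out


def find_crossover(grid, cdf_a, cdf_b) -> float | None:
    """Smallest grid point beyond which CDF_a >= CDF_b for all larger points.

    ``cdf_a``/``cdf_b`` are cumulative |AD| distributions on a common
    increasing grid. Dominance must persist to the end of the grid
    (empirical CDFs wiggle, so a single touching point is not a
    crossover). Returns ``None`` when estimator a never ends up dominant.
    """
    grid = np.asarray(grid, dtype=float)
    a = np.asarray(cdf_a, dtype=float)
    b = np.asarray(cdf_b, dtype=float)
    if not (grid.shape == a.shape == b.shape):
        raise ValueError("grid and CDFs must share a shape")
    for arr, name in ((a, "cdf_a"), (b, "cdf_b")):
        if np.any(np.diff(arr) < 0):
            raise ValueError(f"{name} is not non-decreasing")
    dominated = a >= b
    if not dominated[-1]:
        return None
    # walk back from the end to the last violation
    viol = np.flatnonzero(~dominated)
    if viol.size == 0:
        return float(grid[0])
    return float(grid[viol[-1] + 1])
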