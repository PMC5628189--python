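"""Threshold tuning against manually rated onsets.

The six detection thresholds are tuned by stochastic descent: propose a
small Gaussian perturbation of one threshold, re-run detection on cached
feature matrices, and accept the move iff it lowers the training
objective. The objective is the maximum-likelihood standard deviation of
the residuals from regressing the consensus manual onsets on the
automatic onsets — measuring spread around the fitted line rather than
raw agreement, so neither a constant rater bias nor a constant algorithm
bias is penalized. Trials the detector misses are excluded from the
regression and penalized by scaling the objective by n_total/n_detected,
which stops the search from "improving" by detecting nothing.

The search runs on repeated random train/test partitions; the thresholds
returned are those of the partition with the smallest test objective
(ties broken by the largest test R^2).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .detection import DetectionConfig, ThresholdSet, detect_onset
from .features import FEATURE_NAMES, FeatureMatrix

#: objective value returned for degenerate regressions (no spread, too few trials)
INFEASIBLE = float("inf")


class InsufficientDataError(ValueError):
    """Too few rated trials to form train and test sets."""


@dataclass(frozen=True)
class RatedTrial:
    """A trial with its precomputed features and consensus manual onset."""

    trial_id: str
    features: FeatureMatrix
    manual_onset_ms: float

    @classmethod
    def from_ratings(cls, trial_id: str, features: FeatureMatrix, ratings_ms) -> "RatedTrial":
        """Build from per-rater latencies; the consensus is their mean."""
        return cls(trial_id, features, float(np.mean(np.asarray(ratings_ms, dtype=float))))


@dataclass(frozen=True)
class OptimizationConfig:
    train_fraction: float = 0.8
    max_attempts: int = 1000
    patience: int = 50
    n_partitions: int = 100
    proposal_scale: float = 0.05
    initial_threshold: float = 0.5
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.train_fraction < 1.0):
            raise ValueError("train_fraction must be in (0, 1)")
        if self.patience > self.max_attempts:
            raise ValueError("patience must not exceed max_attempts")


@dataclass
class PartitionTrace:
    """Diagnostics for one train/test partition."""

    thresholds: ThresholdSet
    train_objective: list[float]  # accepted-move trace, non-increasing
    test_sd: float
    test_r2: float
    n_attempts: int


@dataclass
class OptimizationResult:
    thresholds: ThresholdSet
    test_sd: float
    test_r2: float
    partitions: list[PartitionTrace] = field(default_factory=list)


def residual_sd_objective(auto_onsets, manual_onsets) -> float:
    """ML estimate of the SD of residuals of manual regressed on automatic.

    Fits manual = b0 + b1*auto by ordinary least squares and returns
    sqrt(sum(e^2)/n) (divisor n, the maximum-likelihood estimate). Returns
    ``inf`` when fewer than 3 pairs remain or the automatic onsets have
    zero variance (a degenerate regression carries no information).
    """
    x = np.asarray(auto_onsets, dtype=float)
    y = np.asarray(manual_onsets, dtype=float)
    if x.shape != y.shape:
        raise ValueError("auto and manual onset lists must be paired")
    if x.size < 3 or np.ptp(x) == 0.0:
        return INFEASIBLE
    b1, b0 = np.polyfit(x, y, 1)
    resid = y - (b0 + b1 * x)
    return float(np.sqrt(np.mean(resid**2)))


def _r_squared(auto, manual) -> float:
    x = np.asarray(auto, float)
    y = np.asarray(manual, float)
    if x.size < 3 or np.ptp(x) == 0.0 or np.ptp(y) == 0.0:
        return 0.0
    return float(np.corrcoef(x, y)[0, 1] ** 2)


def _evaluate(
    trials: list[RatedTrial],
    th: ThresholdSet,
    det_cfg: DetectionConfig,
) -> tuple[float, float, np.ndarray, np.ndarray]:
    """Penalized objective and R^2 of thresholds on a set of rated trials."""
    auto, manual = [], []
    for tr in trials:
        est = detect_onset(tr.features, th, det_cfg)
        if est.detected:
            auto.append(est.onset_ms)
            manual.append(tr.manual_onset_ms)
    auto_a = np.asarray(auto)
    manual_a = np.asarray(manual)
    sd = residual_sd_objective(auto_a, manual_a)
    if np.isfinite(sd) and len(auto) < len(trials):
        sd *= len(trials) / len(auto)  # undetected-trial penalty
    return sd, _r_squared(auto_a, manual_a), auto_a, manual_a


def optimize_thresholds(
    trials: list[RatedTrial],
    det_cfg: DetectionConfig | None = None,
    opt_cfg: OptimizationConfig | None = None,
) -> OptimizationResult:
    """Stochastic-descent threshold search over random train/test partitions.

    Deterministic given ``opt_cfg.rng_seed``. Requires enough trials for
    at least 3 in each of the train and test splits.
    """
    det_cfg = det_cfg or DetectionConfig()
    opt_cfg = opt_cfg or OptimizationConfig()
    n = len(trials)
    n_train = int(round(opt_cfg.train_fraction * n))
    if n_train < 3 or n - n_train < 3:
        raise InsufficientDataError(
            f"{n} trials leave train={n_train}, test={n - n_train}; need >= 3 in each"
        )
    rng = np.random.default_rng(opt_cfg.rng_seed)
    partitions: list[PartitionTrace] = []
    for _ in range(opt_cfg.n_partitions):
        order = rng.permutation(n)
        train = [trials[i] for i in order[:n_train]]
        test = [trials[i] for i in order[n_train:]]
        th = ThresholdSet.uniform(opt_cfg.initial_threshold)
        best, _, _, _ = _evaluate(train, th, det_cfg)
        trace = [best]
        fails = 0
        attempts = 0
        while attempts < opt_cfg.max_attempts and fails < max(opt_cfg.patience, 1):
            if opt_cfg.patience == 0:
                break
            attempts += 1
            vec = th.as_array()
            j = rng.integers(len(FEATURE_NAMES))
            vec[j] = np.clip(vec[j] + rng.normal(0.0, opt_cfg.proposal_scale), 0.0, 1.0)
            cand = ThresholdSet.from_array(vec)
            obj, _, _, _ = _evaluate(train, cand, det_cfg)
            if obj < best:
                th, best = cand, obj
                trace.append(best)
                fails = 0
            else:
                fails += 1
        test_sd, test_r2, _, _ = _evaluate(test, th, det_cfg)
        partitions.append(
            PartitionTrace(
                thresholds=th,
                train_objective=trace,
                test_sd=test_sd,
                test_r2=test_r2,
                n_attempts=attempts,
            )
        )
    best_part = min(partitions, key=lambda p: (p.test_sd, -p.test_r2))
    return OptimizationResult(
        thresholds=best_part.thresholds,
        test_sd=best_part.test_sd,
        test_r2=best_part.test_r2,
        partitions=partitions,
    )
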