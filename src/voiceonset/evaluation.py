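"""Benchmarking automatic onsets against manual ratings.

Two complementary accuracy measures are reported. Absolute-difference
(AD) scores — manual minus automatic latency per trial — are the field's
traditional precision measure but punish any constant bias. Regression
residuals — from regressing manual onsets on automatic onsets — forgive
constant bias (absorbed into the intercept) while exposing outliers and
unsystematic error. A constant shift of every automatic onset moves the
regression offset and every AD score, but leaves R^2, the residuals and
the residual SD untouched; the two families therefore disagree exactly
when an algorithm is biased but systematic, which is why both are
reported. Inter-rater reliability of the manual ratings themselves is
quantified by the intraclass correlation from a two-way mixed-effects
model (single measures).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats


class PairingError(ValueError):
    """Manual and automatic onset lists differ in length."""


class DegenerateRegressionError(ValueError):
    """Regression undefined (too few pairs or zero-variance predictor)."""


class IncompleteDesignError(ValueError):
    """Ratings matrix has missing cells; the two-way ANOVA needs all of them."""


@dataclass
class ADSummary:
    """Signed difference scores (manual - automatic) and |AD| summaries."""

    differences: np.ndarray  # signed, ms
    prop_within_10ms: float
    sd_abs: float
    sd_signed: float
    n_excluded: int  # pairs dropped for undetected automatic onsets
    cdf_grid: np.ndarray
    cdf: np.ndarray  # CDF of |AD| on cdf_grid


@dataclass
class RegressionSummary:
    offset: float  # beta0, ms
    slope: float  # beta1
    r_squared: float
    residuals: np.ndarray  # e-hat = observed manual - predicted manual, ms
    residual_sd: float  # ML estimate, divisor n
    prop_resid_within_10ms: float
    cdf_grid: np.ndarray
    cdf: np.ndarray  # CDF of |residual| on cdf_grid


@dataclass
class EvaluationReport:
    n_pairs: int
    n_excluded: int
    ad: ADSummary
    regression: RegressionSummary


@dataclass(frozen=True)
class ICCResult:
    icc: float
    model: str  # e.g. "ICC(3,1) two-way mixed, single measures, consistency"
    n_trials: int
    n_raters: int


def _paired(manual, auto) -> tuple[np.ndarray, np.ndarray, int]:
    y = np.asarray(manual, dtype=float)
    x = np.asarray(auto, dtype=float)
    if y.shape != x.shape:
        raise PairingError(f"length mismatch: {y.size} manual vs {x.size} automatic")
    keep = np.isfinite(x) & np.isfinite(y)
    return y[keep], x[keep], int((~keep).sum())


def _cdf(values: np.ndarray, grid: np.ndarray | None = None) -> tuple[np.ndarray, np.ndarray]:
    if grid is None:
        hi = float(values.max()) if values.size else 1.0
        grid = np.linspace(0.0, max(hi, 1.0), 201)
    cdf = np.searchsorted(np.sort(values), grid, side="right") / max(values.size, 1)
    return grid, cdf


def ad_scores(manual, auto, grid: np.ndarray | None = None) -> ADSummary:
    """Difference scores between manual and automatic latencies.

    Signed differences d = manual - auto are retained; the proportion
    within 10 ms, SDs, and the CDF are computed on |d|. Pairs with an
    undetected automatic onset (NaN) are excluded and counted.
    """
    y, x, n_excluded = _paired(manual, auto)
    d = y - x
    abs_d = np.abs(d)
    grid, cdf = _cdf(abs_d, grid)
    return ADSummary(
        differences=d,
        prop_within_10ms=float(np.mean(abs_d <= 10.0)) if d.size else float("nan"),
        sd_abs=float(np.std(abs_d)) if d.size else float("nan"),
        sd_signed=float(np.std(d)) if d.size else float("nan"),
        n_excluded=n_excluded,
        cdf_grid=grid,
        cdf=cdf,
    )


def regression_fit(manual, auto, grid: np.ndarray | None = None) -> RegressionSummary:
    """OLS fit of manual onsets on automatic onsets.

    Reports the intercept as "offset" (the algorithm's constant bias in
    ms), the slope, R^2 (squared Pearson correlation), the residuals
    e-hat, and their ML standard deviation (divisor n).
    """
    y, x, _ = _paired(manual, auto)
    if y.size < 3:
        raise DegenerateRegressionError(f"need >= 3 pairs, got {y.size}")
    if np.ptp(x) == 0.0:
        raise DegenerateRegressionError("automatic onsets have zero variance")
    fit = stats.linregress(x, y)
    resid = y - (fit.intercept + fit.slope * x)
    abs_r = np.abs(resid)
    grid, cdf = _cdf(abs_r, grid)
    return RegressionSummary(
        offset=float(fit.intercept),
        slope=float(fit.slope),
        r_squared=float(fit.rvalue**2),
        residuals=resid,
        residual_sd=float(np.sqrt(np.mean(resid**2))),
        prop_resid_within_10ms=float(np.mean(abs_r <= 10.0)),
        cdf_grid=grid,
        cdf=cdf,
    )


def evaluate(manual, auto) -> EvaluationReport:
    """Full report: AD summaries plus regression fit on the detected pairs."""
    y, x, n_excluded = _paired(manual, auto)
    return EvaluationReport(
        n_pairs=int(y.size),
        n_excluded=n_excluded,
        ad=ad_scores(y, x),
        regression=regression_fit(y, x),
    )


def icc(ratings, variant: str = "consistency") -> ICCResult:
    """Intraclass correlation of a trials x raters matrix.

    Two-way mixed-effects model, single measures. The default
    ``consistency`` variant, ICC(3,1) = (MS_R - MS_E) / (MS_R + (k-1) MS_E),
    ignores constant rater offsets; ``agreement`` (ICC(2,1)-style, raters
    as the fixed second factor) also charges rater mean differences to
    disagreement. Requires a complete matrix of >= 3 trials by >= 2 raters.
    """
    m = np.asarray(ratings, dtype=float)
    if m.ndim != 2:
        raise ValueError("ratings must be a 2-D trials x raters matrix")
    n, k = m.shape
    if n < 3 or k < 2:
        raise ValueError(f"need >= 3 trials and >= 2 raters, got {n} x {k}")
    if not np.all(np.isfinite(m)):
        raise IncompleteDesignError("ratings matrix contains missing cells")
    grand = m.mean()
    row_means = m.mean(axis=1)
    col_means = m.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_total = np.sum((m - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols
    ms_rows = ss_rows / (n - 1)
    ms_cols = ss_cols / (k - 1)
    ms_err = ss_err / ((n - 1) * (k - 1))
    if variant == "consistency":
        denom = ms_rows + (k - 1) * ms_err
        value = 0.0 if denom == 0.0 else (ms_rows - ms_err) / denom
        model = "ICC(3,1) two-way mixed, single measures, consistency"
    elif variant == "agreement":
        denom = ms_rows + (k - 1) * ms_err + k / n * (ms_cols - ms_err)
        value = 0.0 if denom == 0.0 else (ms_rows - ms_err) / denom
        model = "ICC(A,1) two-way, single measures, absolute agreement"
    else:
        raise ValueError(f"unknown ICC variant {variant!r}")
    return ICCResult(icc=float(value), model=model, n_trials=n, n_raters=k)


def grouped_report(manual, auto, labels) -> dict:
    """One :class:`EvaluationReport` per group label.

    A generic split-by-category evaluation (e.g. by initial phoneme class
    or pitch band). Groups with fewer than 3 usable pairs are skipped with
    a warning.
    """
    y = np.asarray(manual, dtype=float)
    x = np.asarray(auto, dtype=float)
    labels = np.asarray(labels)
    if not (y.size == x.size == labels.size):
        raise PairingError("labels must align with the onset pairs")
    out: dict = {}
    for g in sorted(map(str, np.unique(labels))):
        sel = labels.astype(str) == g
        usable = np.isfinite(x[sel]) & np.isfinite(y[sel])
        if usable.sum() < 3:
            warnings.warn(f"group {g!r} has fewer than 3 usable trials; skipped", stacklevel=2)
            continue
        out[g] = evaluate(y[sel], x[sel])
    return out
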