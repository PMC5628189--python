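# voiceonset

Automatic detection of speech-onset latencies in reaction-time experiments.

In naming and reading-aloud paradigms the dependent measure is the time
from stimulus to the first acoustic evidence of the spoken response.
Classic amplitude-threshold voice keys trigger on anything loud — lip
smacks, coughs, breath — and miss quiet unvoiced onsets like [s] or [f].
`voiceonset` instead detects speech from six acoustic features computed
on a multitaper spectrogram, requires the evidence to be *sustained*, and
ships the statistical machinery to tune and validate the detector against
human raters.

## The method

Each mono WAV trial is z-scored and analyzed with a multitaper
spectrogram (k = 8 DPSS tapers, 10 ms windows, 1 ms steps, ±0.5 kHz
half-bandwidth), from which six per-frame features are derived:

| feature | definition | speech signature |
|---|---|---|
| amplitude | log ∑ power, 0.15–22.05 kHz | loud |
| Wiener entropy | GM/AM of the spectrum | peaked spectrum (low WE) |
| spectral change | ∑_f √((∂S/∂t)² + (∂S/∂f)²) | non-stationary |
| amplitude modulation | ∑_f ∂S/∂t | energy rising at onset |
| frequency modulation | arctan(max|∂S/∂t| / max|∂S/∂f|) | stable bands (low FM) |
| harmonic pitch | peak cepstral magnitude, 2–20 ms quefrency | harmonic stack |

Features are Gaussian-smoothed (10 ms FWHM), min–max normalized to [0, 1]
per recording (entropy and FM complemented so "elevated" always means
speech-like), and thresholded: **the onset is the earliest run in which at
least 4 of the 6 features stay above their thresholds for 35 ms**,
refined to the first amplitude-elevated frame inside that run so quiet
unvoiced prefixes are kept. Brief loud transients fail the sustain rule
and are ignored.

The six thresholds θ ∈ [0,1]⁶ are tuned against manually rated onsets by
stochastic descent on the maximum-likelihood SD of the residuals of
y = β₀ + β₁x + e (manual on automatic), over repeated random 80/20
train/test partitions — a bias-insensitive objective. Evaluation reports
both absolute-difference (AD) scores and regression residuals, plus the
two-way mixed-effects ICC(3,1) of the raters. A mixture-of-experts rule
combines two estimators, taking the precise one unless they disagree by
≥ 55 ms. Finally, a Monte Carlo module quantifies the power cost of
measurement error: the index d = (nt1 − nt2)/nt1 compares significant
paired-t outcomes with error-free vs error-laden latencies.

## Worked example

`examples/detect_onset.py` builds a synthetic trial with a voiced onset
at 700 ms and a loud 20 ms burst at 300 ms, then detects:

```
ground-truth onset :   700.0 ms
detected onset     :   711.0 ms
detected offset    :  1785.0 ms
features elevated  : 6 of 6
```

The detector lands within ~10 ms of the true onset and ignores the
burst, which is far louder than the speech but cannot stay elevated for
35 ms. The other example scripts cover threshold optimization
(`optimize_thresholds.py`, held-out residual SD ≈ 3.5 ms against raters
with 5 ms jitter), evaluation statistics (`evaluate_detector.py`,
R² ≈ 0.9996 on 40 trials), the estimator mixture
(`mixture_of_experts.py`) and the power simulation
(`power_loss_simulation.py`).

A thin CLI mirrors the library:

```
voiceonset generate-fixtures --out-dir fixtures --n-trials 50 --seed 1
voiceonset detect --in fixtures --out onsets.tsv
voiceonset evaluate --manual fixtures/ratings.tsv --auto onsets.tsv --out report.json
voiceonset optimize --audio-dir fixtures --ratings fixtures/ratings.tsv --out thresholds.json
voiceonset simulate-power --seed 1 --out grid.tsv
```

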