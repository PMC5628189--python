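# Methods

## Signal model and spectral analysis

A trial is a mono waveform containing stationary background noise and,
somewhere after trial start, a spoken response. The waveform is z-scored
once per recording (gain/DC invariance) and analyzed with a multitaper
spectrogram: 10 ms windows every 1 ms, k = 8 discrete prolate spheroidal
tapers. With the ±0.5 kHz half-bandwidth this is a time–bandwidth product
of NW = 5, which admits up to 2NW − 1 = 9 well-concentrated tapers; we
use the first 8. The FFT length is the next power of two at or above the
window length; zero-padding refines frequency sampling but not
resolution. Frame times are window centers, so a 1 ms step gives 1 ms
onset granularity.

Derivatives over time and frequency are central finite differences
(one-sided at edges), by default on log power with a floor of 1e-12 of
the recording's maximum power — log-domain processing matches the
explicitly logarithmic amplitude feature and keeps derivative magnitudes
comparable across the spectrogram's dynamic range. Linear-power
derivatives are a config switch. Derivative units are per ms and per kHz,
which keeps the two axes on numerically comparable scales for the
features that mix them.

## The six features

Per frame: amplitude (log band power, 0.15–22.05 kHz, clipped to
Nyquist), Wiener entropy (geometric/arithmetic mean of the spectrum,
gain-invariant, 1 for flat spectra), spectral change (summed gradient
magnitude √(d_t² + d_f²) across bins), amplitude modulation (summed time
derivative), frequency modulation (arctan of the ratio of maximal
absolute time- to frequency-derivative) and harmonic pitch (peak
cepstral magnitude in a quefrency band).

Harmonic pitch deserves detail: the cepstrum is the real-FFT magnitude
of the per-frame log power spectrum (mean-removed, zero-padded 4× for
denser quefrency sampling). The largest representable quefrency is
1/(2·df) for spectral bin spacing df — about 8 ms at a 16 kHz rate with
a 256-point FFT — so the default 50–500 Hz pitch band is clipped to the
representable range and an empty band is a configuration error. Even
though the multitaper estimate smooths the spectrum over ±500 Hz,
residual harmonic ripple is ample for the voiced/noise contrast the
detector needs; this is verified by a seeded 100-frame comparison in the
test suite.

Each feature is Gaussian-smoothed over time (10 ms interpreted as FWHM,
σ ≈ 4.25 ms, truncated at ±3σ, nearest-edge extension) and then min–max
normalized per recording; smoothing first guarantees the [0, 1] range
exactly in the output. A constant feature is flagged and set to 0 rather
than divided by zero. Wiener entropy and frequency modulation are high
for noise and low for speech, so the detection-oriented matrix stores
their complement (1 − v): "elevated above threshold" then means
speech-like for all six features. The feature functions themselves
always return the textbook quantities.

One caveat on spectral change: for *noiseless* synthetic tones the
summed gradient magnitude is dominated by the static spectral peak
structure (the d_f term), so a slowly sweeping chirp can score below a
steady tone frame-by-frame. On realistic signals with a noise floor the
feature cleanly separates speech from the stationary background, which
is the property the detector uses and the tests assert.

## Detection rule

q(t) counts features strictly above their thresholds (strict inequality
makes a threshold of 1.0 disable its feature). The detection window is
the earliest run of q(t) ≥ 4 lasting at least ⌈35 ms / step⌉ consecutive
frames; membership of the qualifying four may rotate within the run. The
onset is refined to the first frame inside the run where amplitude is
elevated (catching low-amplitude unvoiced prefixes); the offset is the
run's end. The first and last 10 ms of frames are excluded (derivative
edge bias). Absence of a qualifying run is a valid no-detection result.
Raising any threshold can only delay or remove the qualifying run, never
advance it — asserted as a property test.

## Threshold optimization

The objective for a candidate threshold vector is the maximum-likelihood
SD (divisor n) of the residuals from regressing consensus manual onsets
on automatic onsets, computed on detected trials and multiplied by
n_total/n_detected so that failing to detect is never rewarded; fewer
than 3 detections or a zero-variance regressor scores +∞. The consensus
manual onset is the mean across raters. The search: start all thresholds
at 0.5, perturb one uniformly chosen threshold by a Gaussian step
(σ = 0.05, clipped to [0, 1]), accept only improvements, stop after 1000
attempts or 50 consecutive failures; repeat over 100 random 80/20
partitions (fewer in tests and demos — sizes are stated per run) and
return the partition winner by smallest test SD, ties broken by larger
test R². The objective is piecewise constant in the thresholds, so this
stochastic coordinate search is the appropriate "gradient descent"
reading; feature matrices are cached so each attempt re-runs only the
thresholding.

## Evaluation statistics

AD scores are manual − automatic differences; signed values are kept,
and the within-10 ms proportion, SDs and CDF are computed on their
absolute values. The regression block reports β₀ (offset = constant
bias), β₁, R² (squared Pearson r), residuals and their ML SD, and the
within-10 ms residual proportion. A constant shift of all automatic
onsets moves the offset and the AD scores but leaves R², residuals and
residual SD untouched — the deliberate divergence between the two
families that motivates reporting both. ICC uses the two-way
mixed-effects, single-measures decomposition; the consistency variant
ICC(3,1) = (MS_rows − MS_err)/(MS_rows + (k−1)·MS_err) is the default
(rater mean offsets are measured separately by the regression offset),
with an absolute-agreement variant switchable. The grouped report
re-runs the full evaluation per label (e.g. phonetic onset class),
skipping groups under 3 usable trials.

## Mixture of experts

out(i) = precise(i) if |precise(i) − robust(i)| < 55 ms else robust(i);
missing values fall back to the other expert. The 55 ms default is the
empirical crossover of the two experts' |AD| CDFs; `find_crossover`
returns the smallest grid point beyond which one CDF dominates *for all
larger points* (last-crossing rule), since empirical CDFs wiggle.

## Power-loss simulation

Each experiment: n participants × 2 conditions × 100 trials, latencies
Normal(μ_c, within-SD) with condition means 15 or 30 ms apart; the test
is a dependent-samples two-tailed t on participant condition means at
α = .05. The same data are re-tested after adding independent
Normal(0, 87 ms) noise to every trial — zero-mean because regression
residuals of a calibrated detector are bias-free by construction; 87 ms
is the cross-validated residual SD the detector's tuning produces on
real-corpus material. Per cell d = (nt1 − nt2)/nt1 over 204 simulated
experiments (the acceptance script uses 1000 per cell to tighten the
per-cell Monte Carlo error; both sizes are supported). Grid: within-SD
∈ {50, 75, 100, 125} ms, n ∈ {5, 10, …, 60}. No participant-level random
intercepts are modeled beyond trial noise, and latencies are Gaussian
rather than ex-Gaussian — both acknowledged simplifications. The
error-free arm is cross-checked against the analytic noncentral-t power
formula, and the zero-effect design rejects at α (type-I calibration
test).

## Synthetic data

The generator emulates naming-trial acoustics: Gaussian noise floor;
optional Hann-gated broadband burst (< 35 ms, lip-smack-like); optional
band-limited unvoiced noise prefix (3–7 kHz, like [s]); a voiced segment
as a harmonic stack with 1/k amplitude tilt, random phases and a 20 ms
linear onset ramp. Ground truth is the start of the first speech sound
(prefix start when present, else the voiced onset). Corpus defaults:
1.8 s trials at 16 kHz, f0 uniform 100–250 Hz, onsets uniform
300–1200 ms, voiced SNR uniform 5–30 dB, 30% of trials with a transient,
unvoiced prefixes off unless requested. 16 kHz suffices for the
amplitude band once clipped to Nyquist and keeps feature extraction
around 0.07 s per trial. Simulated raters return truth + per-rater
constant bias + Gaussian jitter.

What the generator does *not* emulate — formant transitions,
coarticulation, amplitude-modulated breathing, room reverberation,
speaker variability — bounds what passing tests show: they establish
that the implementation realizes the detection rule and its statistics
correctly and robustly under controlled acoustics, not that the shipped
default thresholds transfer to any particular recording setup.
Re-optimizing thresholds on a rated sample of one's own recordings is
the intended workflow.

## Numerical choices and degenerate inputs

Power floor 1e-12 × per-recording max before logs and ratios; FFT length
next power of two ≥ window; constant signals raise on standardization;
constant features are flagged, not divided; thresholds validated to
[0, 1] with exactly the six known feature names; undetected trials are
excluded pairwise and counted, never silently dropped; d is NaN (not 0)
when no error-free experiment in a cell is significant. All stochastic
components (generator, optimizer, simulator, rater simulation) take
explicit seeds and are bit-reproducible given them.
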