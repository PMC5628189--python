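"""Tune the six feature thresholds against simulated human ratings.

Generates a 60-trial synthetic corpus, simulates two raters (5 ms jitter
each around the true onsets), and runs the stochastic threshold search:
single-coordinate Gaussian proposals accepted only when they lower the
ML residual SD of manual-on-automatic regression on the training split,
repeated over random 80/20 partitions.
"""

from voiceonset import (
    CorpusConfig,
    DetectionConfig,
    OptimizationConfig,
    RatedTrial,
    compute_features,
    generate_corpus,
    optimize_thresholds,
    simulate_raters,
)

waveforms, truth = generate_corpus(60, CorpusConfig(snr_range_db=(10.0, 30.0)), seed=7)
ratings = simulate_raters(truth["truth_ms"], bias_ms=[0.0, 0.0], jitter_sd_ms=[5.0, 5.0], seed=8)
trials = [
    RatedTrial.from_ratings(w.trial_id, compute_features(w), ratings.iloc[i])
    for i, w in enumerate(waveforms)
]

result = optimize_thresholds(
    trials,
    DetectionConfig(),
    OptimizationConfig(n_partitions=4, max_attempts=300, patience=50, rng_seed=9),
)

print("optimized thresholds:")
for name, value in sorted(result.thresholds.thresholds.items()):
    print(f"  {name:16s} {value:.3f}")
print(f"\nheld-out residual SD : {result.test_sd:6.2f} ms")
print(f"held-out R^2         : {result.test_r2:6.4f}")
print()
print("The residual SD approaches the raters' own jitter (~5 ms): the")
print("detector is then as consistent with the consensus as one rater is.")
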