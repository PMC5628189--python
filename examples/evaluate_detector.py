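"""Benchmark detector output against (simulated) manual ratings.

Detects onsets on a 40-trial synthetic corpus with the packaged
thresholds and compares them with a two-rater consensus: AD scores
(manual minus automatic, the traditional precision measure), the
regression fit whose residuals forgive constant bias, and the
inter-rater ICC of the ratings themselves.
"""

import numpy as np

from voiceonset import (
    CorpusConfig,
    detect_waveforms,
    evaluate,
    generate_corpus,
    icc,
    simulate_raters,
)

waveforms, truth = generate_corpus(40, CorpusConfig(snr_range_db=(10.0, 30.0)), seed=21)
ratings = simulate_raters(truth["truth_ms"], bias_ms=[8.0, -4.0], jitter_sd_ms=[5.0, 6.0], seed=22)
consensus = ratings.mean(axis=1).to_numpy()

estimates = detect_waveforms(waveforms)
auto = np.array([e.onset_ms if e.detected else np.nan for e in estimates])

report = evaluate(consensus, auto)
reliability = icc(ratings.to_numpy())

print(f"trials evaluated        : {report.n_pairs} ({report.n_excluded} undetected)")
print(f"|AD| within 10 ms       : {report.ad.prop_within_10ms:.0%}")
print(f"AD score SD             : {report.ad.sd_signed:6.1f} ms")
print(f"regression offset (b0)  : {report.regression.offset:6.1f} ms")
print(f"regression slope  (b1)  : {report.regression.slope:6.3f}")
print(f"R^2                     : {report.regression.r_squared:6.4f}")
print(f"residual SD (ML)        : {report.regression.residual_sd:6.1f} ms")
print(f"inter-rater ICC(3,1)    : {reliability.icc:6.4f}")
print()
print("High R^2 with a small residual SD means the detector tracks the")
print("raters trial by trial; the offset absorbs any constant bias.")
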