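"""How much statistical power does onset measurement error cost?

Simulates within-participants reaction-time experiments (100 trials per
condition per participant, 15 or 30 ms condition effects) analyzed with a
paired two-tailed t test, then re-analyzes them after adding 87 ms of
per-trial Gaussian measurement error. Reported per cell: the power-loss
index d = (nt1 - nt2)/nt1. A reduced grid keeps this demo fast; the full
grid is the PowerSimConfig default.
"""

from voiceonset import PowerSimConfig, run_grid

cfg = PowerSimConfig(
    effects_ms=(15.0, 30.0),
    within_sd_ms=(75.0, 125.0),
    n_participants=(10, 25, 40),
    experiments_per_cell=204,
    error_sd_ms=87.0,
    rng_seed=3,
)
result = run_grid(cfg)

print(result.grid.to_string(index=False, float_format=lambda v: f"{v:.3f}"))
print()
print(f"max d over cells with n > 22 : {result.max_d(min_n=22):.3f}")
print()
print("Power loss is largest for small samples and small effects; with")
print("more than ~22 participants it stays below 10% and keeps shrinking.")
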