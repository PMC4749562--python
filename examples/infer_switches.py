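"""Infer a cell's transcription profile from one noisy fluorescence trace.

Simulates a single-switch ground truth (rate 5 -> 25 a.u./h at t = 20 h),
runs the reversible-jump sampler with the LNA Kalman likelihood, and
post-processes the posterior into weighted candidate profiles.
"""

import numpy as np

from switchtissue import (
    KineticParams,
    MCMCConfig,
    PriorSpec,
    TranscriptionProfile,
    enumerate_submodels,
    fit_switch_mixture,
    recursive_residuals,
    rjmcmc_sample,
    simulate_reporter_ssa,
)

kp = KineticParams()
grid = np.arange(0.0, 46.001, 0.25)
truth = TranscriptionProfile(np.array([20.0]), np.array([5.0, 25.0]))

rng = np.random.default_rng(0)
m0 = rng.poisson(truth.rates[0] / kp.delta_m)
p0 = rng.poisson(kp.alpha * truth.rates[0] / (kp.delta_m * kp.delta_p))
_, protein = simulate_reporter_ssa(truth, kp, grid, rng, init=(m0, p0))
trace = np.clip(protein + rng.normal(0, 5, len(protein)), 0, None)

samples = rjmcmc_sample(grid, trace, PriorSpec(),
                        MCMCConfig(n_iter=12_000, burn_in=3_000, thin=5), rng=1)
ks, counts = np.unique(samples.k, return_counts=True)
print("posterior over switch count K:",
      {int(k): int(c) for k, c in zip(ks, counts)})

candidates = fit_switch_mixture(samples)
profiles = enumerate_submodels(samples, candidates, cell_id="cell_0")
for p in sorted(profiles.profiles, key=lambda q: -q.weight)[:4]:
    print(f"  profile K={p.n_switches} switches={np.round(p.switch_times, 2)} "
          f"rates={np.round(p.rates, 1)} weight={p.weight:.2f}")
# The dominant profile should place one switch within ~0.5 h of t = 20 h
# with rates near the 5 and 25 a.u./h truth.

diag = recursive_residuals(grid, trace, samples, kp)
print(f"recursive residuals: KS vs N(0,1) p = {diag.ks_pvalue:.2f}, "
      f"lag-1 acf = {diag.lag1_acf:+.3f} (band +/-{diag.band:.3f})")
# A healthy fit gives a KS p-value well above 0.05 and a lag-1
# autocorrelation inside the white-noise band.
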