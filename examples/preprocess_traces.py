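"""Dual-detector fusion and the white-noise autocorrelation diagnostic.

Builds a cell whose sensitive detector saturates at 100 a.u. while an
insensitive detector records an attenuated copy, fuses the two channels
through the inter-channel regression, subtracts background, and checks the
trace against a white-noise null.
"""

import numpy as np

from switchtissue import (
    CellTrack,
    TrackSet,
    autocorrelation_diagnostic,
    fuse_detectors,
    subtract_background,
)

rng = np.random.default_rng(5)
t = 0.25 * np.arange(185)
truth = 200 * (1 - np.exp(-t / 10.0)) + 40 * np.sin(t / 5.0)   # slow dynamics
sensitive = np.clip(truth + rng.normal(0, 2, t.size), 0, 100)
insensitive = 0.1 * truth + rng.normal(0, 1, t.size)

track = CellTrack(cell_id="c0", times=t,
                  fluor=np.column_stack([sensitive, insensitive]),
                  centroids=np.zeros((t.size, 2)),
                  channel_labels=("sensitive", "insensitive"))
fused, fit = fuse_detectors(track, ceiling=100.0)
print(f"fusion: slope {fit.slope:.2f}, intercept {fit.intercept:.2f}, "
      f"R^2 {fit.r_squared:.3f} over {fit.n_points} unsaturated points")
err = np.abs(fused.channel(0) - truth)
print(f"fused-trace error vs truth: median {np.median(err):.1f} a.u. "
      f"(the saturated range is reconstructed from the insensitive channel)")

ts = TrackSet(tracks=[fused], background=rng.uniform(0, 4, (5, t.size)))
ts = subtract_background(ts)

acf, band, outside = autocorrelation_diagnostic(ts.tracks[0].channel(0), max_lag=40)
print(f"autocorrelation: {outside.sum()}/40 lags outside the +/-{band:.3f} "
      f"white-noise band -> clearly structured dynamics, not noise")
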