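"""Raw-trace preprocessing: dual-detector fusion, background subtraction and
the white-noise autocorrelation diagnostic.

The inference model consumes raw fused traces; no detrending, bleaching
correction or smoothing is applied here.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass

import numpy as np
from statsmodels.tsa.stattools import acf as _sm_acf

from .types import CellTrack, TrackSet

log = logging.getLogger(__name__)


@dataclass
class FusionFit:
    """Linear regression linking two detector channels.

    The sensitive (high-gain, saturating) channel is regressed on the
    insensitive one over unsaturated timepoints; above ``threshold`` the
    fused trace switches to the insensitive channel rescaled through the
    regression.
    """

    slope: float
    intercept: float
    threshold: float
    sensitive_channel: str
    insensitive_channel: str
    r_squared: float
    n_points: int


def fuse_detectors(
    track: CellTrack,
    ceiling: float,
    threshold: float | str = "auto",
    sensitive: str | int = 0,
    insensitive: str | int = 1,
) -> tuple[CellTrack, FusionFit | None]:
    """Combine a sensitive and an insensitive detector channel.

    Single-channel tracks pass through unchanged (idempotence).  Otherwise
    the sensitive channel is regressed on the insensitive channel over
    timepoints where the sensitive channel is below ``ceiling`` (the
    saturation exclusion), and the fused trace takes the sensitive value
    where it is below ``threshold`` and the regression-rescaled insensitive
    value elsewhere.  ``threshold='auto'`` uses 95% of the ceiling.
    """
    if track.n_channels == 1:
        return track, None
    ys = track.channel(sensitive)
    yi = track.channel(insensitive)
    thr = 0.95 * ceiling if threshold == "auto" else float(threshold)
    if thr >= ceiling:
        raise ValueError("threshold must lie below the saturation ceiling")
    unsat = ys < ceiling
    if unsat.sum() < 5:
        raise ValueError(
            f"cell {track.cell_id}: only {int(unsat.sum())} unsaturated points; "
            "fusion fit not identifiable"
        )
    slope, intercept = np.polyfit(yi[unsat], ys[unsat], 1)
    if slope <= 0:
        raise ValueError(f"cell {track.cell_id}: non-positive fitted slope; channels inconsistent")
    pred = slope * yi[unsat] + intercept
    ss_res = float(np.sum((ys[unsat] - pred) ** 2))
    ss_tot = float(np.sum((ys[unsat] - ys[unsat].mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    fused = np.where(ys < thr, ys, slope * yi + intercept)
    s_lab = track.channel_labels[sensitive] if isinstance(sensitive, int) else sensitive
    i_lab = track.channel_labels[insensitive] if isinstance(insensitive, int) else insensitive
    fit = FusionFit(
        slope=float(slope),
        intercept=float(intercept),
        threshold=thr,
        sensitive_channel=s_lab,
        insensitive_channel=i_lab,
        r_squared=r2,
        n_points=int(unsat.sum()),
    )
    out = dataclasses.replace(
        track, fluor=np.clip(fused, 0.0, None)[:, None], channel_labels=("fused",)
    )
    return out, fit


def subtract_background(ts: TrackSet) -> TrackSet:
    """Subtract the per-timepoint mean of the background traces.

    Negative values are floored at 0 (fluorescence cannot be negative) and
    the floored count is logged so no data change is silent.
    """
    if ts.zero_background or ts.background.size == 0:
        if not ts.zero_background:
            raise ValueError("no background traces available")
        return ts
    bg_mean = ts.background.mean(axis=0)
    n_floored = 0
    new_tracks = []
    for tr in ts.tracks:
        sub = tr.fluor - bg_mean[:, None]
        n_floored += int((sub < 0).sum())
        new_tracks.append(dataclasses.replace(tr, fluor=np.clip(sub, 0.0, None)))
    if n_floored:
        log.info("background subtraction floored %d negative values at 0", n_floored)
    return dataclasses.replace(ts, tracks=new_tracks, zero_background=True,
                               background=np.zeros((0, 0)))


def autocorrelation_diagnostic(
    trace: np.ndarray, max_lag: int
) -> tuple[np.ndarray, float, np.ndarray]:
    """Sample autocorrelation with the white-noise confidence band.

    Uses the biased (1/N) autocovariance normalisation, under which the
    +/- 1.96/sqrt(N) band is the standard 95% interval for an iid series.

    Returns ``(acf[1..max_lag], band_halfwidth, outside_flags)``.
    """
    trace = np.asarray(trace, dtype=float)
    n = len(trace)
    if n < 10:
        raise ValueError("trace too short for the autocorrelation diagnostic")
    if max_lag >= n / 2:
        raise ValueError("max_lag must be below N/2")
    if np.var(trace) == 0:
        raise ValueError("zero-variance trace")
    r = _sm_acf(trace - trace.mean(), nlags=max_lag, adjusted=False, fft=True)
    band = 1.96 / np.sqrt(n)
    lags = r[1:]
    return lags, float(band), np.abs(lags) > band
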