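"""Posterior post-processing: from raw RJMCMC draws to weighted profile sets
and the downstream weighted summaries.

The marginal posterior of switch times is summarised by a Gaussian mixture
(components = candidate switch positions).  Each MCMC draw is then mapped to
the subset of candidates its switches occupy; the sub-models (subsets) are
mutually exclusive transcriptional profiles whose weights are the sampling
frequencies.  All downstream statistics — switch-count histograms, rate
densities, state durations, inter-switch times, group comparisons — are
weighted averages over these profile sets.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.mixture import GaussianMixture

from .inference import PosteriorSamples
from .types import ProfileSet, TranscriptionProfile

log = logging.getLogger(__name__)

LOW, ACTIVE = "Low", "Active"


@dataclass
class CandidateSwitchSet:
    """Gaussian-mixture summary of the marginal switch-time posterior."""

    means: np.ndarray        # sorted component means (hours)
    sds: np.ndarray          # component SDs (> 0)
    weights: np.ndarray      # mixture weights
    assignment_sd_factor: float = 3.0

    def __post_init__(self) -> None:
        self.means = np.asarray(self.means, float)
        self.sds = np.asarray(self.sds, float)
        self.weights = np.asarray(self.weights, float)
        if np.any(np.diff(self.means) < 0):
            raise ValueError("component means must be sorted")
        if len(self.means) and np.any(self.sds <= 0):
            raise ValueError("component SDs must be positive")

    def __len__(self) -> int:
        return len(self.means)

    def assign(self, t: float) -> int | None:
        """Nearest component within +/- factor * SD, else None."""
        if len(self.means) == 0:
            return None
        i = int(np.argmin(np.abs(self.means - t)))
        if abs(t - self.means[i]) <= self.assignment_sd_factor * self.sds[i]:
            return i
        return None


def fit_switch_mixture(
    samples: PosteriorSamples,
    c_max: int = 8,
    random_state: int = 0,
) -> CandidateSwitchSet:
    """Fit Gaussian mixtures with 1..c_max components to the pooled
    switch-time draws and select the component count by BIC."""
    pool = samples.pooled_switch_times()
    if len(pool) == 0:
        return CandidateSwitchSet(np.empty(0), np.empty(0), np.empty(0))
    x = pool.reshape(-1, 1)
    n_unique = len(np.unique(np.round(pool, 6)))
    best = None
    best_bic = np.inf
    for c in range(1, min(c_max, n_unique, len(pool)) + 1):
        gm = GaussianMixture(
            n_components=c, covariance_type="full",
            reg_covar=1e-4, random_state=random_state, n_init=1,
        ).fit(x)
        bic = gm.bic(x)
        if bic < best_bic:
            best_bic = bic
            best = gm
    order = np.argsort(best.means_.ravel())
    return CandidateSwitchSet(
        means=best.means_.ravel()[order],
        sds=np.sqrt(best.covariances_.ravel()[order]),
        weights=best.weights_[order],
    )


def enumerate_submodels(
    samples: PosteriorSamples,
    candidates: CandidateSwitchSet,
    cell_id: str = "cell",
    max_unclassifiable: float = 0.5,
) -> ProfileSet:
    """Map each draw to its candidate-switch subset and weight the sub-models.

    A draw is classifiable when each of its switches assigns to a distinct
    candidate component (nearest component within the assignment window) in
    increasing order; otherwise it is dropped and counted.  Sub-model weight
    = fraction of classified draws; sub-model rates = conditional posterior
    means of the interval rates given that sub-model.
    """
    counts: dict[tuple[int, ...], int] = {}
    rate_sums: dict[tuple[int, ...], np.ndarray] = {}
    n_unclassifiable = 0
    for sw, rates in zip(samples.switch_times, samples.rates):
        idx = []
        ok = True
        for t in sw:
            a = candidates.assign(float(t))
            if a is None or (idx and a <= idx[-1]):
                ok = False
                break
            idx.append(a)
        if not ok:
            n_unclassifiable += 1
            continue
        key = tuple(idx)
        counts[key] = counts.get(key, 0) + 1
        if key in rate_sums:
            rate_sums[key] += rates
        else:
            rate_sums[key] = rates.astype(float).copy()
    n_total = len(samples)
    if n_total and n_unclassifiable / n_total > max_unclassifiable:
        raise ValueError(
            f"{n_unclassifiable}/{n_total} draws unclassifiable; "
            "mixture fit inadequate for sub-model enumeration"
        )
    if n_unclassifiable:
        log.info("dropped %d/%d unclassifiable draws", n_unclassifiable, n_total)
    n_classified = n_total - n_unclassifiable
    profiles = []
    for key in sorted(counts):
        mean_rates = rate_sums[key] / counts[key]
        # guard against exactly equal adjacent conditional means
        for i in range(len(mean_rates) - 1):
            if mean_rates[i + 1] == mean_rates[i]:
                mean_rates[i + 1] *= 1 + 1e-9
        profiles.append(
            TranscriptionProfile(
                switch_times=candidates.means[list(key)],
                rates=mean_rates,
                weight=counts[key] / n_classified,
            )
        )
    # normalise away float rounding
    total = sum(p.weight for p in profiles)
    for p in profiles:
        p.weight /= total
    return ProfileSet(cell_id=cell_id, profiles=profiles)


def sample_profile(ps: ProfileSet, rng: np.random.Generator) -> TranscriptionProfile:
    """Draw one profile with probability equal to its weight."""
    i = rng.choice(len(ps.profiles), p=ps.weights / ps.weights.sum())
    return ps.profiles[int(i)]


def switch_count_summary(cells: list[ProfileSet]) -> pd.Series:
    """Weighted histogram of switch counts: each profile contributes its
    weight at its K.  Index = K, values = total weight (sums to n cells)."""
    if not cells:
        raise ValueError("need at least one cell")
    acc: dict[int, float] = {}
    for ps in cells:
        for p in ps.profiles:
            acc[p.n_switches] = acc.get(p.n_switches, 0.0) + p.weight
    ks = range(max(acc) + 1)
    return pd.Series([acc.get(k, 0.0) for k in ks], index=list(ks), name="weight")


def expected_switch_counts(cells: list[ProfileSet]) -> np.ndarray:
    """Per-cell posterior-expected switch count."""
    return np.array([ps.expected_switch_count() for ps in cells])


def _weighted_rate_durations(
    cells: list[ProfileSet], window: tuple[float, float]
) -> tuple[np.ndarray, np.ndarray]:
    """Pooled (rate, weight) sample where weight = profile weight x interval
    duration — the occupancy-weighted rate distribution."""
    rates, wts = [], []
    for ps in cells:
        for p in ps.profiles:
            for a, b, r in p.intervals(window):
                rates.append(r)
                wts.append(p.weight * (b - a))
    return np.array(rates), np.array(wts)


def _silverman_bw(x: np.ndarray, w: np.ndarray) -> float:
    w = w / w.sum()
    mu = float(np.sum(w * x))
    sd = math.sqrt(max(float(np.sum(w * (x - mu) ** 2)), 1e-12))
    n_eff = 1.0 / float(np.sum(w**2))
    order = np.argsort(x)
    cw = np.cumsum(w[order])
    q25 = float(x[order][np.searchsorted(cw, 0.25)])
    q75 = float(x[order][np.searchsorted(cw, min(0.75, cw[-1]))])
    spread = min(sd, (q75 - q25) / 1.34) or sd
    if spread < 1e-6 * max(np.abs(x).max(), 1.0):
        # (near-)degenerate sample: smooth at 5% of the data magnitude
        return 0.05 * max(np.abs(x).max(), 1.0)
    return max(0.9 * spread * n_eff ** (-0.2), 1e-6)


def rate_distribution(
    cells: list[ProfileSet],
    window: tuple[float, float],
    mode: str = "density",
    grid: np.ndarray | None = None,
    bandwidth: float | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Weighted kernel estimate of the transcription-rate distribution.

    Each interval contributes its rate with weight (profile weight x interval
    duration).  Gaussian kernel, Silverman bandwidth on the weighted sample.
    ``mode='cdf'`` returns the smoothed cumulative distribution.
    """
    x, w = _weighted_rate_durations(cells, window)
    if len(x) == 0:
        raise ValueError("no profiles to estimate from")
    h = bandwidth or _silverman_bw(x, w)
    if grid is None:
        grid = np.linspace(max(x.min() - 3 * h, 0.0), x.max() + 3 * h, 256)
    wn = w / w.sum()
    z = (grid[:, None] - x[None, :]) / h
    if mode == "density":
        vals = (np.exp(-0.5 * z**2) / math.sqrt(2 * math.pi) @ wn) / h
    elif mode == "cdf":
        vals = stats.norm.cdf(z) @ wn
    else:
        raise ValueError("mode must be 'density' or 'cdf'")
    return grid, vals


def weighted_quantiles(x: np.ndarray, w: np.ndarray, qs: np.ndarray) -> np.ndarray:
    order = np.argsort(x)
    xs, ws = x[order], w[order]
    cw = np.cumsum(ws) / ws.sum()
    return np.interp(qs, cw, xs)


@dataclass
class DurationSample:
    rate: float
    duration: float
    censored: bool      # window-truncated: a minimum duration
    bin_index: int = -1


def profile_durations(
    profile: TranscriptionProfile, window: tuple[float, float]
) -> list[DurationSample]:
    """Interval (rate, duration) pairs; first/last intervals are censored
    because the state was already occupied at the window edge (durations are
    minimum durations)."""
    ivs = profile.intervals(window)
    out = []
    for j, (a, b, r) in enumerate(ivs):
        out.append(DurationSample(rate=r, duration=b - a,
                                  censored=(j == 0 or j == len(ivs) - 1)))
    return out


def duration_by_rate_bin(
    cells: list[ProfileSet],
    window: tuple[float, float],
    binning: str = "deciles",
    rng: np.random.Generator | int | None = None,
) -> pd.DataFrame:
    """State durations grouped by transcription-rate bin.

    One profile is sampled per cell (weight-proportional); its interval
    durations (censored flags kept, as durations are minimum durations) are
    assigned to rate bins whose edges are quantiles of the pooled
    occupancy-weighted rate distribution: ``deciles`` gives ten bins,
    ``q75_split`` two bins (lower three quartiles vs upper quartile).
    Returns one row per duration with bin index and boxplot-ready columns.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    x, w = _weighted_rate_durations(cells, window)
    if binning == "deciles":
        qs = np.arange(1, 10) / 10.0
    elif binning == "q75_split":
        qs = np.array([0.75])
    else:
        raise ValueError("binning must be 'deciles' or 'q75_split'")
    edges = weighted_quantiles(x, w, qs)
    rows = []
    for ps in cells:
        prof = sample_profile(ps, rng)
        for d in profile_durations(prof, window):
            b = int(np.searchsorted(edges, d.rate, side="right"))
            rows.append((ps.cell_id, d.rate, d.duration, d.censored, b))
    return pd.DataFrame(rows, columns=["cell_id", "rate", "duration_h", "censored", "bin"])


def boxplot_stats(durations: np.ndarray) -> dict:
    """Median, IQR and 1.5xIQR whiskers of a duration sample."""
    if len(durations) == 0:
        return {"n": 0}
    q1, med, q3 = np.percentile(durations, [25, 50, 75])
    iqr = q3 - q1
    lo = durations[durations >= q1 - 1.5 * iqr].min()
    hi = durations[durations <= q3 + 1.5 * iqr].max()
    return {"n": int(len(durations)), "median": float(med), "q1": float(q1),
            "q3": float(q3), "whisker_lo": float(lo), "whisker_hi": float(hi)}


def classify_low_active(profile: TranscriptionProfile) -> list[str]:
    """Label each interval Low or Active.

    An interval is Low only when both flanking intervals have higher rates;
    every other interval — including the boundary intervals — is Active.
    Requires at least one switch (no-switch cells are excluded upstream).
    """
    if profile.n_switches < 1:
        raise ValueError("classification requires a profile with >= 1 switch")
    r = profile.rates
    labels = []
    for i in range(len(r)):
        if 0 < i < len(r) - 1 and r[i - 1] > r[i] and r[i + 1] > r[i]:
            labels.append(LOW)
        else:
            labels.append(ACTIVE)
    return labels


def inter_switch_times(cells: list[ProfileSet]) -> tuple[np.ndarray, np.ndarray]:
    """Completely observed inter-switch durations with profile weights.

    Only profiles with more than one switch contribute (the duration between
    two switches is then fully observed, not window-truncated).
    """
    durs, wts = [], []
    for ps in cells:
        for p in ps.profiles:
            if p.n_switches >= 2:
                for d in np.diff(p.switch_times):
                    durs.append(float(d))
                    wts.append(p.weight)
    return np.array(durs), np.array(wts)


def inter_switch_kde(
    cells: list[ProfileSet], grid: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray, float]:
    """Weighted Gaussian KDE of inter-switch times; also returns the total
    contributing weight (the KDE integrates to 1 whenever that is > 0)."""
    d, w = inter_switch_times(cells)
    total = float(w.sum())
    if total == 0:
        return np.empty(0), np.empty(0), 0.0
    h = _silverman_bw(d, w)
    if grid is None:
        grid = np.linspace(0.0, d.max() + 3 * h, 256)
    wn = w / total
    z = (grid[:, None] - d[None, :]) / h
    vals = (np.exp(-0.5 * z**2) / math.sqrt(2 * math.pi) @ wn) / h
    return grid, vals, total


def bootstrap_mannwhitney(
    group_a: list[tuple[np.ndarray, np.ndarray]],
    group_b: list[tuple[np.ndarray, np.ndarray]],
    n_boot: int = 500,
    alpha_line: float = 0.005,
    rng: np.random.Generator | int | None = None,
) -> dict:
    """Bootstrap Mann-Whitney comparison of two groups of weighted
    per-cell duration distributions.

    Each group element is (durations, weights) for one cell.  Per bootstrap
    replicate one duration is sampled per cell and a two-sided Mann-Whitney
    U-test is run; the result is the histogram of replicate p-values and the
    fraction lying below ``alpha_line`` (default 0.5%, i.e. an overall 5%
    level Bonferroni-corrected for ten comparisons).  The significance call
    is that a majority of the p-value mass lies below the line.
    """
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    ga = [(np.asarray(v, float), np.asarray(w, float)) for v, w in group_a if len(v)]
    gb = [(np.asarray(v, float), np.asarray(w, float)) for v, w in group_b if len(v)]
    if not ga or not gb:
        raise ValueError("both groups must contain at least one non-empty cell")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    pvals = np.empty(n_boot)
    for b in range(n_boot):
        xa = [v[rng.choice(len(v), p=w / w.sum())] for v, w in ga]
        xb = [v[rng.choice(len(v), p=w / w.sum())] for v, w in gb]
        pvals[b] = stats.mannwhitneyu(xa, xb, alternative="two-sided").pvalue
    frac = float(np.mean(pvals < alpha_line))
    return {"pvalues": pvals, "frac_below_line": frac,
            "alpha_line": alpha_line, "significant": frac >= 0.5}


def cell_duration_distribution(
    ps: ProfileSet,
    window: tuple[float, float],
    label: str | None = None,
    require_switch: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    """One cell's weighted duration distribution over profile intervals.

    Each profile's weight is split uniformly over its intervals; with
    ``label`` set, only intervals of that Low/Active class contribute (and
    no-switch profiles are skipped, as the classification requires a
    switch).  ``require_switch`` skips K = 0 profiles regardless.
    """
    durs, wts = [], []
    for p in ps.profiles:
        if (label is not None or require_switch) and p.n_switches < 1:
            continue
        labels = classify_low_active(p) if label is not None else None
        ds = profile_durations(p, window)
        share = p.weight / len(ds)
        for j, d in enumerate(ds):
            if label is not None and labels[j] != label:
                continue
            durs.append(d.duration)
            wts.append(share)
    return np.array(durs), np.array(wts)
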