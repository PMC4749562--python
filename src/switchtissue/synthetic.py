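"""Synthetic-tissue generator with known ground truth.

Emulates long-term fluorescence imaging of reporter-expressing cells in a
tissue slice: cells placed in a 2-D field, per-cell multi-state transcription
(telegraph process with a primed/refractory state and continuously
distributed "on" levels), optional spatial coupling of switch events between
neighbouring cells, exact stochastic simulation of the reporter
mRNA/protein network, and a measurement model with additive Gaussian noise
and optional detector saturation.  Every stage records its ground truth so
downstream inference and spatial statistics can be tested end to end.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .types import CellTrack, KineticParams, TranscriptionProfile, TrackSet

OFF, PRIMED, ON = "off", "primed", "on"


@dataclass
class StateProcessConfig:
    """Telegraph-with-priming state process: off -> primed -> on -> off.

    Sojourn times in each state are exponential with the configured means.
    The off and primed states transcribe at ``beta_low``; each "on" sojourn
    draws its transcription rate from a log-normal level distribution, so
    active transcription spans a continuous range of rates rather than a
    single binary level.  ``primed_mean_schedule`` lets the primed mean vary
    in time (piecewise-constant, applied at sojourn entry), which is how a
    population can be driven to a new stable output level.
    """

    off_mean: float = 20.0     # hours
    primed_mean: float = 8.0   # hours
    on_mean: float = 22.0      # hours
    beta_low: float = 0.0      # transcription rate in off/primed states
    on_rate_log_mean: float = float(np.log(10.0))  # log-normal location of "on" rates
    on_rate_log_sd: float = 0.5
    # optional [(t_from, primed_mean), ...] overrides, applied at sojourn entry
    primed_mean_schedule: list[tuple[float, float]] | None = None

    def __post_init__(self) -> None:
        if min(self.off_mean, self.primed_mean, self.on_mean) <= 0:
            raise ValueError("sojourn means must be positive")
        if self.beta_low < 0:
            raise ValueError("beta_low must be non-negative")

    def primed_mean_at(self, t: float) -> float:
        m = self.primed_mean
        for t_from, mean in self.primed_mean_schedule or []:
            if t >= t_from:
                m = mean
        return m

    def draw_on_rate(self, rng: np.random.Generator) -> float:
        return float(rng.lognormal(self.on_rate_log_mean, self.on_rate_log_sd))


@dataclass
class CouplingConfig:
    """Statistical stand-in for local coordination of transcription pulses.

    For every complete "on" pulse of every cell (an up-switch and the
    down-switch closing it, at least ``min_pulse_width`` long), each
    neighbour within ``radius`` receives, with probability ``probability``,
    an inserted copy of the pulse — both switch edges at the source times
    plus independent Gaussian jitters, at the source's rate level — provided
    the copy fits inside one of the neighbour's existing rate intervals and
    recruits it upward (the neighbour's current rate is below the pulse
    level).  Copies reaching past the observation window keep only their
    up edge.  This is an explicit generative stand-in for the coordination
    signature observed in tissue, not a mechanistic model of cell
    communication.

    The width filter exists because copying both edges of *short* pulses
    concentrates opposite-direction switch pairs (one cell's up against the
    other's down) at small time intervals — a signature real tissue lacks;
    for pulses of typical width the copied down-edge intervals blend into
    the background interval distribution.
    """

    radius: float = 30.0          # micrometres
    probability: float = 0.8      # per source pulse, per neighbour
    jitter_sd: float = 1.0        # hours
    min_pulse_width: float = 4.0  # hours; shorter blips do not propagate
    same_direction: bool = True   # False inverts half the copies into troughs

    def __post_init__(self) -> None:
        if self.radius < 0:
            raise ValueError("radius must be non-negative")
        if not 0.0 <= self.probability <= 1.0:
            raise ValueError("probability must lie in [0, 1]")


@dataclass
class DetectorSpec:
    """One acquisition channel: gain, optional saturation ceiling."""

    label: str = "fluor"
    gain: float = 1.0
    ceiling: float | None = None

    def __post_init__(self) -> None:
        if self.gain <= 0:
            raise ValueError("detector gain must be positive")
        if self.ceiling is not None and self.ceiling <= 0:
            raise ValueError("detector ceiling must be positive")


@dataclass
class Sojourn:
    state: str
    start: float
    end: float
    rate: float


@dataclass
class SyntheticTruth:
    """Ground truth of a simulated tissue, for parameter-recovery tests."""

    profiles: list[TranscriptionProfile]
    sojourns: list[list[Sojourn]]
    positions: np.ndarray            # (n, 2) um
    mrna: np.ndarray                 # (n, T) integer counts
    protein: np.ndarray              # (n, T) integer counts
    coupling_log: pd.DataFrame


@dataclass
class TissueConfig:
    """Defaults emulate an adult-like dataset: ~300 active cells observed
    for 46 h at 15-min sampling, at a density giving each cell ~3
    neighbours within the 30 um coupling radius.  Intrinsic switching
    (~2 per 46 h) plus propagated pulse copies keep per-cell switch counts
    in the observed 0-4 range."""

    n_cells: int = 300
    field_size: tuple[float, float] = (530.0, 530.0)
    placement: Literal["CSR", "hard-core"] = "hard-core"
    min_sep: float = 10.0
    t0: float = 0.0
    t1: float = 46.0
    dt: float = 0.25
    n_background: int = 5
    state: StateProcessConfig = field(default_factory=StateProcessConfig)
    coupling: CouplingConfig | None = field(default_factory=CouplingConfig)
    kinetics: KineticParams = field(default_factory=KineticParams)
    detectors: list[DetectorSpec] = field(default_factory=lambda: [DetectorSpec()])

    @property
    def grid(self) -> np.ndarray:
        n = int(round((self.t1 - self.t0) / self.dt))
        return self.t0 + self.dt * np.arange(n + 1)


def place_cells(
    n: int,
    field: tuple[float, float],
    mode: Literal["CSR", "hard-core"] = "CSR",
    min_sep: float = 10.0,
    rng: np.random.Generator | None = None,
    max_rejections: int = 20_000,
) -> np.ndarray:
    """Place ``n`` cell positions in a rectangular field (um).

    ``CSR`` draws uniform iid positions (complete spatial randomness);
    ``hard-core`` additionally enforces a minimum separation ``min_sep`` by
    sequential rejection, emulating the finite size of cells.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng() if rng is None else rng
    w, h = field
    if mode == "CSR":
        return rng.uniform([0, 0], [w, h], size=(n, 2))
    if n * math.pi * (min_sep / 2) ** 2 >= w * h:
        raise ValueError("hard-core packing infeasible: disc area exceeds field area")
    pts: list[np.ndarray] = []
    rejections = 0
    while len(pts) < n:
        p = rng.uniform([0, 0], [w, h])
        if pts and np.min(np.linalg.norm(np.array(pts) - p, axis=1)) < min_sep:
            rejections += 1
            if rejections > max_rejections:
                raise ValueError(
                    f"hard-core placement failed after {max_rejections} rejections"
                )
            continue
        pts.append(p)
    return np.array(pts)


def simulate_sojourns(
    cfg: StateProcessConfig,
    window: tuple[float, float],
    rng: np.random.Generator,
    start_state: str | None = None,
) -> list[Sojourn]:
    """Simulate the off -> primed -> on -> off cycle over ``window``.

    The initial state is drawn from the stationary occupancy of the cycle
    unless ``start_state`` is given.  Returns the full sojourn list,
    truncated to the window.
    """
    t0, t1 = window
    if not t1 > t0:
        raise ValueError("window must be non-empty")
    means = {OFF: cfg.off_mean, PRIMED: cfg.primed_mean, ON: cfg.on_mean}
    order = [OFF, PRIMED, ON]
    if start_state is None:
        occ = np.array([means[s] for s in order])
        start_state = order[rng.choice(3, p=occ / occ.sum())]
    state = start_state
    t = t0
    out: list[Sojourn] = []
    while t < t1:
        mean = cfg.primed_mean_at(t) if state == PRIMED else means[state]
        dur = rng.exponential(mean)
        rate = cfg.draw_on_rate(rng) if state == ON else cfg.beta_low
        out.append(Sojourn(state, t, min(t + dur, t1), rate))
        t += dur
        state = {OFF: PRIMED, PRIMED: ON, ON: OFF}[state]
    return out


def sojourns_to_profile(sojourns: Sequence[Sojourn]) -> TranscriptionProfile:
    """Collapse a sojourn path to a piecewise-constant profile.

    Adjacent sojourns with equal rates (e.g. off followed by primed, both at
    ``beta_low``) merge into one interval, so profile switches are exactly
    the rate changes.
    """
    times: list[float] = []
    rates: list[float] = [sojourns[0].rate]
    for s in sojourns[1:]:
        if s.rate != rates[-1]:
            times.append(s.start)
            rates.append(s.rate)
    return TranscriptionProfile(np.array(times), np.array(rates), weight=1.0)


def simulate_state_path(
    cfg: StateProcessConfig,
    window: tuple[float, float],
    rng: np.random.Generator,
    start_state: str | None = None,
) -> TranscriptionProfile:
    """Draw one cell's ground-truth transcription profile."""
    return sojourns_to_profile(simulate_sojourns(cfg, window, rng, start_state))


def state_occupancy(
    sojourns: Sequence[Sequence[Sojourn]], grid: np.ndarray, state: str = ON
) -> np.ndarray:
    """Fraction of cells occupying ``state`` at each grid time."""
    occ = np.zeros(len(grid))
    for path in sojourns:
        for s in path:
            occ += (grid >= s.start) & (grid < s.end) if s.state == state else 0
    return occ / len(sojourns)


def _insert_pulse(
    edges: list[float], rates: list[float], t_up: float, t_dn: float | None,
    level: float, window: tuple[float, float], min_gap: float = 0.25,
) -> bool:
    """Insert a rate pulse [t_up, t_dn) at ``level`` into a profile.

    Requires the whole span to fall inside one existing interval, clear of
    other switches by ``min_gap``, and to be an upward excursion from the
    host interval's rate (the pulse must recruit, not silence).  With
    ``t_dn=None`` (window-truncated copy) only the up edge is inserted.
    Returns False when the insertion is infeasible.
    """
    t0, t1 = window
    if not (t0 + min_gap < t_up < t1 - min_gap):
        return False
    i = int(np.searchsorted(edges, t_up))
    host_end = edges[i] if i < len(edges) else t1
    if t_up > host_end - min_gap:
        return False
    if level <= rates[i]:
        return False
    if t_dn is not None and t_dn <= host_end - min_gap:
        if t_dn - t_up < 2 * min_gap:
            return False
        edges[i:i] = [t_up, t_dn]
        rates[i + 1:i + 1] = [level, rates[i]]
        return True
    # the span does not fit (or reaches past the window): insert the up edge
    # only and let the target's own next switch close the excursion — but
    # never flip that switch's direction
    if i < len(edges) and np.sign(rates[i + 1] - level) != np.sign(rates[i + 1] - rates[i]):
        return False
    edges.insert(i, t_up)
    rates.insert(i + 1, level)
    return True


def couple_switches(
    profiles: Sequence[TranscriptionProfile],
    positions: np.ndarray,
    cfg: CouplingConfig,
    rng: np.random.Generator,
    window: tuple[float, float],
) -> tuple[list[TranscriptionProfile], pd.DataFrame]:
    """Propagate transcription pulses to spatial neighbours.

    Source pulses are taken from the input profiles only (no cascading).
    Each complete source pulse at least ``min_pulse_width`` long is copied,
    with the configured per-neighbour probability, into every neighbour
    within the coupling radius: both switch edges at the source times plus
    independent Gaussian jitters, at the source's rate level.  Infeasible
    copies (overlapping the target's own switches, or failing to recruit
    the target upward) are skipped.  Returns the coupled profiles and a log
    with one row per propagated switch edge.
    """
    positions = np.asarray(positions, dtype=float)
    n = len(profiles)
    if n != len(positions):
        raise ValueError("profiles and positions must be index-aligned")
    dists = np.linalg.norm(positions[:, None, :] - positions[None, :, :], axis=-1)
    edges = [list(map(float, p.switch_times)) for p in profiles]
    rates = [list(map(float, p.rates)) for p in profiles]
    log_rows = []
    for src in range(n):
        s_times = profiles[src].switch_times
        s_rates = profiles[src].rates
        s_dirs = profiles[src].directions()
        for si in range(len(s_times)):
            if s_dirs[si] != 1:
                continue
            t_up = float(s_times[si])
            level = float(s_rates[si + 1])
            if si + 1 < len(s_times) and s_dirs[si + 1] == -1:
                t_dn = float(s_times[si + 1])
                if t_dn - t_up < cfg.min_pulse_width:
                    continue
            else:
                t_dn = None          # pulse truncated by the window end
            for tgt in np.nonzero((dists[src] < cfg.radius) & (dists[src] > 0))[0]:
                if rng.uniform() >= cfg.probability:
                    continue
                up_j = t_up + (rng.normal(0.0, cfg.jitter_sd) if cfg.jitter_sd else 0.0)
                dn_j = (t_dn + (rng.normal(0.0, cfg.jitter_sd) if cfg.jitter_sd else 0.0)
                        if t_dn is not None else None)
                lv = level
                invert = (not cfg.same_direction) and rng.uniform() < 0.5
                if invert:
                    # trough copy: silence the target over the pulse span
                    i_host = int(np.searchsorted(edges[tgt], up_j))
                    host_rate = rates[tgt][i_host]
                    if host_rate <= 0 or dn_j is None:
                        continue
                    ok = _insert_trough(edges[tgt], rates[tgt], float(up_j),
                                        float(dn_j), window)
                else:
                    ok = _insert_pulse(edges[tgt], rates[tgt], float(up_j),
                                       dn_j if dn_j is None else float(dn_j),
                                       lv, window)
                if ok:
                    d1 = -1 if invert else 1
                    log_rows.append((src, int(tgt), t_up, float(up_j), d1))
                    if dn_j is not None:
                        log_rows.append((src, int(tgt), float(t_dn), float(dn_j), -d1))
    out = [
        TranscriptionProfile(np.array(e), np.array(r), weight=1.0)
        for e, r in zip(edges, rates)
    ]
    log_df = pd.DataFrame(
        log_rows, columns=["source", "target", "source_time_h", "target_time_h", "direction"]
    )
    return out, log_df


def _insert_trough(
    edges: list[float], rates: list[float], t_dn: float, t_up: float,
    window: tuple[float, float], min_gap: float = 0.25,
) -> bool:
    """Inverted copy (direction constraint off): silence the host interval
    to rate 0 over [t_dn, t_up).  Feasibility mirrors :func:`_insert_pulse`."""
    t0, t1 = window
    if not (t0 + min_gap < t_dn < t1 - min_gap):
        return False
    i = int(np.searchsorted(edges, t_dn))
    host_end = edges[i] if i < len(edges) else t1
    if rates[i] <= 0 or t_up > host_end - min_gap or t_up - t_dn < 2 * min_gap:
        return False
    edges[i:i] = [t_dn, t_up]
    rates[i + 1:i + 1] = [0.0, rates[i]]
    return True


def simulate_reporter_ssa(
    profile: TranscriptionProfile,
    kp: KineticParams,
    grid: np.ndarray,
    rng: np.random.Generator,
    init: tuple[int, int] = (0, 0),
) -> tuple[np.ndarray, np.ndarray]:
    """Exact Gillespie simulation of the reporter network on a profile.

    Transcription is piecewise constant; the simulation restarts the waiting
    time draw at switch boundaries (valid by memorylessness of exponential
    clocks), so propensities are constant between reactions.  Returns integer
    mRNA and protein counts sampled at ``grid``.
    """
    grid = np.asarray(grid, dtype=float)
    t_end = grid[-1]
    boundaries = [s for s in profile.switch_times if grid[0] < s < t_end] + [t_end]
    dm, dp, al = kp.delta_m, kp.delta_p, kp.alpha
    m, p = int(init[0]), int(init[1])
    t = float(grid[0])
    gi = 0
    M = np.empty(len(grid), dtype=np.int64)
    P = np.empty(len(grid), dtype=np.int64)
    bi = 0
    beta = float(profile.rate_at(t))
    # chunked random draws: one exp(1) and one uniform per candidate event
    CH = 8192
    exps = rng.exponential(size=CH)
    unis = rng.uniform(size=CH)
    ri = 0
    while True:
        seg_end = boundaries[bi]
        while True:
            a1 = beta
            a2 = dm * m
            a3 = al * m
            a4 = dp * p
            a0 = a1 + a2 + a3 + a4
            if ri == CH:
                exps = rng.exponential(size=CH)
                unis = rng.uniform(size=CH)
                ri = 0
            if a0 <= 0.0:
                t_next = seg_end
            else:
                t_next = t + exps[ri] / a0
            if t_next >= seg_end:
                while gi < len(grid) and grid[gi] <= seg_end:
                    M[gi] = m
                    P[gi] = p
                    gi += 1
                t = seg_end
                break
            # record grid samples passed before the event
            while gi < len(grid) and grid[gi] < t_next:
                M[gi] = m
                P[gi] = p
                gi += 1
            u = unis[ri] * a0
            ri += 1
            if u < a1:
                m += 1
            elif u < a1 + a2:
                m -= 1
            elif u < a1 + a2 + a3:
                p += 1
            else:
                p -= 1
            t = t_next
        bi += 1
        if bi == len(boundaries) and t >= t_end:
            break
        if bi < len(boundaries):
            beta = float(profile.rate_at(t))
        else:
            break
    # the final grid point coincides with t_end
    if gi < len(grid):
        M[gi:] = m
        P[gi:] = p
    return M, P


def apply_measurement(
    protein: np.ndarray,
    kp: KineticParams,
    detectors: Sequence[DetectorSpec],
    rng: np.random.Generator,
) -> np.ndarray:
    """Detector model: channel = clip(gain * kappa * P + noise, 0, ceiling).

    A sensitive channel has high gain and a low saturation ceiling; an
    insensitive channel has low gain and no (or a high) ceiling.
    Returns an array of shape (T, n_channels).
    """
    protein = np.asarray(protein, dtype=float)
    out = np.empty((len(protein), len(detectors)))
    sd = math.sqrt(kp.sigma2)
    for j, det in enumerate(detectors):
        y = det.gain * kp.kappa * protein
        if sd:
            y = y + rng.normal(0.0, sd, size=len(protein))
        hi = det.ceiling if det.ceiling is not None else np.inf
        out[:, j] = np.clip(y, 0.0, hi)
    return out


def simulate_tissue(
    cfg: TissueConfig, rng: np.random.Generator | int
) -> tuple[TrackSet, SyntheticTruth]:
    """Simulate a full synthetic imaging field; deterministic given the seed."""
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    grid = cfg.grid
    window = (cfg.t0, cfg.t1)
    positions = place_cells(cfg.n_cells, cfg.field_size, cfg.placement, cfg.min_sep, rng)
    sojourns = [simulate_sojourns(cfg.state, window, rng) for _ in range(cfg.n_cells)]
    profiles = [sojourns_to_profile(s) for s in sojourns]
    if cfg.coupling is not None and cfg.coupling.probability > 0:
        profiles, coupling_log = couple_switches(profiles, positions, cfg.coupling, rng, window)
    else:
        coupling_log = pd.DataFrame(
            columns=["source", "target", "source_time_h", "target_time_h", "direction"]
        )
    mrna = np.empty((cfg.n_cells, len(grid)), dtype=np.int64)
    protein = np.empty_like(mrna)
    tracks = []
    labels = tuple(d.label for d in cfg.detectors)
    for i, prof in enumerate(profiles):
        # start near the stationary counts of the initial rate
        b0 = prof.rates[0]
        m0 = rng.poisson(b0 / cfg.kinetics.delta_m) if b0 > 0 else 0
        p0 = rng.poisson(cfg.kinetics.alpha * b0 / (cfg.kinetics.delta_m * cfg.kinetics.delta_p)) if b0 > 0 else 0
        M, P = simulate_reporter_ssa(prof, cfg.kinetics, grid, rng, init=(m0, p0))
        mrna[i], protein[i] = M, P
        fluor = apply_measurement(P, cfg.kinetics, cfg.detectors, rng)
        tracks.append(
            CellTrack(
                cell_id=f"cell_{i:04d}",
                times=grid,
                fluor=fluor,
                centroids=np.tile(positions[i], (len(grid), 1)),
                channel_labels=labels,
            )
        )
    sd = math.sqrt(cfg.kinetics.sigma2)
    background = np.clip(rng.normal(0.0, sd, size=(cfg.n_background, len(grid))), 0.0, None)
    ts = TrackSet(
        tracks=tracks,
        background=background,
        stage="synthetic",
        field_extent=cfg.field_size,
    )
    truth = SyntheticTruth(
        profiles=profiles,
        sojourns=sojourns,
        positions=positions,
        mrna=mrna,
        protein=protein,
        coupling_log=coupling_log,
    )
    return ts, truth
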