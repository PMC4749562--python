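"""Shared domain types for the switch-inference pipeline.

Units throughout the package: time in hours, coordinates in micrometres,
fluorescence in arbitrary units (a.u.).  The default sampling grid is
15 minutes (0.25 h), matching long-term confocal imaging of reporter
tissue, but any uniform grid is accepted.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

#: tolerance (hours) for declaring a time grid uniform
GRID_TOL = 1e-6

#: reserved cell-id prefix marking background traces in tracks CSV files
BACKGROUND_PREFIX = "bg_"


@dataclass
class KineticParams:
    """Kinetic and measurement parameters of the reporter network.

    The reporter gene is modelled by the birth-death network

        0 -> mRNA          rate beta(t)
        mRNA -> 0          rate delta_m
        mRNA -> mRNA + P   rate alpha
        P -> 0             rate delta_p

    observed through Y(t) = kappa * P(t) + eps,  eps ~ N(0, sigma2).
    """

    delta_m: float = 0.7    # mRNA degradation rate (1/h)
    delta_p: float = 0.35   # protein degradation rate (1/h), ~2 h half-life
    alpha: float = 5.0      # translation rate (1/mRNA/h)
    kappa: float = 1.0      # fluorescence per protein molecule (a.u.)
    sigma2: float = 25.0    # measurement noise variance (a.u.^2)

    def __post_init__(self) -> None:
        for name in ("delta_m", "delta_p", "alpha", "kappa"):
            if not getattr(self, name) > 0:
                raise ValueError(f"KineticParams.{name} must be strictly positive")
        if self.sigma2 < 0:
            raise ValueError("KineticParams.sigma2 must be non-negative")


@dataclass
class TranscriptionProfile:
    """One candidate piecewise-constant transcription function.

    ``rates[i]`` applies on the half-open interval [s_{i-1}, s_i) where
    s_0 and s_{K+1} are the window boundaries; there are K switch times
    and K + 1 interval rates.  ``weight`` is the posterior probability of
    this profile within a mutually exclusive profile set.
    """

    switch_times: np.ndarray  # shape (K,), strictly increasing, hours
    rates: np.ndarray         # shape (K + 1,), non-negative
    weight: float = 1.0

    def __post_init__(self) -> None:
        self.switch_times = np.asarray(self.switch_times, dtype=float)
        self.rates = np.asarray(self.rates, dtype=float)
        if self.switch_times.ndim != 1 or self.rates.ndim != 1:
            raise ValueError("switch_times and rates must be 1-D")
        if len(self.rates) != len(self.switch_times) + 1:
            raise ValueError(
                f"need K+1 rates for K switches, got {len(self.rates)} rates "
                f"for {len(self.switch_times)} switches"
            )
        if np.any(np.diff(self.switch_times) <= 0):
            raise ValueError("switch_times must be strictly increasing")
        if np.any(self.rates < 0):
            raise ValueError("rates must be non-negative")
        if np.any(np.diff(self.rates) == 0.0):
            raise ValueError("adjacent rates must differ across a switch")
        if not (0.0 <= self.weight <= 1.0 + 1e-12):
            raise ValueError("weight must lie in [0, 1]")

    @property
    def n_switches(self) -> int:
        return len(self.switch_times)

    def rate_at(self, t: np.ndarray | float) -> np.ndarray:
        """Transcription rate at time(s) t under the [s_{i-1}, s_i) convention."""
        idx = np.searchsorted(self.switch_times, np.asarray(t, dtype=float), side="right")
        return self.rates[idx]

    def directions(self) -> np.ndarray:
        """Sign of the rate change at each switch (+1 up, -1 down)."""
        return np.sign(np.diff(self.rates)).astype(int)

    def intervals(self, window: tuple[float, float]) -> list[tuple[float, float, float]]:
        """(start, end, rate) triples covering ``window``."""
        t0, t1 = window
        edges = np.concatenate(([t0], self.switch_times, [t1]))
        return [
            (edges[i], edges[i + 1], self.rates[i])
            for i in range(len(self.rates))
            if edges[i + 1] > edges[i]
        ]


@dataclass
class CellTrack:
    """A single cell's fluorescence time series with centroid positions."""

    cell_id: str
    times: np.ndarray                  # (T,) hours, uniform grid
    fluor: np.ndarray                  # (T, C) a.u., one column per channel
    centroids: np.ndarray              # (T, 2) micrometres
    channel_labels: tuple[str, ...] = ("fluor",)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.fluor = np.asarray(self.fluor, dtype=float)
        if self.fluor.ndim == 1:
            self.fluor = self.fluor[:, None]
        self.centroids = np.asarray(self.centroids, dtype=float)
        self.channel_labels = tuple(self.channel_labels)
        if self.times.ndim != 1 or len(self.times) < 1:
            raise ValueError(f"cell {self.cell_id}: empty time grid")
        dt = np.diff(self.times)
        if len(dt) and (np.any(dt <= 0) or np.ptp(dt) > GRID_TOL):
            raise ValueError(
                f"cell {self.cell_id}: times must be strictly increasing and "
                f"uniformly spaced (tolerance {GRID_TOL} h)"
            )
        if self.fluor.shape[0] != len(self.times):
            raise ValueError(f"cell {self.cell_id}: fluor length mismatch")
        if self.fluor.shape[1] != len(self.channel_labels):
            raise ValueError(f"cell {self.cell_id}: channel label count mismatch")
        if self.centroids.shape != (len(self.times), 2):
            raise ValueError(f"cell {self.cell_id}: centroid shape mismatch")
        if not np.all(np.isfinite(self.fluor)):
            raise ValueError(f"cell {self.cell_id}: non-finite fluorescence")

    @property
    def n_channels(self) -> int:
        return self.fluor.shape[1]

    @property
    def dt(self) -> float:
        return float(self.times[1] - self.times[0]) if len(self.times) > 1 else 0.0

    @property
    def window(self) -> tuple[float, float]:
        return float(self.times[0]), float(self.times[-1])

    def channel(self, label_or_index: str | int = 0) -> np.ndarray:
        if isinstance(label_or_index, str):
            label_or_index = self.channel_labels.index(label_or_index)
        return self.fluor[:, label_or_index]


@dataclass
class TrackSet:
    """All cell tracks of one imaging field plus its background traces."""

    tracks: list[CellTrack]
    background: np.ndarray = field(default_factory=lambda: np.zeros((0, 0)))
    stage: str = "synthetic"            # E18.5 | P1.5 | Adult | synthetic
    treatment: str = "none"
    field_extent: tuple[float, float] | None = None   # (width, height) um
    zero_background: bool = False

    def __post_init__(self) -> None:
        if not self.tracks:
            raise ValueError("TrackSet needs at least one track")
        self.background = np.atleast_2d(np.asarray(self.background, dtype=float))
        t0 = self.tracks[0].times
        for tr in self.tracks[1:]:
            if len(tr.times) != len(t0) or np.max(np.abs(tr.times - t0)) > GRID_TOL:
                raise ValueError(f"cell {tr.cell_id}: time grid differs from the set's grid")
        ids = [tr.cell_id for tr in self.tracks]
        if len(set(ids)) != len(ids):
            raise ValueError("cell_ids must be unique")
        if self.background.size == 0 and not self.zero_background:
            raise ValueError(
                "TrackSet needs >= 1 background trace or zero_background=True"
            )
        if self.background.size and self.background.shape[1] != len(t0):
            raise ValueError("background traces must share the cell time grid")

    @property
    def times(self) -> np.ndarray:
        return self.tracks[0].times

    @property
    def cell_ids(self) -> list[str]:
        return [tr.cell_id for tr in self.tracks]

    def __len__(self) -> int:
        return len(self.tracks)

    def __getitem__(self, i: int) -> CellTrack:
        return self.tracks[i]

    def replace_tracks(self, tracks: list[CellTrack]) -> "TrackSet":
        return dataclasses.replace(self, tracks=tracks)


@dataclass
class ProfileSet:
    """Mutually exclusive candidate profiles for one cell, weights summing to 1."""

    cell_id: str
    profiles: list[TranscriptionProfile]

    def __post_init__(self) -> None:
        if not self.profiles:
            raise ValueError(f"cell {self.cell_id}: empty ProfileSet")
        total = sum(p.weight for p in self.profiles)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(
                f"cell {self.cell_id}: profile weights sum to {total}, expected 1"
            )

    @property
    def weights(self) -> np.ndarray:
        return np.array([p.weight for p in self.profiles])

    def expected_switch_count(self) -> float:
        return float(sum(p.weight * p.n_switches for p in self.profiles))


@dataclass
class RunConfig:
    """Run configuration: seed, paths and per-stage parameter blocks."""

    rng_seed: int = 0
    out_dir: str = "."
    tracks_path: str | None = None
    simulation: dict = field(default_factory=dict)
    preprocess: dict = field(default_factory=dict)
    inference: dict = field(default_factory=dict)
    postprocess: dict = field(default_factory=dict)
    spatial: dict = field(default_factory=dict)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)
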