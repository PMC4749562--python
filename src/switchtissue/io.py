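"""CSV/JSON/YAML readers and writers for tracks, profiles and configs.

Tracks CSV dialect: comma-separated, UTF-8, mandatory header, '.' decimal.
Columns: ``cell_id, time_h, x_um, y_um`` plus one or more fluorescence
columns (default ``fluor``; any column not in the coordinate set is treated
as a channel).  Background traces carry the reserved ``bg_`` cell-id prefix.
"""

from __future__ import annotations

import json
import logging
from importlib.metadata import PackageNotFoundError, version
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .types import (
    BACKGROUND_PREFIX,
    GRID_TOL,
    CellTrack,
    ProfileSet,
    RunConfig,
    TranscriptionProfile,
    TrackSet,
)

log = logging.getLogger(__name__)

try:
    PACKAGE_VERSION = version("switchtissue")
except PackageNotFoundError:  # pragma: no cover - only outside an install
    PACKAGE_VERSION = "unknown"

_COORD_COLS = ("cell_id", "time_h", "x_um", "y_um")


def load_tracks(
    path: str | Path,
    channels: list[str] | None = None,
    gap_tolerance: int = 0,
    **trackset_kwargs,
) -> TrackSet:
    """Read a tracks CSV into a validated :class:`TrackSet`.

    Parameters
    ----------
    channels
        Fluorescence column names; defaults to every non-coordinate column.
    gap_tolerance
        Maximum number of *consecutive* missing timepoints per cell that are
        filled by linear interpolation (0 disables gap filling).  Filled gaps
        are logged.
    """
    df = pd.read_csv(path)
    missing = [c for c in _COORD_COLS if c not in df.columns]
    if missing:
        raise ValueError(f"tracks CSV missing required columns: {missing}")
    if channels is None:
        channels = [c for c in df.columns if c not in _COORD_COLS]
    if not channels:
        raise ValueError("tracks CSV has no fluorescence column")

    if df.duplicated(subset=["cell_id", "time_h"]).any():
        bad = df[df.duplicated(subset=["cell_id", "time_h"])]["cell_id"].iloc[0]
        raise ValueError(f"duplicate (cell_id, time) rows; first offender: {bad}")

    grid = np.sort(df["time_h"].unique())
    if len(grid) > 1:
        dt = np.diff(grid)
        if np.ptp(dt) > GRID_TOL:
            raise ValueError("union of times is not a uniform grid")

    tracks: list[CellTrack] = []
    bg_rows: list[np.ndarray] = []
    for cell_id, g in df.groupby("cell_id", sort=True):
        g = g.sort_values("time_h")
        t = g["time_h"].to_numpy(float)
        if np.any(np.diff(t) <= 0):
            raise ValueError(f"cell {cell_id}: non-monotone times")
        if len(t) != len(grid) or np.max(np.abs(t - grid[: len(t)])) > GRID_TOL:
            t, g = _fill_gaps(str(cell_id), grid, g, channels, gap_tolerance)
        fluor = g[channels].to_numpy(float)
        if np.isnan(fluor).any():
            raise ValueError(f"cell {cell_id}: missing fluorescence values")
        if str(cell_id).startswith(BACKGROUND_PREFIX):
            bg_rows.append(fluor[:, 0])
            continue
        tracks.append(
            CellTrack(
                cell_id=str(cell_id),
                times=t,
                fluor=fluor,
                centroids=g[["x_um", "y_um"]].to_numpy(float),
                channel_labels=tuple(channels),
            )
        )
    background = np.array(bg_rows) if bg_rows else np.zeros((0, 0))
    if background.size == 0:
        trackset_kwargs.setdefault("zero_background", True)
    return TrackSet(tracks=tracks, background=background, **trackset_kwargs)


def _fill_gaps(cell_id, grid, g, channels, gap_tolerance):
    """Align a cell's rows to the set grid, interpolating short gaps."""
    present = np.isin(grid, g["time_h"].to_numpy(float))
    n_missing = int((~present).sum())
    if n_missing == 0:
        raise ValueError(f"cell {cell_id}: ragged time grid")
    if gap_tolerance <= 0:
        raise ValueError(
            f"cell {cell_id}: ragged time grid ({n_missing} missing timepoints)"
        )
    # longest run of consecutive gaps
    run = longest = 0
    for p in present:
        run = 0 if p else run + 1
        longest = max(longest, run)
    if longest > gap_tolerance or not (present[0] and present[-1]):
        raise ValueError(
            f"cell {cell_id}: gap of {longest} consecutive timepoints exceeds "
            f"tolerance {gap_tolerance} (or track does not span the grid)"
        )
    g = g.set_index("time_h").reindex(grid)
    for col in list(channels) + ["x_um", "y_um"]:
        g[col] = g[col].interpolate(method="index")
    g = g.reset_index().rename(columns={"index": "time_h"})
    g["cell_id"] = cell_id
    log.info("cell %s: linearly interpolated %d missing timepoint(s)", cell_id, n_missing)
    return grid.astype(float), g


def write_tracks(ts: TrackSet, path: str | Path) -> None:
    """Write a TrackSet to the tracks CSV dialect (lossless round trip)."""
    frames = []
    for tr in ts.tracks:
        d = {"cell_id": tr.cell_id, "time_h": tr.times,
             "x_um": tr.centroids[:, 0], "y_um": tr.centroids[:, 1]}
        for j, lab in enumerate(tr.channel_labels):
            d[lab] = tr.fluor[:, j]
        frames.append(pd.DataFrame(d))
    labels = ts.tracks[0].channel_labels
    for i, bg in enumerate(np.atleast_2d(ts.background)):
        if ts.background.size == 0:
            break
        d = {"cell_id": f"{BACKGROUND_PREFIX}{i}", "time_h": ts.times,
             "x_um": 0.0, "y_um": 0.0}
        for lab in labels:
            d[lab] = bg
        frames.append(pd.DataFrame(d))
    pd.concat(frames, ignore_index=True).to_csv(path, index=False, float_format="%.12g")


def median_positions(ts: TrackSet) -> pd.DataFrame:
    """Per-cell position = componentwise median of the centroid time course."""
    rows = [
        (tr.cell_id, float(np.median(tr.centroids[:, 0])), float(np.median(tr.centroids[:, 1])))
        for tr in ts.tracks
    ]
    return pd.DataFrame(rows, columns=["cell_id", "x", "y"])


def write_profiles(profile_sets: list[ProfileSet], path: str | Path, seed: int | None = None) -> None:
    """Serialise per-cell weighted profile sets to JSON."""
    payload = {
        "package_version": PACKAGE_VERSION,
        "rng_seed": seed,
        "cells": {
            ps.cell_id: [
                {
                    "switch_times": p.switch_times.tolist(),
                    "rates": p.rates.tolist(),
                    "weight": p.weight,
                }
                for p in ps.profiles
            ]
            for ps in profile_sets
        },
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def read_profiles(path: str | Path) -> list[ProfileSet]:
    payload = json.loads(Path(path).read_text())
    return [
        ProfileSet(
            cell_id=cid,
            profiles=[
                TranscriptionProfile(
                    switch_times=np.array(p["switch_times"], dtype=float),
                    rates=np.array(p["rates"], dtype=float),
                    weight=float(p["weight"]),
                )
                for p in plist
            ],
        )
        for cid, plist in payload["cells"].items()
    ]


def write_config(cfg: RunConfig, path: str | Path) -> None:
    d = cfg.to_dict()
    d["package_version"] = PACKAGE_VERSION
    Path(path).write_text(yaml.safe_dump(d, sort_keys=False))


def read_config(path: str | Path) -> RunConfig:
    d = yaml.safe_load(Path(path).read_text()) or {}
    d.pop("package_version", None)
    return RunConfig.from_dict(d)
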