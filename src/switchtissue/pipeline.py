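"""Pipeline orchestration: simulate -> preprocess -> infer -> postprocess ->
spatial, with per-stage child seeds and a JSON manifest.

Child seeds are spawned from the master seed by a counter-based scheme
(``numpy.random.SeedSequence``), so each stage is independently
reproducible and a stage subset re-run produces identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as stio
from .inference import MCMCConfig, PriorSpec, rjmcmc_sample
from .postprocess import enumerate_submodels, fit_switch_mixture, switch_count_summary
from .preprocess import autocorrelation_diagnostic, fuse_detectors, subtract_background
from .spatial import make_distance_bins, permutation_null, ripley_k, switch_synchrony
from .synthetic import CouplingConfig, StateProcessConfig, TissueConfig, simulate_tissue
from .types import KineticParams, ProfileSet, RunConfig

log = logging.getLogger(__name__)

STAGES = ("simulate", "preprocess", "infer", "postprocess", "spatial")


def stage_seed(master: int, stage: str) -> int:
    """Deterministic child seed for a named stage."""
    counter = STAGES.index(stage)
    return int(np.random.SeedSequence(master, spawn_key=(counter,)).generate_state(1)[0] % 2**31)


def _config_hash(block: dict) -> str:
    return hashlib.sha256(json.dumps(block, sort_keys=True, default=str).encode()).hexdigest()[:12]


def _build_tissue_config(block: dict) -> TissueConfig:
    block = dict(block)
    state = StateProcessConfig(**block.pop("state", {}))
    coupling_block = block.pop("coupling", {})
    coupling = None if coupling_block is None else CouplingConfig(**coupling_block)
    kinetics = KineticParams(**block.pop("kinetics", {}))
    return TissueConfig(state=state, coupling=coupling, kinetics=kinetics, **block)


def run_pipeline(cfg: RunConfig, stages: list[str] | None = None) -> dict:
    """Execute the requested stages and return the manifest.

    Each stage reads its inputs from the output directory (so a subset of
    stages can be re-run against prior outputs) and appends a manifest
    record with its config hash, seed and runtime.
    """
    stages = list(stages or STAGES)
    unknown = set(stages) - set(STAGES)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stio.write_config(cfg, out / "config.yaml")
    manifest: dict = {"rng_seed": cfg.rng_seed, "stages": []}

    def record(name, block, t0, outputs):
        manifest["stages"].append({
            "name": name,
            "config_hash": _config_hash(block),
            "seed": stage_seed(cfg.rng_seed, name),
            "runtime_s": round(time.time() - t0, 3),
            "outputs": [str(p) for p in outputs],
        })

    for name in STAGES:       # declared order, regardless of request order
        if name not in stages:
            continue
        t0 = time.time()
        if name == "simulate":
            tissue_cfg = _build_tissue_config(cfg.simulation)
            ts, truth = simulate_tissue(tissue_cfg, stage_seed(cfg.rng_seed, name))
            stio.write_tracks(ts, out / "tracks.csv")
            pd.DataFrame(truth.positions, columns=["x", "y"]).to_csv(
                out / "positions.csv", index=False)
            truth.coupling_log.to_csv(out / "coupling_log.csv", index=False)
            truth_sets = [
                ProfileSet(cell_id=ts.cell_ids[i],
                           profiles=[dataclasses.replace(truth.profiles[i], weight=1.0)])
                for i in range(len(ts))
            ]
            stio.write_profiles(truth_sets, out / "truth_profiles.json", seed=cfg.rng_seed)
            record(name, cfg.simulation, t0, ["tracks.csv", "positions.csv",
                                              "coupling_log.csv", "truth_profiles.json"])
        elif name == "preprocess":
            ts = stio.load_tracks(out / "tracks.csv")
            if ts.tracks[0].n_channels == 2 and cfg.preprocess.get("fuse", True):
                ceiling = float(cfg.preprocess.get("ceiling", ts.tracks[0].fluor.max()))
                ts = ts.replace_tracks(
                    [fuse_detectors(tr, ceiling)[0] for tr in ts.tracks])
            ts = subtract_background(ts)
            stio.write_tracks(ts, out / "tracks_preprocessed.csv")
            n_t = len(ts.times)
            max_lag = int(cfg.preprocess.get("max_lag", min(40, (n_t - 1) // 2)))
            rows = []
            for tr in ts.tracks:
                acf, band, outside = autocorrelation_diagnostic(tr.channel(0), max_lag)
                for lag in range(1, max_lag + 1):
                    rows.append((tr.cell_id, lag, acf[lag - 1], band, bool(outside[lag - 1])))
            pd.DataFrame(rows, columns=["cell_id", "lag", "acf", "band", "outside"]).to_csv(
                out / "autocorrelation.csv", index=False)
            record(name, cfg.preprocess, t0,
                   ["tracks_preprocessed.csv", "autocorrelation.csv"])
        elif name == "infer":
            ts = stio.load_tracks(out / "tracks_preprocessed.csv")
            priors = PriorSpec(**cfg.inference.get("priors", {}))
            mcmc = MCMCConfig(**cfg.inference.get("mcmc", {}))
            n_cells = cfg.inference.get("max_cells")
            tracks = ts.tracks[:n_cells] if n_cells else ts.tracks
            seed0 = stage_seed(cfg.rng_seed, name)
            profile_sets = []
            for i, tr in enumerate(tracks):
                samples = rjmcmc_sample(tr.times, tr.channel(0), priors, mcmc,
                                        rng=seed0 + i)
                cands = fit_switch_mixture(samples)
                profile_sets.append(enumerate_submodels(samples, cands, cell_id=tr.cell_id))
            stio.write_profiles(profile_sets, out / "profiles.json", seed=cfg.rng_seed)
            record(name, cfg.inference, t0, ["profiles.json"])
        elif name == "postprocess":
            psets = stio.read_profiles(out / "profiles.json")
            hist = switch_count_summary(psets)
            hist.rename_axis("n_switches").to_frame().to_csv(out / "switch_counts.csv")
            record(name, cfg.postprocess, t0, ["switch_counts.csv"])
        else:  # spatial
            ts = stio.load_tracks(out / "tracks_preprocessed.csv")
            seed_sp = stage_seed(cfg.rng_seed, name)
            bins = make_distance_bins(float(cfg.spatial.get("max_um", 60.0)))
            res = permutation_null(ts, bins,
                                   n_perm=int(cfg.spatial.get("n_perm", 1999)),
                                   rng=seed_sp)
            res.table.to_csv(out / "correlation_vs_distance.csv", index=False)
            pos = stio.median_positions(ts)[["x", "y"]].to_numpy()
            outputs = ["correlation_vs_distance.csv"]
            field = cfg.spatial.get("field_size") or ts.field_extent \
                or (float(pos[:, 0].max()), float(pos[:, 1].max()))
            if len(pos) >= 10:
                rip = ripley_k(pos, tuple(field), n_sim=99, rng=seed_sp)
                pd.DataFrame({"r": rip.radii, "k_obs": rip.k_obs, "k_theo": rip.k_theo,
                              "k_lo": rip.k_lo, "k_hi": rip.k_hi}).to_csv(
                    out / "ripley_k.csv", index=False)
                outputs.append("ripley_k.csv")
            profiles_path = out / "profiles.json"
            if not profiles_path.exists():
                profiles_path = out / "truth_profiles.json"
            if profiles_path.exists():
                psets = stio.read_profiles(profiles_path)
                m = min(len(psets), len(pos))
                syn = switch_synchrony(psets[:m], pos[:m], rng=seed_sp, n_resample=1)
                Path(out / "synchrony_ks.json").write_text(json.dumps(syn.ks_tests, indent=1))
                outputs.append("synchrony_ks.json")
            record(name, cfg.spatial, t0, outputs)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest
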