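"""File plumbing: configs, trajectories, result tables, run manifests.

All artifacts are plain text: configs and manifests are JSON (floats at
full precision), trajectories and leaderboards are tidy CSV.  Every
saved trajectory carries a manifest (config hash, seed, package version,
onset record) sufficient to re-execute the run exactly.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .config import ParameterSet, RegionLayout, SimulationConfig
from .engine import Trajectory

__all__ = ["ParseError", "config_to_dict", "config_from_dict",
           "save_config", "load_config", "config_hash",
           "save_trajectory", "load_trajectory", "world_snapshot"]


class ParseError(ValueError):
    """Raised when a file cannot be parsed into the expected object."""


_TUPLE_FIELDS = {f.name for f in dataclasses.fields(ParameterSet)
                 if "tuple" in str(f.type)}


def config_to_dict(config: SimulationConfig) -> dict:
    d = dataclasses.asdict(config)
    return d


def config_from_dict(d: dict) -> SimulationConfig:
    try:
        d = dict(d)
        params = dict(d.pop("params"))
        layout = dict(d.pop("region_layout"))
        for name in _TUPLE_FIELDS & set(params):
            params[name] = tuple(params[name])
        return SimulationConfig(params=ParameterSet(**params),
                                region_layout=RegionLayout(**layout), **d)
    except (KeyError, TypeError) as exc:
        raise ParseError(f"malformed configuration: {exc}") from exc


def save_config(config: SimulationConfig, path) -> None:
    Path(path).write_text(json.dumps(config_to_dict(config), indent=2))


def load_config(path) -> SimulationConfig:
    try:
        d = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise ParseError(f"{path}: invalid JSON at line {exc.lineno}") from exc
    return config_from_dict(d)


def config_hash(config: SimulationConfig) -> str:
    blob = json.dumps(config_to_dict(config), sort_keys=True)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


# ----------------------------------------------------------------------

def _manifest_path(csv_path) -> Path:
    p = Path(csv_path)
    return p.with_suffix(p.suffix + ".meta.json")


def save_trajectory(traj: Trajectory, csv_path,
                    config: SimulationConfig | None = None) -> None:
    """Tidy CSV (tick, week, counts...) plus a JSON run manifest."""
    df = pd.DataFrame({"tick": np.arange(len(traj.series["n_healthy_beta"])),
                       "week": traj.weeks})
    for k, v in traj.series.items():
        df[k] = v
    df.to_csv(csv_path, index=False)
    manifest = {
        "onset_week": traj.onset_week,
        "censored": traj.censored,
        "onset_threshold_frac": traj.onset_threshold_frac,
        "beta_init": traj.beta_init,
        "seed": traj.seed,
        "package": "t1dsim",
        "config_hash": config_hash(config) if config is not None else None,
    }
    _manifest_path(csv_path).write_text(json.dumps(manifest, indent=2))


def load_trajectory(csv_path) -> Trajectory:
    df = pd.read_csv(csv_path)
    required = {"tick", "week", "n_healthy_beta"}
    if not required <= set(df.columns):
        raise ParseError(
            f"{csv_path}: header line is missing columns "
            f"{sorted(required - set(df.columns))}")
    meta = json.loads(_manifest_path(csv_path).read_text())
    series = {k: df[k].to_numpy() for k in df.columns
              if k not in ("tick", "week")}
    return Trajectory(series=series, onset_week=meta["onset_week"],
                      censored=meta["censored"],
                      onset_threshold_frac=meta["onset_threshold_frac"],
                      beta_init=meta["beta_init"], seed=meta["seed"])


# ----------------------------------------------------------------------

def _rle(values) -> list[list[int]]:
    out = []
    for v in values:
        if out and out[-1][0] == int(v):
            out[-1][1] += 1
        else:
            out.append([int(v), 1])
    return out


def world_snapshot(world) -> dict:
    """JSON-able snapshot: run-length-encoded region map + agent lists."""
    return {
        "clock_h": world.clock_h,
        "onset_threshold_frac": world.onset_threshold_frac,
        "beta_init": world.beta_init,
        "region_rle": _rle(world.region.ravel()),
        "shape": list(world.region.shape),
        "beta": {
            "pos": world.beta_pos.tolist(),
            "status": world.beta_status.tolist(),
        },
        "agents": {cls: [[a.x, a.y, a.age_h, a.lifespan_h] for a in lst]
                   for cls, lst in world.agents.items()},
    }
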