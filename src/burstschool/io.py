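"""Configuration files, CSV schemas and run manifests.

Config files are TOML or JSON with three sections::

    [model]   gamma_att, gamma_ali, l_att, l_ali, epsilon, gamma_r, tau0,
              k, n_fish, kick_mean, kick_sd, kick_min, kick_max, noise_mean
    [run]     kicks_per_fish, n_runs, seed, snapshot_interval
    [init]    mode ("circle" | "ellipse"), a, b, stagger

Missing model fields take the standard defaults (l_att = l_ali = 3,
gamma_r = 0.2, tau0 = 0.8, epsilon = 0.8, unit mean kick); the interaction
strengths gamma_att and gamma_ali must be given explicitly.
"""

from __future__ import annotations

import dataclasses
import json
import tomllib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .params import ModelParams

TIMESERIES_COLUMNS = ["time", "P", "M", "D", "NG", "G1", "DG"]
TRAJECTORY_COLUMNS = ["time", "fish_id", "x", "y", "heading", "speed", "kick_index"]

#: explored range of the interaction strengths; values outside are rejected
STRENGTH_RANGE = (0.0, 1.2)

_MODEL_KEYS = {f.name for f in dataclasses.fields(ModelParams)}
_RUN_KEYS = {"kicks_per_fish", "n_runs", "seed", "snapshot_interval"}
_INIT_KEYS = {"mode", "a", "b", "stagger"}


class ConfigError(ValueError):
    """Raised for unknown keys or out-of-range values in a config file."""


@dataclass
class RunConfig:
    """Validated simulation configuration."""

    params: ModelParams
    kicks_per_fish: int = 2000
    n_runs: int = 1
    seed: int = 0
    snapshot_interval: float = 1.0
    init_mode: str = "circle"
    a: Optional[float] = None
    b: Optional[float] = None
    stagger: bool = True

    def to_dict(self) -> dict:
        return {
            "model": self.params.to_dict(),
            "run": {"kicks_per_fish": self.kicks_per_fish, "n_runs": self.n_runs,
                    "seed": self.seed, "snapshot_interval": self.snapshot_interval},
            "init": {"mode": self.init_mode, "a": self.a, "b": self.b,
                     "stagger": self.stagger},
        }


def _check_keys(section: dict, allowed: set, name: str) -> None:
    unknown = sorted(set(section) - allowed)
    if unknown:
        raise ConfigError(f"unknown keys in [{name}]: {', '.join(unknown)}")


def config_from_dict(raw: dict) -> RunConfig:
    _check_keys(raw, {"model", "run", "init"}, "top level")
    model = dict(raw.get("model", {}))
    run = dict(raw.get("run", {}))
    init = dict(raw.get("init", {}))
    _check_keys(model, _MODEL_KEYS, "model")
    _check_keys(run, _RUN_KEYS, "run")
    _check_keys(init, _INIT_KEYS, "init")
    for key in ("gamma_att", "gamma_ali"):
        if key not in model:
            raise ConfigError(f"[model] {key} must be given explicitly")
        lo, hi = STRENGTH_RANGE
        if not (lo <= model[key] <= hi):
            raise ConfigError(
                f"[model] {key}={model[key]} outside the explored range "
                f"[{lo}, {hi}] (attraction 0-0.6, alignment 0-1.2)")
    try:
        params = ModelParams(**model)
    except ValueError as exc:
        raise ConfigError(str(exc)) from exc
    init_mode = init.get("mode", "circle")
    if init_mode not in ("circle", "ellipse"):
        raise ConfigError(f"[init] mode must be 'circle' or 'ellipse', got {init_mode!r}")
    if init_mode == "ellipse" and ("a" not in init or "b" not in init):
        raise ConfigError("[init] ellipse mode requires half-axes a and b")
    return RunConfig(
        params=params,
        kicks_per_fish=int(run.get("kicks_per_fish", 2000)),
        n_runs=int(run.get("n_runs", 1)),
        seed=int(run.get("seed", 0)),
        snapshot_interval=float(run.get("snapshot_interval", 1.0)),
        init_mode=init_mode,
        a=init.get("a"),
        b=init.get("b"),
        stagger=bool(init.get("stagger", True)),
    )


def load_config(path) -> RunConfig:
    """Load and validate a TOML or JSON configuration file."""
    path = Path(path)
    if path.suffix == ".toml":
        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
    else:
        with open(path) as fh:
            raw = json.load(fh)
    return config_from_dict(raw)


def save_config(config: RunConfig, path) -> None:
    """Write a configuration as JSON (loadable by load_config)."""
    data = config.to_dict()
    data["init"] = {k: v for k, v in data["init"].items() if v is not None}
    with open(path, "w") as fh:
        json.dump(data, fh, indent=2)


# ---------------------------------------------------------------------------
# CSV schemas

def write_timeseries(records, path) -> None:
    """Write a time,P,M,D,NG,G1,DG table (records: DataFrame or row dicts)."""
    df = pd.DataFrame(records, columns=TIMESERIES_COLUMNS if not isinstance(
        records, pd.DataFrame) else None)
    if isinstance(records, pd.DataFrame):
        missing = [c for c in TIMESERIES_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"missing column(s): {', '.join(missing)}")
        df = df[TIMESERIES_COLUMNS]
    df.to_csv(path, index=False)


def read_timeseries(path) -> pd.DataFrame:
    """Read a time-series CSV; columns are matched by header name."""
    df = pd.read_csv(path)
    for col in TIMESERIES_COLUMNS:
        if col not in df.columns:
            raise ValueError(f"missing column: {col}")
    return df[TIMESERIES_COLUMNS]


def write_trajectory(trajectory, path) -> None:
    """Write the long-format trajectory CSV (rows ordered by time, then id)."""
    trajectory.to_dataframe().to_csv(path, index=False)


def read_trajectory(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    for col in TRAJECTORY_COLUMNS:
        if col not in df.columns:
            raise ValueError(f"missing column: {col}")
    return df[TRAJECTORY_COLUMNS]


# ---------------------------------------------------------------------------
# manifest

@dataclass
class RunManifest:
    """Reproducibility metadata written next to every output set."""

    config: dict
    master_seed: int
    code_version: str
    n_kick_events: int = 0
    outputs: list = field(default_factory=list)

    def write(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2)


def make_manifest(config: RunConfig) -> RunManifest:
    from . import __version__

    return RunManifest(config=config.to_dict(), master_seed=config.seed,
                       code_version=__version__)
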