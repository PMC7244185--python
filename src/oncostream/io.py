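"""Configuration handling, presets, trajectory files and run manifests.

Configs are flat key-value files in YAML or JSON (JSON being a YAML
subset, one loader reads both) with keys mirroring the parameter tables:
a, b, c, alpha, beta, L, d, N, dt, T, record_every, init_mode, seed.
Trajectories persist to HDF5 (one dataset per field) and export to a
tidy delimited table; a JSON manifest records everything needed to
reproduce a run.
"""

from __future__ import annotations

import datetime
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from . import __version__
from .model import ModelParams
from .simulate import SimulationConfig, Trajectory
from .model import CellConfiguration

# Parameter presets mirroring the published tables.  Semi-axes are half
# the printed front/back and side diameters (2a = 11 μm, 2b = 6 μm).
# The 3D preset uses the reduced box L = 70 μm that keeps the volume
# fraction comparable to the 2D runs (the table's printed L = 300 μm row
# is superseded by the text).
PRESETS: dict[str, dict] = {
    "table1": dict(a=5.5, b=3.0, c=10.0, alpha=40.0, beta=1.0, L=300.0, d=2,
                   N=1000, dt=0.01, T=1000.0, record_every=10.0,
                   init_mode="random", seed=0),
    "table2": dict(a=5.5, b=3.0, c=10.0, alpha=100.0, beta=0.1, L=300.0, d=2,
                   N=1000, dt=0.01, T=1000.0, record_every=10.0,
                   init_mode="random", seed=0,
                   alpha_range=(10.0, 200.0), beta_range=(0.1, 10.0),
                   N_values=(1000, 1500, 2000)),
    "table3": dict(a=5.5, b=3.0, c=10.0, alpha=100.0, beta=0.1, L=70.0, d=3,
                   N=1000, dt=0.01, T=1000.0, record_every=10.0,
                   init_mode="random", seed=0,
                   N_values=(1000, 1500, 2000)),
}

_PARAM_KEYS = {"a", "b", "c", "alpha", "beta", "L", "d"}
_SIM_KEYS = {"dt", "T", "record_every", "init_mode", "seed", "epsilon"}
_META_KEYS = {"N", "preset", "alpha_range", "beta_range", "N_values"}


def preset(name: str) -> dict:
    """A copy of one of the named parameter presets."""
    try:
        return dict(PRESETS[name])
    except KeyError:
        raise KeyError(
            f"unknown preset {name!r}; available: {sorted(PRESETS)}"
        ) from None


def parse_config(cfg: dict):
    """Validate a flat config dict -> (ModelParams, SimulationConfig, N)."""
    cfg = dict(cfg)
    if "preset" in cfg:
        base = preset(cfg.pop("preset"))
        base.update(cfg)
        cfg = base
    unknown = set(cfg) - _PARAM_KEYS - _SIM_KEYS - _META_KEYS
    missing = (_PARAM_KEYS | {"N"}) - set(cfg)
    problems = []
    if unknown:
        problems.append(f"unknown keys: {sorted(unknown)}")
    if missing:
        problems.append(f"missing keys: {sorted(missing)}")
    if problems:
        raise ValueError("invalid configuration: " + "; ".join(problems))
    params = ModelParams(
        a=float(cfg["a"]), b=float(cfg["b"]), c=float(cfg["c"]),
        alpha=float(cfg["alpha"]), beta=float(cfg["beta"]),
        L=float(cfg["L"]), d=int(cfg["d"]),
    )
    sim_kw = {k: cfg[k] for k in _SIM_KEYS if k in cfg}
    if "seed" in sim_kw:
        sim_kw["seed"] = int(sim_kw["seed"])
    sim = SimulationConfig(**sim_kw)
    return params, sim, int(cfg["N"])


def load_config(path):
    """Read a YAML/JSON config file -> (ModelParams, SimulationConfig, N)."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"config file {path} must hold a mapping")
    return parse_config(cfg)


def save_trajectory(trajectory: Trajectory, path) -> None:
    """Write a trajectory to HDF5: times, positions, orientations + attrs."""
    pos = np.stack([s.positions for s in trajectory.states])
    ori = np.stack([s.orientations for s in trajectory.states])
    with h5py.File(path, "w") as fh:
        fh.create_dataset("times", data=trajectory.times)
        fh.create_dataset("positions", data=pos)
        fh.create_dataset("orientations", data=ori)
        for key, val in asdict(trajectory.params).items():
            fh.attrs[f"params/{key}"] = val
        for key, val in asdict(trajectory.sim_config).items():
            fh.attrs[f"sim/{key}"] = val
        fh.attrs["software_version"] = __version__


def load_trajectory(path) -> Trajectory:
    with h5py.File(path, "r") as fh:
        times = fh["times"][()]
        pos = fh["positions"][()]
        ori = fh["orientations"][()]
        params = ModelParams(**{
            key.split("/", 1)[1]: val.item() if hasattr(val, "item") else val
            for key, val in fh.attrs.items() if key.startswith("params/")
        })
        sim_kw = {
            key.split("/", 1)[1]: val.item() if hasattr(val, "item") else val
            for key, val in fh.attrs.items() if key.startswith("sim/")
        }
        sim_kw["init_mode"] = str(sim_kw.get("init_mode", "random"))
        sim_kw["seed"] = int(sim_kw.get("seed", 0))
        sim = SimulationConfig(**sim_kw)
    states = [
        CellConfiguration(pos[k], ori[k], time=float(times[k]))
        for k in range(len(times))
    ]
    return Trajectory(times=times, states=states, params=params, sim_config=sim)


def trajectory_table(trajectory: Trajectory) -> pd.DataFrame:
    """Long-format snapshot table: time, cell_id, x, y[, z], wx, wy[, wz]."""
    d = trajectory.params.d
    pos_cols = ["x", "y", "z"][:d]
    ori_cols = ["wx", "wy", "wz"][:d]
    frames = []
    n = trajectory.n_cells
    for cfg in trajectory.states:
        df = pd.DataFrame(cfg.positions, columns=pos_cols)
        df[ori_cols] = cfg.orientations
        df.insert(0, "cell_id", np.arange(n))
        df.insert(0, "time", cfg.time)
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


@dataclass
class RunManifest:
    """Reproducibility record for one simulation run."""

    config: dict
    seed: int
    software_version: str = __version__
    started: str = ""
    finished: str = ""
    outputs: list = field(default_factory=list)

    @classmethod
    def begin(cls, config: dict, seed: int) -> "RunManifest":
        return cls(config=dict(config), seed=int(seed),
                   started=datetime.datetime.now().isoformat())

    def end(self, outputs) -> "RunManifest":
        self.finished = datetime.datetime.now().isoformat()
        self.outputs = [str(p) for p in outputs]
        return self

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)

    @classmethod
    def load(cls, path) -> "RunManifest":
        with open(path) as fh:
            return cls(**json.load(fh))

    def replay_inputs(self):
        """(ModelParams, SimulationConfig, N) reproducing the run."""
        cfg = dict(self.config)
        cfg["seed"] = self.seed
        return parse_config(cfg)
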