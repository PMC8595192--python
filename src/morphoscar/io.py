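"""Trajectory serialization: per-time CSV files plus an index JSON."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .config import atomic_write_text, config_hash
from .fem import NumericsConfig, Trajectory
from .model_core import FieldState

__all__ = ["write_trajectory", "read_trajectory"]

_COLUMNS = ("x", "c", "N", "M", "rho", "v", "eps", "u")


def write_trajectory(traj: Trajectory, out_dir) -> Path:
    """Write one CSV per stored time under ``out_dir/states`` and an
    ``index.json`` with times, marker nodes, and the parameter hash."""
    out_dir = Path(out_dir)
    state_dir = out_dir / "states"
    state_dir.mkdir(parents=True, exist_ok=True)
    files = []
    for t, st in zip(traj.times, traj.states):
        name = f"state_{t:07.2f}.csv"
        df = pd.DataFrame({c: getattr(st, c) for c in _COLUMNS})
        atomic_write_text(state_dir / name, df.to_csv(index=False))
        sidecar = {"t": float(t),
                   "param_hash": config_hash(traj.params.to_dict())}
        atomic_write_text(state_dir / (name + ".json"),
                          json.dumps(sidecar))
        files.append(f"states/{name}")
    index = {
        "times": [float(t) for t in traj.times],
        "files": files,
        "edge_index": traj.edge_index,
        "edge_index_right": traj.edge_index_right,
        "numerics": vars(traj.config),
        "param_hash": config_hash(traj.params.to_dict()),
    }
    atomic_write_text(out_dir / "index.json",
                      json.dumps(index, indent=2, default=float))
    return out_dir


def read_trajectory(out_dir, params=None) -> Trajectory:
    """Rebuild a Trajectory from :func:`write_trajectory` output.

    ``params`` (the originating ParameterSet) is optional; it is only
    needed for strain-energy evaluation with a non-default stiffness.
    """
    from .params import ParameterSet

    out_dir = Path(out_dir)
    index = json.loads((out_dir / "index.json").read_text())
    states = []
    for t, fname in zip(index["times"], index["files"]):
        df = pd.read_csv(out_dir / fname)
        states.append(FieldState(
            t=float(t), **{c: df[c].to_numpy() for c in _COLUMNS}))
    cfg = NumericsConfig(**index["numerics"])
    return Trajectory(times=np.asarray(index["times"], dtype=float),
                      states=states, config=cfg,
                      params=params or ParameterSet(),
                      edge_index=index["edge_index"],
                      edge_index_right=index["edge_index_right"])
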