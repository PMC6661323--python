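"""HDF5 persistence for trajectories (one group per run)."""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import h5py
import numpy as np

from .models import ModelSpec
from .simulate import SimConfig, Trajectory

__all__ = ["save_trajectory", "load_trajectory"]


def save_trajectory(path: str | Path, traj: Trajectory, group: str = "run") -> None:
    """Write a trajectory (states, grids and full parameter provenance)."""
    with h5py.File(path, "a") as fh:
        if group in fh:
            del fh[group]
        g = fh.create_group(group)
        g.create_dataset("t", data=traj.t)
        g.create_dataset("x", data=traj.x)
        g.create_dataset("y", data=traj.y)
        if traj.z is not None:
            g.create_dataset("z", data=traj.z)
        g.attrs["dt"] = traj.dt
        g.attrs["stride"] = traj.stride
        g.attrs["frequency_hz"] = traj.frequency_hz
        g.attrs["steady_start"] = traj.steady_start
        g.attrs["model"] = json.dumps(asdict(traj.model))
        g.attrs["config"] = json.dumps(asdict(traj.config))
        g.attrs["provenance"] = json.dumps(traj.provenance)


def load_trajectory(path: str | Path, group: str = "run") -> Trajectory:
    with h5py.File(path, "r") as fh:
        g = fh[group]
        z = np.asarray(g["z"]) if "z" in g else None
        return Trajectory(
            t=np.asarray(g["t"]),
            x=np.asarray(g["x"]),
            y=np.asarray(g["y"]),
            z=z,
            dt=float(g.attrs["dt"]),
            stride=int(g.attrs["stride"]),
            frequency_hz=float(g.attrs["frequency_hz"]),
            steady_start=int(g.attrs["steady_start"]),
            model=ModelSpec(**json.loads(g.attrs["model"])),
            config=SimConfig(**json.loads(g.attrs["config"])),
            provenance=json.loads(g.attrs["provenance"]),
        )
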