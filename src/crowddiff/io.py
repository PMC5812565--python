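"""Plain-text serialization: trajectories, obstacle fields, configs.

Trajectory tables are tidy delimited text with one row per (frame, tracer):
``time_ms, tracer_id, x_um, y_um, bound`` where x/y are unwrapped
displacements since the measurement origin.  Obstacle fields serialize as
``row,col,kind`` site lists.  Run configuration round-trips through a flat
YAML mapping mirroring the constructor parameters.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .engine import Trajectory
from .world import CRO, PRO, LatticeConfig, ObstacleField

__all__ = [
    "trajectory_frame",
    "write_trajectory",
    "read_trajectory_frame",
    "write_obstacle_sites",
    "read_obstacle_sites",
    "load_config",
    "write_manifest",
]


def trajectory_frame(traj: Trajectory) -> pd.DataFrame:
    """Long-format table of a trajectory that recorded full displacements."""
    if traj.disp_um is None:
        raise ValueError("trajectory was run without record_trajectories=True")
    n_frames, n_tr, _ = traj.disp_um.shape
    times = np.repeat(traj.times_ms, n_tr)
    ids = np.tile(np.arange(n_tr), n_frames)
    df = pd.DataFrame({
        "time_ms": times,
        "tracer_id": ids,
        "x_um": traj.disp_um[:, :, 0].ravel(),
        "y_um": traj.disp_um[:, :, 1].ravel(),
    })
    if traj.bound_frac is not None and traj.engine == "lattice":
        df["bound_frac_frame"] = np.repeat(traj.bound_frac, n_tr)
    return df


def write_trajectory(traj: Trajectory, path) -> None:
    trajectory_frame(traj).to_csv(path, index=False)


def read_trajectory_frame(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_obstacle_sites(fld: ObstacleField, path) -> None:
    """Site list 'row,col,kind' for CRO/PRO sites (empty sites omitted)."""
    with open(path, "w") as fh:
        fh.write("# row,col,kind\n")
        rows, cols = np.nonzero(fld.site_kind)
        for r, c in zip(rows, cols):
            kind = "CRO" if fld.site_kind[r, c] == CRO else "PRO"
            fh.write(f"{r},{c},{kind}\n")


def read_obstacle_sites(path, n_side: int, binding_energy: float = 0.0,
                        reflect_probability: float = 0.5) -> ObstacleField:
    kinds = np.zeros((n_side, n_side), dtype=np.int8)
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            r, c, kind = line.split(",")
            kinds[int(r), int(c)] = CRO if kind == "CRO" else PRO
    return ObstacleField(kinds, binding_energy, reflect_probability)


def load_config(path) -> dict:
    """Flat YAML key-value run configuration; returns a plain dict."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError("config file must contain a YAML mapping")
    return cfg


def lattice_config_from_dict(d: dict) -> LatticeConfig:
    if "n_side" in d and "step_length_um" in d:
        return LatticeConfig(
            n_side=int(d["n_side"]),
            step_length_um=float(d["step_length_um"]),
            time_step_ms=float(d.get("time_step_ms", 1e-3)),
            free_diffusion_um2_per_ms=float(d.get("free_diffusion_um2_per_ms", 0.2e-3)),
        )
    return LatticeConfig.from_physical(
        free_diffusion_um2_per_ms=float(d.get("free_diffusion_um2_per_ms", 0.2e-3)),
        time_step_ms=float(d.get("time_step_ms", 1e-3)),
        target_area_side_um=float(d.get("target_area_side_um", 1.0)),
    )


def write_manifest(meta: dict, path) -> None:
    Path(path).write_text(json.dumps(meta, indent=2, default=float))
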