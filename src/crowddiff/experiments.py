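"""Reproducible experiment orchestration: sweeps, presets, convergence.

A sweep runs a grid of crowding conditions (tracer density a_DT, reflecting
obstacle density a_CRO, binding obstacle density a_PRO, binding energy)
through either engine, characterizes each cell's ensemble MSD, and emits a
tidy results table plus per-cell summaries.  ``scale`` records whether the
run uses reference-scale parameters (1119^2 lattice, 2 s measurements,
hundreds of ensembles) or reduced desk-scale ones; desk runs shrink the
lattice, duration and ensemble count while keeping dl, dt, D and all
probabilities at their physical values, so area fractions — the controlled
variables — still set the statistical regime, at reduced precision.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .analysis import UM2_PER_MS_TO_NM2_PER_US, characterize, ensemble_msd
from .engine import SimulationSchedule, simulate_ensemble
from .continuum import simulate_disk_ensemble
from .world import LatticeConfig

__all__ = [
    "SweepSpec",
    "run_sweep",
    "convergence_report",
    "REFERENCE_A_DT_GRID",
    "REFERENCE_A_PRO_GRID",
    "REFERENCE_BINDING_GRID",
    "desk_preset",
]

#: reference-scale condition grids
REFERENCE_A_DT_GRID = (0.00001, 0.0001, 0.001, 0.005, 0.01, 0.1)
REFERENCE_A_CRO_GRID = (0.0, 0.1, 0.2, 0.25, 0.3, 0.35, 0.4, 0.45, 0.5, 0.6)
REFERENCE_A_PRO_GRID = (0.2, 0.4, 0.6, 0.8)
REFERENCE_BINDING_GRID = (2.0, 6.0, 10.0)


@dataclass(frozen=True)
class SweepSpec:
    """Grid of crowding conditions to simulate and characterize."""

    engine: str = "lattice"  # "lattice" | "continuous"
    a_dt: tuple = (0.0001,)
    a_cro: tuple = (0.0,)
    a_pro: tuple = (0.0,)
    binding_energy: tuple = (0.0,)
    exclusion: bool = False
    recursive: bool = True
    schedule: SimulationSchedule = field(default_factory=SimulationSchedule)
    scale: str = "desk"  # "reference" | "desk"
    n_side: int = 200
    box_side_um: float = 1.0
    base_seed: int = 0

    def cells(self):
        return list(itertools.product(self.a_dt, self.a_cro, self.a_pro,
                                      self.binding_energy))


def _cell_seed(base_seed: int, cell_index: int) -> int:
    return int(np.random.SeedSequence([base_seed, cell_index]).generate_state(1)[0]) % (2**31 - 1)


def run_sweep(spec: SweepSpec) -> pd.DataFrame:
    """Run every grid cell; one row per cell with its MSD characterization.

    Deterministic given ``base_seed`` (per-cell seeds are derived from it).
    Infeasible cells (e.g. over-capacity tracer placement) become rows with
    ``status="failed"`` rather than crashing the sweep.
    """
    rows = []
    for ci, (a_dt, a_cro, a_pro, be) in enumerate(spec.cells()):
        seed = _cell_seed(spec.base_seed, ci)
        sched = SimulationSchedule(
            anneal_ms=spec.schedule.anneal_ms,
            measure_ms=spec.schedule.measure_ms,
            record_interval_ms=spec.schedule.record_interval_ms,
            n_ensembles=spec.schedule.n_ensembles,
            seed=seed,
        )
        row = {
            "cell": ci, "engine": spec.engine, "scale": spec.scale,
            "a_dt": a_dt, "a_cro": a_cro, "a_pro": a_pro,
            "binding_energy": be, "exclusion": spec.exclusion,
            "recursive": spec.recursive, "seed": seed,
            "n_ensembles": sched.n_ensembles,
        }
        try:
            if spec.engine == "lattice":
                cfg = (LatticeConfig.from_physical() if spec.scale == "reference"
                       else LatticeConfig.desk(spec.n_side))
                trajs = simulate_ensemble(
                    cfg, sched, a_dt=a_dt, a_cro=a_cro, a_pro=a_pro,
                    binding_energy=be, exclusion=spec.exclusion,
                    recursive=spec.recursive,
                )
            elif spec.engine == "continuous":
                trajs = simulate_disk_ensemble(
                    a_dt, sched, box_side_um=spec.box_side_um,
                    exclusion=spec.exclusion,
                )
            else:
                raise ValueError(f"unknown engine {spec.engine!r}")
            prof = ensemble_msd(trajs)
            char = characterize(prof)
            row.update(
                status="ok",
                n_tracers=prof.n_tracers,
                realized_a_dt=trajs[0].meta.get("a_dt", a_dt),
                realized_a_cro=trajs[0].meta.get("a_cro", a_cro),
                realized_a_pro=trajs[0].meta.get("a_pro", a_pro),
                alpha=char.alpha,
                d_fit_um2_per_ms=char.d_fit_um2_per_ms,
                d_eff_um2_per_ms=char.d_eff_um2_per_ms,
                d_eff_nm2_per_us=char.d_eff_um2_per_ms * UM2_PER_MS_TO_NM2_PER_US,
                regime=char.regime,
                crossover_time_ms=char.crossover_time_ms,
                crossover_length_um2=char.crossover_length_um2,
            )
        except ValueError as err:
            row.update(status="failed", error=str(err))
        rows.append(row)
    return pd.DataFrame(rows)


def convergence_report(
    trajectories_by_cell: dict,
    n_blocks: int = 5,
    se_alpha_flag: float = 0.05,
    rng_seed: int = 0,
) -> pd.DataFrame:
    """Block-resampling standard errors of alpha and D_eff per cell.

    ``trajectories_by_cell`` maps a cell label to its list of per-ensemble
    trajectories.  Ensembles are split into blocks; each block is
    characterized separately and the SE across blocks reported.  Cells
    with a single ensemble are flagged, not errored.
    """
    rows = []
    rng = np.random.default_rng(rng_seed)
    for label, trajs in trajectories_by_cell.items():
        n_ens = len(trajs)
        if n_ens < 2:
            rows.append({"cell": label, "n_ensembles": n_ens,
                         "se_alpha": np.nan, "se_d_eff": np.nan,
                         "wide_se": True})
            continue
        k = min(n_blocks, n_ens)
        order = rng.permutation(n_ens)
        alphas, deffs = [], []
        for b in range(k):
            block = [trajs[i] for i in order[b::k]]
            char = characterize(ensemble_msd(block))
            alphas.append(char.alpha)
            deffs.append(char.d_eff_um2_per_ms)
        se_a = float(np.std(alphas, ddof=1) / np.sqrt(k))
        se_d = float(np.std(deffs, ddof=1) / np.sqrt(k))
        rows.append({"cell": label, "n_ensembles": n_ens,
                     "se_alpha": se_a, "se_d_eff": se_d,
                     "wide_se": bool(n_ens < 2 or se_a > se_alpha_flag)})
    return pd.DataFrame(rows)


def desk_preset(name: str, base_seed: int = 0) -> SweepSpec:
    """Named desk-scale presets for quick reproduction of the key effects."""
    if name == "crowding-switch":
        # self-crowding switch: alpha(a_DT=0.01) < alpha(a_DT=0.0001)
        return SweepSpec(
            engine="lattice", a_dt=(0.0001, 0.01), exclusion=True,
            schedule=SimulationSchedule(measure_ms=200.0,
                                        record_interval_ms=0.2,
                                        n_ensembles=20),
            n_side=200, base_seed=base_seed,
        )
    if name == "cro-monotone":
        return SweepSpec(
            engine="lattice", a_dt=(0.005,), a_cro=(0.0, 0.1, 0.2, 0.3),
            exclusion=False,
            schedule=SimulationSchedule(measure_ms=100.0,
                                        record_interval_ms=0.1,
                                        n_ensembles=2),
            n_side=200, base_seed=base_seed,
        )
    if name == "binding-mini":
        return SweepSpec(
            engine="lattice", a_dt=(0.005,), a_pro=(0.2, 0.4, 0.6),
            binding_energy=(2.0, 6.0), exclusion=False,
            schedule=SimulationSchedule(anneal_ms=200.0, measure_ms=200.0,
                                        record_interval_ms=0.2,
                                        n_ensembles=2),
            n_side=200, base_seed=base_seed,
        )
    raise ValueError(f"unknown preset {name!r}")


def sweep_manifest(spec: SweepSpec) -> str:
    """JSON manifest from which any results row can be regenerated."""
    d = asdict(spec)
    d["schedule"] = asdict(spec.schedule)
    return json.dumps(d, indent=2, default=float)
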