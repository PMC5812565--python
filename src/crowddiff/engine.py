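"""Lattice hopping engine: direction sampling, obstacle rules, recursion.

Each time step every tracer attempts one nearest-neighbour hop:

* the direction is drawn from quartiles of a uniform variate
  (u < 0.25 left, < 0.5 right, < 0.75 up, else down);
* a CRO destination always reflects; a PRO destination reflects with
  probability P_reflect and binds the tracer on arrival;
* a bound tracer escapes its PRO with per-step probability
  P_escape = exp(-E/kBT) and, on escape, immediately attempts one
  isotropic hop;
* with self-crowding (steric exclusion), a destination holding another
  tracer blocks the hop, and a PRO holding a bound tracer acts as a CRO.

Sequential updates create *false self-blocking*: a tracer can be blocked
by a neighbour that vacates the contested site later in the same step.
The recursive scheme therefore re-examines every tracer labelled
"blocked by another DT" in a second pass over the same pre-drawn
directions; destinations freed during pass one are then taken.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from . import _kernels
from .world import CRO, PRO, LatticeConfig, ObstacleField, TracerPopulation

__all__ = [
    "DIRECTIONS",
    "StepOutcome",
    "SimulationSchedule",
    "Trajectory",
    "sample_direction",
    "escape_probability",
    "attempt_hop",
    "step_population_recursive",
    "step_population_independent",
    "run_simulation",
    "simulate_ensemble",
]

DIRECTIONS = ("left", "right", "up", "down")
_DIR_INDEX = {name: i for i, name in enumerate(DIRECTIONS)}


def sample_direction(u: float) -> str:
    """Map a uniform variate in [0,1) onto one of the four hop directions."""
    if not 0.0 <= u < 1.0:
        raise ValueError("direction variate must lie in [0, 1)")
    return DIRECTIONS[int(u * 4.0)]


def escape_probability(binding_energy: float) -> float:
    """Per-step escape probability exp(-E/kBT) of a bound tracer."""
    if binding_energy < 0:
        raise ValueError("binding energy must be non-negative")
    return math.exp(-binding_energy)


@dataclass
class StepOutcome:
    """Per-tracer bookkeeping of one time step."""

    moved: np.ndarray
    blocked_by_dt: np.ndarray
    newly_bound: np.ndarray
    newly_unbound: np.ndarray


@dataclass(frozen=True)
class SimulationSchedule:
    """Annealing/measurement/recording plan for one condition."""

    anneal_ms: float = 0.0
    measure_ms: float = 2000.0
    record_interval_ms: float = 1.0
    n_ensembles: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.measure_ms <= 0:
            raise ValueError("measurement duration must be positive")
        if self.record_interval_ms <= 0:
            raise ValueError("record interval must be positive")
        if self.anneal_ms < 0:
            raise ValueError("anneal duration must be non-negative")
        if self.n_ensembles < 1:
            raise ValueError("need at least one ensemble")

    @classmethod
    def reference(cls, a_pro: float = 0.0, n_ensembles: int = 250, seed: int = 0,
              measure_ms: float = 2000.0) -> "SimulationSchedule":
        """Reference schedule: 2 s recording, 2 s annealing iff PROs present."""
        return cls(
            anneal_ms=2000.0 if a_pro > 0 else 0.0,
            measure_ms=measure_ms,
            record_interval_ms=1.0,
            n_ensembles=n_ensembles,
            seed=seed,
        )

    def steps(self, time_step_ms: float) -> tuple[int, int, int]:
        """(anneal, measure, record) in units of time steps; validates grid."""
        rec = self.record_interval_ms / time_step_ms
        if abs(rec - round(rec)) > 1e-9:
            raise ValueError("record interval must be an integer multiple of the time step")
        return (
            int(round(self.anneal_ms / time_step_ms)),
            int(round(self.measure_ms / time_step_ms)),
            int(round(rec)),
        )


@dataclass
class Trajectory:
    """Recorded output of one simulation run (lattice or continuous).

    msd is the tracer-averaged squared unwrapped displacement (um^2) at
    each recorded time; disp optionally holds the full per-tracer unwrapped
    displacement (um) when trajectories were requested.
    """

    times_ms: np.ndarray
    msd: np.ndarray
    n_tracers: int
    engine: str
    time_step_ms: float
    disp_um: np.ndarray | None = None
    bound_frac: np.ndarray | None = None
    anneal_bound_frac: np.ndarray | None = None
    meta: dict = field(default_factory=dict)


def _direction_codes(directions: Sequence[str | int]) -> np.ndarray:
    out = np.empty(len(directions), dtype=np.int64)
    for i, d in enumerate(directions):
        out[i] = _DIR_INDEX[d] if isinstance(d, str) else int(d)
    return out


def attempt_hop(
    tracer: int,
    direction: str | int,
    fld: ObstacleField,
    pop: TracerPopulation,
    u_reflect: float = 1.0,
) -> dict:
    """Reference single-tracer hop attempt (mutates the population).

    Implements the destination rules in pure Python; the numba kernels
    apply the same logic in bulk.  Returns a dict with ``moved``,
    ``blocked_by_dt``, ``newly_bound`` and ``newly_unbound`` flags.
    """
    n = fld.n_side
    d = _DIR_INDEX[direction] if isinstance(direction, str) else int(direction)
    dr, dc = int(_kernels._DR[d]), int(_kernels._DC[d])
    r, c = int(pop.rows[tracer]), int(pop.cols[tracer])
    nr, nc = (r + dr) % n, (c + dc) % n
    was_bound = bool(pop.bound[tracer])
    kind = int(fld.site_kind[nr, nc])
    moved = False
    blocked = False
    if kind == CRO:
        pass
    elif pop.exclusion and np.any((pop.rows == nr) & (pop.cols == nc)):
        blocked = True  # occupied by a tracer; a bound one makes the PRO a CRO
    elif kind == PRO and u_reflect < fld.reflect_probability:
        pass
    else:
        pop.rows[tracer], pop.cols[tracer] = nr, nc
        pop.disp_rows[tracer] += dr
        pop.disp_cols[tracer] += dc
        pop.bound[tracer] = kind == PRO
        moved = True
    if not moved:
        pop.bound[tracer] = int(fld.site_kind[r, c]) == PRO
    now_bound = bool(pop.bound[tracer])
    return {
        "moved": moved,
        "blocked_by_dt": blocked,
        "newly_bound": now_bound and not was_bound,
        "newly_unbound": was_bound and not now_bound,
    }


def _python_draw_moves(pop, fld, rng, literal_escape):
    n_tr = pop.n_tracers
    dirs = np.empty(n_tr, dtype=np.int64)
    uref = np.zeros(n_tr, dtype=np.float64)
    p_esc = escape_probability(fld.binding_energy)
    for i in range(n_tr):
        if pop.bound[i]:
            u = rng.random()
            escaped = (u >= p_esc) if literal_escape else (u < p_esc)
            if not escaped:
                dirs[i] = -1
                continue
        dirs[i] = int(rng.random() * 4.0)
        uref[i] = rng.random()
    return dirs, uref


def _step_exclusion_common(pop, fld, rng, recursive, literal_escape, directions):
    if not pop.exclusion:
        raise ValueError("population is not in exclusion (self-crowding) mode")
    n_tr = pop.n_tracers
    if directions is not None:
        dirs = _direction_codes(directions)
        uref1 = rng.random(n_tr)
    else:
        dirs, uref1 = _python_draw_moves(pop, fld, rng, literal_escape)
    uref2 = rng.random(n_tr)
    occ = np.zeros((fld.n_side, fld.n_side), dtype=np.uint8)
    occ[pop.rows, pop.cols] = 1
    moved = np.zeros(n_tr, dtype=np.bool_)
    blocked = np.zeros(n_tr, dtype=np.bool_)
    before = pop.bound.copy()
    _kernels.step_exclusion(
        fld.site_kind, occ, pop.rows, pop.cols, pop.disp_rows, pop.disp_cols,
        pop.bound, dirs, uref1, uref2, fld.reflect_probability,
        recursive, moved, blocked,
    )
    return StepOutcome(
        moved=moved,
        blocked_by_dt=blocked,
        newly_bound=pop.bound & ~before,
        newly_unbound=before & ~pop.bound,
    )


def step_population_recursive(
    pop: TracerPopulation,
    fld: ObstacleField,
    rng: np.random.Generator | int = 0,
    *,
    literal_escape: bool = False,
    directions: Sequence[str | int] | None = None,
) -> StepOutcome:
    """Advance one step with exclusion and the two-pass recursion.

    ``directions`` optionally forces the per-tracer hop directions (all
    tracers participate), which is how degenerate configurations such as
    the two-neighbour false-blocking case are exercised deterministically.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    return _step_exclusion_common(pop, fld, rng, True, literal_escape, directions)


def step_population_nonrecursive(
    pop: TracerPopulation,
    fld: ObstacleField,
    rng: np.random.Generator | int = 0,
    *,
    literal_escape: bool = False,
    directions: Sequence[str | int] | None = None,
) -> StepOutcome:
    """Single-pass variant (no re-check of blocked tracers), for comparison."""
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    return _step_exclusion_common(pop, fld, rng, False, literal_escape, directions)


def step_population_independent(
    pop: TracerPopulation,
    fld: ObstacleField,
    rng: np.random.Generator | int = 0,
    *,
    literal_escape: bool = False,
    directions: Sequence[str | int] | None = None,
) -> StepOutcome:
    """Advance one step without tracer-tracer exclusion."""
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    n_tr = pop.n_tracers
    if directions is not None:
        dirs = _direction_codes(directions)
        uref1 = rng.random(n_tr)
    else:
        dirs, uref1 = _python_draw_moves(pop, fld, rng, literal_escape)
    moved = np.zeros(n_tr, dtype=np.bool_)
    before = pop.bound.copy()
    _kernels.step_independent(
        fld.site_kind, pop.rows, pop.cols, pop.disp_rows, pop.disp_cols,
        pop.bound, dirs, uref1, fld.reflect_probability, moved,
    )
    return StepOutcome(
        moved=moved,
        blocked_by_dt=np.zeros(n_tr, dtype=np.bool_),
        newly_bound=pop.bound & ~before,
        newly_unbound=before & ~pop.bound,
    )


def run_simulation(
    cfg: LatticeConfig,
    fld: ObstacleField,
    pop: TracerPopulation,
    schedule: SimulationSchedule,
    *,
    recursive: bool = True,
    literal_escape: bool = False,
    record_trajectories: bool = False,
    seed: int | None = None,
) -> Trajectory:
    """Anneal (unrecorded), zero the displacement clock, then record.

    The unwrapped displacement accumulators are reset when measurement
    starts, so the MSD is measured from the post-anneal configuration.
    Identical seeds give bit-identical output.
    """
    n_anneal, n_measure, rec = schedule.steps(cfg.time_step_ms)
    kseed = int(schedule.seed if seed is None else seed) % (2**31 - 1)
    msd_sum, bound_frac, traj, anneal_bound, *_final = _kernels.run_lattice(
        fld.site_kind, pop.rows, pop.cols, pop.bound,
        pop.exclusion, recursive, literal_escape,
        fld.reflect_probability, escape_probability(fld.binding_energy),
        n_anneal, n_measure, rec, kseed, record_trajectories,
    )
    dl = cfg.step_length_um
    n_frames = msd_sum.size
    times = (np.arange(1, n_frames + 1) * rec) * cfg.time_step_ms
    n_tr = max(pop.n_tracers, 1)
    return Trajectory(
        times_ms=times,
        msd=msd_sum / n_tr * dl * dl,
        n_tracers=pop.n_tracers,
        engine="lattice",
        time_step_ms=cfg.time_step_ms,
        disp_um=traj.astype(np.float64) * dl if record_trajectories else None,
        bound_frac=bound_frac,
        anneal_bound_frac=anneal_bound,
        meta={
            "recursive": recursive,
            "exclusion": pop.exclusion,
            "a_dt": pop.a_dt,
            "a_cro": fld.a_cro,
            "a_pro": fld.a_pro,
            "binding_energy": fld.binding_energy,
            "reflect_probability": fld.reflect_probability,
            "seed": kseed,
            "n_side": cfg.n_side,
        },
    )


def simulate_ensemble(
    cfg: LatticeConfig,
    schedule: SimulationSchedule,
    *,
    a_dt: float,
    a_cro: float = 0.0,
    a_pro: float = 0.0,
    binding_energy: float = 0.0,
    reflect_probability: float = 0.5,
    exclusion: bool = False,
    recursive: bool = True,
    literal_escape: bool = False,
) -> list[Trajectory]:
    """Independent ensembles of lattices: fresh obstacles, placement and
    stepping noise per ensemble, with seeds spawned from the schedule seed."""
    from .world import build_obstacle_field, place_tracers

    root = np.random.SeedSequence(schedule.seed)
    children = root.spawn(schedule.n_ensembles)
    out = []
    for child in children:
        rng = np.random.default_rng(child)
        fld = build_obstacle_field(cfg, a_cro, a_pro, binding_energy,
                                   reflect_probability, rng)
        pop = place_tracers(cfg, fld, a_dt, exclusion, rng)
        kseed = int(child.generate_state(1)[0]) % (2**31 - 1)
        out.append(run_simulation(cfg, fld, pop, schedule,
                                  recursive=recursive,
                                  literal_escape=literal_escape,
                                  seed=kseed))
    return out
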