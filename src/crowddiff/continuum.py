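"""Continuous-space Brownian dynamics of hard disks.

Receptors are modelled as hard circular disks (exclusion radius 6 nm) in a
periodic square box.  Each time step every disk is proposed a displacement
``(dx, dy) = sqrt(2 D dt) * (xi_x, xi_y)`` with independent standard-normal
noise; disks are updated sequentially, and a proposal that would bring any
pair of centres closer than twice the radius (minimum image) is rejected,
the disk keeping its position.  This rejection scheme is the standard
Monte-Carlo realization of hard-core steric exclusion.

The engine serves as the continuous-space oracle against which the lattice
model's recursive self-crowding algorithm is checked for convergence.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from . import _kernels
from .engine import SimulationSchedule, Trajectory

__all__ = [
    "DiskWorld",
    "disk_count",
    "propose_step",
    "apply_exclusion",
    "place_disks",
    "run_continuous",
]

#: hard-disk exclusion radius of a receptor, um (6 nm)
DISK_RADIUS_UM: float = 6e-3


def disk_count(a_dt: float, box_side_um: float, radius_um: float = DISK_RADIUS_UM) -> int:
    """Number of disks realizing area fraction a_dt in a square box."""
    if a_dt < 0 or box_side_um <= 0 or radius_um <= 0:
        raise ValueError("area fraction must be >= 0, box and radius positive")
    return int(round(a_dt * box_side_um**2 / (math.pi * radius_um**2)))


@dataclass
class DiskWorld:
    """Hard disks in a periodic square box (lengths in um, times in ms)."""

    box_side_um: float
    radius_um: float
    x: np.ndarray
    y: np.ndarray
    diffusion_um2_per_ms: float
    time_step_ms: float
    exclusion: bool = True

    @property
    def n_disks(self) -> int:
        return self.x.size

    @property
    def step_sigma_um(self) -> float:
        """Per-axis standard deviation sqrt(2 D dt) of one proposal."""
        return math.sqrt(2.0 * self.diffusion_um2_per_ms * self.time_step_ms)

    def min_pair_distance(self) -> float:
        """Smallest pairwise centre distance under the minimum image."""
        if self.n_disks < 2:
            return math.inf
        dx = np.abs(self.x[:, None] - self.x[None, :])
        dy = np.abs(self.y[:, None] - self.y[None, :])
        L = self.box_side_um
        dx = np.minimum(dx, L - dx)
        dy = np.minimum(dy, L - dy)
        d = np.sqrt(dx**2 + dy**2)
        np.fill_diagonal(d, np.inf)
        return float(d.min())


def propose_step(world: DiskWorld, rng: np.random.Generator | int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Draw per-disk Gaussian displacement proposals sqrt(2 D dt) * xi."""
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    s = world.step_sigma_um
    return s * rng.standard_normal(world.n_disks), s * rng.standard_normal(world.n_disks)


def apply_exclusion(world: DiskWorld, px: np.ndarray, py: np.ndarray) -> np.ndarray:
    """Apply one sequential sweep of proposals; returns accepted mask.

    Mutates the world positions in place.  Rejected disks keep their
    position; accepted moves are those leaving every pair at centre
    distance >= 2 * radius.
    """
    n = world.n_disks
    ux = np.zeros(n)
    uy = np.zeros(n)
    x_before = world.x.copy()
    head = np.full(1, -1, dtype=np.int64)
    nxt = np.full(max(n, 1), -1, dtype=np.int64)
    _kernels.sweep_disks(
        world.x, world.y, ux, uy,
        np.ascontiguousarray(px, dtype=np.float64),
        np.ascontiguousarray(py, dtype=np.float64),
        world.box_side_um, 4.0 * world.radius_um**2,
        world.exclusion, 0, head, nxt,
    )
    return (ux != 0) | (uy != 0) | (world.x != x_before)


def place_disks(
    a_dt: float,
    box_side_um: float = 1.0,
    radius_um: float = DISK_RADIUS_UM,
    diffusion_um2_per_ms: float = 0.2e-3,
    time_step_ms: float = 1e-3,
    exclusion: bool = True,
    rng: np.random.Generator | int = 0,
    max_attempts_per_disk: int = 200,
) -> DiskWorld:
    """Uniform non-overlapping initial placement.

    Rejection sampling of uniform centres; beyond the density where that
    saturates (random sequential adsorption fills only ~0.55), placement
    falls back to a square grid seed, which the caller should follow with
    an equilibration (anneal) phase before measuring.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    n = disk_count(a_dt, box_side_um, radius_um)
    placement = "rejection"
    if n == 0:
        x = np.empty(0)
        y = np.empty(0)
    elif not exclusion:
        x = rng.uniform(0, box_side_um, n)
        y = rng.uniform(0, box_side_um, n)
    else:
        x = np.empty(n)
        y = np.empty(n)
        d2min = (2 * radius_um) ** 2
        L = box_side_um
        placed = 0
        budget = max_attempts_per_disk * n
        while placed < n and budget > 0:
            cx, cy = rng.uniform(0, L), rng.uniform(0, L)
            dx = np.abs(x[:placed] - cx)
            dy = np.abs(y[:placed] - cy)
            dx = np.minimum(dx, L - dx)
            dy = np.minimum(dy, L - dy)
            if placed == 0 or np.min(dx**2 + dy**2) >= d2min:
                x[placed], y[placed] = cx, cy
                placed += 1
            budget -= 1
        if placed < n:
            # dense regime: deterministic grid seed (spacing must clear 2r)
            m = math.ceil(math.sqrt(n))
            spacing = L / m
            if spacing < 2 * radius_um:
                raise ValueError(
                    f"cannot place {n} disks of radius {radius_um} in a box of side {L}"
                )
            gi = np.arange(n)
            x = (gi % m + 0.5) * spacing
            y = (gi // m + 0.5) * spacing
            placement = "grid"
    world = DiskWorld(box_side_um, radius_um, x, y,
                      diffusion_um2_per_ms, time_step_ms, exclusion)
    world.placement = placement  # recorded for the run manifest
    return world


def run_continuous(
    world: DiskWorld,
    schedule: SimulationSchedule,
    *,
    record_trajectories: bool = False,
    seed: int | None = None,
) -> Trajectory:
    """Anneal then record; same trajectory schema as the lattice engine."""
    n_anneal, n_steps, rec = schedule.steps(world.time_step_ms)
    kseed = int(schedule.seed if seed is None else seed) % (2**31 - 1)
    msd_sum, traj, _x, _y, acc_rate = _kernels.run_disks(
        world.x, world.y, world.box_side_um, world.radius_um,
        world.step_sigma_um, world.exclusion,
        n_anneal, n_steps, rec, kseed, record_trajectories,
    )
    n_frames = msd_sum.size
    times = (np.arange(1, n_frames + 1) * rec) * world.time_step_ms
    n = max(world.n_disks, 1)
    return Trajectory(
        times_ms=times,
        msd=msd_sum / n,
        n_tracers=world.n_disks,
        engine="continuous",
        time_step_ms=world.time_step_ms,
        disp_um=traj if record_trajectories else None,
        meta={
            "box_side_um": world.box_side_um,
            "radius_um": world.radius_um,
            "exclusion": world.exclusion,
            "acceptance_rate": float(acc_rate),
            "placement": getattr(world, "placement", "given"),
            "seed": kseed,
        },
    )


def simulate_disk_ensemble(
    a_dt: float,
    schedule: SimulationSchedule,
    *,
    box_side_um: float = 1.0,
    radius_um: float = DISK_RADIUS_UM,
    diffusion_um2_per_ms: float = 0.2e-3,
    time_step_ms: float = 1e-3,
    exclusion: bool = True,
) -> list[Trajectory]:
    """Independent hard-disk ensembles with seeds spawned from the schedule."""
    root = np.random.SeedSequence(schedule.seed)
    out = []
    for child in root.spawn(schedule.n_ensembles):
        rng = np.random.default_rng(child)
        world = place_disks(a_dt, box_side_um, radius_um,
                            diffusion_um2_per_ms, time_step_ms, exclusion, rng)
        kseed = int(child.generate_state(1)[0]) % (2**31 - 1)
        out.append(run_continuous(world, schedule, seed=kseed))
    return out
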