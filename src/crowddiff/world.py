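"""Discrete simulation world: lattice geometry, obstacle fields, tracer placement.

The membrane patch is a square lattice with periodic boundaries.  Each site
is empty, holds a completely-reflecting obstacle (CRO, e.g. an inert
transmembrane protein) or a partially-reflecting-cum-binding obstacle (PRO,
e.g. a submembranous scaffold protein).  Diffusing tracers (DTs) represent
receptors; they hop between nearest-neighbour sites once per time step.

The lattice constants follow from the free-diffusion closed form
``<r^2>(t) = 4 D t``: with one hop of length dl per time step dt the
single-step mean squared displacement is dl^2 = 4 D dt, so
``dl = sqrt(4 D dt)``.  With the receptor free-diffusion coefficient
D = 0.2e-3 um^2/ms and dt = 1e-3 ms this gives dl = 8.944e-4 um and a
1 um x 1 um patch of 1119 x 1119 sites (1118 edges per side).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "EMPTY",
    "CRO",
    "PRO",
    "LatticeConfig",
    "ObstacleField",
    "TracerPopulation",
    "derive_step_length",
    "derive_n_side",
    "build_obstacle_field",
    "place_tracers",
]

# site_kind codes (shared with the numba kernels)
EMPTY: int = 0
CRO: int = 1
PRO: int = 2

#: receptor free-diffusion coefficient in the unobstructed membrane, um^2/ms
FREE_DIFFUSION_UM2_PER_MS: float = 0.2e-3
#: simulation time step, ms
TIME_STEP_MS: float = 1e-3


def derive_step_length(free_diffusion_um2_per_ms: float, time_step_ms: float) -> float:
    """Lattice edge length dl = sqrt(4 D dt) in um.

    This is the hop length for which an unobstructed random walk with one
    hop per time step reproduces normal diffusion at coefficient D.
    """
    if free_diffusion_um2_per_ms <= 0 or time_step_ms <= 0:
        raise ValueError("diffusion coefficient and time step must be positive")
    return math.sqrt(4.0 * free_diffusion_um2_per_ms * time_step_ms)


def derive_n_side(target_area_side_um: float, step_length_um: float) -> int:
    """Number of lattice sites per side approximating a square patch.

    Sites = edges + 1: a patch of side L needs round(L/dl) edges, hence
    round(L/dl) + 1 sites per side.
    """
    if target_area_side_um <= 0 or step_length_um <= 0:
        raise ValueError("side length and step length must be positive")
    return int(round(target_area_side_um / step_length_um)) + 1


@dataclass(frozen=True)
class LatticeConfig:
    """Physical and discrete geometry of the square lattice."""

    n_side: int
    step_length_um: float
    time_step_ms: float
    free_diffusion_um2_per_ms: float
    boundary: str = "periodic"

    def __post_init__(self) -> None:
        if self.n_side < 3:
            raise ValueError("n_side must be at least 3")
        if self.step_length_um <= 0 or self.time_step_ms <= 0:
            raise ValueError("step length and time step must be positive")
        if self.boundary != "periodic":
            raise ValueError("only periodic boundaries are supported")

    @classmethod
    def from_physical(
        cls,
        free_diffusion_um2_per_ms: float = FREE_DIFFUSION_UM2_PER_MS,
        time_step_ms: float = TIME_STEP_MS,
        target_area_side_um: float = 1.0,
    ) -> "LatticeConfig":
        """Derive dl from D and dt, then size the lattice to the target patch."""
        dl = derive_step_length(free_diffusion_um2_per_ms, time_step_ms)
        return cls(
            n_side=derive_n_side(target_area_side_um, dl),
            step_length_um=dl,
            time_step_ms=time_step_ms,
            free_diffusion_um2_per_ms=free_diffusion_um2_per_ms,
        )

    @classmethod
    def desk(cls, n_side: int = 200) -> "LatticeConfig":
        """Reduced lattice at unchanged physical constants (dl, dt, D).

        Area fractions, not absolute counts, control the statistics, so a
        smaller patch preserves the regime at reduced precision.
        """
        dl = derive_step_length(FREE_DIFFUSION_UM2_PER_MS, TIME_STEP_MS)
        return cls(n_side, dl, TIME_STEP_MS, FREE_DIFFUSION_UM2_PER_MS)

    @property
    def n_sites(self) -> int:
        return self.n_side * self.n_side


def _rounded_count(fraction: float, n_sites: int) -> int:
    # round-half-up of fraction * n_sites
    return int(math.floor(fraction * n_sites + 0.5))


@dataclass
class ObstacleField:
    """Immobile obstacle occupancy of the lattice.

    site_kind is an (n_side, n_side) int8 grid of EMPTY/CRO/PRO codes.
    binding_energy is the uniform tracer-PRO binding energy in kBT units;
    reflect_probability is the chance a PRO reflects an incoming tracer.
    a_cro / a_pro are the *realized* area fractions.
    """

    site_kind: np.ndarray
    binding_energy: float = 0.0
    reflect_probability: float = 0.5
    a_cro: float = field(init=False)
    a_pro: float = field(init=False)

    def __post_init__(self) -> None:
        if self.binding_energy < 0:
            raise ValueError("binding energy must be non-negative")
        if not 0.0 <= self.reflect_probability <= 1.0:
            raise ValueError("reflect probability must lie in [0, 1]")
        kinds = np.asarray(self.site_kind, dtype=np.int8)
        if kinds.ndim != 2 or kinds.shape[0] != kinds.shape[1]:
            raise ValueError("site_kind must be a square grid")
        self.site_kind = kinds
        n_sites = kinds.size
        self.a_cro = float(np.count_nonzero(kinds == CRO)) / n_sites
        self.a_pro = float(np.count_nonzero(kinds == PRO)) / n_sites

    @property
    def n_side(self) -> int:
        return self.site_kind.shape[0]


def build_obstacle_field(
    cfg: LatticeConfig,
    a_cro: float = 0.0,
    a_pro: float = 0.0,
    binding_energy: float = 0.0,
    reflect_probability: float = 0.5,
    rng_seed: int | np.random.Generator = 0,
) -> ObstacleField:
    """Place CRO and PRO obstacles uniformly at random without overlap.

    Exactly round-half-up(a * n_sites) sites of each kind are placed, so
    the realized fraction matches the requested one to within half a site.
    """
    if not (0.0 <= a_cro <= 1.0 and 0.0 <= a_pro <= 1.0):
        raise ValueError("area fractions must lie in [0, 1]")
    if a_cro + a_pro > 1.0:
        raise ValueError("obstacle fractions sum above 1")
    rng = np.random.default_rng(rng_seed) if not isinstance(rng_seed, np.random.Generator) else rng_seed
    n_sites = cfg.n_sites
    n_cro = _rounded_count(a_cro, n_sites)
    n_pro = _rounded_count(a_pro, n_sites)
    if n_cro + n_pro > n_sites:
        raise ValueError("requested obstacle counts exceed the lattice size")
    kinds = np.zeros(n_sites, dtype=np.int8)
    chosen = rng.choice(n_sites, size=n_cro + n_pro, replace=False)
    kinds[chosen[:n_cro]] = CRO
    kinds[chosen[n_cro:]] = PRO
    return ObstacleField(
        site_kind=kinds.reshape(cfg.n_side, cfg.n_side),
        binding_energy=binding_energy,
        reflect_probability=reflect_probability,
    )


@dataclass
class TracerPopulation:
    """Diffusing tracers on the lattice.

    rows/cols are 0-based site coordinates; disp_rows/disp_cols accumulate
    the unwrapped displacement in lattice units (MSD across the periodic
    boundary is only meaningful on unwrapped coordinates).  In exclusion
    mode at most one tracer occupies a site (self-crowding); without it
    tracers are independent and may share sites.
    """

    rows: np.ndarray
    cols: np.ndarray
    disp_rows: np.ndarray
    disp_cols: np.ndarray
    bound: np.ndarray
    exclusion: bool
    a_dt: float

    @property
    def n_tracers(self) -> int:
        return self.rows.size

    def copy(self) -> "TracerPopulation":
        return TracerPopulation(
            self.rows.copy(), self.cols.copy(),
            self.disp_rows.copy(), self.disp_cols.copy(),
            self.bound.copy(), self.exclusion, self.a_dt,
        )


def place_tracers(
    cfg: LatticeConfig,
    fld: ObstacleField,
    a_dt: float,
    exclusion: bool,
    rng_seed: int | np.random.Generator = 0,
) -> TracerPopulation:
    """Place round-half-up(a_dt * n_sites) tracers uniformly on non-CRO sites.

    Tracers never start on a CRO; starting on a PRO is allowed and such
    tracers begin in the bound state.  In exclusion mode the chosen sites
    are distinct; a request exceeding the number of non-CRO sites raises.
    """
    if not 0.0 <= a_dt <= 1.0:
        raise ValueError("tracer area fraction must lie in [0, 1]")
    rng = np.random.default_rng(rng_seed) if not isinstance(rng_seed, np.random.Generator) else rng_seed
    n_sites = cfg.n_sites
    count = _rounded_count(a_dt, n_sites)
    free = np.flatnonzero(fld.site_kind.ravel() != CRO)
    if exclusion and count > free.size:
        raise ValueError(
            f"cannot place {count} mutually excluding tracers on {free.size} non-CRO sites"
        )
    if count > 0 and free.size == 0:
        raise ValueError("no non-CRO sites available for tracer placement")
    sites = rng.choice(free, size=count, replace=not exclusion)
    rows, cols = np.divmod(sites.astype(np.int64), cfg.n_side)
    bound = fld.site_kind[rows, cols] == PRO
    return TracerPopulation(
        rows=rows,
        cols=cols,
        disp_rows=np.zeros(count, dtype=np.int64),
        disp_cols=np.zeros(count, dtype=np.int64),
        bound=bound.astype(np.bool_),
        exclusion=bool(exclusion),
        a_dt=count / n_sites,
    )
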