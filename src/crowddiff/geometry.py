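"""Bridging arithmetic between molecular geometry and lattice area fractions.

The simulation engines work with dimensionless area fractions (the fraction
of the membrane patch covered by the steric-exclusion footprints of tracers,
reflecting obstacles, or scaffold binding sites).  Experimental literature
instead reports molecular dimensions (nm) and areal densities (count per
square micron).  This module converts between the two pictures:

    density [um^-2] x exclusion area [um^2]  ->  occupied area fraction

Canonical internal unit is um^2; nm^2 inputs are converted explicitly
(1 nm^2 = 1e-6 um^2).  Reference footprints: an AMPA-receptor extracellular
domain projects to roughly a 16 nm x 8 nm rectangle (128 nm^2); a PSD-95
scaffold protein is taken as a disc of radius 2.5 nm.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

NM2_PER_UM2 = 1e6

__all__ = [
    "MolecularFootprint",
    "exclusion_area",
    "area_fraction_from_density",
    "density_from_count",
    "AMPAR_FOOTPRINT",
    "PSD95_FOOTPRINT",
]


@dataclass(frozen=True)
class MolecularFootprint:
    """Two-dimensional steric footprint of a membrane molecule.

    Parameters
    ----------
    shape : {"rectangle", "disc"}
    length_nm, width_nm : rectangle sides (rectangle only)
    radius_nm : disc radius (disc only)
    """

    shape: str
    length_nm: float = 0.0
    width_nm: float = 0.0
    radius_nm: float = 0.0
    exclusion_area_nm2: float = field(init=False)

    def __post_init__(self) -> None:
        if self.shape == "rectangle":
            if self.length_nm <= 0 or self.width_nm <= 0:
                raise ValueError("rectangle footprint needs positive length and width")
            area = self.length_nm * self.width_nm
        elif self.shape == "disc":
            if self.radius_nm <= 0:
                raise ValueError("disc footprint needs a positive radius")
            area = math.pi * self.radius_nm**2
        else:
            raise ValueError(f"unknown footprint shape {self.shape!r}")
        object.__setattr__(self, "exclusion_area_nm2", area)

    @property
    def exclusion_area_um2(self) -> float:
        return self.exclusion_area_nm2 / NM2_PER_UM2


#: AMPA receptor extracellular-domain footprint, 16 nm x 8 nm rectangle.
AMPAR_FOOTPRINT = MolecularFootprint("rectangle", length_nm=16.0, width_nm=8.0)
#: PSD-95 scaffold protein footprint, disc of radius 2.5 nm.
PSD95_FOOTPRINT = MolecularFootprint("disc", radius_nm=2.5)


def exclusion_area(footprint: MolecularFootprint) -> float:
    """Steric exclusion area of a footprint in nm^2."""
    return footprint.exclusion_area_nm2


def area_fraction_from_density(
    density_per_um2: float | None = None,
    exclusion_area_nm2: float = 0.0,
    *,
    count: int | None = None,
    region_area_um2: float | None = None,
) -> float:
    """Fraction of membrane area covered by a molecular population.

    Either pass ``density_per_um2`` directly, or a raw ``count`` together
    with ``region_area_um2`` (the count is converted to a density first).

    Raises
    ------
    ValueError
        on non-positive exclusion area, inconsistent arguments, or when the
        resulting fraction exceeds 1 (over-packed membrane).
    """
    if exclusion_area_nm2 <= 0:
        raise ValueError("exclusion area must be positive")
    if density_per_um2 is None:
        if count is None or region_area_um2 is None:
            raise ValueError("pass density_per_um2, or count with region_area_um2")
        if region_area_um2 <= 0:
            raise ValueError("region area must be positive")
        density_per_um2 = count / region_area_um2
    if density_per_um2 < 0:
        raise ValueError("density must be non-negative")
    fraction = density_per_um2 * exclusion_area_nm2 / NM2_PER_UM2
    if fraction > 1:
        raise ValueError(f"occupied fraction {fraction:.3g} exceeds 1 (over-packing)")
    return fraction


def density_from_count(
    count: int,
    *,
    disc_radius_nm: float | None = None,
    area_um2: float | None = None,
) -> float:
    """Areal density (um^-2) of ``count`` molecules in a region.

    The region is given either as a disc radius in nm (e.g. a 100 nm PSD)
    or directly as an area in um^2.
    """
    if count < 0:
        raise ValueError("count must be non-negative")
    if disc_radius_nm is not None:
        if disc_radius_nm <= 0:
            raise ValueError("disc radius must be positive")
        area_um2 = math.pi * (disc_radius_nm * 1e-3) ** 2
    if area_um2 is None or area_um2 <= 0:
        raise ValueError("pass a positive disc_radius_nm or area_um2")
    return count / area_um2
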