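"""Vesicle geometry and protein-binding stoichiometry.

A large unilamellar vesicle of outer diameter d with bilayer thickness h
holds ``(4 pi (d/2)^2 + 4 pi (d/2 - h)^2) / a`` lipids (outer plus inner
leaflet over the area per lipid a).  The theoretical surface capacity for an
adsorbed protein with elliptical footprint axes (a, b) is
``floor(4 pi (d/2)^2 / (pi a b))``.  The measured binding value P_B
(g protein per mol lipid) converts to molecules per vesicle via
``P_B * lipids_per_vesicle / M_protein``.

Defaults: bilayer thickness 5 nm, area per lipid 0.71 nm^2 (fluid
phosphatidylcholine), BSA footprint 14 x 4 nm ellipsoid of revolution and
molar mass 66,430 g/mol.
"""

from __future__ import annotations

import math
from dataclasses import dataclass


@dataclass(frozen=True)
class VesicleSpec:
    outer_diameter: float          # nm
    bilayer_thickness: float = 5.0  # nm
    area_per_lipid: float = 0.71   # nm^2

    def __post_init__(self):
        if self.outer_diameter <= 0 or self.bilayer_thickness < 0 or self.area_per_lipid <= 0:
            raise ValueError("vesicle parameters must be positive")
        if self.outer_diameter <= 2 * self.bilayer_thickness:
            raise ValueError("outer diameter must exceed twice the bilayer thickness")


@dataclass(frozen=True)
class ProteinFootprint:
    axis_a: float = 14.0           # nm
    axis_b: float = 4.0            # nm
    molar_mass: float = 66_430.0   # g/mol (BSA)

    def __post_init__(self):
        if self.axis_a <= 0 or self.axis_b <= 0 or self.molar_mass <= 0:
            raise ValueError("footprint parameters must be positive")

    @property
    def area(self) -> float:
        """Elliptical footprint area pi * a * b (nm^2), with the printed
        axis values entering directly."""
        return math.pi * self.axis_a * self.axis_b


@dataclass(frozen=True)
class BindingResult:
    p_b: float                 # g protein / mol lipid
    lipids_per_vesicle: int
    protein_per_vesicle: float

    def __post_init__(self):
        if self.p_b < 0 or self.lipids_per_vesicle < 0 or self.protein_per_vesicle < 0:
            raise ValueError("binding quantities must be non-negative")


def sphere_surface_area(diameter: float) -> float:
    """Surface area 4 pi (d/2)^2 in nm^2."""
    if diameter <= 0:
        raise ValueError("diameter must be positive")
    return 4.0 * math.pi * (diameter / 2.0) ** 2


def lipids_per_vesicle(v: VesicleSpec) -> int:
    """Lipid count over both leaflets, rounded to the nearest integer."""
    outer = sphere_surface_area(v.outer_diameter)
    inner_d = v.outer_diameter - 2.0 * v.bilayer_thickness
    inner = sphere_surface_area(inner_d) if inner_d > 0 else outer
    # degenerate thickness h = 0 -> both leaflets share the outer radius
    if v.bilayer_thickness == 0:
        inner = outer
    return round((outer + inner) / v.area_per_lipid)


def protein_surface_capacity(diameter: float, fp: ProteinFootprint = ProteinFootprint()) -> int:
    """Maximum proteins packed side-by-side on the outer surface (floored)."""
    return math.floor(sphere_surface_area(diameter) / fp.area)


def bound_protein_per_vesicle(
    p_b: float, v: VesicleSpec, fp: ProteinFootprint = ProteinFootprint()
) -> float:
    """Protein molecules per vesicle from the binding value P_B."""
    if p_b < 0:
        raise ValueError("P_B must be non-negative")
    return p_b * lipids_per_vesicle(v) / fp.molar_mass


def pb_from_concentrations(protein: float, lipid: float) -> float:
    """P_B = protein mass concentration (g/L) over lipid molarity (mol/L)."""
    if lipid <= 0:
        raise ValueError("lipid concentration must be positive")
    if protein < 0:
        raise ValueError("protein concentration must be non-negative")
    return protein / lipid


def binding_stoichiometry(
    p_b: float,
    diameter: float,
    bilayer_thickness: float = 5.0,
    area_per_lipid: float = 0.71,
    fp: ProteinFootprint = ProteinFootprint(),
) -> BindingResult:
    """Convenience wrapper: P_B plus vesicle size -> full stoichiometry."""
    v = VesicleSpec(diameter, bilayer_thickness, area_per_lipid)
    n_lip = lipids_per_vesicle(v)
    return BindingResult(
        p_b=p_b,
        lipids_per_vesicle=n_lip,
        protein_per_vesicle=p_b * n_lip / fp.molar_mass,
    )
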