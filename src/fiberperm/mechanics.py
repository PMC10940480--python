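"""Hyperelastic material model of the polypropylene fiber wall.

The fiber wall is described by a compressible Neo-Hookean strain-energy
potential

    U = C10 * (I1_bar - 3) + (1 / D1) * (J_el - 1)^2

with ``I1_bar`` the first deviatoric strain invariant and ``J_el`` the
elastic volume ratio.  The shipped default constants (C10 = 17.308 MPa,
D1 = 0.027 MPa^-1) were calibrated on transverse-compression tests of
commercial 380 um polypropylene oxygenator fibers; they correspond to a
small-strain shear modulus of ~34.6 MPa, a bulk modulus of ~74 MPa and a
Poisson ratio of ~0.30.

The structural contact problem itself (pressing fiber layers together) is
outside the scope of this package; the material model is kept as the
physical anchor of the flattened-contact geometry approximation and for
downstream structural work.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "InvalidStrainError",
    "NeoHookeanMaterial",
    "StrainState",
    "strain_energy",
    "derived_moduli",
    "DEFAULT_FIBER_MATERIAL",
]


class InvalidStrainError(ValueError):
    """Strain state outside the admissible domain (I1_bar >= 3, J > 0)."""


@dataclass(frozen=True)
class NeoHookeanMaterial:
    """Neo-Hookean constants: C10 in MPa, D1 in 1/MPa."""

    C10: float
    D1: float

    def __post_init__(self):
        if not self.C10 > 0:
            raise ValueError("C10 must be positive")
        if not self.D1 > 0:
            raise ValueError("D1 must be positive")


@dataclass(frozen=True)
class StrainState:
    """Isochoric/volumetric strain measures entering the potential."""

    I1_bar: float
    J_el: float = 1.0

    def __post_init__(self):
        if self.I1_bar < 3.0:
            raise InvalidStrainError("first deviatoric invariant must be >= 3")
        if not self.J_el > 0:
            raise InvalidStrainError("elastic volume ratio must be positive")


def strain_energy(mat: NeoHookeanMaterial, state: StrainState) -> float:
    """Strain-energy density U in MPa (= MJ/m^3)."""
    return mat.C10 * (state.I1_bar - 3.0) + (state.J_el - 1.0) ** 2 / mat.D1


def derived_moduli(mat: NeoHookeanMaterial) -> tuple:
    """Small-strain (shear modulus, bulk modulus, Poisson ratio).

    mu0 = 2*C10 and K = 2/D1 are the standard small-strain limits of the
    potential; the Poisson ratio follows from the isotropic relation
    nu = (3K - 2mu) / (2(3K + mu)).
    """
    mu0 = 2.0 * mat.C10
    bulk = 2.0 / mat.D1
    nu = (3.0 * bulk - 2.0 * mu0) / (2.0 * (3.0 * bulk + mu0))
    return mu0, bulk, nu


#: Constants calibrated on fiber transverse-compression testing.
DEFAULT_FIBER_MATERIAL = NeoHookeanMaterial(C10=17.308, D1=0.027)
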