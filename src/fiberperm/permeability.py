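"""Darcy permeability extraction and normalization.

Permeability follows from the unit-cell flow solution through Darcy's law

    K = mu * (Q / A) * (L / dP)

with Q the volumetric flow rate through the cell, A the total cross-section
of the porous medium associated with the cell (normal to the flow), L the
cell length along the flow direction and dP the pressure drop across the
cell.  A and L are taken from the nominal box dimensions at the current
press-fit degree, so the Z extent shrinks with compression while the
in-plane extents do not.

Press-fit sweeps are reported normalized by K0, the same-direction
permeability of the undeformed cell.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .geometry import UnitCell
from .flow import (FlowProblem, SolverSettings, Fluid, WATER, solve_flow,
                   _AXES)
from .voxel import voxelize, enforce_min_gap, measure_porosity

__all__ = [
    "SingularInputError",
    "IncompleteSweepError",
    "DarcyInputs",
    "PermeabilityResult",
    "darcy_K",
    "directional_permeability",
    "normalize",
]


class SingularInputError(ValueError):
    """Darcy's law evaluated with a vanishing pressure drop."""


class IncompleteSweepError(ValueError):
    """Normalization requested without a 0%-press-fit reference entry."""


@dataclass(frozen=True)
class DarcyInputs:
    """SI inputs of Darcy's law."""

    Q: float  # m^3/s
    A: float  # m^2
    L: float  # m
    dP: float  # Pa
    mu: float  # kg/(m s)

    def __post_init__(self):
        for name in ("Q", "A", "L", "mu"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def darcy_K(inputs: DarcyInputs) -> float:
    """K = mu * (Q/A) * (L/dP), in m^2."""
    if inputs.dP == 0:
        raise SingularInputError("pressure drop is zero")
    return inputs.mu * (inputs.Q / inputs.A) * (inputs.L / inputs.dP)


@dataclass
class PermeabilityResult:
    """Directional permeability of one unit cell.

    ``K0`` and ``K_normalized`` are populated by :func:`normalize` once a
    press-fit sweep is complete.
    """

    K: float  # m^2
    direction: str
    porosity: float
    press_fit_degree: float
    method: str
    bundle_id: str = ""
    K0: float | None = None
    K_normalized: float | None = None
    dP: float | None = None
    Q: float | None = None
    reynolds: float | None = None
    spacing: float | None = None  # um
    solver_info: dict | None = None


def directional_permeability(cell: UnitCell, direction, resolution: float | None = None,
                             settings: SolverSettings | None = None,
                             fluid: Fluid = WATER, min_gap: float = 1.0,
                             lateral_bc: str | None = None,
                             bundle_id: str = "") -> PermeabilityResult:
    """Voxelize, enforce the minimum gap, solve the flow and apply Darcy.

    Parameters
    ----------
    cell : UnitCell
        Possibly press-fitted repetitive unit.
    direction : {"x", "y", "z"}
    resolution : float, optional
        Voxel spacing in um; default outer_diameter / 32.
    lateral_bc : str, optional
        Default: symmetry faces for orthogonal cells (as valid), periodic
        for angled cells.
    """
    d = cell.spec.outer_diameter
    spacing = resolution if resolution is not None else d / 32.0
    if lateral_bc is None:
        lateral_bc = ("symmetry" if cell.layout.configuration == "orthogonal"
                      else "periodic")
    grid = enforce_min_gap(voxelize(cell, spacing), min_gap)
    poro = measure_porosity(grid)
    problem = FlowProblem(grid=grid, flow_direction=direction,
                          lateral_bc=lateral_bc, fluid=fluid)
    field = solve_flow(problem, settings)
    ax = _AXES[direction]
    box = np.array(cell.box_dimensions) * 1e-6  # m
    A = float(np.prod(np.delete(box, ax)))
    L = float(box[ax])
    K = darcy_K(DarcyInputs(Q=field.Q, A=A, L=L, dP=field.dP, mu=fluid.viscosity))
    return PermeabilityResult(
        K=K,
        direction=str(direction),
        porosity=poro.porosity,
        press_fit_degree=cell.press_fit.degree,
        method=cell.press_fit.method,
        bundle_id=bundle_id,
        dP=field.dP,
        Q=field.Q,
        reynolds=field.reynolds,
        spacing=spacing,
        solver_info=field.info,
    )


def normalize(results: Sequence[PermeabilityResult]) -> list:
    """Populate K0 and K_normalized against the 0%-degree entry per group.

    Entries are grouped by (bundle_id, direction, deformation-method family);
    the degree-0 entry of each group is the reference.  Raises
    :class:`IncompleteSweepError` if a group has no reference.
    """
    out = []
    refs = {}
    for r in results:
        if r.press_fit_degree == 0.0:
            refs[(r.bundle_id, r.direction)] = r.K
    for r in results:
        key = (r.bundle_id, r.direction)
        if key not in refs:
            raise IncompleteSweepError(
                f"no 0% press-fit reference for bundle={r.bundle_id!r} "
                f"direction={r.direction!r}"
            )
        k0 = refs[key]
        out.append(replace_result(r, K0=k0, K_normalized=r.K / k0))
    return out


def replace_result(r: PermeabilityResult, **kw) -> PermeabilityResult:
    d = dict(r.__dict__)
    d.update(kw)
    return PermeabilityResult(**d)
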