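"""Periodic unit-cell flow at low Reynolds number.

Solves steady incompressible laminar flow through a voxelized repetitive
unit, driven by a uniform body force along the flow direction with fully
periodic pressure.  In the Darcy regime this driving is equivalent to a
prescribed mass-flow-rate pair with zero outlet pressure; the cell pressure
drop is reported as (force density) x (cell length).

The discrete solver is the D3Q19 TRT lattice Boltzmann kernel in
:mod:`fiberperm.lattice`.  ``advection="stokes"`` (default) drops the
quadratic equilibrium terms: the update is exactly linear, which guarantees
the Darcy proportionality between pressure drop and flow rate and lets the
solution be rescaled exactly to the target Reynolds number.
``advection="navier_stokes"`` keeps the inertial terms and adjusts the
driving force iteratively until the superficial velocity matches the target
Reynolds number.

Reynolds number convention: Re = rho * u_superficial * d_outer / mu, with
the fiber outer diameter as the characteristic length.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .geometry import FiberSpec
from .lattice import W as W_REST
from .lattice import build_lattice, run_to_steady
from .voxel import VoxelGrid, check_percolation, voxelize, enforce_min_gap

__all__ = [
    "FlowError",
    "NoFlowError",
    "ConvergenceError",
    "Fluid",
    "WATER",
    "SolverSettings",
    "FlowProblem",
    "FlowField",
    "ConvergenceReport",
    "solve_flow",
    "grid_convergence",
    "reynolds",
    "superficial_velocity_for_reynolds",
]

_AXES = {"x": 0, "y": 1, "z": 2, 0: 0, 1: 1, 2: 2}
_UM = 1e-6


class FlowError(RuntimeError):
    pass


class NoFlowError(FlowError):
    """The fluid phase does not percolate in the requested direction."""


class ConvergenceError(FlowError):
    """The iterative solver did not reach the residual threshold."""


@dataclass(frozen=True)
class Fluid:
    """Newtonian fluid: dynamic viscosity kg/(m s), density kg/m^3."""

    viscosity: float = 1.0e-3
    density: float = 998.0

    def __post_init__(self):
        if self.viscosity <= 0 or self.density <= 0:
            raise ValueError("fluid properties must be positive")

    @property
    def kinematic_viscosity(self) -> float:
        return self.viscosity / self.density


#: Water at the permeability-test operating point.
WATER = Fluid()


@dataclass(frozen=True)
class SolverSettings:
    """Iteration controls for the lattice kernel.

    ``residual_tolerance`` bounds the relative L1 change of the velocity
    field over one 100-step check interval (on two consecutive checks).
    ``lattice_viscosity`` is the kinematic viscosity in lattice units; with
    the TRT magic parameter fixed the extracted permeability is insensitive
    to it.  When unset it defaults to 0.5 in Stokes mode (fast relaxation of
    the exactly linear update) and 1/6 in Navier-Stokes mode (the unit
    relaxation time, which keeps the quadratic update robust).
    """

    residual_tolerance: float = 1.0e-5
    max_iterations: int = 200_000
    advection: str = "stokes"  # "stokes" | "navier_stokes"
    lattice_viscosity: float | None = None  # default 0.5 (stokes), 1/6 (NS)

    def __post_init__(self):
        if self.residual_tolerance <= 0:
            raise ValueError("residual_tolerance must be positive")
        if self.advection not in ("stokes", "navier_stokes"):
            raise ValueError(f"unknown advection model {self.advection!r}")


@dataclass
class FlowProblem:
    """A periodic flow problem on a voxel grid.

    ``lateral_bc`` may be "symmetry" only for geometries whose lateral cell
    faces are mirror planes (the orthogonal configuration); angled cells
    require fully periodic lateral faces.
    """

    grid: VoxelGrid
    flow_direction: object = "z"
    lateral_bc: str = "periodic"
    fluid: Fluid = WATER
    driving: str = "body_force"  # "body_force" | "pressure_jump"
    target_Re: float = 1.0
    char_length: float | None = None  # um; default: fiber outer diameter

    def __post_init__(self):
        if self.lateral_bc not in ("periodic", "symmetry"):
            raise ValueError(f"unknown lateral_bc {self.lateral_bc!r}")
        cell = self.grid.cell
        if (self.lateral_bc == "symmetry" and cell is not None
                and cell.layout.configuration == "angled"):
            raise ValueError("angled cells require periodic lateral faces")
        if self.driving not in ("body_force", "pressure_jump"):
            raise ValueError(f"unknown driving {self.driving!r}")

    @property
    def axis(self) -> int:
        return _AXES[self.flow_direction]

    def characteristic_length(self) -> float:
        if self.char_length is not None:
            return self.char_length
        if self.grid.cell is not None:
            return self.grid.cell.spec.outer_diameter
        raise ValueError("char_length required for grids without a source cell")


@dataclass
class FlowField:
    """Steady solution of a periodic flow problem (SI units).

    ``pressure`` is the periodic part of the pressure; the mean driving
    gradient is carried by ``dP`` over the cell length.
    """

    velocity: np.ndarray  # (nx, ny, nz, 3) m/s, zero on solid voxels
    pressure: np.ndarray  # (nx, ny, nz) Pa, periodic part
    dP: float  # Pa across the cell along the flow direction
    Q: float  # m^3/s through the cell cross-section
    superficial_velocity: float  # m/s, Q / (total cross-section area)
    reynolds: float
    problem: FlowProblem
    info: dict = field(default_factory=dict)

    def plane_flow_rates(self) -> np.ndarray:
        """Volumetric flow rate through every cross-section plane, m^3/s."""
        ax = self.problem.axis
        grid = self.problem.grid
        h = grid.actual_spacing * _UM
        area = float(np.prod(np.delete(h, ax)))
        u = np.moveaxis(self.velocity[..., ax], ax, 0)
        return u.sum(axis=(1, 2)) * area

    def divergence_norm(self) -> float:
        """Max |div u| scaled by (voxel / mean speed); periodic differences."""
        grid = self.problem.grid
        h = grid.actual_spacing * _UM
        div = np.zeros(grid.shape)
        for ax in range(3):
            u = self.velocity[..., ax]
            div += (np.roll(u, -1, axis=ax) - np.roll(u, 1, axis=ax)) / (2 * h[ax])
        speed = np.linalg.norm(self.velocity, axis=-1)
        u_ref = speed[grid.fluid].mean()
        if u_ref == 0:
            return 0.0
        return float(np.abs(div[grid.fluid]).max() * np.mean(h) / u_ref)


def reynolds(u_superficial: float, spec: FiberSpec, fluid: Fluid = WATER) -> float:
    """Re = rho * u * d_outer / mu (d_outer converted from um)."""
    return fluid.density * u_superficial * spec.outer_diameter * _UM / fluid.viscosity


def superficial_velocity_for_reynolds(Re: float, spec: FiberSpec,
                                      fluid: Fluid = WATER) -> float:
    """Superficial velocity (m/s) at which the bundle Reynolds number is Re."""
    return Re * fluid.viscosity / (fluid.density * spec.outer_diameter * _UM)


def solve_flow(problem: FlowProblem, settings: SolverSettings | None = None) -> FlowField:
    """Solve the periodic flow problem to the residual threshold.

    Raises
    ------
    NoFlowError
        If the fluid phase does not percolate along the flow direction.
    ConvergenceError
        If the residual threshold is not met within ``max_iterations``.
    """
    settings = settings or SolverSettings()
    grid = problem.grid
    ax = problem.axis
    if not check_percolation(grid, ax):
        raise NoFlowError(
            f"no 6-connected fluid path crosses the cell along axis {ax}"
        )
    stokes = settings.advection == "stokes"
    # Only the in-plane (x, y) faces of the orthogonal cell are mirror planes
    # of the geometry; its z faces lie between fiber layers.  Cell-less grids
    # (synthetic fixtures) are trusted to be mirror-symmetric when the caller
    # asks for symmetry faces.
    mirror_axes = (0, 1) if grid.cell is not None else (0, 1, 2)
    lat = build_lattice(grid.solid, ax, problem.lateral_bc, mirror_axes)
    nu_lat = settings.lattice_viscosity
    if nu_lat is None:
        nu_lat = 0.5 if stokes else 1.0 / 6.0
    h = float(np.exp(np.mean(np.log(grid.actual_spacing)))) * _UM  # m
    d_lat = problem.characteristic_length() * _UM / h
    u_target_lat = problem.target_Re * nu_lat / d_lat

    force = np.zeros(3)
    force[ax] = 1.0e-5
    total_steps = 0
    residual = np.inf

    def _iterate(as_stokes):
        nonlocal total_steps, residual
        steps, residual, converged = run_to_steady(
            lat, force, nu_lat, as_stokes, settings.residual_tolerance,
            settings.max_iterations - total_steps,
        )
        total_steps += steps
        if not converged:
            raise ConvergenceError(
                f"residual {residual:.3e} after {total_steps} steps "
                f"(tolerance {settings.residual_tolerance:.1e})"
            )
        u = lat.velocity(force, as_stokes)
        return u, float(u[ax].mean())

    if stokes:
        u_lat, ubar = _iterate(True)
        if ubar <= 0 and problem.target_Re > 0:
            raise FlowError("non-positive mean flow; geometry may be sealed")
    else:
        # The problem is nearly linear at Re <= 1: a Stokes pre-solve fixes
        # the driving force for the target superficial velocity exactly up to
        # the (small) inertial correction, then the full iteration refines it.
        u_lat, ubar = _iterate(True)
        if ubar <= 0:
            raise FlowError("non-positive mean flow; geometry may be sealed")
        for attempt in range(8):
            scale = u_target_lat / ubar
            force[ax] *= scale
            # warm start: rescale the non-equilibrium part with the force
            lat.f[:] = lat.f * scale + W_REST[:, None] * (1.0 - scale)
            u_lat, ubar = _iterate(False)
            if ubar <= 0:
                raise FlowError("non-positive mean flow; geometry may be sealed")
            if abs(ubar - u_target_lat) <= 2e-3 * u_target_lat:
                break
        else:
            raise ConvergenceError(
                "force targeting did not settle on the target Re")

    # --- unit conversion -------------------------------------------------
    fluid = problem.fluid
    nu_phys = fluid.kinematic_viscosity
    dt = nu_lat * h * h / nu_phys
    u_scale = h / dt
    if stokes:
        # linear problem: rescale the solution exactly onto the target Re
        u_target = problem.target_Re * fluid.viscosity / (
            fluid.density * problem.characteristic_length() * _UM)
        sigma = u_target / (ubar * u_scale)
    else:
        sigma = 1.0
    velocity = np.moveaxis(u_lat, 0, -1) * (u_scale * sigma)
    rho_lat = lat.density()
    p_scale = fluid.density * u_scale ** 2 * sigma
    pressure = (rho_lat - rho_lat[grid.fluid].mean()) / 3.0 * p_scale
    pressure[grid.solid] = 0.0
    force_phys = force[ax] * fluid.density * h / dt ** 2 * sigma
    L = grid.box[ax] * _UM
    dP = force_phys * L
    box = np.array(grid.box) * _UM
    area = float(np.prod(np.delete(box, ax)))
    u_sup = ubar * u_scale * sigma
    Q = u_sup * area
    Re = fluid.density * u_sup * problem.characteristic_length() * _UM / fluid.viscosity
    return FlowField(
        velocity=velocity,
        pressure=pressure,
        dP=dP,
        Q=Q,
        superficial_velocity=u_sup,
        reynolds=Re,
        problem=problem,
        info={
            "iterations": total_steps,
            "residual": residual,
            "converged": True,
            "force_lattice": force[ax],
            "mean_velocity_lattice": ubar,
            "permeability_lattice": nu_lat * ubar / force[ax],
            "permeability_m2": nu_lat * ubar / force[ax] * h * h,
            "spacing_m": h,
            "advection": settings.advection,
        },
    )


@dataclass
class ConvergenceReport:
    """Grid sensitivity of the cell pressure drop.

    ``optimal_spacing`` is the coarsest level whose pressure drop differs
    from the finest level by less than ``criterion`` (relative).
    """

    spacings: list
    dP: list
    rel_diff_vs_finest: list
    optimal_spacing: float | None
    criterion: float = 0.01


def grid_convergence(problem, levels: Sequence[float],
                     settings: SolverSettings | None = None,
                     grid_factory: Callable[[float], VoxelGrid] | None = None,
                     min_gap: float | None = 1.0) -> ConvergenceReport:
    """Pressure drop across the cell at a sequence of voxel spacings.

    ``problem`` is a template :class:`FlowProblem`; its grid is rebuilt at
    each spacing, either from the grid's source cell or through
    ``grid_factory``.  At least three levels are required.
    """
    if len(levels) < 3:
        raise ValueError("grid_convergence needs at least 3 spacing levels")
    if grid_factory is None:
        cell = problem.grid.cell
        if cell is None:
            raise ValueError("grid has no source cell; pass grid_factory")

        def grid_factory(spacing):
            g = voxelize(cell, spacing)
            return enforce_min_gap(g, min_gap) if min_gap else g

    dps = []
    for s in levels:
        g = grid_factory(s)
        prob = FlowProblem(
            grid=g, flow_direction=problem.flow_direction,
            lateral_bc=problem.lateral_bc, fluid=problem.fluid,
            driving=problem.driving, target_Re=problem.target_Re,
            char_length=problem.char_length,
        )
        dps.append(solve_flow(prob, settings).dP)
    finest = int(np.argmin(levels))
    ref = dps[finest]
    rel = [abs(dp - ref) / abs(ref) for dp in dps]
    optimal = None
    for s, r in sorted(zip(levels, rel), key=lambda t: -t[0]):
        if r < 0.01:
            optimal = s
            break
    return ConvergenceReport(list(levels), dps, rel, optimal)
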