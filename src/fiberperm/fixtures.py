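"""Synthetic voxel geometries with closed-form permeability oracles.

The analysis pipeline has no external data: its inputs are geometric
parameters.  These fixtures generate the periodic fibrous/channel solids the
pipeline assumes, at parameterizations where porosity and permeability are
known in closed form, so the voxelization + flow + Darcy chain can be
validated end to end:

* plane channel -- exact plane-Poiseuille permeability h^2/3 (h half-width);
* square array of parallel cylinders -- Gebart's lubrication closed form for
  transverse flow and the Drummond-Tahir lattice solution for axial flow.

Gebart's transverse formula is asymptotic in the narrow-gap limit: it is
accurate for dense arrays and overpredicts K at moderate fiber fractions
(by ~13% at a fraction of 0.4 against converged numerics).  The default
validation fraction is therefore chosen at 0.55, where the lubrication
assumption holds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
import numpy as np

from .voxel import VoxelGrid

__all__ = [
    "Fixture",
    "fixture_channel",
    "fixture_cylinder_array",
    "gebart_transverse_K",
    "drummond_tahir_axial_K",
]

MAX_SQUARE_PACKING = math.pi / 4.0


def gebart_transverse_K(radius_m: float, fiber_fraction: float) -> float:
    """Gebart closed-form transverse permeability of a square cylinder array.

    K = 16/(9*pi*sqrt(2)) * (sqrt(pi/(4*Vf)) - 1)^(5/2) * R^2, in m^2.
    """
    if not 0 < fiber_fraction < MAX_SQUARE_PACKING:
        raise ValueError("fiber fraction must lie in (0, pi/4) for a square array")
    c = 16.0 / (9.0 * math.pi * math.sqrt(2.0))
    return c * (math.sqrt(math.pi / (4.0 * fiber_fraction)) - 1.0) ** 2.5 * radius_m ** 2


def drummond_tahir_axial_K(radius_m: float, fiber_fraction: float) -> float:
    """Drummond-Tahir axial permeability of a square cylinder array.

    K = R^2/(4*Vf) * (-ln Vf - 1.476 + 2*Vf - 0.5*Vf^2), in m^2.
    """
    vf = fiber_fraction
    if not 0 < vf < MAX_SQUARE_PACKING:
        raise ValueError("fiber fraction must lie in (0, pi/4) for a square array")
    return radius_m ** 2 / (4.0 * vf) * (-math.log(vf) - 1.476 + 2.0 * vf - 0.5 * vf * vf)


@dataclass
class Fixture:
    """A synthetic voxel geometry with its closed-form oracles.

    ``oracle_K`` maps a flow direction to the closed-form permeability in
    m^2 (superficial-velocity convention noted per fixture); ``grid`` is the
    generated :class:`VoxelGrid` (``cell`` is None: fixtures carry no fiber
    contacts).
    """

    name: str
    grid: VoxelGrid
    porosity: float
    oracle_K: dict
    char_length: float  # um, for Reynolds scaling
    params: dict = field(default_factory=dict)


def fixture_channel(half_width: float, resolution: int = 32,
                    wall_voxels: int = 4) -> Fixture:
    """Plane channel of half-width ``half_width`` um between solid walls.

    Flow along x; walls normal to z.  ``resolution`` is the number of voxels
    across the full channel width.  Oracles (m^2):

    * ``fluid``: K referred to the channel cross-section = h^2/3 (the
      plane-Poiseuille mean);
    * ``superficial``: K referred to the whole box cross-section =
      porosity * h^2/3.
    """
    if half_width <= 0:
        raise ValueError("half_width must be positive")
    if resolution < 4:
        raise ValueError("resolution floor: need >= 4 voxels across the channel")
    h = 2.0 * half_width / resolution  # voxel edge, um
    nz = resolution + wall_voxels
    nxy = 4
    solid = np.zeros((nxy, nxy, nz), dtype=bool)
    lo = wall_voxels // 2
    hi = wall_voxels - lo
    if lo:
        solid[:, :, :lo] = True
    solid[:, :, nz - hi:] = True
    grid = VoxelGrid(solid=solid, spacing=h,
                     box=(nxy * h, nxy * h, nz * h))
    porosity = resolution / nz
    k_fluid = (half_width * 1e-6) ** 2 / 3.0
    return Fixture(
        name=f"channel_h{half_width:g}",
        grid=grid,
        porosity=porosity,
        oracle_K={"fluid": k_fluid, "superficial": porosity * k_fluid},
        char_length=2.0 * half_width,
        params={"half_width": half_width, "resolution": resolution,
                "flow_direction": "x"},
    )


def fixture_cylinder_array(fiber_fraction: float, resolution: int = 64,
                           radius: float = 100.0, nz: int = 2) -> Fixture:
    """Square array of parallel solid cylinders (axes along z).

    ``fiber_fraction`` is the cylinder volume fraction (< pi/4);
    ``resolution`` is the number of voxels across the cylinder diameter.
    Oracles (m^2, superficial-velocity convention): transverse flow (x or y)
    from Gebart, axial flow (z) from Drummond-Tahir.
    """
    if not 0 < fiber_fraction < MAX_SQUARE_PACKING:
        raise ValueError(
            "fiber fraction must lie in (0, pi/4): cylinders touch at pi/4"
        )
    a = radius * math.sqrt(math.pi / fiber_fraction)  # lattice pitch, um
    h = 2.0 * radius / resolution
    n = int(round(a / h))
    hx = a / n
    x = (np.arange(n) + 0.5) * hx - a / 2.0
    X, Y = np.meshgrid(x, x, indexing="ij")
    disk = X * X + Y * Y <= radius * radius
    solid = np.repeat(disk[:, :, None], nz, axis=2)
    grid = VoxelGrid(solid=solid, spacing=hx, box=(a, a, nz * hx))
    r_m = radius * 1e-6
    return Fixture(
        name=f"cyl_array_vf{fiber_fraction:g}",
        grid=grid,
        porosity=1.0 - fiber_fraction,
        oracle_K={
            "x": gebart_transverse_K(r_m, fiber_fraction),
            "y": gebart_transverse_K(r_m, fiber_fraction),
            "z": drummond_tahir_axial_K(r_m, fiber_fraction),
        },
        char_length=2.0 * radius,
        params={"fiber_fraction": fiber_fraction, "radius": radius,
                "resolution": resolution},
    )
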