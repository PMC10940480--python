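"""Voxelization of repetitive units and porosity measurement.

A :class:`VoxelGrid` is a regular fluid/solid labeling of the unit-cell box.
A voxel is solid iff its center lies inside any (deformed) fiber outer
surface, with periodic wrap applied when testing membership.  The grid is the
discrete analogue of the Boolean fluid-domain construction (box minus fibers
and the volume inside them) and is the input of the flow solver.

The per-axis voxel counts are the nearest integers to box/spacing, so the
grid tiles the true box exactly; the per-axis spacings therefore differ from
the nominal isotropic spacing by less than one part in the voxel count.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
import numpy as np
from scipy import ndimage

from .geometry import UnitCell

__all__ = [
    "ResolutionError",
    "DegenerateGapError",
    "VoxelGrid",
    "PorosityResult",
    "voxelize",
    "enforce_min_gap",
    "measure_porosity",
    "monte_carlo_porosity",
    "check_percolation",
]

_AXES = {"x": 0, "y": 1, "z": 2, 0: 0, 1: 1, 2: 2}


class ResolutionError(ValueError):
    """Requested voxel spacing too coarse for the fiber diameter."""


class DegenerateGapError(ValueError):
    """Minimum-gap rule invoked with a gap comparable to the whole box."""


@dataclass
class VoxelGrid:
    """Regular fluid/solid phase labeling of a unit cell.

    Attributes
    ----------
    solid : ndarray of bool, shape (nx, ny, nz)
        True on solid voxels (fiber wall or lumen).
    spacing : float
        Nominal isotropic voxel edge, um.
    box : tuple of float
        True cell box dimensions (Lx, Ly, Lz), um.
    origin : ndarray
        Position of the box corner, um.
    cell : UnitCell or None
        Source geometry, kept for gap enforcement and re-voxelization.
    """

    solid: np.ndarray
    spacing: float
    box: tuple
    origin: np.ndarray = None
    cell: UnitCell | None = None

    def __post_init__(self):
        if self.origin is None:
            self.origin = np.zeros(3)
        self.box = tuple(float(v) for v in self.box)

    @property
    def shape(self) -> tuple:
        return self.solid.shape

    @property
    def fluid(self) -> np.ndarray:
        return ~self.solid

    @property
    def actual_spacing(self) -> np.ndarray:
        return np.array(self.box) / np.array(self.shape)

    @property
    def voxel_volume(self) -> float:
        return float(np.prod(self.actual_spacing))

    def axis_coords(self, axis: int) -> np.ndarray:
        """Voxel-center coordinates along one axis, um."""
        n = self.shape[axis]
        h = self.box[axis] / n
        return self.origin[axis] + (np.arange(n) + 0.5) * h

    def centers(self) -> np.ndarray:
        """All voxel centers as an (N, 3) array, C-order of the grid."""
        xs = [self.axis_coords(a) for a in range(3)]
        g = np.meshgrid(*xs, indexing="ij")
        return np.stack([a.ravel() for a in g], axis=1)


@dataclass(frozen=True)
class PorosityResult:
    """Porosity with its supporting volumes; method is how it was measured."""

    porosity: float
    fluid_volume: float  # um^3
    box_volume: float  # um^3
    method: str  # "analytic" | "voxel_count" | "monte_carlo"


def voxelize(cell: UnitCell, spacing: float) -> VoxelGrid:
    """Sample the unit cell on a regular grid by voxel-center membership.

    Parameters
    ----------
    cell : UnitCell
    spacing : float
        Nominal voxel edge, um.  Must be at most outer_diameter / 20.
    """
    d = cell.spec.outer_diameter
    if spacing > d / 20.0:
        raise ResolutionError(
            f"spacing {spacing} um exceeds outer_diameter/20 = {d / 20:.3g} um"
        )
    shape = tuple(max(1, int(round(L / spacing))) for L in cell.box_dimensions)
    grid = VoxelGrid(
        solid=np.zeros(shape, dtype=bool), spacing=float(spacing),
        box=cell.box_dimensions, cell=cell,
    )
    pts = grid.centers()
    solid = np.zeros(len(pts), dtype=bool)
    # chunked to bound peak memory on fine grids
    chunk = 1_000_000
    for lo in range(0, len(pts), chunk):
        solid[lo:lo + chunk] = cell.is_solid(pts[lo:lo + chunk])
    grid.solid = solid.reshape(shape)
    return grid


def enforce_min_gap(grid: VoxelGrid, min_gap: float = 1.0) -> VoxelGrid:
    """Solidify fluid slivers thinner than ``min_gap`` at fiber contacts.

    Mirrors the contact-area extension used when meshing touching fibers:
    around every fiber-to-fiber contact, fluid whose passage between the two
    surfaces is thinner than ``min_gap`` (default 1 um) is absorbed into the
    solid, so every remaining fluid passage is at least ``min_gap`` thick.
    A voxel center lies in such a sliver when the sum of its distances to the
    two contacting surfaces is below ``min_gap``.

    Grids without a source cell (synthetic fixtures) have no fiber contacts
    and are returned unchanged.
    """
    if min_gap >= min(grid.box):
        raise DegenerateGapError("min_gap is of the order of the cell box")
    if grid.cell is None:
        return grid
    contacts = grid.cell.contact_points(gap_tol=min_gap)
    if not contacts:
        return grid
    solid = grid.solid.copy()
    pts = grid.centers()
    fluid_idx = np.flatnonzero(~solid.ravel())
    fpts = pts[fluid_idx]
    r = grid.cell.spec.outer_radius
    for q, fi, fj in contacts:
        near = np.linalg.norm(fpts - q, axis=1) <= r
        if not near.any():
            continue
        di = fi.surface_distance(fpts[near])
        dj = fj.surface_distance(fpts[near])
        sliver = (di >= 0) & (dj >= 0) & (di + dj < min_gap)
        idx = fluid_idx[np.flatnonzero(near)[sliver]]
        solid.ravel()[idx] = True
    out = replace(grid, solid=solid)
    return out


def measure_porosity(grid: VoxelGrid) -> PorosityResult:
    """Fluid-voxel fraction of the grid, with volumes in um^3."""
    box_volume = float(np.prod(grid.box))
    frac = float(grid.fluid.mean())
    return PorosityResult(
        porosity=frac,
        fluid_volume=frac * box_volume,
        box_volume=box_volume,
        method="voxel_count",
    )


def monte_carlo_porosity(cell: UnitCell, n_points: int = 1_000_000,
                         seed: int = 0) -> PorosityResult:
    """Monte-Carlo membership estimate of the cell porosity (test oracle)."""
    rng = np.random.default_rng(seed)
    box = np.array(cell.box_dimensions)
    pts = rng.random((n_points, 3)) * box
    frac = 1.0 - float(cell.is_solid(pts).mean())
    v = float(np.prod(box))
    return PorosityResult(frac, frac * v, v, "monte_carlo")


def check_percolation(grid: VoxelGrid, direction) -> bool:
    """True iff a 6-connected fluid path crosses the periodic cell.

    The grid is tiled twice along the flow axis; labels are merged across the
    periodic lateral faces, and percolation requires a component spanning the
    doubled domain from the first to the last layer.  A spanning path in the
    doubled domain continues periodically, so this detects every physically
    conducting geometry of interest here.
    """
    ax = _AXES[direction]
    fluid = np.moveaxis(grid.fluid, ax, 0)
    if not fluid.any():
        return False
    tiled = np.concatenate([fluid, fluid], axis=0)
    structure = ndimage.generate_binary_structure(3, 1)
    labels, n = ndimage.label(tiled, structure=structure)
    if n == 0:
        return False
    parent = np.arange(n + 1)

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    def union(a, b):
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[rb] = ra

    # merge across the two periodic lateral axes
    for lat in (1, 2):
        lo = np.take(labels, 0, axis=lat)
        hi = np.take(labels, -1, axis=lat)
        both = (lo > 0) & (hi > 0)
        for a, b in set(zip(lo[both].ravel(), hi[both].ravel())):
            union(a, b)
    first = {find(v) for v in np.unique(labels[0]) if v > 0}
    last = {find(v) for v in np.unique(labels[-1]) if v > 0}
    return bool(first & last)
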