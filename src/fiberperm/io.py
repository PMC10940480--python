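"""Export of cells, grids and flow fields.

* JSON descriptor of a unit cell (box + fiber instances): exact and
  re-loadable for reproducibility.
* Legacy-ASCII VTK structured-points files for voxel phase fields and flow
  solutions, readable by ParaView and friends.
* STL surface triangulations of the fiber set (via ``trimesh`` when it is
  installed; geometry export is optional and the rest of the package does
  not depend on it).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .geometry import UnitCell
from .voxel import VoxelGrid

__all__ = ["write_cell_json", "write_vtk", "write_stl"]


def write_cell_json(cell: UnitCell, path) -> None:
    Path(path).write_text(cell.to_json())


def _vtk_header(f, grid: VoxelGrid, title: str):
    nx, ny, nz = grid.shape
    sx, sy, sz = grid.actual_spacing
    f.write("# vtk DataFile Version 3.0\n")
    f.write(f"{title}\n")
    f.write("ASCII\nDATASET STRUCTURED_POINTS\n")
    f.write(f"DIMENSIONS {nx} {ny} {nz}\n")
    f.write(f"ORIGIN {sx/2:.6g} {sy/2:.6g} {sz/2:.6g}\n")
    f.write(f"SPACING {sx:.6g} {sy:.6g} {sz:.6g}\n")
    f.write(f"POINT_DATA {nx*ny*nz}\n")


def _write_scalars(f, name, values, fmt="%.6g"):
    f.write(f"SCALARS {name} float 1\nLOOKUP_TABLE default\n")
    np.savetxt(f, values.reshape(-1, order="F"), fmt=fmt)


def write_vtk(path, grid: VoxelGrid, velocity: np.ndarray | None = None,
              pressure: np.ndarray | None = None) -> None:
    """Write the phase field (and optionally a flow solution) to legacy VTK."""
    with open(path, "w") as f:
        _vtk_header(f, grid, "fiberperm voxel grid (lengths in um)")
        _write_scalars(f, "solid", grid.solid.astype(np.int8), fmt="%d")
        if pressure is not None:
            _write_scalars(f, "pressure_Pa", pressure)
        if velocity is not None:
            f.write("VECTORS velocity_m_per_s float\n")
            np.savetxt(f, velocity.reshape(-1, 3)[_fortran_order(grid.shape)],
                       fmt="%.6g")


def _fortran_order(shape):
    idx = np.arange(int(np.prod(shape))).reshape(shape)
    return idx.ravel(order="F")


def _tube_mesh(fiber, length: float, n_axial: int = 64, n_circ: int = 32):
    """Triangulated outer surface of one fiber over [-length/2, length/2]."""
    import trimesh

    u = fiber.axis_direction
    ew = np.cross(u, np.array([0.0, 0.0, 1.0]))
    ew /= np.linalg.norm(ew)
    s = np.linspace(-length / 2, length / 2, n_axial)
    th = np.linspace(0, 2 * np.pi, n_circ, endpoint=False)
    a, b = fiber.semi_axes(s)
    pts = (fiber.axis_point[None, None, :]
           + s[:, None, None] * u[None, None, :]
           + (a[:, None] * np.cos(th)[None, :])[:, :, None] * ew[None, None, :]
           + (b[:, None] * np.sin(th)[None, :])[:, :, None]
           * np.array([0.0, 0.0, 1.0])[None, None, :])
    verts = pts.reshape(-1, 3)
    faces = []
    for i in range(n_axial - 1):
        for j in range(n_circ):
            j2 = (j + 1) % n_circ
            v00, v01 = i * n_circ + j, i * n_circ + j2
            v10, v11 = (i + 1) * n_circ + j, (i + 1) * n_circ + j2
            faces.append((v00, v10, v11))
            faces.append((v00, v11, v01))
    return trimesh.Trimesh(vertices=verts, faces=np.array(faces), process=False)


def write_stl(path, cell: UnitCell) -> None:
    """Triangulate the fiber surfaces crossing the box and write an STL."""
    import trimesh

    lx, ly, lz = cell.box_dimensions
    length = 2.0 * float(np.hypot(lx, ly))
    meshes = [_tube_mesh(f, length) for f in cell.periodic_images(margin=0.0)]
    trimesh.util.concatenate(meshes).export(path)
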