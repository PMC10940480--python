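"""D3Q19 two-relaxation-time lattice Boltzmann kernel.

Steady creeping flow through the voxelized unit cell is obtained as the
stationary state of a body-force-driven lattice Boltzmann iteration:

* D3Q19 velocity set, two-relaxation-time (TRT) collision with the "magic"
  parameter Lambda = (1/omega_plus - 1/2)(1/omega_minus - 1/2) = 3/16, which
  pins the halfway bounce-back wall exactly midway between fluid and solid
  voxel centers (plane Poiseuille flow is then resolved exactly) and makes
  the extracted permeability essentially independent of the relaxation rate.
* Halfway bounce-back on solid voxels; periodic wrap or specular (symmetry)
  reflection on the domain faces.
* Guo-style body forcing.  In ``stokes`` mode the equilibrium is linear in
  the velocity, so the update is an exactly linear map and the flow scales
  exactly with the force; ``navier_stokes`` mode keeps the quadratic
  equilibrium terms and resolves the (small) inertial corrections at the
  simulated Reynolds number.

Everything in this module works in lattice units (voxel = 1, time step = 1,
reference density 1); unit handling lives in :mod:`fiberperm.flow`.

The streaming step is precomputed as per-node source tables: for every fluid
node and direction, the (node, direction) pair to pull from, with periodic
wrap, specular reflection and bounce-back already folded in.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["LatticeProblem", "build_lattice", "run_to_steady"]

# -- D3Q19 constants ---------------------------------------------------------

C = np.array(
    [
        (0, 0, 0),
        (1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1),
        (1, 1, 0), (-1, -1, 0), (1, -1, 0), (-1, 1, 0),
        (1, 0, 1), (-1, 0, -1), (1, 0, -1), (-1, 0, 1),
        (0, 1, 1), (0, -1, -1), (0, 1, -1), (0, -1, 1),
    ],
    dtype=np.int8,
)
W = np.array([1 / 3] + [1 / 18] * 6 + [1 / 36] * 12)
Q = 19


def _lookup(c):
    table = {tuple(v): i for i, v in enumerate(C.tolist())}
    return np.array([table[tuple(v)] for v in c.tolist()], dtype=np.int8)


OPP = _lookup(-C)
MIRROR = [_lookup(C * np.array(m, dtype=np.int8)) for m in
          ((-1, 1, 1), (1, -1, 1), (1, 1, -1))]
PAIR_I = np.array([1, 3, 5, 7, 9, 11, 13, 15, 17], dtype=np.int8)

CXf = C[:, 0].astype(np.float64)
CYf = C[:, 1].astype(np.float64)
CZf = C[:, 2].astype(np.float64)


class LatticeProblem:
    """Precomputed streaming tables and state for one voxel geometry."""

    def __init__(self, solid: np.ndarray, bc: tuple):
        """``bc`` is a per-axis tuple of "periodic" or "symmetry"."""
        self.solid = np.ascontiguousarray(solid, dtype=bool)
        self.shape = solid.shape
        self.bc = tuple(bc)
        self.n_total = int(solid.size)
        flat_solid = self.solid.ravel()
        self.fluid_ids = np.flatnonzero(~flat_solid).astype(np.int64)
        nf = self.fluid_ids.size
        ix, iy, iz = np.unravel_index(self.fluid_ids, self.shape)
        src_idx = np.empty((Q, nf), dtype=np.int64)
        src_dir = np.empty((Q, nf), dtype=np.int8)
        bounced = np.zeros((Q, nf), dtype=np.bool_)
        n3 = np.array(self.shape)
        for i in range(Q):
            s = [ix - C[i, 0], iy - C[i, 1], iz - C[i, 2]]
            j = np.full(nf, i, dtype=np.int8)
            for ax in range(3):
                if self.bc[ax] == "periodic":
                    s[ax] = np.mod(s[ax], n3[ax])
                else:  # specular reflection about the face planes
                    out = (s[ax] < 0) | (s[ax] >= n3[ax])
                    if out.any():
                        s[ax] = np.where(out, (ix, iy, iz)[ax], s[ax])
                        j[out] = MIRROR[ax][j[out]]
            flat = np.ravel_multi_index(tuple(s), self.shape)
            hit = flat_solid[flat]
            flat[hit] = self.fluid_ids[hit]
            j[hit] = OPP[i]
            bounced[i] = hit
            src_idx[i] = flat
            src_dir[i] = j
        self.src_idx = src_idx
        self.src_dir = src_dir
        self.bounced = bounced
        # distributions at rest
        self.f = np.tile(W[:, None], (1, self.n_total))
        self._g = np.empty_like(self.f)

    # -- macroscopic fields ---------------------------------------------

    def velocity(self, force: np.ndarray, stokes: bool) -> np.ndarray:
        """Velocity field (lattice units), zero on solid nodes; shape (3, *grid)."""
        f = self.f
        j = np.stack([CXf @ f, CYf @ f, CZf @ f]) + 0.5 * force[:, None]
        if not stokes:
            rho = f.sum(axis=0)
            j = j / rho
        j[:, self.solid.ravel()] = 0.0
        return j.reshape((3,) + self.shape)

    def density(self) -> np.ndarray:
        rho = self.f.sum(axis=0)
        rho[self.solid.ravel()] = 1.0
        return rho.reshape(self.shape)


def build_lattice(solid: np.ndarray, flow_axis: int, lateral_bc: str,
                  mirror_axes: tuple = (0, 1)) -> LatticeProblem:
    """Assemble the lattice with the requested boundary conditions.

    ``mirror_axes`` lists the axes whose cell faces are mirror planes of the
    geometry; "symmetry" is only applied on lateral axes in that set (other
    lateral faces stay periodic, which is always valid).
    """
    bc = ["periodic"] * 3
    if lateral_bc == "symmetry":
        for ax in range(3):
            if ax != flow_axis and ax in mirror_axes:
                bc[ax] = "symmetry"
    return LatticeProblem(solid, tuple(bc))


@njit(cache=True, fastmath=True)
def _steps(fa, fb, src_idx, src_dir, bounced, fluid_ids, fx, fy, fz,
           omega_p, omega_m, stokes, nsteps):
    """Advance an even number of fused stream(pull)+collide steps."""
    w0 = 1.0 / 3.0
    loc = np.empty(19)
    # force correction on bounce-back links: restores the exact midway wall
    # of the magic-parameter TRT for body-force-driven flow
    bbc = np.empty(19)
    for i in range(19):
        bbc[i] = -6.0 * W[i] * (CXf[i] * fx + CYf[i] * fy + CZf[i] * fz)
    ap = 1.0 - 0.5 * omega_p
    am = 1.0 - 0.5 * omega_m
    for step in range(nsteps):
        if step % 2 == 0:
            fin, fout = fa, fb
        else:
            fin, fout = fb, fa
        for k in range(fluid_ids.size):
            n = fluid_ids[k]
            rho = 0.0
            jx = 0.5 * fx
            jy = 0.5 * fy
            jz = 0.5 * fz
            for i in range(19):
                v = fin[src_dir[i, k], src_idx[i, k]]
                if bounced[i, k]:
                    v += bbc[i]
                loc[i] = v
                rho += v
                jx += CXf[i] * v
                jy += CYf[i] * v
                jz += CZf[i] * v
            if stokes:
                ux, uy, uz = jx, jy, jz
                usq = 0.0
                ufdot = 0.0
            else:
                ux, uy, uz = jx / rho, jy / rho, jz / rho
                usq = ux * ux + uy * uy + uz * uz
                ufdot = ux * fx + uy * fy + uz * fz
            # rest direction (purely even)
            if stokes:
                feq0 = w0 * rho
            else:
                feq0 = w0 * rho * (1.0 - 1.5 * usq)
            fout[0, n] = loc[0] - omega_p * (loc[0] - feq0) + ap * (-3.0 * w0 * ufdot)
            for m in range(9):
                i = 1 + 2 * m
                ib = i + 1
                wi = W[i]
                cu = CXf[i] * ux + CYf[i] * uy + CZf[i] * uz
                cf = CXf[i] * fx + CYf[i] * fy + CZf[i] * fz
                fp = 0.5 * (loc[i] + loc[ib])
                fm = 0.5 * (loc[i] - loc[ib])
                if stokes:
                    # linear equilibrium, no even force source: the update is
                    # exactly linear in (u, F) and conserves mass identically
                    feqp = wi * rho
                    feqm = 3.0 * wi * cu
                    se = 0.0
                else:
                    # standard compressible equilibrium
                    feqp = wi * rho * (1.0 + 4.5 * cu * cu - 1.5 * usq)
                    feqm = 3.0 * wi * rho * cu
                    se = wi * (9.0 * cu * cf - 3.0 * ufdot)
                so = 3.0 * wi * cf
                even = fp - omega_p * (fp - feqp) + ap * se
                odd = fm - omega_m * (fm - feqm) + am * so
                fout[i, n] = even + odd
                fout[ib, n] = even - odd


def run_to_steady(lat: LatticeProblem, force: np.ndarray, viscosity: float,
                  stokes: bool, tol: float, max_steps: int,
                  check_every: int = 100):
    """Iterate to the stationary state.

    The residual is the L1 norm of the velocity-field change over one check
    interval, relative to the L1 norm of the field.  Returns
    (steps_taken, residual, converged).
    """
    omega_p = 1.0 / (3.0 * viscosity + 0.5)
    lam = 3.0 / 16.0
    omega_m = 1.0 / (lam / (1.0 / omega_p - 0.5) + 0.5)
    check_every += check_every % 2  # keep the double-buffer in phase
    fx, fy, fz = (float(v) for v in force)
    u_prev = None
    steps = 0
    residual = np.inf
    hits = 0  # require two consecutive sub-tolerance checks (transients can
    # momentarily stall the field change without being converged)
    while steps < max_steps:
        _steps(lat.f, lat._g, lat.src_idx, lat.src_dir, lat.bounced,
               lat.fluid_ids, fx, fy, fz, omega_p, omega_m, stokes, check_every)
        steps += check_every
        u = lat.velocity(force, stokes)
        if u_prev is not None:
            num = np.abs(u - u_prev).sum()
            den = np.abs(u).sum()
            residual = num / den if den > 0 else 0.0
            hits = hits + 1 if residual < tol else 0
            if hits >= 2:
                return steps, residual, True
        u_prev = u
    return steps, residual, False
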