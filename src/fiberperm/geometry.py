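"""Parametric repetitive units of hollow-fiber bundle microstructure.

A blood-oxygenator fiber bundle is an idealized periodic lattice of hollow
fibers: mats of parallel fibers are stacked with the fiber orientation
alternating between layers, either by 90 degrees (orthogonal / stacked
configuration) or by +/- a layup angle relative to the axial Y direction
(angled / wrapped configuration).  This module builds the smallest periodic
repetitive unit of such a lattice from the fiber geometry (outer diameter,
wall thickness) and the bundle layout (pitch, configuration, layer angle),
and applies press-fit deformation models along the stacking direction Z.

Two press-fit models are provided:

``interpenetrated``
    Rigid movement of the fiber layers towards each other; the circular
    cross-sections are unchanged and fiber-to-fiber overlap is permitted.
``flattened``
    The same rigid layer movement, but near every fiber-to-fiber contact the
    circular cross-section is replaced by an area-preserving ellipse (minor
    semi-axis along Z), blended smoothly into the circular section over one
    fiber diameter of axial length.  This is a parametric approximation of
    the contact flattening a deformable fiber wall undergoes; it removes the
    non-physical interpenetration of the rigid model.

All lengths in this module are micrometres.  The coordinate system is
right-handed with Z the stacking / press-fit direction and Y the axial
direction of an angled layup.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

__all__ = [
    "GeometryError",
    "OverlapWithinLayerError",
    "DegenerateLayoutError",
    "InvalidPressFitError",
    "LumenCollapseError",
    "FiberSpec",
    "BundleLayout",
    "PressFit",
    "Interpenetration",
    "FlattenedContacts",
    "FiberInstance",
    "UnitCell",
    "build_unit_cell",
    "analytic_porosity",
    "apply_press_fit",
    "apply_flattened_contact",
]

_Z = np.array([0.0, 0.0, 1.0])


class GeometryError(ValueError):
    """Base class for invalid bundle geometry."""


class OverlapWithinLayerError(GeometryError):
    """Pitch does not exceed the fiber outer diameter: parallel fibers overlap."""


class DegenerateLayoutError(GeometryError):
    """Angled layout requested with a layer angle of 0 or 90 degrees."""


class InvalidPressFitError(GeometryError):
    """Press-fit degree outside the meaningful range."""


class LumenCollapseError(GeometryError):
    """Flattening would push the ellipse minor semi-axis inside the fiber lumen."""


@dataclass(frozen=True)
class FiberSpec:
    """Geometry of one hollow-fiber type.

    Parameters
    ----------
    outer_diameter : float
        Fiber outer diameter in micrometres.
    wall_thickness : float
        Fiber wall thickness in micrometres; must be positive and smaller
        than the outer radius.
    """

    outer_diameter: float
    wall_thickness: float

    def __post_init__(self) -> None:
        if not self.outer_diameter > 0:
            raise GeometryError("outer_diameter must be positive")
        if not 0 < self.wall_thickness < self.outer_diameter / 2:
            raise GeometryError(
                "wall_thickness must lie in (0, outer_diameter/2)"
            )

    @property
    def outer_radius(self) -> float:
        return self.outer_diameter / 2.0

    @property
    def inner_radius(self) -> float:
        return self.outer_diameter / 2.0 - self.wall_thickness


@dataclass(frozen=True)
class BundleLayout:
    """Arrangement of fiber layers in the bundle.

    ``pitch`` is the center-to-center spacing of parallel fibers within one
    layer, measured perpendicular to their axes.  For the orthogonal
    configuration layers alternate between 0 and 90 degrees; for the angled
    configuration they alternate between +layer_angle and -layer_angle
    relative to the Y (axial) direction.
    """

    configuration: str  # "orthogonal" | "angled"
    pitch: float
    layer_angle: float = 90.0

    def __post_init__(self) -> None:
        if self.configuration not in ("orthogonal", "angled"):
            raise GeometryError(f"unknown configuration {self.configuration!r}")
        if not self.pitch > 0:
            raise GeometryError("pitch must be positive")
        if self.configuration == "angled" and not 0.0 < self.layer_angle < 90.0:
            raise DegenerateLayoutError(
                "angled layout needs a layer angle strictly between 0 and 90 deg"
            )


@dataclass(frozen=True)
class PressFit:
    """Press-fit description: relative Z-compression of the bundle.

    ``degree`` is the fractional reduction of the bundle height when the
    bundle is forced into the rigid oxygenator housing (0 to 0.2).
    """

    degree: float = 0.0
    method: str = "none"  # "none" | "interpenetrated" | "flattened"

    def __post_init__(self) -> None:
        if not 0.0 <= self.degree <= 0.2:
            raise InvalidPressFitError("press-fit degree must lie in [0, 0.2]")
        if self.method not in ("none", "interpenetrated", "flattened"):
            raise InvalidPressFitError(f"unknown press-fit method {self.method!r}")
        if self.method == "none" and self.degree != 0.0:
            raise InvalidPressFitError("method 'none' requires degree 0")


@dataclass(frozen=True)
class Interpenetration:
    """Deformation marker for the rigid interpenetrated-fibers model.

    ``overlap_depth`` is the depth (um) by which the surfaces of two touching
    fibers of adjacent layers penetrate each other: d * degree.
    """

    overlap_depth: float


@dataclass(frozen=True)
class FlattenedContacts:
    """Elliptical contact flattening along a fiber.

    The cross-section interpolates from a circle of the nominal outer radius
    far from contacts to an ellipse with semi-axes ``a`` (in-plane) and ``b``
    (along Z) at each contact, over an axial blending length ``blend_length``.
    Contacts repeat along the axis with period ``contact_period`` starting at
    axial coordinate ``contact_phase`` (measured from the fiber axis point).
    """

    a: float
    b: float
    blend_length: float
    contact_period: float
    contact_phase: float


def _smoothstep(x: np.ndarray) -> np.ndarray:
    x = np.clip(x, 0.0, 1.0)
    return x * x * (3.0 - 2.0 * x)


@dataclass(frozen=True)
class FiberInstance:
    """One (possibly deformed) fiber: an axis line plus a cross-section law."""

    axis_point: np.ndarray
    axis_direction: np.ndarray
    outer_radius: float
    deformation: Interpenetration | FlattenedContacts | None = None

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "axis_point", np.asarray(self.axis_point, dtype=float)
        )
        u = np.asarray(self.axis_direction, dtype=float)
        n = np.linalg.norm(u)
        if not np.isfinite(n) or abs(n - 1.0) > 1e-9:
            u = u / n
        object.__setattr__(self, "axis_direction", u)
        if not self.outer_radius > 0:
            raise GeometryError("outer_radius must be positive")

    # Local frame: s along axis, w in-plane normal, v along Z.
    def local_coords(self, points: np.ndarray):
        rel = points - self.axis_point
        u = self.axis_direction
        s = rel @ u
        ew = np.cross(u, _Z)
        ew = ew / np.linalg.norm(ew)
        w = rel @ ew
        v = rel @ _Z
        return s, w, v

    def semi_axes(self, s: np.ndarray):
        """Effective cross-section semi-axes (in-plane, vertical) at axial s."""
        r = self.outer_radius
        d = self.deformation
        if not isinstance(d, FlattenedContacts):
            return np.full_like(s, r, dtype=float), np.full_like(s, r, dtype=float)
        t = s - d.contact_phase
        m = np.abs(t - d.contact_period * np.round(t / d.contact_period))
        g = _smoothstep((d.blend_length - m) / d.blend_length)
        return r + (d.a - r) * g, r + (d.b - r) * g

    def contains(self, points: np.ndarray) -> np.ndarray:
        """True where a point lies inside the fiber outer surface.

        The lumen counts as inside: for porosity and flow purposes the fiber
        and the volume inside it are both solid.
        """
        s, w, v = self.local_coords(points)
        if isinstance(self.deformation, FlattenedContacts):
            ae, be = self.semi_axes(s)
            return (w / ae) ** 2 + (v / be) ** 2 <= 1.0
        r = self.outer_radius
        return w * w + v * v <= r * r

    def surface_distance(self, points: np.ndarray) -> np.ndarray:
        """Approximate signed distance to the fiber outer surface (um).

        Exact for circular sections; first-order (scaled level-set) for
        flattened sections, which is adequate for the micrometre-scale
        minimum-gap bookkeeping it supports.
        """
        s, w, v = self.local_coords(points)
        if isinstance(self.deformation, FlattenedContacts):
            ae, be = self.semi_axes(s)
            rho = np.sqrt((w / ae) ** 2 + (v / be) ** 2)
            return (rho - 1.0) * np.minimum(ae, be)
        return np.sqrt(w * w + v * v) - self.outer_radius

    def translated(self, shift: np.ndarray) -> "FiberInstance":
        return replace(self, axis_point=self.axis_point + np.asarray(shift, float))


@dataclass(frozen=True)
class UnitCell:
    """A periodic repetitive unit of the bundle.

    ``box_dimensions`` is (Lx, Ly, Lz) in micrometres; the fiber set is
    periodic under translation by any box vector.  Adjacent fiber layers
    touch: their center planes are spaced by outer_diameter * (1 - degree).
    """

    box_dimensions: tuple
    fibers: tuple
    layout: BundleLayout
    spec: FiberSpec
    press_fit: PressFit = PressFit()

    def __post_init__(self) -> None:
        object.__setattr__(self, "box_dimensions", tuple(float(v) for v in self.box_dimensions))
        object.__setattr__(self, "fibers", tuple(self.fibers))

    @property
    def box_volume(self) -> float:
        lx, ly, lz = self.box_dimensions
        return lx * ly * lz

    def periodic_images(self, margin: float | None = None) -> list:
        """Fiber instances translated by +/- one box vector in each axis,
        pruned to those that can intersect the box (with ``margin``)."""
        lx, ly, lz = self.box_dimensions
        if margin is None:
            margin = self.spec.outer_radius
        out = []
        for f in self.fibers:
            for ix in (-1, 0, 1):
                for iy in (-1, 0, 1):
                    for iz in (-1, 0, 1):
                        g = f.translated((ix * lx, iy * ly, iz * lz))
                        # prune by distance from the axis line to the box center
                        c = np.array([lx / 2, ly / 2, lz / 2])
                        rel = c - g.axis_point
                        rel -= (rel @ g.axis_direction) * g.axis_direction
                        half_diag = 0.5 * math.sqrt(lx * lx + ly * ly + lz * lz)
                        if np.linalg.norm(rel) <= half_diag + g.outer_radius + margin:
                            out.append(g)
        return out

    def is_solid(self, points: np.ndarray) -> np.ndarray:
        """Periodic solid-phase membership of arbitrary points (um)."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        box = np.array(self.box_dimensions)
        pts = np.mod(pts, box)
        solid = np.zeros(len(pts), dtype=bool)
        for f in self.periodic_images():
            todo = ~solid
            if not todo.any():
                break
            solid[todo] |= f.contains(pts[todo])
        return solid

    def contact_points(self, gap_tol: float = 1.0) -> list:
        """Fiber-to-fiber contact sites among periodic images.

        Returns a list of (point, fiber_i, fiber_j) where the two fiber
        surfaces approach within ``gap_tol`` um (contact or interpenetration),
        with the point inside the box.
        """
        images = self.periodic_images()
        box = np.array(self.box_dimensions)
        found: list = []
        for i, fi in enumerate(images):
            for fj in images[i + 1:]:
                p = _axes_closest_point(fi, fj)
                if p is None:
                    continue
                q = np.mod(p, box)
                di = float(fi.surface_distance(q[None, :])[0])
                dj = float(fj.surface_distance(q[None, :])[0])
                if di <= gap_tol and dj <= gap_tol:
                    if not any(np.allclose(q, g[0], atol=1e-3) for g in found):
                        found.append((q, fi, fj))
        return found

    def to_json(self) -> str:
        """JSON descriptor of the box and fiber instances (reproducibility)."""
        def fiber_dict(f: FiberInstance):
            d = {
                "axis_point": f.axis_point.tolist(),
                "axis_direction": f.axis_direction.tolist(),
                "outer_radius": f.outer_radius,
            }
            if isinstance(f.deformation, Interpenetration):
                d["deformation"] = {
                    "kind": "interpenetration",
                    "overlap_depth": f.deformation.overlap_depth,
                }
            elif isinstance(f.deformation, FlattenedContacts):
                d["deformation"] = {
                    "kind": "flattened",
                    "a": f.deformation.a,
                    "b": f.deformation.b,
                    "blend_length": f.deformation.blend_length,
                    "contact_period": f.deformation.contact_period,
                    "contact_phase": f.deformation.contact_phase,
                }
            else:
                d["deformation"] = None
            return d

        return json.dumps(
            {
                "box_dimensions": list(self.box_dimensions),
                "spec": {
                    "outer_diameter": self.spec.outer_diameter,
                    "wall_thickness": self.spec.wall_thickness,
                },
                "layout": {
                    "configuration": self.layout.configuration,
                    "pitch": self.layout.pitch,
                    "layer_angle": self.layout.layer_angle,
                },
                "press_fit": {
                    "degree": self.press_fit.degree,
                    "method": self.press_fit.method,
                },
                "fibers": [fiber_dict(f) for f in self.fibers],
            },
            indent=2,
        )


def _axes_closest_point(fi: FiberInstance, fj: FiberInstance):
    """Midpoint of the common perpendicular of two non-parallel axis lines."""
    u, v = fi.axis_direction, fj.axis_direction
    w0 = fi.axis_point - fj.axis_point
    a, b, c = u @ u, u @ v, v @ v
    d, e = u @ w0, v @ w0
    den = a * c - b * b
    if den < 1e-12:  # parallel axes: no localized contact point
        return None
    sc = (b * e - c * d) / den
    tc = (a * e - b * d) / den
    pi = fi.axis_point + sc * u
    pj = fj.axis_point + tc * v
    return 0.5 * (pi + pj)


def build_unit_cell(spec: FiberSpec, layout: BundleLayout) -> UnitCell:
    """Build the undeformed repetitive unit for a bundle layout.

    Orthogonal: a (pitch x pitch x 2d) box holding one fiber along X at
    z = d/2 and one along Y at z = 3d/2 (layers touch; d = outer diameter).
    Angled: a (pitch/cos(alpha) x pitch/sin(alpha) x 2d) box holding one
    fiber of each +/-alpha family, both passing through the in-plane center
    of the box.  This is the smallest rectangular cell that tiles both fiber
    families with zero lateral registration offset.
    """
    d = spec.outer_diameter
    p = layout.pitch
    if p <= d:
        raise OverlapWithinLayerError(
            f"pitch {p} um must exceed the fiber outer diameter {d} um"
        )
    r = spec.outer_radius
    if layout.configuration == "orthogonal":
        box = (p, p, 2 * d)
        fibers = (
            FiberInstance(np.array([0.0, p / 2, r]), np.array([1.0, 0.0, 0.0]), r),
            FiberInstance(np.array([p / 2, 0.0, 3 * r]), np.array([0.0, 1.0, 0.0]), r),
        )
    else:
        alpha = math.radians(layout.layer_angle)
        lx = p / math.cos(alpha)
        ly = p / math.sin(alpha)
        box = (lx, ly, 2 * d)
        c = np.array([lx / 2, ly / 2, 0.0])
        fibers = (
            FiberInstance(c + np.array([0.0, 0.0, r]),
                          np.array([math.sin(alpha), math.cos(alpha), 0.0]), r),
            FiberInstance(c + np.array([0.0, 0.0, 3 * r]),
                          np.array([-math.sin(alpha), math.cos(alpha), 0.0]), r),
        )
    return UnitCell(box, fibers, layout, spec, PressFit())


def analytic_porosity(spec: FiberSpec, layout: BundleLayout) -> float:
    """Closed-form porosity of the undeformed unit: 1 - pi*d/(4*pitch).

    Fiber lumens count as solid.  The result is independent of the layer
    configuration: per unit volume both configurations hold the same length
    of fiber.
    """
    d = spec.outer_diameter
    p = layout.pitch
    if p <= d:
        raise OverlapWithinLayerError(
            f"pitch {p} um must exceed the fiber outer diameter {d} um"
        )
    return 1.0 - math.pi * d / (4.0 * p)


def _compressed(cell: UnitCell, degree: float) -> tuple:
    """Box and rigidly shifted fibers at a given press-fit degree."""
    lx, ly, lz = cell.box_dimensions
    s = 1.0 - degree
    box = (lx, ly, lz * s)
    fibers = []
    for f in cell.fibers:
        ap = f.axis_point.copy()
        ap[2] *= s
        fibers.append(replace(f, axis_point=ap))
    return box, fibers


def apply_press_fit(cell: UnitCell, pf: PressFit) -> UnitCell:
    """Interpenetrated-fibers press-fit: rigid Z-compaction of the layers.

    The box height and the fiber layer center-planes scale by (1 - degree);
    cross-sections are unchanged and fibers of adjacent layers overlap where
    they cross.  In-plane dimensions are unchanged (the housing loads the
    bundle along Z only).
    """
    if not 0.0 <= pf.degree < 1.0:
        raise InvalidPressFitError("press-fit degree must lie in [0, 1)")
    if pf.degree == 0.0:
        return replace(cell, press_fit=pf)
    if pf.method != "interpenetrated":
        raise InvalidPressFitError(
            "apply_press_fit implements the interpenetrated method"
        )
    box, fibers = _compressed(cell, pf.degree)
    depth = cell.spec.outer_diameter * pf.degree
    fibers = [replace(f, deformation=Interpenetration(depth)) for f in fibers]
    return UnitCell(box, tuple(fibers), cell.layout, cell.spec, pf)


def apply_flattened_contact(cell: UnitCell, pf: PressFit) -> UnitCell:
    """Press-fit with area-preserving elliptical contact flattening.

    Box and layer positions move as in the interpenetrated model, but each
    fiber cross-section near every contact becomes an ellipse with minor
    semi-axis b = r*(1 - degree) along Z and major semi-axis a = r^2/b
    in-plane (preserving the cross-sectional area), blended into the circular
    section over one diameter of axial length.  At the contact mid-plane the
    flattened surfaces exactly touch, so no interpenetration remains there.
    """
    if not 0.0 <= pf.degree < 1.0:
        raise InvalidPressFitError("press-fit degree must lie in [0, 1)")
    if pf.degree == 0.0:
        return replace(cell, press_fit=pf)
    if pf.method != "flattened":
        raise InvalidPressFitError(
            "apply_flattened_contact implements the flattened method"
        )
    spec = cell.spec
    if pf.degree >= 2.0 * spec.wall_thickness / spec.outer_diameter:
        raise LumenCollapseError(
            "flattening degree would push the ellipse wall inside the lumen"
        )
    r = spec.outer_radius
    b = r * (1.0 - pf.degree)
    a = r * r / b
    blend = spec.outer_diameter
    box, fibers = _compressed(cell, pf.degree)
    out = []
    for i, f in enumerate(fibers):
        period, phase = _contact_lattice(f, [g for j, g in enumerate(fibers) if j != i],
                                         cell.layout.pitch, box)
        out.append(replace(f, deformation=FlattenedContacts(a, b, blend, period, phase)))
    return UnitCell(box, tuple(out), cell.layout, cell.spec, pf)


def _contact_lattice(f: FiberInstance, others: Sequence[FiberInstance],
                     pitch: float, box: tuple) -> tuple:
    """Axial period and phase of the contacts along fiber ``f``.

    Fibers of the adjacent layers form a parallel family with in-plane
    spacing ``pitch``; crossings with ``f`` repeat along its axis with period
    pitch / |sin(crossing angle)|.
    """
    u = f.axis_direction
    for g in others + [g.translated((0, 0, box[2])) for g in others] + \
            [g.translated((0, 0, -box[2])) for g in others]:
        if abs(abs(u @ g.axis_direction) - 1.0) < 1e-9:
            continue  # parallel: same family
        n2 = np.cross(g.axis_direction, _Z)
        n2 = n2 / np.linalg.norm(n2)
        un2 = u @ n2
        period = pitch / abs(un2)
        phase = float(((g.axis_point - f.axis_point) @ n2) / un2)
        phase = phase % period
        return period, phase
    raise GeometryError("no crossing fiber family found for contact lattice")
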