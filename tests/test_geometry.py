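import json
import math

import numpy as np
import pytest
from hypothesis import given, settings as hsettings
from hypothesis import strategies as st

from fiberperm import (
    BundleLayout,
    FiberSpec,
    PressFit,
    analytic_porosity,
    apply_flattened_contact,
    apply_press_fit,
    build_unit_cell,
)
from fiberperm.geometry import (
    DegenerateLayoutError,
    GeometryError,
    InvalidPressFitError,
    LumenCollapseError,
    OverlapWithinLayerError,
)


class TestBuildUnitCell:
    def test_orthogonal_reference_box_and_layers(self, ortho_cell):
        assert ortho_cell.box_dimensions == (500.0, 500.0, 760.0)
        z = sorted(f.axis_point[2] for f in ortho_cell.fibers)
        assert z == [190.0, 570.0]
        dirs = {tuple(np.abs(f.axis_direction).round(12)) for f in ortho_cell.fibers}
        assert dirs == {(1.0, 0.0, 0.0), (0.0, 1.0, 0.0)}

    def test_angled_reference_box(self, angled_cell):
        lx, ly, lz = angled_cell.box_dimensions
        assert lx == pytest.approx(500 / math.cos(math.radians(20)), abs=0.05)
        assert ly == pytest.approx(500 / math.sin(math.radians(20)), abs=0.05)
        assert lz == 760.0
        # +/-20 degrees to the Y axis
        for f in angled_cell.fibers:
            ang = math.degrees(math.atan2(abs(f.axis_direction[0]),
                                          f.axis_direction[1]))
            assert ang == pytest.approx(20.0, abs=1e-9)

    def test_pitch_below_diameter_rejected(self):
        with pytest.raises(OverlapWithinLayerError):
            build_unit_cell(FiberSpec(380, 50), BundleLayout("orthogonal", 300))

    @pytest.mark.parametrize("angle", [0.0, 90.0])
    def test_degenerate_angle_rejected(self, angle):
        with pytest.raises(DegenerateLayoutError):
            BundleLayout("angled", 500, angle)

    def test_fiber_spec_invariants(self):
        with pytest.raises(GeometryError):
            FiberSpec(380, 200)  # wall thicker than the radius
        with pytest.raises(GeometryError):
            FiberSpec(-1, 0.1)


class TestPeriodicity:
    @pytest.mark.parametrize("which", ["ortho", "angled", "pressed", "flattened"])
    def test_solid_phase_is_box_periodic(self, which, ortho_cell, angled_cell, rng):
        cell = {
            "ortho": ortho_cell,
            "angled": angled_cell,
            "pressed": apply_press_fit(ortho_cell, PressFit(0.15, "interpenetrated")),
            "flattened": apply_flattened_contact(
                angled_cell, PressFit(0.10, "flattened")),
        }[which]
        box = np.array(cell.box_dimensions)
        pts = rng.random((20000, 3)) * box
        base = cell.is_solid(pts)
        for ax in range(3):
            shift = np.zeros(3)
            shift[ax] = box[ax]
            assert np.array_equal(cell.is_solid(pts + shift), base)
            assert np.array_equal(cell.is_solid(pts - shift), base)


class TestAnalyticPorosity:
    @pytest.mark.parametrize("d, p, expected", [
        (380, 500, 0.40),
        (380, 450, 0.34),
        (380, 550, 0.46),
        (200, 263, 0.40),
        (300, 395, 0.40),
    ])
    def test_printed_bundle_porosities(self, d, p, expected):
        eps = analytic_porosity(FiberSpec(d, d / 10), BundleLayout("orthogonal", p))
        assert round(eps, 2) == expected

    def test_no_solid_limit(self):
        eps = analytic_porosity(FiberSpec(1e-6, 4e-7),
                                BundleLayout("orthogonal", 500))
        assert eps == pytest.approx(1.0, abs=1e-8)

    def test_configuration_independent(self):
        spec = FiberSpec(380, 50)
        assert analytic_porosity(spec, BundleLayout("orthogonal", 500)) == \
            analytic_porosity(spec, BundleLayout("angled", 500, 20.0))

    @hsettings(deadline=None, max_examples=50)
    @given(d=st.floats(50, 400), dp=st.floats(1.0, 300), dd=st.floats(1.0, 40))
    def test_monotone_in_pitch_and_diameter(self, d, dp, dd):
        """Porosity grows with pitch and falls with diameter."""
        spec = FiberSpec(d, d / 10)
        lo = BundleLayout("orthogonal", d + 1.0)
        hi = BundleLayout("orthogonal", d + 1.0 + dp)
        assert analytic_porosity(spec, hi) > analytic_porosity(spec, lo)
        big = FiberSpec(d + dd, d / 10)
        p = BundleLayout("orthogonal", d + dd + 1.0)
        assert analytic_porosity(big, p) < analytic_porosity(spec, p)


class TestPressFit:
    def test_zero_degree_is_identity(self, ortho_cell):
        out = apply_press_fit(ortho_cell, PressFit(0.0, "interpenetrated"))
        assert out.box_dimensions == ortho_cell.box_dimensions
        for a, b in zip(out.fibers, ortho_cell.fibers):
            assert np.array_equal(a.axis_point, b.axis_point)
            assert a.deformation is b.deformation

    def test_fifteen_percent_layer_spacing(self, ortho_cell):
        out = apply_press_fit(ortho_cell, PressFit(0.15, "interpenetrated"))
        assert out.box_dimensions[2] == pytest.approx(646.0)
        z = sorted(f.axis_point[2] for f in out.fibers)
        assert z[1] - z[0] == pytest.approx(323.0)
        assert out.box_dimensions[:2] == ortho_cell.box_dimensions[:2]

    def test_invalid_degree_rejected(self, ortho_cell):
        with pytest.raises(InvalidPressFitError):
            PressFit(-0.1, "interpenetrated")
        with pytest.raises(InvalidPressFitError):
            PressFit(0.5, "interpenetrated")

    def test_methods_identical_at_zero_degree(self, ortho_cell):
        a = apply_press_fit(ortho_cell, PressFit(0.0, "interpenetrated"))
        b = apply_flattened_contact(ortho_cell, PressFit(0.0, "flattened"))
        assert a.box_dimensions == b.box_dimensions
        for fa, fb in zip(a.fibers, b.fibers):
            assert np.array_equal(fa.axis_point, fb.axis_point)
            assert np.array_equal(fa.axis_direction, fb.axis_direction)
            assert fa.outer_radius == fb.outer_radius
            assert fa.deformation is None and fb.deformation is None


class TestFlattenedContact:
    def test_area_preserving_ellipse_axes(self, ortho_cell):
        out = apply_flattened_contact(ortho_cell, PressFit(0.15, "flattened"))
        for f in out.fibers:
            assert f.deformation.b == pytest.approx(161.5)
            assert f.deformation.a == pytest.approx(190.0 ** 2 / 161.5, abs=0.05)
            assert f.deformation.a * f.deformation.b == pytest.approx(190.0 ** 2)

    def test_contact_lattice_period(self, ortho_cell, angled_cell):
        out = apply_flattened_contact(ortho_cell, PressFit(0.1, "flattened"))
        for f in out.fibers:
            assert f.deformation.contact_period == pytest.approx(500.0)
        out = apply_flattened_contact(angled_cell, PressFit(0.1, "flattened"))
        for f in out.fibers:
            assert f.deformation.contact_period == pytest.approx(
                500.0 / math.sin(math.radians(40)), rel=1e-9)

    def test_lumen_collapse_detected(self):
        thin = build_unit_cell(FiberSpec(380, 30), BundleLayout("orthogonal", 500))
        with pytest.raises(LumenCollapseError):
            apply_flattened_contact(thin, PressFit(0.16, "flattened"))

    def test_surfaces_touch_at_contact(self, ortho_cell):
        """At the contact mid-plane the flattened surfaces exactly meet."""
        out = apply_flattened_contact(ortho_cell, PressFit(0.15, "flattened"))
        f1, f2 = out.fibers
        # contact is at (x, y) = (250, 250); fiber tops/bottoms along z
        contact_x = np.array([250.0, 250.0, 0.0])
        z1 = f1.axis_point[2] + f1.deformation.b
        z2 = f2.axis_point[2] - f2.deformation.b
        assert z1 == pytest.approx(z2, abs=1e-9)


class TestCellJson:
    def test_descriptor_roundtrip_fields(self, angled_cell):
        data = json.loads(angled_cell.to_json())
        assert data["layout"]["configuration"] == "angled"
        assert data["spec"]["outer_diameter"] == 380
        assert len(data["fibers"]) == 2
        assert data["fibers"][0]["deformation"] is None
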