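import numpy as np
import pytest

from fiberperm import (
    PressFit,
    VoxelGrid,
    apply_press_fit,
    build_preset,
    check_percolation,
    enforce_min_gap,
    measure_porosity,
    monte_carlo_porosity,
    voxelize,
    analytic_porosity,
)
from fiberperm.voxel import DegenerateGapError, ResolutionError

D = 380.0


class TestVoxelize:
    def test_resolution_floor(self, ortho_cell):
        with pytest.raises(ResolutionError):
            voxelize(ortho_cell, D / 10)

    def test_reference_porosity_matches_analytic_and_monte_carlo(self, ortho_cell):
        grid = voxelize(ortho_cell, 2.5)
        eps = measure_porosity(grid).porosity
        assert eps == pytest.approx(0.4031, abs=0.005)
        mc = monte_carlo_porosity(ortho_cell, 2_000_000, seed=7).porosity
        assert eps == pytest.approx(mc, abs=0.005)

    def test_porosity_converges_under_refinement(self, ortho_cell):
        coarse = measure_porosity(voxelize(ortho_cell, D / 64)).porosity
        fine = measure_porosity(voxelize(ortho_cell, D / 128)).porosity
        assert abs(fine - coarse) / fine < 0.005

    def test_shape_spans_box(self, angled_cell):
        grid = voxelize(angled_cell, D / 24)
        box = np.array(angled_cell.box_dimensions)
        assert np.all(np.abs(np.array(grid.shape) * grid.spacing - box)
                      <= grid.spacing)

    @pytest.mark.parametrize("name", ["O_380_50_550", "O_200_25_263"])
    def test_preset_voxel_porosity_matches_analytic(self, name):
        cell = build_preset(name)
        grid = voxelize(cell, cell.spec.outer_diameter / 64)
        eps = measure_porosity(grid).porosity
        assert eps == pytest.approx(
            analytic_porosity(cell.spec, cell.layout), abs=0.005)


class TestMeasurePorosity:
    def test_all_fluid(self):
        g = VoxelGrid(solid=np.zeros((4, 4, 4), bool), spacing=1.0, box=(4, 4, 4))
        res = measure_porosity(g)
        assert res.porosity == 1.0
        assert res.fluid_volume == res.box_volume

    def test_interpenetrated_table_spot_checks(self, ortho_cell, angled_cell):
        c = apply_press_fit(ortho_cell, PressFit(0.10, "interpenetrated"))
        eps = measure_porosity(voxelize(c, D / 64)).porosity
        assert round(eps, 2) == 0.35
        c = apply_press_fit(angled_cell, PressFit(0.15, "interpenetrated"))
        eps = measure_porosity(voxelize(c, D / 64)).porosity
        assert round(eps, 2) == 0.32


class TestMinGap:
    def test_grid_without_contacts_unchanged(self):
        g = VoxelGrid(solid=np.zeros((4, 4, 4), bool), spacing=1.0, box=(4, 4, 4))
        assert enforce_min_gap(g, 1.0) is g

    def test_degenerate_gap_rejected(self, ortho_cell):
        g = voxelize(ortho_cell, D / 20)
        with pytest.raises(DegenerateGapError):
            enforce_min_gap(g, 1e6)

    def test_contact_extension_small_and_one_sided(self, ortho_cell):
        g = voxelize(ortho_cell, D / 48)
        out = enforce_min_gap(g, 1.0)
        e0 = measure_porosity(g).porosity
        e1 = measure_porosity(out).porosity
        assert e1 <= e0  # never adds fluid
        assert e0 - e1 < 0.005

    def test_remaining_passages_thicker_than_gap(self, ortho_cell):
        """After enforcement no fluid voxel sits in a sub-gap contact sliver."""
        g = enforce_min_gap(voxelize(ortho_cell, D / 48), 1.0)
        contacts = ortho_cell.contact_points(gap_tol=1.0)
        assert contacts
        pts = g.centers()[~g.solid.ravel()]
        for q, fi, fj in contacts:
            near = np.linalg.norm(pts - q, axis=1) <= 190.0
            di = fi.surface_distance(pts[near])
            dj = fj.surface_distance(pts[near])
            inside = (di >= 0) & (dj >= 0)
            assert np.all(di[inside] + dj[inside] >= 1.0 - 1e-9)

    @pytest.mark.parametrize("name", ["O_380_50_450", "A_380_50_500"])
    def test_percolation_preserved_at_max_press_fit(self, name):
        cell = apply_press_fit(build_preset(name), PressFit(0.15, "interpenetrated"))
        d = cell.spec.outer_diameter
        g = voxelize(cell, d / 48)
        out = enforce_min_gap(g, 1.0)
        for ax in ("x", "y", "z"):
            if check_percolation(g, ax):
                assert check_percolation(out, ax)


class TestPercolation:
    def test_all_solid_false(self):
        g = VoxelGrid(solid=np.ones((4, 4, 4), bool), spacing=1.0, box=(4, 4, 4))
        assert not check_percolation(g, "z")

    def test_open_lattice_true(self, ortho_cell):
        g = voxelize(ortho_cell, D / 24)
        assert check_percolation(g, "z")

    def test_sealed_slab_blocks_one_axis_only(self):
        solid = np.zeros((6, 6, 6), bool)
        solid[:, :, 3] = True
        g = VoxelGrid(solid=solid, spacing=1.0, box=(6, 6, 6))
        assert not check_percolation(g, "z")
        assert check_percolation(g, "x")
        assert check_percolation(g, "y")

    def test_tightest_press_fit_still_percolates(self):
        cell = apply_press_fit(build_preset("O_380_50_450"),
                               PressFit(0.15, "interpenetrated"))
        g = voxelize(cell, cell.spec.outer_diameter / 48)
        assert check_percolation(g, "z")
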