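import numpy as np
import pytest

from fiberperm import (
    FiberSpec,
    Fluid,
    FlowProblem,
    SolverSettings,
    VoxelGrid,
    fixture_channel,
    grid_convergence,
    reynolds,
    solve_flow,
    superficial_velocity_for_reynolds,
    voxelize,
)
from fiberperm.flow import NoFlowError

WATER = Fluid()


def channel_problem(resolution=32, half_width=32.0, **kw):
    fx = fixture_channel(half_width, resolution=resolution)
    return fx, FlowProblem(grid=fx.grid, flow_direction="x",
                           char_length=fx.char_length, **kw)


class TestPlanePoiseuille:
    def test_profile_and_permeability(self, tight_settings):
        fx, prob = channel_problem()
        field = solve_flow(prob, tight_settings)
        u = field.velocity[..., 0]
        fluid = prob.grid.fluid
        mean = u[fluid].mean()
        assert u.max() / mean == pytest.approx(1.5, rel=0.02)
        L = prob.grid.box[0] * 1e-6
        K_fluid = WATER.viscosity * mean / (field.dP / L)
        assert K_fluid == pytest.approx(fx.oracle_K["fluid"], rel=0.02)

    def test_zero_driving_gives_zero_field(self):
        fx, prob = channel_problem(target_Re=0.0)
        field = solve_flow(prob)
        assert np.all(field.velocity == 0.0)
        assert field.Q == 0.0 and field.dP == 0.0

    def test_mass_conservation_along_flow(self, tight_settings):
        fx, prob = channel_problem()
        field = solve_flow(prob, tight_settings)
        q = field.plane_flow_rates()
        assert (q.max() - q.min()) / q.mean() < 1e-3

    def test_velocity_field_divergence_free(self, tight_settings):
        fx, prob = channel_problem()
        field = solve_flow(prob, tight_settings)
        assert field.divergence_norm() < 0.01

    def test_no_slip_on_solid(self, tight_settings):
        fx, prob = channel_problem()
        field = solve_flow(prob, tight_settings)
        assert np.all(field.velocity[prob.grid.solid] == 0.0)


class TestBoundaryConditions:
    def test_symmetry_equals_periodic_on_orthogonal_cell(self, coarse_ortho_grid):
        dps = {}
        for bc in ("periodic", "symmetry"):
            for direction in ("z", "x"):
                f = solve_flow(FlowProblem(grid=coarse_ortho_grid,
                                           flow_direction=direction,
                                           lateral_bc=bc))
                dps[(bc, direction)] = f.dP
        for direction in ("z", "x"):
            a, b = dps[("periodic", direction)], dps[("symmetry", direction)]
            assert abs(a - b) / a < 0.01

    def test_transverse_directions_equivalent(self, coarse_ortho_grid):
        """X and Y see the same microstructure in the orthogonal cell."""
        kx = solve_flow(FlowProblem(grid=coarse_ortho_grid, flow_direction="x")
                        ).info["permeability_m2"]
        ky = solve_flow(FlowProblem(grid=coarse_ortho_grid, flow_direction="y")
                        ).info["permeability_m2"]
        assert kx == pytest.approx(ky, rel=0.01)

    def test_angled_cell_rejects_symmetry(self, angled_cell):
        g = voxelize(angled_cell, 380 / 20)
        with pytest.raises(ValueError):
            FlowProblem(grid=g, flow_direction="z", lateral_bc="symmetry")

    def test_sealed_geometry_raises(self):
        solid = np.zeros((6, 6, 8), bool)
        solid[:, :, 4] = True
        g = VoxelGrid(solid=solid, spacing=2.0, box=(12, 12, 16))
        with pytest.raises(NoFlowError):
            solve_flow(FlowProblem(grid=g, flow_direction="z", char_length=10))


class TestDarcyRegime:
    def test_stokes_solution_scales_exactly_with_flow_rate(self):
        """In Stokes mode dP/Q is independent of the target Reynolds number."""
        fx, _ = channel_problem()
        ratios = []
        for re in (0.1, 1.0):
            prob = FlowProblem(grid=fx.grid, flow_direction="x",
                               char_length=fx.char_length, target_Re=re)
            f = solve_flow(prob)
            ratios.append(f.dP / f.Q)
        assert ratios[0] == pytest.approx(ratios[1], rel=1e-9)

    def test_viscosity_independence_of_permeability(self, coarse_ortho_grid):
        ks = []
        for mu in (1e-3, 2e-3):
            f = solve_flow(FlowProblem(grid=coarse_ortho_grid, flow_direction="z",
                                       fluid=Fluid(viscosity=mu)),
                           SolverSettings(residual_tolerance=1e-7))
            ks.append(f.info["permeability_m2"])
        assert ks[0] == pytest.approx(ks[1], rel=1e-6)


class TestGridConvergence:
    def test_channel_monotone_and_optimal_level(self):
        def factory(spacing):
            res = int(round(64.0 / spacing))
            return fixture_channel(32.0, resolution=res).grid

        fx, prob = channel_problem()
        rep = grid_convergence(prob, [4.0, 2.0, 1.0], grid_factory=factory,
                               min_gap=None)
        assert rep.optimal_spacing is not None
        assert rep.rel_diff_vs_finest[-1] == 0.0
        # refinement approaches the closed form
        oracle_dp = None
        diffs = rep.rel_diff_vs_finest
        assert diffs[0] >= diffs[1] >= diffs[2]

    def test_identical_levels_zero_difference(self):
        def factory(spacing):
            return fixture_channel(32.0, resolution=16).grid

        fx, prob = channel_problem(resolution=16)
        rep = grid_convergence(prob, [2.0, 2.0, 2.0], grid_factory=factory,
                               min_gap=None)
        assert max(rep.rel_diff_vs_finest) == 0.0

    def test_needs_three_levels(self, coarse_ortho_grid):
        prob = FlowProblem(grid=coarse_ortho_grid, flow_direction="z")
        with pytest.raises(ValueError):
            grid_convergence(prob, [19.0, 11.875])


class TestReynolds:
    def test_operating_velocity_at_unit_reynolds(self):
        spec = FiberSpec(380, 50)
        u = superficial_velocity_for_reynolds(1.0, spec)
        assert u == pytest.approx(2.64e-3, rel=0.01)
        assert reynolds(u, spec) == pytest.approx(1.0, rel=1e-12)

    def test_zero_and_linearity(self):
        spec = FiberSpec(380, 50)
        assert reynolds(0.0, spec) == 0.0
        assert reynolds(2e-3, spec) == pytest.approx(2 * reynolds(1e-3, spec))

    def test_solution_reports_target_reynolds(self, coarse_ortho_grid):
        f = solve_flow(FlowProblem(grid=coarse_ortho_grid, flow_direction="z"))
        assert f.reynolds == pytest.approx(1.0, rel=1e-6)
        area = 500e-6 * 500e-6
        assert f.Q == pytest.approx(f.superficial_velocity * area, rel=1e-9)
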