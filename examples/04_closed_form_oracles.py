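"""Validate the flow solver against closed-form permeabilities.

Two synthetic periodic solids with known answers: a plane channel (exact
plane-Poiseuille permeability h^2/3) and a square array of parallel
cylinders (Gebart's transverse lubrication formula, Drummond-Tahir's axial
lattice solution).
"""

from fiberperm import (
    FlowProblem,
    SolverSettings,
    fixture_channel,
    fixture_cylinder_array,
    solve_flow,
)

settings = SolverSettings(residual_tolerance=1e-7)

fx = fixture_channel(32.0, resolution=64)
field = solve_flow(FlowProblem(grid=fx.grid, flow_direction="x",
                               char_length=fx.char_length), settings)
u = field.velocity[..., 0]
mean = u[fx.grid.fluid].mean()
K = 1e-3 * mean / (field.dP / (fx.grid.box[0] * 1e-6))
print(f"channel h=32 um : K = {K:.4e} m^2, closed form {fx.oracle_K['fluid']:.4e}"
      f"  (ratio {K / fx.oracle_K['fluid']:.4f}, max/mean {u.max()/mean:.4f})")

for vf, direction, name in ((0.6, "x", "transverse/Gebart"),
                            (0.4, "z", "axial/Drummond-Tahir")):
    fx = fixture_cylinder_array(vf, resolution=64)
    field = solve_flow(FlowProblem(grid=fx.grid, flow_direction=direction,
                                   char_length=fx.char_length), settings)
    K = field.info["permeability_m2"]
    print(f"cylinders vf={vf} {name}: K = {K:.4e} m^2, "
          f"closed form {fx.oracle_K[direction]:.4e}  "
          f"(ratio {K / fx.oracle_K[direction]:.4f})")

print("\nthe channel is exact by construction of the lattice kernel; the")
print("cylinder arrays agree with their closed forms within a few percent")
print("at 64 voxels per diameter, in the regimes where those forms hold.")
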