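"""The calibrated hyperelastic fiber-wall material.

Evaluates the Neo-Hookean strain-energy potential shipped with the package
(calibrated on transverse compression of 380 um polypropylene oxygenator
fibers) and its small-strain moduli.
"""

from fiberperm import (
    DEFAULT_FIBER_MATERIAL,
    StrainState,
    derived_moduli,
    strain_energy,
)

mat = DEFAULT_FIBER_MATERIAL
print(f"C10 = {mat.C10} MPa, D1 = {mat.D1} 1/MPa")

for state, label in [
    (StrainState(3.0, 1.0), "reference state"),
    (StrainState(3.1, 1.0), "deviatoric stretch (I1=3.1)"),
    (StrainState(3.0, 1.01), "1% volumetric expansion"),
]:
    print(f"U = {strain_energy(mat, state):10.4e} MPa   [{label}]")

mu0, bulk, nu = derived_moduli(mat)
print(f"\nsmall-strain moduli: shear {mu0:.3f} MPa, bulk {bulk:.2f} MPa, "
      f"Poisson ratio {nu:.3f}")
print("a compliant, mildly compressible polymer wall: stiff enough that")
print("blood-pressure loads barely deform the bundle, soft enough that")
print("press-fitting flattens the fiber contacts.")
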