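# Methods

This note documents the models, numerical choices and limitations behind
`fiberperm`.  Everything quantitative stated here is computed by the test
suite or by `scripts/acceptance.py`.

## Geometry: the repetitive unit

The bundle is idealized as a perfectly regular lattice of straight hollow
fibers with alternating layer orientation, layers touching (center-plane
spacing equal to the outer diameter d).  Fiber lumens count as solid: the
fluid domain is the cell box minus the fibers and the volume inside them.
All lengths are micrometres internally; permeability is reported in m².
Coordinates are right-handed with Z the stacking/press-fit direction and Y
the axial direction of angled layups.

* **Orthogonal cell** — box (p × p × 2d) holding one fiber along X at
  z = d/2 and one along Y at z = 3d/2 (p = pitch).  Its in-plane (x, y) cell
  faces are mirror planes of the geometry; the z faces lie between layers
  and are periodic only.
* **Angled cell (±α to Y)** — the smallest rectangular periodic box is
  (p/cos α × p/sin α × 2d); one fiber of each family passes through the
  in-plane box center ("zero registration").  Any in-plane extent and
  registration consistent with the two line families tiles the same
  microstructure; the choice is validated by the porosity invariant
  (orthogonal and angled cells with equal d, p have identical porosity,
  analytically 1 − πd/4p).

The undeformed porosity is analytic: ε₀ = 1 − πd/(4p), independent of the
layer configuration (per unit volume both configurations hold the same fiber
length).

## Press-fit models

Press-fitting by a degree f compresses the bundle along Z only: the box
height and the layer center-planes scale by (1 − f); pitch is unchanged
(the housing constrains Z only).

* **Interpenetrated** (`apply_press_fit`): cross-sections stay circular and
  fibers of adjacent layers overlap where they cross.  Porosity uses the
  compressed nominal box.  Exact unioned-cylinder geometry gives
  0.4031 / 0.3740 / 0.3463 / 0.3200 at f = 0 / 5 / 10 / 15 % for the
  reference bundles — and provably the *same* numbers for the orthogonal and
  angled configuration: per unit volume the orthogonal cell holds 2
  perpendicular overlap lenses where the angled cell holds 4 lenses that are
  each 1/sin 2α larger in a cell 2× bigger, which cancels exactly.
* **Flattened** (`apply_flattened_contact`): a parametric approximation of
  the contact flattening a deformable wall undergoes.  Near every contact
  the circular section becomes an ellipse with minor semi-axis
  b = (d/2)(1 − f) along Z and major semi-axis a = (d/2)²/b in-plane
  (cross-sectional area preserved, mimicking the near-incompressible bending
  of the wall), blended into the circle by a smoothstep over one diameter of
  axial length.  At the contact mid-plane the flattened surfaces exactly
  touch; no interpenetration remains.  This is a geometric stand-in for a
  full hyperelastic contact solution: it reproduces the porosity trend
  (ε ≈ 0.295 at f = 15 % for the orthogonal reference bundle) but only the
  qualitative shape of the deformed fiber, so permeabilities derived from it
  are comparative, not calibrated.
* The contact lattice along each fiber (period p/|sin θ| with θ the
  crossing angle, phase from the crossing family's in-plane offset) is
  computed from the axis lines, so both models apply to orthogonal and
  angled layups uniformly.

The fiber-wall material is Neo-Hookean, U = C₁₀(Ī₁ − 3) + (J_el − 1)²/D₁,
with shipped constants C₁₀ = 17.308 MPa and D₁ = 0.027 MPa⁻¹ calibrated on
transverse compression of commercial 380 µm polypropylene fibers
(small-strain shear modulus 34.6 MPa, bulk modulus 74.1 MPa, ν ≈ 0.30).
The structural contact simulation itself is out of scope; the constants
anchor the flattened-contact geometry and downstream structural work.

## Voxelization and porosity

A voxel is solid iff its center lies inside any (deformed) fiber outer
surface, with periodic wrap.  Per-axis voxel counts are the nearest integers
to box/spacing, so the grid tiles the true box exactly; per-axis spacings
then deviate from the nominal isotropic spacing by < 1 part in the voxel
count (< 0.5 % here), and the flow kernel treats the lattice as cubic with
the geometric-mean spacing.  Defaults: d/64 for porosity (|ε_voxel − ε_exact|
< 0.002 for the reference cell), d/32 for flow.  Center-testing was chosen
over volume-fraction antialiasing for simplicity; its error is first order
in spacing and is controlled by the convergence study.

**Minimum-gap rule.**  Touching fibers create wedge-shaped fluid slivers of
vanishing thickness around each contact line.  Mirroring the practice of
slightly extending the contact area when meshing such geometries, fluid
whose passage between the two contacting surfaces is thinner than 1 µm
(sum of distances to the two surfaces < 1 µm) is absorbed into the solid.
On production grids (spacing ≥ 4 µm) this affects at most a handful of
voxels and changes porosity by ≪ 0.005; it exists so that the discrete
fluid domain never depends on sub-micrometre slivers the solver cannot
resolve.

**Percolation** is checked before every solve: 6-connected fluid must cross
the cell in the flow direction (tested on a domain doubled along the flow
axis with lateral periodic label merging).

## Flow solver

Steady incompressible creeping flow through the periodic cell is computed
with a D3Q19 two-relaxation-time (TRT) lattice Boltzmann kernel:

* halfway bounce-back on solid voxels; periodic wrap, or specular
  (symmetry) reflection on lateral faces that are mirror planes of the
  geometry (only the in-plane faces of the orthogonal cell qualify);
* magic parameter Λ = (1/ω⁺ − ½)(1/ω⁻ − ½) = 3/16, which pins the
  bounce-back wall exactly midway between voxel centers and makes the
  extracted permeability insensitive to the relaxation rate;
* uniform body force along the flow direction (Guo forcing) with an
  additional −6wᵢ(cᵢ·F) correction on bounce-back links; without this
  correction a body-force-driven channel flow shows a spurious wall slip of
  2ν (lattice units) even at Λ = 3/16.  With it, plane Poiseuille flow is
  reproduced to machine precision at any lattice viscosity, including the
  discrete-sampling factor (2m² + 1)/2m² of an m-voxel channel;
* `advection="stokes"` (default, used for all permeability extraction):
  linear equilibrium, no even-order force term.  The update is exactly
  linear in (u, F), so ΔP ∝ Q identically, the solution is rescaled exactly
  onto the target Reynolds number, and K is viscosity-independent by
  construction (verified to 10⁻⁶ relative).  Lattice viscosity 0.5 for fast
  relaxation.
* `advection="navier_stokes"`: standard compressible quadratic equilibrium
  at unit relaxation time (lattice viscosity 1/6), force pre-targeted by a
  Stokes solve and refined until the superficial velocity matches the
  target Re within 0.2 %.  Used to demonstrate that inertial corrections at
  Re ≤ 1 are negligible: ΔP/Q varies by ~0.05 % between Re = 0.1 and 1 on
  the reference cell.  (An earlier hybrid incompressible-equilibrium variant
  was nonlinearly unstable on large pore geometries and was replaced by the
  standard equilibrium.)

Convergence is declared when the relative L1 change of the velocity field
over a 100-step interval falls below the residual tolerance (default 10⁻⁵,
10⁻⁶ in the acceptance runs) on two consecutive checks.  Pressure is
cₛ²(ρ − ρ̄) (periodic part); the mean gradient is carried by the body force
and reported as ΔP = F·L.  Body-force driving with fully periodic pressure
is equivalent, in the Darcy regime, to the prescribed mass-flow-rate /
zero-outlet-pressure setup of a pressure-jump formulation.

Reynolds convention: Re = ρ u_superficial d_outer/µ with water
(µ = 10⁻³ kg m⁻¹ s⁻¹, ρ = 998 kg m⁻³).  At Re = 1 and d = 380 µm the
operating superficial velocity is 2.64 mm/s.  ρ only enters through this
scaling; K is geometric.

## Darcy extraction

K = µ(Q/A)(L/ΔP) per direction, with A and L from the nominal box at the
current press-fit degree (Z-flow: L = 2d(1 − f), A = Lx·Ly; in-plane flow:
L = the in-plane box length, A includes the compressed Z extent).  Q is the
superficial velocity (box average of the velocity component) times A.
Press-fit sweeps are normalized by the same-direction undeformed K₀.

## Validation and measured accuracy

Computed by the test suite on one CPU:

* plane Poiseuille: exact (machine precision, after the discrete-sampling
  factor);
* square cylinder array, transverse flow at fiber fraction 0.6, 64 voxels
  per diameter: within 1 % of the Gebart lubrication closed form.  (At
  fraction 0.4 the lubrication assumption itself overpredicts K by ~9 %
  against grid-converged numerics, so the moderate-fraction regime is
  validated axially instead.)
* square cylinder array, axial flow at fraction 0.4: within 3 % of the
  Drummond–Tahir lattice solution;
* orthogonal reference cell: K from X-flow equals K from Y-flow to < 0.1 %,
  and symmetry vs periodic lateral faces agree to < 0.1 %.

At the production resolution d/32 the voxel staircase biases bundle
permeabilities a few percent low; the grid-sensitivity report
(`grid_convergence`, the < 1 % pressure-drop rule applied against the finest
level) shows level-to-level scatter of ~3–4 % for bundle cells — dominated
by the re-snapping of the cell box to integer voxel counts — and clean
monotone convergence on snap-free geometries (the channel fixture meets the
< 1 % rule immediately).  The resulting undeformed anisotropy values are
4–7 % below the body-fitted finite-volume reference values for all five
bundle/direction combinations, comfortably inside the ±15 % band used for
acceptance, with both anisotropy orderings (K_Z > K_X orthogonal;
K_Y > K_Z > K_X angled) reproduced.

## What the synthetic fixtures do and do not show

The fixtures (plane channel, square cylinder array) are periodic solids
with closed-form ε and K — the structure the analysis assumes.  They
validate the voxelization → minimum-gap → flow → Darcy chain end to end,
but they contain no fiber-fiber contacts, no layup anisotropy and no
deformation, so passing them says nothing about the press-fit models;
those are anchored by the analytic porosity results instead.

## Known limitations

* The flattened-contact model is a parametric approximation: it preserves
  wall cross-sectional area and removes interpenetration but does not solve
  the contact mechanics, so its permeabilities track the qualitative effect
  of fiber widening only.  FE-derived deformed-geometry permeabilities
  (normalized-K curves of structurally simulated press-fit) are outside the
  package's scope.
* Perfect fiber alignment and uniformity are assumed; no random positional
  irregularity, no bundle curvature (angled layups are treated in a
  Cartesian frame).
* Blood rheology, gas-side flow, fluid-structure interaction and
  pressurization effects are out of scope; the working fluid is water at
  the Re = 1 operating point.
* One printed reference entry is internally inconsistent with the exact
  interpenetrated geometry (see the porosity table test: the orthogonal
  5 %-press-fit interpenetrated entry); the package reports the exact
  geometric value 0.374, which equals the angled-configuration value as it
  must.
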