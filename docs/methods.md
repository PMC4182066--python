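# Methods

`orbishock` simulates the impulsive loading of the bony orbital walls in a
blowout-fracture scenario and quantifies the outward-then-retrograde wall
motion that has been proposed as the mechanism of posttraumatic orbital
emphysema: the floor first bulges toward the maxillary sinus, then a
"recurring" wave carries previously outward-displaced regions back toward
the orbital interior, reversing the trans-wall pressure gradient and
potentially drawing sinus air into the orbit.

## Model

### Geometry

No patient geometry ships with the package; the `orbit_geometry` module
generates a parametric *average adult orbit* as a triangulated midsurface:

- Four walls (floor, medial, roof, lateral) converge from a
  rounded-rectangular anterior rim to a truncated posterior apex carrying
  the circular optic-canal aperture. Cross-sections are superellipses
  morphing from exponent 4 (rounded rectangle) at the rim to 2 (circle) at
  the apex, resampled to equal arc length per ring.
- Defaults: rim 40 x 35 mm, depth 45 mm, optic-canal radius 2.5 mm,
  inferior-orbital-fissure slit 20 x 3 mm between posterior floor and
  lateral wall — standard anatomical averages, all configurable.
- `bulge` (default 0.08) widens the cavity fractionally behind the rim,
  peaking mid-depth. The orbit is widest a short distance behind the
  entrance, not at it; geometrically this gives every wall meridian a
  slight outward convexity. It also matters mechanically: on a perfectly
  straight frustum meridian the buckling direction of a wall under rim
  thrust is indeterminate, whereas the (real) outward bow makes the
  outward response well-posed. `bulge=0` recovers the pure frustum.
- Ring spacing is graded so band height tracks the local cross-section
  perimeter, keeping triangle aspect ratios near one from rim to apex;
  the default target of 969 elements matches the reference model size
  within 10% (the generator produces 908).
- Wall thickness by region (mm): floor 0.5 anterior / 1.0 posterior
  (thicker posteriorly, as in real floors), medial 0.3 (lamina
  papyracea), roof 1.0, lateral 1.5, rim band 3.0.
- Boundary conditions: all six generalized displacements are fixed on the
  apex-aperture ring and on the superior half of the rim (where the walls
  continue into the skull). The inferior rim is left free so the strike
  can act on unconstrained nodes; fixing it would make the load case
  meaningless.
- Six strike nodes are placed on the free inferior rim arc, equally
  spaced by arc length (a small dynamic program minimizes gap-length
  variance). Probe A sits on the anterior floor near 25% depth, between
  the inferomedial (nasolacrimal) corner and the inferior midline.
- Node jitter (up to 5% of the local edge length, seeded) breaks
  structured-mesh symmetry; `jitter=0` gives the exact structured grid.
  The generator is deterministic for a fixed seed and scale-equivariant:
  scaling all midsurface lengths scales node coordinates exactly. The
  thickness map is deliberately not touched by `OrbitParams.scaled`,
  since thickness is a shell parameter with its own validity range.

### Shell finite elements

Flat-facet triangles superposing a constant-strain membrane (CST) with the
discrete Kirchhoff plate-bending triangle (DKT), six dofs per node. The
DKT rotation interpolation is constructed from its definition — quadratic
rotation field, linear edge-normal rotation, edge-tangential rotation from
the midpoint slope of the Hermite cubic deflection — rather than from
precomputed coefficient tables. The drilling rotation (about the shell
normal) is stabilized by a penalty tying each nodal drilling rotation to
the element's membrane in-plane rotation ½(∂v/∂x − ∂u/∂y); the penalty
stiffness is 1e-4 × E·t·A (membrane scale). Scaling it from the bending
stiffness instead would leave the spurious drilling modes numerically
indistinguishable from rigid-body modes on thin shells (bending ~ E·t³
vs membrane ~ E·t). All six rigid-body motions are exactly zero-energy,
and an unconstrained flat assembly has exactly six near-zero eigenvalues.

Material: linear elastic isotropic. E = 1.2 GPa is the mean extensometer
measurement on human orbital-wall bone samples; Poisson's ratio 0.3 and
density 1900 kg/m³ are standard cortical-bone values (neither was
measured). Rayleigh damping is available but defaults to zero so the
energy checks are exact.

Internal units are mm–N–tonne–s (stress in MPa), which keeps assembled
matrix entries well scaled; SI inputs (Pa, kg/m³) are converted at the
`Material` boundary.

Mass is lumped: ρ·A·t/3 per node per element for translations; rotational
entries use I = m_node·A/6, i.e. nodal mass times a length² of the order
of the element size. This conventional explicit-dynamics choice keeps
rotational dofs from dominating the stable time step while adding
negligible rotary inertia to structural modes spanning many elements (the
plate-frequency benchmark error stays below 0.3%).

### Load case and integration

The strike: 14400 N total, split as 6 × 2400 N point forces on the
inferior-rim strike nodes, directed posteriorly along the orbital axis
(+x). The pulse is a symmetric triangular ramp 0 → 1 → 0 with knots at
0, 1.3 ms and 2.6 ms — the simplest profile consistent with a stated peak
time and end time. The response is recorded at 1 ms snapshots over 10 ms.

Default integrator: explicit central difference with the lumped mass,
`dt = 0.8 × 2/ω_max` (≈ 2.2e-7 s on the default mesh, ~45k steps in a few
seconds). ω_max is estimated by power iteration on M^(-1/2)K M^(-1/2)
with a residual-based stopping rule (‖Av − θv‖ ≤ ½·tol·θ), which bounds
the eigenvalue error directly and stays sharp when the top modes cluster;
against a dense eigensolve on small meshes the estimate is within 0.1%.
A step above the stability limit is not rejected up front: the stepper's
divergence guard (displacement norm exceeding 10³ × the model scale, or
non-finite) aborts with the step index.

The implicit Newmark average-acceleration scheme (β=¼, γ=½, one sparse
LU factorization) serves as a cross-check; on a reduced orbit at
dt = stable_dt/2 the two probe traces agree to 0.01% of peak amplitude.

Energy bookkeeping uses the discrete central-difference identities
(midpoint kinetic energy ½v_{n+½}ᵀMv_{n+½}, symmetrized strain product
½u_nᵀKu_{n+1}, work increment f_n·(u_{n+1}−u_{n−1})/2), for which the
undamped balance holds to round-off — the 1% tolerance in the checks is
pure headroom.

### Wave analysis

The signed wall displacement projects each node's translation onto its
reference wall normal (area-weighted average of adjacent facet normals,
pointing into the cavity): positive = toward the orbital interior,
negative = toward the sinus/exterior. The alternative `orbital_axis` mode
projects onto the anteroposterior axis and signs by wall side, mirroring
the convention of measuring along the orbit's sagittal axis; which of the
two the original figures used is ambiguous, so both are provided.

- *Load-window floor statistics* are area-weighted: the swept volume
  ∫u·n dA over the floor (the physically meaningful quantity for the
  pressure argument) and the fraction of floor area moving outward.
  Node counting would measure mesh grading, not wall motion, because the
  graded mesh concentrates nodes posteriorly.
- *Retrograde detection*: earliest snapshot at which any floor/medial-base
  node crosses from below −ε to above +ε (default ε = 0.1 mm — above
  numerical noise, below the smallest reported relocation of 0.5 mm).
- *Peak inward* is reported over the post-reversal phase when a reversal
  is detected: it is the amplitude of the recurring wave. During the
  strike itself parts of the wall transiently move inward as the flexural
  wave passes; that early motion is not the recurring wave and would
  otherwise dominate the statistic.
- *Stress recovery*: per element, surface strain ε_m ∓ (t/2)κ at the two
  fibers through the plane-stress law; von Mises of the 2D tensor. The
  fracture surrogate is a configurable von Mises limit, default 80 MPa
  (order of cortical-bone tensile strength); only the first exceedance
  *time* in the floor is reported, never assumed.

## What the synthetic data can and cannot show

The generator emulates the average orbit's proportions, regional
thicknesses, apertures and support conditions, and the default run
reproduces the qualitative sequence: net outward floor motion during the
load window, a detected reversal after the outward peak, and an inward
rebound strictly weaker than the outward excursion, with the probe-A
asymmetry in the same sense as the reference trace (4.37 mm out vs
1.55 mm in).

It does not reproduce, and is not expected to reproduce, the reference
millimetre values: the original mesh was averaged from 100 patients' CT
and is unpublished. Differences that matter: the synthetic rim band is a
thin shell strip rather than the massive rim arch backed by the maxillary
sinus walls, so rim-adjacent displacements are several-fold larger and
the response peaks earlier (1–4 ms rather than 4–9 ms); the stress limit
is exceeded immediately rather than at 2.6 ms; soft tissue, periosteum
and the globe are absent; post-fracture mechanics are out of scope (the
run continues past the threshold without element failure, and exceedance
is only flagged). Displacements of several millimetres on a ~40 mm organ
also stretch the linear-kinematics assumption; the solver is geometrically
linear throughout, which is a stated limitation.

## Numerical choices

- Drilling penalty 1e-4 × E·t·A (see above).
- Static solves: sparse LU on the constrained operator; residual checked
  against 1e-8·‖f‖; singular systems raise a diagnostic listing near-zero
  eigenvalues. Inhomogeneous Dirichlet data is applied by elimination.
- Element stresses and strains are reported in the element's local frame
  (first edge = local x); von Mises and the wave metrics are frame
  invariant.
- Snapshots land exactly on the reporting grid: the solver dt is rounded
  down so an integer number of steps spans each 1 ms interval.
- Degenerate triangles (area ≤ ~1e-12 of edge²) raise an element error
  naming the element; generated meshes reject any triangle with an
  internal angle ≤ 10°.
- Benchmark problem sizes: the plate checks use 32×32 (deflection) and
  24×24 (frequency) subdivisions, the energy-balance and cross-integrator
  checks a ~300-element orbit, and the dense stable-dt oracle a
  ~185-element orbit — sizes at which every oracle comparison sits well
  inside its tolerance while the whole verification suite runs in
  seconds.

## Known limitations

Linear kinematics and linear elasticity; no contact, no fracture
propagation, no fluid (air) coupling — the pressure-swing interpretation
of the swept-volume curve is exactly that, an interpretation. The
fissure is a bare slit without soft-tissue content. The element is the
simplest well-validated thin-shell formulation; equivalence with any
particular commercial shell element cannot be asserted, only the
benchmark-level correctness documented by the verification suite.
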