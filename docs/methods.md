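# Methods

`pfmsim` simulates the second stage of labor at desk scale: a rigid sphere
standing in for the fetal head descends under gravity through an elastic
sheet standing in for the pelvic floor muscle (PFM), with frictional
contact, and the fields are post-processed into the peak/extremum metrics
used in the biomechanics literature (equivalent and principal stress and
strain with occurrence times, displacement extrema, extension ratios).

## Model overview and unit system

All quantities use the consistent mm–ton–s–MPa system: lengths mm, mass
ton, time s, stress MPa, density ton/mm³, force N, energy mJ, gravity
g = 9810 mm/s². The head is an analytic rigid sphere of biparietal diameter
D ∈ {80, 90, 100} mm and density 7.86×10⁻⁹ ton/mm³, so its mass
(π/6)·D³·ρ is ≈3.0 kg at D = 90 — the typical newborn weight that
motivates the density value. The head translates vertically only (1 DOF);
fetal rotation and extension are outside scope. The muscle is isotropic
elastic with E = 0.2 MPa, ν = 0.4, ρ = 1.12×10⁻⁹ ton/mm³.

## The surrogate geometry

No subject geometry is available, so the deformable body is a parametric
surrogate: a constant-thickness (6 mm) curved sheet spanning a
70 mm × 60 mm footprint whose mid-surface sags into a bowl 34 mm deep
(bounding height 40 mm), pierced by a 50 × 30 mm elliptical urogenital
hiatus at the center. X is the 70 mm length (anteroposterior), Y the 60 mm
width, Z vertical (descent is −Z). The bowl wall descends steeply from the
attachment margin (a cosine-quarter-wave profile raised to the
`bowl_profile` exponent, steep at the rim and levelling into a full-depth
floor inside `plateau_fraction` of the normalized footprint radius), so the
whole footprint is the bowl mouth, as in the anatomical levator funnel.
Every head diameter exceeds both hiatus axes, so passage requires large
stretch of the opening.

Only the bounding dimensions, the central hiatus and the constrained
attachment are treated as faithful; everything else (profile, thickness,
hiatus axes) is a documented surrogate choice. Field magnitudes on this
surrogate are **not** comparable to subject-specific values; trends across
D and the metric arithmetic are.

### Attachment (boundary conditions)

All degrees of freedom are fixed on the attachment margin. By default this
is the anterior (x = −35 mm) margin, modelled as **two lateral bands**
(|y| ≥ 24 mm): the pubococcygeus inserts on the pubic bone on either side
of the midline urogenital gap, through which urethra and vagina pass and
where no muscle attaches. Two geometric facts motivate the banded default:

* a closed fixed ring of a 70 × 60 mm footprint cannot pass any head with
  D ≥ 80 mm — a fully clamped perimeter arrests the sphere after ~26 mm of
  descent, which contradicts the deformation pattern the study describes;
* with heads this large, every plan point of the footprint lies within the
  swept cylinder of the largest head, so rigid anchors directly in the
  sweep act as crush lines. The 24 mm gap keeps the anchors outside the
  swept volume of the 80 and 90 mm heads entirely; the 100 mm head retains
  ~7.6 mm of irreducible overlap at the band tips (every footprint point
  is within 50 mm of the axis), which shows up as the strongest local
  strain concentration of the D100 run.

Continuous margins (`sides=("all",)` etc.) remain available in
`select_fixed_rim`.

Contact is evaluated at unconstrained nodes only: the fixed insertion line
represents muscle fused to bone; the obstacle effect of the bony pelvis
itself (through which the real head passes with clearance) is not
modelled.

### Meshing

The mesher is purpose-built (structured, deterministic): a quadrilateral
annular grid between the hiatus ellipse and the footprint rectangle, both
boundary curves sampled uniformly by arc length and joined by spokes that
are re-sampled by 3-D arc length (so element edges track the target size
on the steep wall); the grid is extruded vertically through the sheet
thickness and every hexahedral cell is split into six tetrahedra with the
Kuhn main-diagonal pattern. Because the extrusion is a vertical shear and
every Kuhn tetrahedron spans exactly three node columns, each tetrahedron's
volume equals (base-triangle area)·(layer height)/3 exactly — the mesh is
inversion-free by construction and its volume equals the polygonal
footprint area times the thickness. Node sets are selected geometrically
afterwards. Supported exports: VTU/PVD, Gmsh MSH 2.2, Abaqus INP (C3D4 +
NSET).

The default run mesh is 3 mm (≈3.5 k nodes, ≈13 k tets); 2 mm is supported
and converges to the same solid volume within 5%.

## Mechanics

The published constitutive choice is an isotropic linear elastic law, but
the published stretches exceed 100%, where the small-strain law is not
objective. The package therefore uses the Saint Venant–Kirchhoff (SVK)
model — the same two constants applied to the Green–Lagrange strain
E = (FᵀF − I)/2, S = λ tr(E) I + 2μ E — which is rotation-safe and reduces
to Hooke's law at small strain (verified to 0.5% in the tests). A strict
small-strain mode exists for verification only. Stress is reported as
Cauchy stress σ = F S Fᵀ/det F (what a deformed-configuration contour plot
shows); "principal strain" is the largest eigenvalue of the Green strain.
SVK softens under strong compression and offers no failure model: at rigid
anchors in the load path, local strains can grow far beyond physiological
magnitudes (the model's analog of attachment-point lesions) — these field
maxima are mesh-sensitive and should be read qualitatively.

Internal forces are the exact gradient of the SVK strain energy on linear
tetrahedra (total-Lagrangian single-point kernel), assembled in a compiled
(numba) loop with a pure-numpy fallback.

## Time integration

Central-difference (leapfrog) explicit dynamics with lumped masses (each
tetrahedron's mass split equally over its four nodes). The stable step is
the element characteristic length over the dilatational wave speed
c = √(E(1−ν)/((1+ν)(1−2ν)ρ)) ≈ 1.96×10⁴ mm/s; `stable_dt` exposes the
textbook minimum-edge estimate, while the simulator uses the conservative
minimum-altitude (3V/A_max) measure. Because the SVK tangent stiffness
grows roughly with the squared stretch, the run-time step adapts: the
force kernel returns max trace(FᵀF) (a free upper bound on the squared
principal stretch), and the step is divided by the corresponding tangent
wave-speed factor √((3λ²−1)/2), plus a fixed safety (`stiffening_safety`,
default 1.5) and a penalty-stiffness cap combined in quadrature. The
variable-step leapfrog advances velocities over the midpoint span, which
keeps the constant-gravity free-fall solution exact to machine precision —
the free-fall oracle (110.36 mm drop in 0.15 s) tests exactly this.

Two stabilizers damp non-physical high-frequency content. Element
strain-rate viscosity adds a viscous second Piola–Kirchhoff stress
η·Ė (Ė the Green-strain rate, η = `element_viscosity`·ρ·c·h per element,
default 0.1 of element-critical) — the explicit-dynamics bulk-viscosity
idea, objective because rigid rotation has zero strain rate; its
dissipation enters the ledger. It does not, and is not meant to, bound the
chaotic stress excursions of elements snatched against the rigid anchor
bands: those field maxima remain singular and should be read
qualitatively (see the limitations section).

Mass-proportional damping is set to `damping_ratio` (default 0.05) of
critical at an estimate of the structure's lowest mode — the first bending
mode of a cantilever plate with the sheet's thickness and longest span
(≈17 rad/s at defaults, giving α ≈ 1.7 s⁻¹). Using any dilatational
frequency here would overdamp gross motion.

Gravity acts on the head; by default it is not applied to the muscle
(`gravity_on_muscle=False`): the sheet weighs ≈0.2 N against ≈30–100 N
contact forces, but left switched on it would dominate the free motion of
a one-margin-anchored sheet over 0.15 s and swamp the diameter dependence
under study.

## Contact and friction

Node-to-analytic-sphere penalty contact: a node at distance d < R from the
center receives k(R−d) along the outward radial; the reaction on the head
is minus the nodal sum (its Z component drives the head's single DOF). The
penalty default auto-scales as max(10·E·h, m_head·g/(6 × 0.005 mm)) so
that worst-case support on a handful of nodes penetrates ≲0.005 mm; the
acceptance-level bound is 0.1 mm. Friction is Coulomb with μ = 0.03,
regularized by a linear viscous law below 1 mm/s sliding speed; the
viscous coefficient is additionally capped at 0.25·m_node/Δt per node so
the stick regime cannot destabilize the explicit scheme (the Coulomb bound
μ|f_n| always holds). Friction dissipation, penalty spring energy and
damping dissipation all enter the energy ledger.

## Energy ledger

Per run the ledger tracks kinetic energy (velocities live at half steps),
SVK strain energy and penalty spring energy (exact state functions),
gravity work (computed from positions, hence path-exact), and the
accumulated friction and damping dissipation. The audit quantity is
|W_ext − (K + U + U_contact + D_friction + D_damping)|, required to stay
within 5% of the peak external work at every sample; at the default
conditions it stays below 0.1%.

## Outputs and metrics

Snapshots are stored every 0.03 s of the 0.15 s run (six states) with
nodal displacement and per-element Cauchy stress and Green strain; a dense
monitor series (every `monitor_every` steps, default 100) tracks the field
peaks between snapshots, because the published occurrence times (e.g.
0.0825 s) fall between snapshot times. The per-diameter report takes peaks
and times from the monitors and end values from the final snapshot.
Displacement conventions follow the published definitions: maximum Z
displacement is the descent-positive nodal maximum over nodes and time;
the X span is max(u_X) − min(u_X) over nodes at one instant, maximized
over time; extension ratios divide these by the 40 mm height and 70 mm
length respectively, in percent. The ratio arithmetic reproduces five of
the six printed percentages exactly; the printed D80 Z ratio (128.90%)
contradicts its own printed inputs (50.358/40 = 125.90%) and is treated as
a typo — the package computes 125.90% and does not correct toward the
printed value.

## What the surrogate does and does not show

Passing tests demonstrate: correct constitutive and kinematic kernels
(against closed forms and finite-difference oracles), exact metric
arithmetic, contact that respects the Coulomb cone and the penetration
bound, a closing energy ledger, deterministic reruns, and the qualitative
trends — peak stress and strain grow with head diameter, and the sheet is
stretched beyond 100% of its height with lateral stretch of the same order
as the published ~1.8–2×. They do **not** validate subject-specific field
magnitudes, tissue anisotropy/viscoelasticity, tearing, head rotation, or
multi-organ support. Two qualitative targets are geometry-limited on this
surrogate: the thin sheet drapes around the head and goes taut late, so
the strain peak of the smallest head falls in the last tenth of the run
rather than mid-run, and for D80 the vertical ratio slightly exceeds the
lateral one — the subject geometry (a much bulkier, fully-margined bowl)
arrests the head mid-run, which a 6 mm two-band-anchored sheet cannot
reproduce. Likewise the *magnitude ordering* of the equivalent-stress
field maximum across diameters is not robust: that maximum lives in
elements snatched against the rigid anchors, a mesh-singular quantity
whose chaotic excursions (10²–10⁴ MPa) swamp the diameter effect, while
the principal-strain maximum orders reliably with diameter.

## Problem sizes and numerical defaults

Default study runs use the 3 mm mesh, full 0.15 s duration, CFL factor
0.8, monitor stride 100; a three-diameter sweep takes minutes on one CPU
core (≈80–160 k adaptive steps per run). The 2 mm mesh of the source
protocol is available through `simulation.mesh_edge` at proportionally
higher cost. Geometry, meshing and integration are deterministic for fixed
inputs; `rng_seed` is recorded in the manifest for provenance.
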