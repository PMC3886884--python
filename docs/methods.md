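# Methods

## Scope and model

The package simulates the elastic response of a plant epidermis
represented as a pressurized thin membrane (the *tissue pressure*
picture: stiff outer wall, inner tissues reduced to a uniform turgor
pressure p acting along the deformed outward normals).  The membrane is
a triangulated surface whose triangles are grouped into polygonal
cells; the element model is the triangular biquadratic spring (TRBS):
the element energy depends only on the resting and current edge
lengths, which determine the in-plane Green–Lagrange strain
E = (FᵀF − I)/2 of the affine rest→current map.  There is no bending
energy; curvature resistance emerges only from stretching of the
triangulated geometry.  Strains of interest are a few percent, where a
St. Venant–Kirchhoff law (quadratic energy in E) is appropriate.

### Anisotropic energy

The transversely isotropic plane-stress energy density is

    W(E) = λ_T/2 (tr E)² + μ_T tr(E²)
         + Δλ/2 (aᵀE a)(tr E) + Δμ (aᵀE² a),

with λ(E*, ν) = E*ν/(1−ν²), μ(E*, ν) = E*/(2(1+ν)) evaluated at the
transverse (E_T) and longitudinal (E_L) Young moduli, Δλ = λ_L − λ_T,
Δμ = μ_L − μ_T, and a the fiber axis projected into the element plane.
The anisotropic part is the fiber-direction share of the
equipartitioned isotropic invariants, re-weighted by the
longitudinal/transverse difference.  The binding property — verified in
the test suite — is small-strain consistency: a uniaxial patch test
recovers a stiffness of E_L along the fiber and E_T across it to within
1% at elasticity ratio 2 (the single shared Poisson ratio makes the law
only approximately orthotropic; at ratio 5 the deviation grows to a few
percent).  One Poisson ratio ν for both directions follows the original
model family; ν < 1 is required by plane stress.

Fibers are axial (sign-free) 3D unit vectors stored per cell; before
every energy/stress evaluation they are projected onto each triangle's
resting plane and renormalized.  Directional signals extracted from the
current configuration are likewise treated as axial vectors; mixing
rest-plane material axes with current-configuration signals is accurate
to the (small) element rotations at the strain levels simulated.

### Stress and strain evaluation

Per triangle the package evaluates the Green–Lagrange strain (resting
frame), its conjugate second Piola–Kirchhoff stress S = ∂W/∂E, the
Almansi strain e = (I − B⁻¹)/2 and the Cauchy stress σ = F S Fᵀ/J in
the current local frame.  Cauchy stress is reported
*thickness-integrated* (σ·t, units MPa·µm = force/length) so membrane
values are directly comparable across wall thicknesses.  Cell-level
tensors are area-weighted averages of triangle tensors rotated into the
cell's tangent frame (built from the cell's mean normal);
eigen-decomposition is applied after averaging.  Principal directions
of near-isotropic tensors (relative gap < 1e-3) are flagged degenerate
and excluded from direction statistics and updates.

### Loads, boundary conditions, equilibria

Follower pressure is conservative here: for clamped open surfaces and
closed surfaces the load is the gradient of p·V.  Open *stem* templates
are treated as capped tubes: the base rim is clamped and the free rim
is closed by a virtual flat cap whose volume term transmits the
pressure resultant p·πR² onto the rim — without it a doubly clamped
open tube carries only the Poisson-coupled longitudinal stress
(ratio ≈ 0.24 instead of the thin-wall 0.5).  Dome templates clamp
their rim; closed ellipsoids need no constraints.  Since clamping
distorts nearby fields, analyses exclude cells within two mean cell
diameters of boundary vertices.

Equilibria are stationary points of Π(x) = elastic energy − p·V − f·x.
The default solver minimizes Π directly (L-BFGS-B over free degrees of
freedom; the elastic gradient is the analytic nodal-force field, tested
against finite differences to 1e-5 relative).  Over-damped explicit
integrators (fixed-step RK4, adaptive RK45) of dx/dt = F/γ are provided
for following transients and are verified to reach the same equilibria;
they are impractically slow for production runs because the
pressurized-shell spectrum is stiff.  The default convergence threshold
is scale-aware: max residual force < 1e-6 × (pressure × mean cell
area).  Element inversion aborts with the offending triangle id;
non-convergence is reported, never silent.

### Fiber model and feedback dynamics

A tension-clamped anisotropy measure is computed per cell from the
cell-averaged tensor: relative form (s₁−s₂)/s₁ (compressive principal
values set to zero first), or absolute form (s₁−s₂)/s_max with s_max
the largest tensile principal value over interior cells — used where
stress magnitudes span a wide range (the dome templates), because a
relative measure overestimates anisotropy in low-stress regions.  In
the baseline model the *degree* of anisotropy is driven by the stress
anisotropy under both direction rules; a strain-driven variant
(`measure_source='strain'`) exists for the supplementary
orthogonal-strain experiments.

The response α(a) ∈ [0,1] maps the measure to target moduli
E_L = E_m + E_f(1+α)/2, E_T = E_m + E_f(1−α)/2 (conserving
E_L + E_T = 2E_m + E_f).  Two response forms are implemented:

* `hill` — α = aⁿ/(aⁿ+Kⁿ): gentle, half-saturation at K;
* `hill_odds` — the same Hill applied to the odds a/(1−a):
  α = aⁿ/(aⁿ + Kⁿ(1−a)ⁿ), which saturates exactly at a = 1 and is
  already near its maximum (α(0.5) = 0.86 at K = 0.4, n = 2) at
  anisotropy 0.5.

The steep form is what makes the dome zonation possible: with the
gentle form the induced elasticity ratio E_L/E_T(a) stays below the
parallel/perpendicular phase boundary for every a, so the perpendicular
(periphery) class never forms.  The stem recipes use the gentle form,
which reproduces the reported stem deformation range; the dome recipes
use the steep form with the absolute measure.  Both are plain
configuration switches.

Feedback is staggered and quasi-static: mechanics is fully relaxed,
cell tensors are evaluated, then one Euler step moves the moduli toward
their targets (rate k_mat) and rotates each fiber toward its signal
(rate k_dir, signal sign-flipped into the fiber's hemisphere, blended,
projected to the cell tangent plane, renormalized; isotropic-tensor
cells are skipped).  The loop stops when the largest per-iteration
fiber rotation < 0.2° and the largest relative modulus change < 2e-4.
Results are insensitive to the rates when they are small; the library
defaults are k_dir = 0.1, k_mat = 0.01, while the shipped recipes use
0.2 / 0.1, which converge in 50–250 outer iterations at the shipped
problem sizes.  Intermediate relaxations run at a 30× looser residual
threshold; the final reported state is relaxed at the tight one.

## Parameters and defaults

| quantity | default | notes |
| --- | --- | --- |
| turgor pressure p | 0.1 MPa (stem), 0.05 (paraboloid), 0.08 (meristem) | published values |
| wall thickness t | 1 µm | published |
| matrix modulus E_m | 50 MPa (stem, meristem), 40 (paraboloid) | published |
| fiber modulus E_f | 120 MPa (stem), 100 (paraboloid), 150 (meristem) | published |
| Poisson ratio ν | 0.2 | published |
| fiber response K, n | 0.4, 2 | published; form per recipe (above) |
| cell size | 10–20 µm | published range |
| cylinder R × L | 100 × 400 µm (recipes: L = 300, cells 20 µm) | geometry not published; R from stem scale, L desk-scaled |
| paraboloid R₀, height | 50, 90 µm | geometry not published; depth chosen so flank strains reach the reported few-percent range and the flank force anisotropy approaches its paraboloid limit 0.5 |
| meristem dome, primordium | R₀ 50 µm, height 90 µm; bump radius 20 µm at offset 55 µm along the base normal | two isotropic-curvature apices and a saddle valley, as required |
| ellipsoid study | R = 1, t = 0.01, E_m = 4, E_f = 8, p = 0.01 | printed parameter set is internally inconsistent (it implies strains ≫ 1); these conserve the printed saturated moduli 12/4 and give ~5% strains |

## What the synthetic templates do and do not capture

Templates are idealized surfaces with Voronoi cells from a jittered,
Lloyd-relaxed hexagonal lattice: cells are roughly isotropic, sizes
controlled, boundaries reproducible from a seed.  Real epidermis has
cell-wall two-layer structure, heterogeneous wall thickness, lobed cell
shapes, and topological change (division); none of that is modeled, and
elastic strain is only a *proxy* for growth — there is no plasticity or
yield.  Passing tests therefore validate the mechanics and the feedback
logic on clean geometries, not predictions for any particular imaged
meristem.

## Numerical choices

* Tessellation: jittered hex lattice (±0.15 spacing), one Lloyd step,
  Voronoi polygons clipped by mirror seeds (periodic seam for the
  cylinder, radial reflection for disks), rim vertices snapped onto the
  exact boundary circle; merged vertices keyed by rounded coordinates
  (1e-6 µm).
* Local frames: resting frame e₁ along the first triangle edge; current
  frame likewise.  All 2×2 tensor algebra is unrolled component-wise in
  the hot path.
* Eigen-decomposition by the closed 2×2 form; ties (degenerate tensors)
  keep the previous fiber direction.
* The phase-diagram feedback scans iterate the *direction* rule only
  (the elasticity-ratio axis prescribes the moduli) and seed the fiber
  5° off the load axis: the axis is a fixed point of both rules, and
  the offset probes its stability.
* Shape anisotropy uses the unweighted vertex covariance (exact for
  affinely stretched templates; an area-weighted moment underestimates
  elongation).
* Determinism: a single integer seed controls tessellation jitter;
  the solvers are deterministic.

## Known limitations

* No bending stiffness: compressive/buckling regimes (e.g. deep
  saddles) are outside the validity envelope; the solver reports
  element inversion rather than resolving wrinkles.
* The single-ν transversely isotropic St.V-K law is only approximately
  orthotropic at large elasticity ratios.
* With the gentle (`hill`) response the stem's maximal-strain direction
  ends marginally parallel to the stress (the induced anisotropy
  E_L/E_T ≈ 2 sits at the phase boundary); the steep response or a
  prealigned saturated material (E_L = E_m + E_f, E_T = E_m) yields the
  longitudinal strain direction expected for stems, and that is how the
  direction-distribution checks are posed.
* Stationarity of the feedback loop is declared by thresholds on
  per-iteration changes; oscillating states are reported as
  non-stationary with their history, not silently accepted.
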