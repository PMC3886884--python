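# morphospring

Mechanics of the growing plant epidermis on triangulated surfaces:
a **triangular biquadratic spring (TRBS)** membrane simulator for
anisotropic cell-wall material under tissue pressure, with dynamic
feedback of mechanical **stress** or **strain** on the orientation and
strength of cellulose-fiber anisotropy.

## Who this is for

Researchers in plant morphodynamics who want to ask: *given turgor
pressure, wall moduli and a tissue shape, where do stresses and strains
point, and can they orient the cellulose fibers that in turn set the
tissue's mechanical anisotropy?*  The package reproduces the classic
computational experiments of this field — stem (cylinder), naked
meristem (paraboloid) and meristem-with-primordium templates — and the
two competing feedback hypotheses:

* **MSD** — fibers align with the maximal principal stress direction;
* **OsD** — fibers align orthogonally to the maximal principal strain
  direction.

## The model

Each polygonal cell of a tissue template is fan-triangulated through
its centroid.  A triangle's elastic energy is a biquadratic function of
its resting and current edge lengths: the lengths determine the
in-plane Green–Lagrange strain **E** = (FᵀF − I)/2 of the affine map
between configurations, and the energy density is a transversely
isotropic St. Venant–Kirchhoff form under plane stress,

```
W(E) = λ_T/2 (tr E)² + μ_T tr(E²) + Δλ/2 (aᵀE a)(tr E) + Δμ (aᵀE² a)
```

with `a` the in-plane unit fiber axis, (λ_T, μ_T) the plane-stress Lamé
constants of the transverse modulus E_T, and Δλ, Δμ the longitudinal −
transverse differences (same Poisson ratio ν).  Small-strain uniaxial
stiffness is E_L along the fiber and E_T across it.  Turgor acts as a
follower pressure on the deformed surface; equilibria are found by
minimizing the total potential (or by damped RK4/RK45 dynamics), and
Almansi strain / thickness-integrated Cauchy stress are evaluated per
triangle and averaged per cell.

The **fiber model** converts a tension-clamped stress-anisotropy
measure a = (σ₁−σ₂)/σ₁ ∈ [0, 1] into moduli through a saturating
response α(a) with K = 0.4, n = 2, conserving the overall elasticity:

```
E_L = E_m + E_f (1+α)/2,    E_T = E_m + E_f (1−α)/2.
```

Fiber directions and moduli relax toward their targets with small
per-iteration rates between full mechanical relaxations.

## Worked example

Pressurize a stem template (radius 100 µm, wall thickness 1 µm,
turgor 0.1 MPa, E_m = 50 MPa, E_f = 120 MPa, ν = 0.2) under stress
feedback and look at the stationary fiber field:

```python
import numpy as np
from morphospring import run_recipe

out = run_recipe("cylinder-msd", "runs/stem", seed=1)
import pandas as pd
cells = pd.read_csv(out / "cells.tsv", sep="\t")
print(cells[["s1", "s2", "e1", "e2", "aniso_stress"]].describe().loc[["mean"]])
```

which prints (seed 1):

```
             s1        s2       e1        e2  aniso_stress
mean  10.028123  5.105409  0.05188  0.044811      0.490856
```

Mean maximal principal stress ≈ 10.0 MPa·µm (the thin-wall hoop value
p·R at the inflated radius), mean second principal ≈ 5.1 (the capped-
tube longitudinal value ≈ p·R/2), stress anisotropy ≈ 0.49 — and the
fiber field in `cells.tsv` is circumferential: stress feedback
spontaneously reproduces the circumferential cortical-microtubule
pattern seen in stems.  Running `cylinder-osd` instead flips the fibers
longitudinal — the orthogonal-strain rule is unstable on a stem — and
`paraboloid-msd` / `meristem-msd` produce the radial zonation of a
shoot apex: isotropic slow-expanding center, anisotropic radially
straining periphery, fibers circumferential around the apex.

The same experiments are available from the shell:

```
morphospring simulate cylinder-msd --out runs/stem --seed 1
morphospring phase-diagram --mode msd --out runs/phase
morphospring zonation --recipe paraboloid-msd --out runs/dome
morphospring recipes
```

## Layout

| module | contents |
| --- | --- |
| `morphospring.mesh` | `SurfaceMesh` container, curvature estimation |
| `morphospring.templates` | patch / cylinder / paraboloid / meristem / ellipsoid generators |
| `morphospring.mechanics` | strain measures, anisotropic St.V-K law, nodal forces |
| `morphospring.dynamics` | pressure + cap loads, relaxation solvers, feedback loop |
| `morphospring.feedback` | anisotropy measures, fiber model, update rules |
| `morphospring.analysis` | phase diagrams, distributions, zonation, shape anisotropy |
| `morphospring.io` | VTK-legacy / PLY / per-cell TSV |
| `morphospring.config`, `.recipes`, `.cli` | validated configs, canned experiments, CLI |

See `docs/methods.md` for the modeling choices, parameter defaults and
known limitations.
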