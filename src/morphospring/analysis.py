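"""Derived quantities and the canned computational experiments:
stress–strain angle maps, phase diagrams, direction distributions,
meristem zonation and the shape-anisotropy study.

All angle statistics treat eigenvectors and fibers as axial (sign-free)
directions, so angles live in [0°, 90°] and every result is invariant
to eigenvector sign flips.  Cells within a margin (default two cell
diameters) of clamped boundaries are excluded, because clamping
distorts nearby stresses.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dynamics import (
    FeedbackResult,
    LoadSpec,
    SolverConfig,
    run_feedback_simulation,
)
from .feedback import FeedbackConfig, anisotropy_relative
from .mechanics import TissueMaterial, principal_fields
from .mesh import SurfaceMesh
from .templates import make_ellipsoid, make_square_patch


# ----------------------------------------------------------------------
# stress / strain direction comparison
def stress_strain_angle(cell_stress, cell_strain, degeneracy_tol: float = 1e-3):
    """|cos| of the angle between maximal-stress and maximal-strain
    directions per cell, with a mask flagging degenerate (isotropic)
    tensors that carry no direction."""
    s1, s2, ds, deg_s = principal_fields(cell_stress, degeneracy_tol)
    e1, e2, de, deg_e = principal_fields(cell_strain, degeneracy_tol)
    cos = np.abs(np.einsum("ci,ci->c", ds, de))
    return cos, (deg_s | deg_e)


# ----------------------------------------------------------------------
# biaxial patch machinery (the quadrilateral patch experiments)
def patch_biaxial_loads(
    mesh: SurfaceMesh, traction_x: float, traction_y: float
) -> LoadSpec:
    """Dead boundary tractions (µN per µm of edge, i.e. thickness-
    integrated stress) pulling the four edges of a flat square patch
    outward; the patch is kept planar (z fixed) and rigid in-plane
    motions are pinned at the center.
    """
    side = mesh.info["side"]
    x = mesh.rest_vertices
    t = mesh.triangles
    edges = np.concatenate([t[:, [0, 1]], t[:, [1, 2]], t[:, [2, 0]]])
    und = np.sort(edges, axis=1)
    uniq, counts = np.unique(und, axis=0, return_counts=True)
    open_edges = uniq[counts == 1]
    f = np.zeros_like(x)
    tol = 1e-9 * side
    for a, b in open_edges:
        pa, pb = x[a], x[b]
        mid = 0.5 * (pa + pb)
        ln = np.linalg.norm(pb - pa)
        if abs(mid[0]) < tol:
            d = np.array([-traction_x, 0.0, 0.0])
        elif abs(mid[0] - side) < tol:
            d = np.array([traction_x, 0.0, 0.0])
        elif abs(mid[1]) < tol:
            d = np.array([0.0, -traction_y, 0.0])
        else:
            d = np.array([0.0, traction_y, 0.0])
        f[a] += 0.5 * ln * d
        f[b] += 0.5 * ln * d
    fixed = np.zeros((mesh.n_vertices, 3), dtype=bool)
    fixed[:, 2] = True  # planar problem
    center = int(np.argmin(np.linalg.norm(x[:, :2] - side / 2.0, axis=1)))
    fixed[center, :2] = True
    # pin rotation: fix y of a vertex to the right of center at (almost) the same y
    same_y = np.abs(x[:, 1] - x[center, 1]) < 0.26 * side / max(1, mesh.info["n_divisions"])
    cand = np.nonzero(same_y & (x[:, 0] > x[center, 0] + tol))[0]
    right = int(cand[np.argmax(x[cand, 0])])
    fixed[right, 1] = True
    return LoadSpec(pressure=0.0, vertex_forces=f, clamped=np.array([], dtype=int), fixed_dofs=fixed)


@dataclass
class PhasePoint:
    force_anisotropy: float
    elasticity_ratio: float
    cos_angle: float
    degenerate: bool


def phase_diagram(
    force_anisotropies=None,
    elasticity_ratios=None,
    mode: str = "static",
    nu: float = 0.2,
    E_T: float = 400.0,
    traction: float = 0.4,
    thickness: float = 0.01,
    n_divisions: int = 4,
    max_outer: int = 80,
    perturb_deg: float = 5.0,
    solver: SolverConfig | None = None,
) -> pd.DataFrame:
    """Map |cos(max-stress, max-strain)| over the (force anisotropy,
    elasticity ratio) plane on the biaxial square patch.

    ``mode``: 'static' evaluates the prescribed material once (fiber
    along the maximal load, x); 'msd'/'osd' iterate the corresponding
    direction feedback to stationarity at fixed moduli before
    evaluating.  Feedback runs seed the fiber ``perturb_deg`` off the
    load axis: the axis is a fixed point of both rules, and the offset
    probes its stability (a stable rule returns, an unstable one
    escapes).  Force anisotropy is (f_x − f_y)/f_x with f_x fixed at
    ``traction``.
    """
    if force_anisotropies is None:
        force_anisotropies = np.linspace(0.0, 1.0, 21)
    if elasticity_ratios is None:
        elasticity_ratios = np.linspace(1.0, 5.0, 21)
    if mode not in ("static", "msd", "osd"):
        raise ValueError(f"unknown phase-diagram mode {mode!r}")
    rows = []
    for ratio in elasticity_ratios:
        for fa in force_anisotropies:
            mesh = make_square_patch(1.0, n_divisions)
            loads = patch_biaxial_loads(mesh, traction, traction * (1.0 - fa))
            fb = None
            fib0 = [1.0, 0.0, 0.0]
            if mode in ("msd", "osd"):
                fb = FeedbackConfig(mode=mode, update_moduli=False, k_dir=0.3)
                th_p = np.radians(perturb_deg)
                fib0 = [np.cos(th_p), np.sin(th_p), 0.0]
            mat = TissueMaterial.uniform(
                mesh.n_cells, E_L=ratio * E_T, E_T=E_T, fiber=fib0,
                nu=nu, thickness=thickness,
            )
            res = run_feedback_simulation(
                mesh, mat, loads, fb, solver, max_outer=max_outer if fb else 1
            )
            cos, deg = stress_strain_angle(res.cell_stress, res.cell_strain)
            # patch state is homogeneous: the median cell represents it
            ok = ~deg
            cval = float(np.median(cos[ok])) if ok.any() else 1.0
            rows.append(
                {
                    "force_anisotropy": float(fa),
                    "elasticity_ratio": float(ratio),
                    "cos_angle": cval,
                    "degenerate": bool(~ok.any()),
                }
            )
    return pd.DataFrame(rows)


def fixed_point_response(
    fiber_angle_deg: float,
    E_T: float = 400.0,
    E_L: float = 800.0,
    nu: float = 0.2,
    traction_x: float = 0.8,
    traction_y: float = 0.2,
    thickness: float = 0.01,
    n_divisions: int = 4,
):
    """Signal angles of the two feedback rules on the anisotropic patch.

    The fiber is placed at ``fiber_angle_deg`` to the maximal load (x);
    returns (msd_angle, osd_angle): the angle to x of the maximal-stress
    direction and of the perpendicular-to-maximal-strain direction.
    A rule's 0° fixed point is stable iff its response angle stays
    below the imposed fiber angle.
    """
    th = np.radians(fiber_angle_deg)
    mesh = make_square_patch(1.0, n_divisions)
    loads = patch_biaxial_loads(mesh, traction_x, traction_y)
    mat = TissueMaterial.uniform(
        mesh.n_cells, E_L=E_L, E_T=E_T, fiber=[np.cos(th), np.sin(th), 0.0],
        nu=nu, thickness=thickness,
    )
    res = run_feedback_simulation(mesh, mat, loads, None)
    w = mesh.cell_areas()
    stress = np.einsum("c,cij->ij", w, res.cell_stress) / w.sum()
    strain = np.einsum("c,cij->ij", w, res.cell_strain) / w.sum()
    u, v, n = res.cell_frames
    # cell frames of a flat patch are identical; map principal dirs to 3D
    s1, s2, ds, _ = principal_fields(stress[None])
    e1_, e2_, de, _ = principal_fields(strain[None])
    d_stress = ds[0, 0] * u[0] + ds[0, 1] * v[0]
    d_strain = de[0, 0] * u[0] + de[0, 1] * v[0]
    d_osd = np.cross(n[0], d_strain)
    xax = np.array([1.0, 0.0, 0.0])

    def ang(d):
        return float(np.degrees(np.arccos(np.clip(abs(d @ xax) / np.linalg.norm(d), 0, 1))))

    return ang(d_stress), ang(d_osd)


# ----------------------------------------------------------------------
# cylinder direction distributions
def direction_distribution(
    mesh: SurfaceMesh, result: FeedbackResult, mat: TissueMaterial, margin: float = 2.0
) -> pd.DataFrame:
    """Angles (deg, in [0, 90]) of max-stress, max-strain and fiber
    directions to the circumferential direction, per interior cell."""
    axis = np.asarray(mesh.info.get("axis", [0.0, 0.0, 1.0]), dtype=float)
    cen = mesh.cell_centroids()
    radial = cen - np.outer(cen @ axis, axis)
    nr = np.linalg.norm(radial, axis=1, keepdims=True)
    radial = radial / np.where(nr == 0, 1.0, nr)
    circ = np.cross(axis, radial)
    u, v, n = result.cell_frames
    out = {}
    for name, tensors in (("stress", result.cell_stress), ("strain", result.cell_strain)):
        s1, s2, d, deg = principal_fields(tensors)
        d3 = d[:, 0, None] * u + d[:, 1, None] * v
        cos = np.abs(np.einsum("ci,ci->c", d3, circ))
        out[f"angle_{name}"] = np.degrees(np.arccos(np.clip(cos, 0, 1)))
        out[f"degenerate_{name}"] = deg
    cosf = np.abs(np.einsum("ci,ci->c", mat.fiber, circ))
    out["angle_fiber"] = np.degrees(np.arccos(np.clip(cosf, 0, 1)))
    out["area"] = mesh.cell_areas()
    df = pd.DataFrame(out)
    df["interior"] = False
    df.loc[mesh.interior_cells(margin), "interior"] = True
    return df


# ----------------------------------------------------------------------
# zonation on dome-like templates
def zonation_map(
    mesh: SurfaceMesh,
    result: FeedbackResult,
    mat: TissueMaterial,
    margin: float = 2.0,
    cos_threshold: float = 0.5,
) -> pd.DataFrame:
    """Per-cell zonation table for a relaxed dome template.

    Classes: 'parallel' where |cos(max stress, max strain)| ≥ threshold
    (apex / central zone and deep valleys), 'perpendicular' elsewhere
    (periphery).  Also reports the material anisotropy E_L/E_T and the
    relative area expansion (current/resting − 1).
    """
    cos, deg = stress_strain_angle(result.cell_stress, result.cell_strain)
    apex = np.asarray(mesh.info.get("apex", [0.0, 0.0, 0.0]), dtype=float)
    axis = np.asarray(mesh.info.get("axis", [0.0, 0.0, 1.0]), dtype=float)
    cen = mesh.cell_centroids(rest=True)
    rel = cen - apex
    r = np.linalg.norm(rel - np.outer(rel @ axis, axis), axis=1)
    df = pd.DataFrame(
        {
            "cell": np.arange(mesh.n_cells),
            "radius": r,
            "cos_angle": cos,
            "degenerate": deg,
            "elasticity_ratio": mat.E_L / mat.E_T,
            "area_expansion": mesh.cell_areas() / mesh.cell_areas(rest=True) - 1.0,
        }
    )
    df["zone"] = np.where(cos >= cos_threshold, "parallel", "perpendicular")
    df["interior"] = False
    df.loc[mesh.interior_cells(margin), "interior"] = True
    return df


def zonation_transition(df: pd.DataFrame, cell_diameter: float):
    """Radial sharpness of the parallel→perpendicular transition.

    Returns (r_mid, width): midpoint radius and the overlap width
    between the outermost parallel and innermost perpendicular interior
    cells (a clean zonation has width of order one cell diameter).
    """
    d = df[df.interior & ~df.degenerate]
    par = d[d.zone == "parallel"]
    per = d[d.zone == "perpendicular"]
    if len(par) == 0 or len(per) == 0:
        return np.nan, np.inf
    r_hi = float(par.radius.max())
    r_lo = float(per.radius.min())
    return 0.5 * (r_hi + r_lo), (r_hi - r_lo)


# ----------------------------------------------------------------------
# shape anisotropy (ellipsoid study)
def shape_anisotropy(mesh: SurfaceMesh, rest: bool = False) -> float:
    """Ratio (≥1) of largest to smallest principal axis of the surface,
    from the second-moment (covariance) tensor of the surface vertices.

    Vertices enter with equal weight: the vertex set of a stretched
    template is the affine image of the unstretched one, so the square
    roots of the covariance eigenvalues scale exactly like the semi-axes
    (an area-weighted moment would underestimate elongation, because
    stretching dilutes area near the poles).  1 for a sphere;
    translation- and rotation-invariant.
    """
    x = mesh.rest_vertices if rest else mesh.vertices
    d = x - x.mean(axis=0)
    cov = d.T @ d / len(d)
    ev = np.sort(np.linalg.eigvalsh(cov))
    return float(np.sqrt(ev[-1] / ev[0]))


def feedback_shape_comparison(
    aspect_ratios=(1.0, 1.5, 2.0),
    radius: float = 1.0,
    cell_size: float = 0.35,
    E_matrix: float = 4.0,
    E_fiber: float = 8.0,
    nu: float = 0.2,
    thickness: float = 0.01,
    pressure: float = 0.01,
    seed: int = 0,
    max_outer: int = 60,
    solver: SolverConfig | None = None,
) -> pd.DataFrame:
    """Pressurize ellipsoids of increasing elongation under the two
    feedback models and an isotropic material of the same overall
    elasticity (E = E_matrix + E_fiber/2, so 2E_m + E_f is conserved),
    and report deformed shape anisotropy and mean cell strain
    anisotropy, each normalized by the isotropic run."""
    rows = []
    E_iso = E_matrix + E_fiber / 2.0
    for ar in aspect_ratios:
        semi = (ar * radius, radius, radius)
        results = {}
        for label in ("isotropic", "msd", "osd"):
            mesh = make_ellipsoid(semi, cell_size, seed=seed)
            if label == "isotropic":
                mat = TissueMaterial.isotropic(mesh.n_cells, E_iso, nu, thickness)
                fb = None
            else:
                mat = TissueMaterial.isotropic(mesh.n_cells, E_iso, nu, thickness)
                fb = FeedbackConfig(
                    mode=label, E_matrix=E_matrix, E_fiber=E_fiber, k_dir=0.2, k_mat=0.1
                )
            loads = LoadSpec(pressure=pressure, clamped=np.array([], dtype=int))
            res = run_feedback_simulation(mesh, mat, loads, fb, solver, max_outer=max_outer)
            s1, s2, _, _ = principal_fields(res.cell_strain)
            results[label] = {
                "shape": shape_anisotropy(mesh),
                "strain_aniso": float(np.mean(anisotropy_relative(s1, s2))),
            }
        iso = results["isotropic"]
        for label in ("msd", "osd"):
            rows.append(
                {
                    "resting_anisotropy": float(ar),
                    "mode": label,
                    "shape_anisotropy": results[label]["shape"],
                    "shape_vs_isotropic": results[label]["shape"] / iso["shape"],
                    "strain_aniso_vs_isotropic": (
                        results[label]["strain_aniso"] / iso["strain_aniso"]
                        if iso["strain_aniso"] > 0
                        else np.nan
                    ),
                }
            )
    return pd.DataFrame(rows)
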