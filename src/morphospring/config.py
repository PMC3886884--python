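"""Configuration schema, experiment builders and canned recipes.

A simulation is described by a validated, fully serializable
configuration (YAML on disk).  Unknown keys are rejected with the
offending key path; every run writes the resolved configuration
(defaults included) next to its results, and a recipe plus a seed
reproduces byte-identical TSV outputs.

Units project-wide: lengths µm, moduli and pressure MPa, forces µN
(= MPa·µm²); thickness-integrated stresses MPa·µm.
"""

from __future__ import annotations

from typing import Literal, Optional, Sequence

import numpy as np
from pydantic import BaseModel, ConfigDict, ValidationError

from . import templates as _tpl
from .dynamics import (
    LoadSpec,
    SolverConfig,
    boundary_loops,
    run_feedback_simulation,
)
from .feedback import FeedbackConfig
from .mechanics import TissueMaterial
from .mesh import SurfaceMesh


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class TemplateSection(_Strict):
    kind: Literal["square_patch", "cylinder", "paraboloid", "meristem", "ellipsoid"] = "cylinder"
    cell_size: float = 15.0
    # square_patch
    side: float = 1.0
    n_divisions: int = 10
    # cylinder
    radius: float = 100.0
    length: float = 400.0
    # paraboloid / meristem
    apex_curvature_radius: float = 50.0
    height: float = 90.0
    dome_radius: float = 50.0
    primordium_radius: float = 20.0
    primordium_offset: float = 55.0
    meristem_height: float = 90.0
    # ellipsoid
    semi_axes: tuple[float, float, float] = (1.0, 1.0, 1.0)


class FeedbackSection(_Strict):
    mode: Literal["none", "msd", "osd"] = "none"
    measure: Literal["relative", "absolute"] = "relative"
    measure_source: Literal["stress", "strain"] = "stress"
    K: float = 0.4
    n: float = 2.0
    response: Literal["hill", "hill_odds"] = "hill"
    k_dir: float = 0.1
    k_mat: float = 0.01
    update_moduli: bool = True
    update_direction: bool = True
    boundary_margin: float = 2.0


class SolverSection(_Strict):
    method: Literal["minimize", "rk4_fixed", "rk45_adaptive"] = "minimize"
    damping: float = 1.0
    dt: float = 1e-3
    tol: Optional[float] = None
    rtol: float = 1e-6
    max_steps: int = 200000


class AxialLoadSection(_Strict):
    """Extra axial tension applied to a band of a cylindrical template:
    dead loads ±F/n on the vertex rings nearest the band edges."""

    force_total: float = 0.0  # µN, total tension across the band
    band: tuple[float, float] = (100.0, 200.0)  # z-range (µm)


class SimulationConfig(_Strict):
    template: TemplateSection = TemplateSection()
    pressure: float = 0.1
    thickness: float = 1.0
    E_matrix: float = 50.0
    E_fiber: float = 120.0
    nu: float = 0.2
    initial_fiber: Literal["circumferential", "longitudinal"] = "circumferential"
    feedback: FeedbackSection = FeedbackSection()
    solver: SolverSection = SolverSection()
    axial_load: Optional[AxialLoadSection] = None
    max_outer: int = 150
    angle_tol_deg: float = 0.2
    moduli_rtol: float = 2e-4
    seed: int = 0


def config_from_dict(d: dict) -> SimulationConfig:
    try:
        return SimulationConfig.model_validate(d)
    except ValidationError as err:
        paths = ", ".join(".".join(str(p) for p in e["loc"]) for e in err.errors())
        raise ValueError(f"invalid configuration key(s): {paths}") from err


# ----------------------------------------------------------------------
# builders
def build_mesh(cfg: SimulationConfig) -> SurfaceMesh:
    t = cfg.template
    if t.kind == "square_patch":
        return _tpl.make_square_patch(t.side, t.n_divisions)
    if t.kind == "cylinder":
        return _tpl.make_cylinder(t.radius, t.length, t.cell_size, cfg.seed)
    if t.kind == "paraboloid":
        return _tpl.make_paraboloid(t.apex_curvature_radius, t.height, t.cell_size, cfg.seed)
    if t.kind == "meristem":
        return _tpl.make_meristem(
            t.dome_radius, t.primordium_radius, t.primordium_offset,
            t.cell_size, cfg.seed, height=t.meristem_height,
        )
    return _tpl.make_ellipsoid(t.semi_axes, t.cell_size, cfg.seed)


def build_loads(mesh: SurfaceMesh, cfg: SimulationConfig) -> LoadSpec:
    """Boundary conditions by template kind: cylinders clamp the base rim
    and cap the free rim (a stem is a closed tube, mechanically); open
    domes clamp their rim; closed surfaces need no clamping."""
    kind = mesh.info.get("kind")
    vertex_forces = None
    if kind == "cylinder":
        loops = boundary_loops(mesh)
        zm = [mesh.rest_vertices[l, 2].mean() for l in loops]
        bot = loops[int(np.argmin(zm))]
        top = loops[int(np.argmax(zm))]
        if cfg.axial_load is not None and cfg.axial_load.force_total != 0:
            z = mesh.rest_vertices[:, 2]
            z1, z2 = cfg.axial_load.band
            vertex_forces = np.zeros_like(mesh.rest_vertices)
            for zb, sgn in ((z1, -1.0), (z2, 1.0)):
                ring = np.nonzero(np.abs(z - zb) < 0.5 * mesh.info["cell_size"])[0]
                if len(ring) == 0:
                    raise ValueError("axial-load band edge hits no vertex ring")
                vertex_forces[ring, 2] += sgn * cfg.axial_load.force_total / len(ring)
        return LoadSpec(
            pressure=cfg.pressure, clamped=bot, cap_loops=[top], vertex_forces=vertex_forces
        )
    return LoadSpec(pressure=cfg.pressure)  # clamped defaults to the boundary


def initial_fiber_field(mesh: SurfaceMesh, cfg: SimulationConfig) -> np.ndarray:
    """Tangent unit fibers: circumferential about the template axis (or
    longitudinal/meridional), with a deterministic fallback where the
    circumferential direction is undefined (on the axis)."""
    axis = np.asarray(mesh.info.get("axis", [0.0, 0.0, 1.0]), dtype=float)
    cen = mesh.cell_centroids(rest=True)
    radial = cen - np.outer(cen @ axis, axis)
    nr = np.linalg.norm(radial, axis=1)
    fallback = nr < 1e-9
    radial[fallback] = [1.0, 0.0, 0.0]
    radial /= np.linalg.norm(radial, axis=1, keepdims=True)
    circ = np.cross(axis, radial)
    if cfg.initial_fiber == "circumferential":
        f = circ
    else:
        n = mesh.cell_normals(rest=True)
        f = np.cross(circ, n)  # meridional/longitudinal, in the tangent plane
        f /= np.linalg.norm(f, axis=1, keepdims=True)
    return f


def build_material(mesh: SurfaceMesh, cfg: SimulationConfig) -> TissueMaterial:
    E0 = cfg.E_matrix + cfg.E_fiber / 2.0
    return TissueMaterial(
        E_L=np.full(mesh.n_cells, E0),
        E_T=np.full(mesh.n_cells, E0),
        fiber=initial_fiber_field(mesh, cfg),
        nu=cfg.nu,
        thickness=cfg.thickness,
    )


def build_feedback(cfg: SimulationConfig) -> FeedbackConfig | None:
    f = cfg.feedback
    if f.mode == "none":
        return None
    return FeedbackConfig(
        mode=f.mode,
        measure=f.measure,
        measure_source=f.measure_source,
        K=f.K,
        n=f.n,
        response=f.response,
        k_dir=f.k_dir,
        k_mat=f.k_mat,
        E_matrix=cfg.E_matrix,
        E_fiber=cfg.E_fiber,
        update_moduli=f.update_moduli,
        update_direction=f.update_direction,
        boundary_margin=f.boundary_margin,
    )


def build_solver(cfg: SimulationConfig) -> SolverConfig:
    s = cfg.solver
    return SolverConfig(
        method=s.method, damping=s.damping, dt=s.dt, tol=s.tol,
        rtol=s.rtol, max_steps=s.max_steps, seed=cfg.seed,
    )


def run_simulation(cfg: SimulationConfig):
    """Build everything from the configuration and run to stationarity.

    Returns (mesh, material, FeedbackResult)."""
    mesh = build_mesh(cfg)
    loads = build_loads(mesh, cfg)
    mat = build_material(mesh, cfg)
    fb = build_feedback(cfg)
    solver = build_solver(cfg)
    res = run_feedback_simulation(
        mesh, mat, loads, fb, solver,
        max_outer=cfg.max_outer,
        angle_tol_deg=cfg.angle_tol_deg,
        moduli_rtol=cfg.moduli_rtol,
        record=True,
    )
    return mesh, mat, res
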