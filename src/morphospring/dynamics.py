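"""Loads, boundary conditions and relaxation to elastic equilibrium.

Tissue pressure is a follower load: each triangle pushes p × (current
area) along its current outward normal, distributed equally to its
three vertices.  For clamped open surfaces and for closed surfaces this
load is conservative with potential −p·V, V the signed volume enclosed
against the clamped boundary, so equilibria are stationary points of

    Π(x) = elastic energy(x) − p·V(x) − f_dead·x.

The default solver minimizes Π directly (L-BFGS-B over the unclamped
degrees of freedom); overdamped explicit integrators (fixed-step RK4
and adaptive RK45) of dx/dt = F(x)/γ are provided as well and converge
to the same equilibria — they integrate the physical damped dynamics
and are useful for following the transient.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import RK45
from scipy.optimize import minimize

from .mechanics import (
    ElementInversionError,
    TissueMaterial,
    energy_and_forces,
    evaluate_mechanics,
)
from .mesh import SurfaceMesh


# ----------------------------------------------------------------------
@dataclass
class LoadSpec:
    """Pressure + optional dead loads + clamped vertex set.

    ``cap_loops`` lists ordered boundary loops (see
    :func:`boundary_loops`) to be closed by a virtual flat cap: the cap
    transmits the pressure's resultant (p × projected loop area, a
    follower load) onto the loop vertices, mimicking a closed tip — the
    stem templates are capped tubes, mechanically.
    """

    pressure: float = 0.0  # MPa, along current outward normals
    vertex_forces: np.ndarray | None = None  # (V,3) µN dead loads
    clamped: np.ndarray | None = None  # vertex ids; default: mesh boundary
    fixed_dofs: np.ndarray | None = None  # (V,3) bool mask, ANDed with clamped
    cap_loops: list | None = None  # each an ordered array of boundary vertex ids

    def __post_init__(self):
        if self.pressure < 0:
            raise ValueError("pressure must be >= 0")

    def dof_mask(self, mesh: SurfaceMesh) -> np.ndarray:
        """(V,3) boolean mask of *free* degrees of freedom."""
        free = np.ones((mesh.n_vertices, 3), dtype=bool)
        clamped = self.clamped if self.clamped is not None else mesh.boundary_vertices
        clamped = np.asarray(clamped, dtype=np.int64)
        if len(clamped) and (clamped.min() < 0 or clamped.max() >= mesh.n_vertices):
            raise ValueError("clamped ids outside the mesh vertex range")
        free[clamped] = False
        if self.fixed_dofs is not None:
            free &= ~np.asarray(self.fixed_dofs, dtype=bool)
        return free


@dataclass
class SolverConfig:
    method: str = "minimize"  # minimize | rk4_fixed | rk45_adaptive
    damping: float = 1.0  # γ: force -> velocity (µN per (µm/time))
    dt: float = 1e-3  # fixed step (rk4) or initial step (rk45)
    tol: float | None = None  # residual force threshold; None = scale-aware default
    rtol: float = 1e-6  # rk45 relative tolerance
    max_steps: int = 200000
    seed: int = 0

    def __post_init__(self):
        if self.damping <= 0 or self.dt <= 0:
            raise ValueError("damping and dt must be positive")
        if self.method not in ("minimize", "rk4_fixed", "rk45_adaptive"):
            raise ValueError(f"unknown solver method {self.method!r}")


@dataclass
class EquilibriumResult:
    positions: np.ndarray
    converged: bool
    n_steps: int
    residual: float
    residual_history: list = field(default_factory=list)


# ----------------------------------------------------------------------
def boundary_loops(mesh: SurfaceMesh) -> list[np.ndarray]:
    """Ordered open-boundary vertex loops, traversed in the direction the
    shell's triangles traverse them (surface to the left, so a cap fan
    closing the loop in the *reverse* direction restores a consistent
    outward orientation)."""
    t = mesh.triangles
    edges = np.concatenate([t[:, [0, 1]], t[:, [1, 2]], t[:, [2, 0]]])
    und = np.sort(edges, axis=1)
    uniq, inv, counts = np.unique(und, axis=0, return_inverse=True, return_counts=True)
    open_mask = counts[inv] == 1
    nxt = {int(a): int(b) for a, b in edges[open_mask]}
    loops = []
    seen = set()
    for start in list(nxt):
        if start in seen:
            continue
        loop = [start]
        seen.add(start)
        v = nxt[start]
        while v != start:
            loop.append(v)
            seen.add(v)
            v = nxt[v]
        loops.append(np.array(loop, dtype=np.int64))
    return loops


def _cap_volume_and_grad(x: np.ndarray, loop: np.ndarray):
    """Signed volume of the flat fan closing a boundary loop (traversed
    reversed, see :func:`boundary_loops`) and its gradient."""
    v = x[loop]
    c = v.mean(axis=0)
    nxt = np.roll(v, -1, axis=0)
    # cap triangles are (c, v_{k+1}, v_k): T_k = c . (v_{k+1} x v_k) / 6
    cross_kn = np.cross(nxt, v)
    vol = float(c @ cross_kn.sum(axis=0)) / 6.0
    grad = np.zeros_like(x)
    # d/dv_k of c.(v_{k+1} x v_k) = c x v_{k+1}; of c.(v_k x v_{k-1}) = v_{k-1} x c
    prev = np.roll(v, 1, axis=0)
    g = np.cross(c, nxt) + np.cross(prev, c)
    g += cross_kn.sum(axis=0) / len(loop)  # via the centroid
    np.add.at(grad, loop, g / 6.0)
    return vol, grad


def _shell_volume_gradient(x: np.ndarray, t: np.ndarray) -> np.ndarray:
    """∂/∂x of Σ x0·(x1×x2)/6.  Coincides with the 1/3-distributed
    follower load divided by p at every interior vertex; differs only on
    open-boundary vertices (where the closure terms live)."""
    g = np.zeros_like(x)
    np.add.at(g, t[:, 0], np.cross(x[t[:, 1]], x[t[:, 2]]) / 6.0)
    np.add.at(g, t[:, 1], np.cross(x[t[:, 2]], x[t[:, 0]]) / 6.0)
    np.add.at(g, t[:, 2], np.cross(x[t[:, 0]], x[t[:, 1]]) / 6.0)
    return g


def pressure_forces(
    mesh: SurfaceMesh, pressure: float, positions=None, cap_loops=None
) -> np.ndarray:
    """Follower pressure load.

    Without caps: p × current area × current normal per triangle, split
    equally (1/3) among the vertices.  With virtual caps the load is the
    exact gradient of p·(V_shell + V_caps), which reproduces the 1/3
    distribution at interior vertices and adds the cap closure forces on
    the free rim.
    """
    x = mesh.vertices if positions is None else positions
    t = mesh.triangles
    if cap_loops:
        g = _shell_volume_gradient(x, t)
        for loop in cap_loops:
            _, gc = _cap_volume_and_grad(x, loop)
            g += gc
        return pressure * g
    a, b, c = x[t[:, 0]], x[t[:, 1]], x[t[:, 2]]
    an = 0.5 * np.cross(b - a, c - a)  # area-weighted normal
    f = np.zeros_like(x)
    contrib = (pressure / 3.0) * an
    for k in range(3):
        np.add.at(f, t[:, k], contrib)
    return f


def enclosed_volume(mesh: SurfaceMesh, positions=None, cap_loops=None) -> float:
    """Signed volume Σ x0·(x1×x2)/6 (+ virtual cap fans); its gradient on
    free dofs equals the follower pressure load divided by p (exact for
    clamped boundaries and capped loops)."""
    x = mesh.vertices if positions is None else positions
    t = mesh.triangles
    vol = float(np.einsum("ij,ij->i", x[t[:, 0]], np.cross(x[t[:, 1]], x[t[:, 2]])).sum() / 6.0)
    if cap_loops:
        for loop in cap_loops:
            v, _ = _cap_volume_and_grad(x, loop)
            vol += v
    return vol


def total_forces(mesh: SurfaceMesh, mat: TissueMaterial, loads: LoadSpec, positions=None):
    _, f = energy_and_forces(mesh, mat, positions)
    if loads.pressure:
        f = f + pressure_forces(mesh, loads.pressure, positions, loads.cap_loops)
    if loads.vertex_forces is not None:
        f = f + loads.vertex_forces
    return f


def _default_tol(mesh: SurfaceMesh, mat: TissueMaterial, loads: LoadSpec) -> float:
    """Scale-aware residual threshold: 1e-6 × (load scale × mean cell area)."""
    area = float(mesh.cell_areas(rest=True).mean())
    scale = loads.pressure * area
    if loads.vertex_forces is not None:
        scale = max(scale, float(np.abs(loads.vertex_forces).max()))
    if scale == 0.0:  # unloaded: fall back to an elastic force scale
        scale = float(mat.E_T.mean()) * mat.thickness * np.sqrt(area) * 1e-3
    return 1e-6 * scale


def relax_to_equilibrium(
    mesh: SurfaceMesh,
    mat: TissueMaterial,
    loads: LoadSpec,
    solver: SolverConfig | None = None,
    update_mesh: bool = True,
) -> EquilibriumResult:
    """Drive the mesh to elastic equilibrium under the given loads.

    Clamped vertices stay at their current positions.  Returns the final
    positions and convergence diagnostics; on success (and by default)
    the mesh's current vertices are updated in place.
    """
    solver = solver or SolverConfig()
    free = loads.dof_mask(mesh)
    if not free.any():
        raise ValueError("no free degrees of freedom")
    tol = solver.tol if solver.tol is not None else _default_tol(mesh, mat, loads)

    x0 = mesh.vertices.copy()

    def residual(x):
        f = total_forces(mesh, mat, loads, x)
        return float(np.abs(f[free]).max())

    if solver.method == "minimize":
        res = _relax_minimize(mesh, mat, loads, free, x0, tol, solver)
    elif solver.method == "rk4_fixed":
        res = _relax_rk4(mesh, mat, loads, free, x0, tol, solver)
    else:
        res = _relax_rk45(mesh, mat, loads, free, x0, tol, solver)

    res.residual = residual(res.positions)
    res.converged = res.residual <= tol
    if update_mesh:
        mesh.vertices = res.positions.copy()
    return res


def _relax_minimize(mesh, mat, loads, free, x0, tol, solver) -> EquilibriumResult:
    idx = np.nonzero(free.ravel())[0]
    base = x0.ravel().copy()
    hist = []

    def fun(q):
        x = base.copy()
        x[idx] = q
        x = x.reshape(-1, 3)
        energy, forces = energy_and_forces(mesh, mat, x)
        grad = -forces
        if loads.pressure:
            energy -= loads.pressure * enclosed_volume(mesh, x, loads.cap_loops)
            grad -= pressure_forces(mesh, loads.pressure, x, loads.cap_loops)
        if loads.vertex_forces is not None:
            energy -= float(np.einsum("ij,ij->", loads.vertex_forces, x))
            grad -= loads.vertex_forces
        hist.append(float(np.abs(grad.ravel()[idx]).max()))
        return energy, grad.ravel()[idx]

    out = minimize(
        fun,
        base[idx],
        jac=True,
        method="L-BFGS-B",
        options={"maxiter": solver.max_steps, "gtol": tol, "ftol": 1e-16, "maxcor": 20},
    )
    x = base.copy()
    x[idx] = out.x
    return EquilibriumResult(
        positions=x.reshape(-1, 3),
        converged=False,  # set by caller from the residual
        n_steps=int(out.nit),
        residual=np.nan,
        residual_history=hist[:: max(1, len(hist) // 200)],
    )


def _relax_rk4(mesh, mat, loads, free, x0, tol, solver) -> EquilibriumResult:
    x = x0.copy()
    gamma = solver.damping
    dt = solver.dt
    hist = []

    def vel(x):
        f = total_forces(mesh, mat, loads, x) / gamma
        f[~free] = 0.0
        return f

    n = 0
    res = np.inf
    check = max(1, int(round(1.0 / dt / 100))) if dt < 1 else 1
    while n < solver.max_steps:
        k1 = vel(x)
        k2 = vel(x + 0.5 * dt * k1)
        k3 = vel(x + 0.5 * dt * k2)
        k4 = vel(x + dt * k3)
        x = x + (dt / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
        n += 1
        if n % check == 0 or n == solver.max_steps:
            res = float(np.abs((total_forces(mesh, mat, loads, x))[free]).max())
            hist.append(res)
            if res <= tol:
                break
    return EquilibriumResult(x, res <= tol, n, res, hist)


def _relax_rk45(mesh, mat, loads, free, x0, tol, solver) -> EquilibriumResult:
    gamma = solver.damping
    shape = x0.shape
    hist = []

    def rhs(_t, q):
        x = q.reshape(shape)
        f = total_forces(mesh, mat, loads, x) / gamma
        f[~free] = 0.0
        return f.ravel()

    # force scale -> velocity scale for the absolute tolerance
    f0 = float(np.abs(total_forces(mesh, mat, loads, x0)[free]).max())
    atol = max(f0, 1e-12) / gamma * 1e-8
    stepper = RK45(
        rhs, 0.0, x0.ravel(), t_bound=np.inf, rtol=solver.rtol, atol=atol, first_step=solver.dt
    )
    n = 0
    res = np.inf
    while n < solver.max_steps:
        stepper.step()
        n += 1
        if n % 20 == 0:
            x = stepper.y.reshape(shape)
            res = float(np.abs(total_forces(mesh, mat, loads, x)[free]).max())
            hist.append(res)
            if res <= tol:
                break
        if stepper.status != "running":
            break
    x = stepper.y.reshape(shape)
    res = float(np.abs(total_forces(mesh, mat, loads, x)[free]).max())
    return EquilibriumResult(x, res <= tol, n, res, hist)


# ----------------------------------------------------------------------
# staggered feedback simulation
@dataclass
class FeedbackResult:
    converged: bool
    n_outer: int
    mesh: SurfaceMesh
    material: TissueMaterial
    cell_stress: np.ndarray  # (C,2,2) cell-averaged Cauchy (thickness-integrated)
    cell_strain: np.ndarray  # (C,2,2) cell-averaged Almansi
    cell_frames: tuple  # (u, v, n) arrays (C,3)
    history: list = field(default_factory=list)


def cell_tensor_fields(mesh: SurfaceMesh, mat: TissueMaterial):
    """Cell-averaged Cauchy stress and Almansi strain at the current
    configuration, in each cell's tangent frame."""
    from .feedback import cell_average_tensor

    st = evaluate_mechanics(mesh, mat)
    stress, frames = cell_average_tensor(mesh, st.cauchy, st.cur_e1, st.cur_e2)
    strain, _ = cell_average_tensor(mesh, st.almansi, st.cur_e1, st.cur_e2)
    return stress, strain, frames


def run_feedback_simulation(
    mesh: SurfaceMesh,
    mat: TissueMaterial,
    loads: LoadSpec,
    feedback=None,
    solver: SolverConfig | None = None,
    max_outer: int = 200,
    angle_tol_deg: float = 0.2,
    moduli_rtol: float = 2e-4,
    loose_factor: float = 30.0,
    record: bool = False,
) -> FeedbackResult:
    """Alternate mechanical relaxation with material-state updates.

    Mechanics is fully relaxed between updates (quasi-static limit);
    each outer iteration then applies one Euler step of the fiber
    direction (rate ``k_dir``) and, if enabled, of the moduli (rate
    ``k_mat``).  The loop stops when both the largest fiber rotation
    per iteration falls below ``angle_tol_deg`` and the largest relative
    modulus change falls below ``moduli_rtol`` (or immediately after
    mechanical relaxation if ``feedback`` is None).  Mesh and material
    are updated in place.
    """
    from .feedback import (
        anisotropy_absolute,
        anisotropy_relative,
        axial_angle,
        cell_average_tensor,
        fiber_targets,
        update_direction,
        update_moduli,
    )
    from .mechanics import principal_fields

    solver = solver or SolverConfig()
    history = []
    if feedback is None:
        relax_to_equilibrium(mesh, mat, loads, solver)
        stress, strain, frames = cell_tensor_fields(mesh, mat)
        return FeedbackResult(True, 0, mesh, mat, stress, strain, frames, history)

    # intermediate relaxations may be looser: only the final state is reported
    loop_solver = SolverConfig(**dict(solver.__dict__))
    loop_solver.tol = (
        solver.tol if solver.tol is not None else _default_tol(mesh, mat, loads)
    ) * loose_factor

    interior = mesh.interior_cells(feedback.boundary_margin)
    converged = False
    n_outer = 0
    stress = strain = None
    frames = None
    for n_outer in range(1, max_outer + 1):
        relax_to_equilibrium(mesh, mat, loads, loop_solver)
        stress, strain, frames = cell_tensor_fields(mesh, mat)
        u, v, n = frames
        # the fiber model (moduli) is driven by measure_source (stress in
        # the baseline model); the direction rule is set by the mode
        m_tensors = stress if feedback.measure_source == "stress" else strain
        ms1, ms2, _, _ = principal_fields(m_tensors, feedback.degeneracy_tol)
        if feedback.measure == "relative":
            a = anisotropy_relative(ms1, ms2)
        else:
            s_max = float(np.maximum(ms1[interior], 0.0).max()) if len(interior) else 0.0
            a = anisotropy_absolute(ms1, ms2, s_max)
        d_tensors = stress if feedback.mode == "msd" else strain
        s1, s2, d1, degenerate = principal_fields(d_tensors, feedback.degeneracy_tol)

        old_EL, old_ET = mat.E_L.copy(), mat.E_T.copy()
        if feedback.update_moduli:
            EL_t, ET_t = fiber_targets(
                a, feedback.E_matrix, feedback.E_fiber, feedback.K, feedback.n,
                form=feedback.response,
            )
            mat.E_L = update_moduli(mat.E_L, EL_t, feedback.k_mat)
            mat.E_T = update_moduli(mat.E_T, ET_t, feedback.k_mat)

        # 3D signal direction in the cell tangent plane
        d3 = d1[:, 0, None] * u + d1[:, 1, None] * v
        if feedback.mode == "osd":
            d3 = np.cross(n, d3)  # in-plane perpendicular of max-strain dir
        old_fiber = mat.fiber.copy()
        if feedback.update_direction:
            new_fiber = update_direction(mat.fiber, d3, feedback.k_dir, tangent_normal=n)
            new_fiber[degenerate] = mat.fiber[degenerate]
            mat.fiber = new_fiber

        dang = np.degrees(np.atleast_1d(axial_angle(old_fiber, mat.fiber))).max()
        dmod = max(
            float(np.abs(mat.E_L - old_EL).max() / np.abs(old_EL).max()),
            float(np.abs(mat.E_T - old_ET).max() / np.abs(old_ET).max()),
        )
        if record:
            history.append(
                {"iter": n_outer, "dangle_deg": float(dang), "dmod": dmod,
                 "mean_a": float(np.mean(a[interior]) if len(interior) else np.mean(a))}
            )
        if dang < angle_tol_deg and dmod < moduli_rtol:
            converged = True
            break

    # final state after the last update
    relax_to_equilibrium(mesh, mat, loads, solver)
    stress, strain, frames = cell_tensor_fields(mesh, mat)
    return FeedbackResult(converged, n_outer, mesh, mat, stress, strain, frames, history)
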