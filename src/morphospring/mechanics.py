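"""Triangular-biquadratic-spring mechanics core.

Each triangle is a membrane element whose elastic energy is a
biquadratic function of its resting and current edge lengths: the
in-plane Green–Lagrange strain E = (FᵀF − I)/2 of the affine map
between the two configurations is determined by the six lengths alone,
and the strain energy density is a transversely isotropic St. Venant–
Kirchhoff form under plane stress,

    W(E) = λ_T/2 (tr E)² + μ_T tr(E²)
         + Δλ/2 (aᵀE a)(tr E) + Δμ (aᵀE² a),

where a is the in-plane unit fiber direction, (λ_T, μ_T) are the
plane-stress Lamé constants of the transverse Young modulus E_T, and
Δλ = λ_L − λ_T, Δμ = μ_L − μ_T with (λ_L, μ_L) built from the
longitudinal modulus E_L and the same Poisson ratio.  The anisotropic
part is the fiber-direction share of the equipartitioned isotropic
invariants, re-weighted by the longitudinal/transverse difference; it
vanishes when E_L = E_T and recovers a small-strain uniaxial stiffness
of E_L along the fiber and E_T across it.

Units: lengths µm, moduli MPa; energies are MPa·µm³ = pN·µm·10⁻⁶ …
consistently, forces come out in MPa·µm² = µN.  Reported Cauchy
stresses are integrated over the wall thickness (units MPa·µm, i.e.
force per unit length of wall cross-section).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np

from .mesh import SurfaceMesh


class ElementInversionError(RuntimeError):
    """A triangle collapsed or inverted during simulation."""

    def __init__(self, triangle: int):
        super().__init__(f"degenerate/inverted current triangle {triangle}")
        self.triangle = triangle


# ----------------------------------------------------------------------
# material parameters
class LameConstants(NamedTuple):
    lam: float
    mu: float


def lame_plane_stress(E, nu):
    """Plane-stress Lamé constants λ = Eν/(1−ν²), μ = E/(2(1+ν))."""
    E = np.asarray(E, dtype=float)
    nu = np.asarray(nu, dtype=float)
    if np.any(E <= 0):
        raise ValueError("Young modulus must be positive")
    if np.any(nu < 0) or np.any(nu >= 1):
        raise ValueError("plane-stress Poisson ratio must lie in [0, 1)")
    lam = E * nu / (1.0 - nu**2)
    mu = E / (2.0 * (1.0 + nu))
    if lam.ndim == 0:
        return LameConstants(float(lam), float(mu))
    return LameConstants(lam, mu)


@dataclass
class MaterialState:
    """Mechanical state of one cell's wall material."""

    E_T: float
    E_L: float
    nu: float
    fiber: np.ndarray  # unit axial 3D vector (sign-free)
    thickness: float = 1.0

    def __post_init__(self):
        self.fiber = np.asarray(self.fiber, dtype=float)
        n = np.linalg.norm(self.fiber)
        if n == 0:
            raise ValueError("fiber vector must be nonzero")
        self.fiber = self.fiber / n
        if not (self.E_L >= self.E_T > 0):
            raise ValueError("moduli must satisfy E_L >= E_T > 0")
        if not (0 <= self.nu < 1):
            raise ValueError("Poisson ratio must lie in [0, 1)")
        if self.thickness <= 0:
            raise ValueError("thickness must be positive")


@dataclass
class TissueMaterial:
    """Per-cell material arrays for a whole mesh.

    fiber directions are axial (v and -v equivalent) 3D unit vectors.
    """

    E_L: np.ndarray  # (C,)
    E_T: np.ndarray  # (C,)
    fiber: np.ndarray  # (C, 3)
    nu: float = 0.2
    thickness: float = 1.0

    def __post_init__(self):
        self.E_L = np.atleast_1d(np.asarray(self.E_L, dtype=float)).copy()
        self.E_T = np.atleast_1d(np.asarray(self.E_T, dtype=float)).copy()
        self.fiber = np.asarray(self.fiber, dtype=float).copy()
        self.fiber /= np.linalg.norm(self.fiber, axis=1, keepdims=True)
        if np.any(self.E_T <= 0) or np.any(self.E_L < self.E_T - 1e-9):
            raise ValueError("moduli must satisfy E_L >= E_T > 0 per cell")

    @classmethod
    def isotropic(cls, n_cells: int, E: float, nu: float = 0.2, thickness: float = 1.0):
        fiber = np.tile([1.0, 0.0, 0.0], (n_cells, 1))
        return cls(
            E_L=np.full(n_cells, float(E)),
            E_T=np.full(n_cells, float(E)),
            fiber=fiber,
            nu=nu,
            thickness=thickness,
        )

    @classmethod
    def uniform(cls, n_cells, E_L, E_T, fiber, nu=0.2, thickness=1.0):
        f = np.asarray(fiber, dtype=float)
        if f.ndim == 1:
            f = np.tile(f, (n_cells, 1))
        return cls(
            E_L=np.full(n_cells, float(E_L)),
            E_T=np.full(n_cells, float(E_T)),
            fiber=f,
            nu=nu,
            thickness=thickness,
        )

    def state(self, cell: int) -> MaterialState:
        return MaterialState(
            E_T=float(self.E_T[cell]),
            E_L=float(self.E_L[cell]),
            nu=self.nu,
            fiber=self.fiber[cell].copy(),
            thickness=self.thickness,
        )

    def copy(self) -> "TissueMaterial":
        return TissueMaterial(
            E_L=self.E_L, E_T=self.E_T, fiber=self.fiber, nu=self.nu, thickness=self.thickness
        )


# ----------------------------------------------------------------------
# single-triangle operations (reference / oracle path)
def _embed_triangle(lengths):
    """2D coordinates (P0=(0,0), P1=(l01,0), P2) of a triangle given its
    edge lengths (l01, l12, l20)."""
    l01, l12, l20 = (float(v) for v in lengths)
    for a, b, c in ((l01, l12, l20), (l12, l20, l01), (l20, l01, l12)):
        if a + b <= c:
            raise ValueError("edge lengths violate the strict triangle inequality")
    x2 = (l01**2 + l20**2 - l12**2) / (2.0 * l01)
    y2sq = l20**2 - x2**2
    if y2sq <= 0:
        raise ValueError("degenerate (zero-area) triangle")
    return np.array([[0.0, 0.0], [l01, 0.0], [x2, np.sqrt(y2sq)]])


def deformation_gradient_from_edges(rest_lengths, cur_lengths) -> np.ndarray:
    """In-plane 2x2 deformation gradient of the affine map between the
    canonical embeddings of the resting and current triangles."""
    P = _embed_triangle(rest_lengths)
    Q = _embed_triangle(cur_lengths)
    dP = np.column_stack([P[1] - P[0], P[2] - P[0]])
    dQ = np.column_stack([Q[1] - Q[0], Q[2] - Q[0]])
    return dQ @ np.linalg.inv(dP)


def green_lagrange_from_edges(rest_lengths, cur_lengths) -> np.ndarray:
    """Green–Lagrange strain E = (FᵀF − I)/2 in the resting local frame.

    Depends on the six edge lengths only, hence is invariant under rigid
    motions of either configuration.
    """
    F = deformation_gradient_from_edges(rest_lengths, cur_lengths)
    return 0.5 * (F.T @ F - np.eye(2))


def almansi_from_edges(rest_lengths, cur_lengths) -> np.ndarray:
    """Almansi strain e = (I − (FFᵀ)⁻¹)/2 in the current local frame."""
    F = deformation_gradient_from_edges(rest_lengths, cur_lengths)
    B = F @ F.T
    return 0.5 * (np.eye(2) - np.linalg.inv(B))


def _inplane_fiber(fiber3, e1, e2):
    a = np.array([fiber3 @ e1, fiber3 @ e2])
    n = np.linalg.norm(a)
    if n < 1e-8:
        return np.array([1.0, 0.0])  # fiber normal to the element: direction moot
    return a / n


def strain_energy_density(E: np.ndarray, m: MaterialState, fiber2=None) -> float:
    """Transversely isotropic St.V-K energy density (MPa) for one tensor.

    ``fiber2`` is the in-plane unit fiber vector in the frame of ``E``;
    by default the first two components of ``m.fiber`` are projected
    (appropriate when E is expressed in a frame whose plane contains
    the fiber).
    """
    lamT, muT = lame_plane_stress(m.E_T, m.nu)
    lamL, muL = lame_plane_stress(m.E_L, m.nu)
    dlam, dmu = lamL - lamT, muL - muT
    if fiber2 is None:
        a = np.asarray(m.fiber[:2], dtype=float)
        n = np.linalg.norm(a)
        a = np.array([1.0, 0.0]) if n < 1e-8 else a / n
    else:
        a = np.asarray(fiber2, dtype=float)
        a = a / np.linalg.norm(a)
    tr = np.trace(E)
    E2 = E @ E
    W = 0.5 * lamT * tr**2 + muT * np.trace(E2)
    W += 0.5 * dlam * (a @ E @ a) * tr + dmu * (a @ E2 @ a)
    return float(W)


def second_piola_kirchhoff(E: np.ndarray, m: MaterialState, fiber2=None) -> np.ndarray:
    """S = ∂W/∂E for the energy of :func:`strain_energy_density`."""
    lamT, muT = lame_plane_stress(m.E_T, m.nu)
    lamL, muL = lame_plane_stress(m.E_L, m.nu)
    dlam, dmu = lamL - lamT, muL - muT
    if fiber2 is None:
        a = np.asarray(m.fiber[:2], dtype=float)
        n = np.linalg.norm(a)
        a = np.array([1.0, 0.0]) if n < 1e-8 else a / n
    else:
        a = np.asarray(fiber2, dtype=float)
        a = a / np.linalg.norm(a)
    I2 = np.eye(2)
    A = np.outer(a, a)
    tr = np.trace(E)
    S = lamT * tr * I2 + 2.0 * muT * E
    S += 0.5 * dlam * ((a @ E @ a) * I2 + tr * A)
    S += dmu * (E @ A + A @ E)
    return S


def cauchy_stress(rest_lengths, cur_lengths, m: MaterialState, fiber2=None) -> np.ndarray:
    """Thickness-integrated Cauchy stress σ·t = (t/J)·F S Fᵀ (MPa·µm) in
    the current local frame of the triangle."""
    F = deformation_gradient_from_edges(rest_lengths, cur_lengths)
    E = 0.5 * (F.T @ F - np.eye(2))
    S = second_piola_kirchhoff(E, m, fiber2=fiber2)
    J = np.linalg.det(F)
    return (m.thickness / J) * F @ S @ F.T


def principal_decomposition(T: np.ndarray, degeneracy_tol: float = 1e-3):
    """Eigen-decomposition of a symmetric 2x2 tensor.

    Returns (s1, s2, dir1, dir2, degenerate) with s1 >= s2 and unit
    orthogonal axial eigenvectors; ``degenerate`` flags a tensor whose
    anisotropy is below ``degeneracy_tol`` (direction then meaningless).
    """
    a, b, c = T[0, 0], T[0, 1], T[1, 1]
    mval = 0.5 * (a + c)
    r = np.sqrt((0.5 * (a - c)) ** 2 + b**2)
    s1, s2 = mval + r, mval - r
    theta = 0.5 * np.arctan2(2.0 * b, a - c)
    d1 = np.array([np.cos(theta), np.sin(theta)])
    d2 = np.array([-d1[1], d1[0]])
    scale = max(abs(s1), abs(s2), np.finfo(float).eps)
    degenerate = (s1 - s2) / scale < degeneracy_tol
    return float(s1), float(s2), d1, d2, bool(degenerate)


def mises_equivalent_strain(e: np.ndarray) -> float:
    """2D von Mises equivalent strain sqrt(e1² − e1·e2 + e2²)."""
    s1, s2, *_ = principal_decomposition(np.asarray(e, dtype=float))
    return float(np.sqrt(s1 * s1 - s1 * s2 + s2 * s2))


# ----------------------------------------------------------------------
# batched mesh evaluation
class MechanicsState(NamedTuple):
    """All per-triangle mechanics fields at one configuration.

    Tensors are 2x2: ``green`` in the resting local frame (mesh
    ``rest_kinematics`` axes), ``cauchy`` (thickness-integrated) and
    ``almansi`` in the current local frame (axes ``cur_e1``/``cur_e2``).
    """

    energy: float  # total elastic energy (MPa µm^3)
    W: np.ndarray  # (T,) energy density
    green: np.ndarray  # (T,2,2)
    spk: np.ndarray  # (T,2,2) second Piola-Kirchhoff
    cauchy: np.ndarray  # (T,2,2) thickness-integrated
    almansi: np.ndarray  # (T,2,2)
    forces: np.ndarray  # (V,3) elastic nodal forces
    area_ratio: np.ndarray  # (T,)
    cur_e1: np.ndarray  # (T,3)
    cur_e2: np.ndarray  # (T,3)


def _material_per_triangle(mesh: SurfaceMesh, mat: TissueMaterial):
    cid = mesh.cell_of_triangle
    lamT, muT = lame_plane_stress(mat.E_T[cid], mat.nu)
    lamL, muL = lame_plane_stress(mat.E_L[cid], mat.nu)
    return lamT, muT, lamL - lamT, muL - muT, mat.fiber[cid]


def _core(mesh: SurfaceMesh, mat: TissueMaterial, x: np.ndarray):
    """Shared per-triangle kinematics + constitutive evaluation.

    Returns the pieces needed by both the lean force path and the full
    field evaluation.  All 2x2 algebra is unrolled component-wise (this
    is the innermost loop of every simulation).
    """
    t = mesh.triangles
    rk = mesh.rest_kinematics()
    lamT, muT, dlam, dmu, fib3 = _material_per_triangle(mesh, mat)
    th = mat.thickness
    m00 = rk.dm_inv[:, 0, 0]
    m01 = rk.dm_inv[:, 0, 1]
    m10 = rk.dm_inv[:, 1, 0]
    m11 = rk.dm_inv[:, 1, 1]

    d1 = x[t[:, 1]] - x[t[:, 0]]
    d2 = x[t[:, 2]] - x[t[:, 0]]
    # deformation gradient rest-local (2) -> world (3), by columns
    F1 = d1 * m00[:, None] + d2 * m10[:, None]
    F2c = d1 * m01[:, None] + d2 * m11[:, None]
    C00 = (F1 * F1).sum(1)
    C01 = (F1 * F2c).sum(1)
    C11 = (F2c * F2c).sum(1)
    E00 = 0.5 * (C00 - 1.0)
    E01 = 0.5 * C01
    E11 = 0.5 * (C11 - 1.0)

    # in-plane fiber in the resting frame
    a1 = (fib3 * rk.e1).sum(1)
    a2 = (fib3 * rk.e2).sum(1)
    an = np.sqrt(a1 * a1 + a2 * a2)
    small = an < 1e-8
    safe = np.where(small, 1.0, an)
    a1 = np.where(small, 1.0, a1 / safe)
    a2 = np.where(small, 0.0, a2 / safe)

    trE = E00 + E11
    E2_00 = E00 * E00 + E01 * E01
    E2_01 = E01 * (E00 + E11)
    E2_11 = E11 * E11 + E01 * E01
    aEa = a1 * a1 * E00 + 2.0 * a1 * a2 * E01 + a2 * a2 * E11
    aE2a = a1 * a1 * E2_00 + 2.0 * a1 * a2 * E2_01 + a2 * a2 * E2_11
    W = 0.5 * lamT * trE**2 + muT * (E2_00 + E2_11) + 0.5 * dlam * aEa * trE + dmu * aE2a
    energy = float(np.sum(W * rk.area * th))

    # S = dW/dE, unrolled
    A00, A01, A11 = a1 * a1, a1 * a2, a2 * a2
    M00 = E00 * A00 + E01 * A01  # M = E @ A
    M01 = E00 * A01 + E01 * A11
    M10 = E01 * A00 + E11 * A01
    M11 = E01 * A01 + E11 * A11
    S00 = lamT * trE + 2.0 * muT * E00 + 0.5 * dlam * (aEa + trE * A00) + 2.0 * dmu * M00
    S11 = lamT * trE + 2.0 * muT * E11 + 0.5 * dlam * (aEa + trE * A11) + 2.0 * dmu * M11
    S01 = 2.0 * muT * E01 + 0.5 * dlam * trE * A01 + dmu * (M01 + M10)

    # nodal forces: H = (A t) F3 S Dm_inv^T ; f1 = -H[:,0], f2 = -H[:,1]
    sc = (rk.area * th)[:, None]
    FS1 = F1 * S00[:, None] + F2c * S01[:, None]
    FS2 = F1 * S01[:, None] + F2c * S11[:, None]
    H1 = (FS1 * m00[:, None] + FS2 * m01[:, None]) * sc
    H2 = (FS1 * m10[:, None] + FS2 * m11[:, None]) * sc
    forces = np.zeros_like(x)
    np.add.at(forces, t[:, 1], -H1)
    np.add.at(forces, t[:, 2], -H2)
    np.add.at(forces, t[:, 0], H1 + H2)

    return {
        "t": t, "rk": rk, "th": th, "d1": d1, "d2": d2,
        "E": (E00, E01, E11), "S": (S00, S01, S11), "W": W,
        "energy": energy, "forces": forces,
    }


def energy_and_forces(mesh: SurfaceMesh, mat: TissueMaterial, positions=None):
    """Lean path for the solvers: total elastic energy and nodal forces."""
    x = mesh.vertices if positions is None else positions
    c = _core(mesh, mat, x)
    return c["energy"], c["forces"]


def evaluate_mechanics(
    mesh: SurfaceMesh, mat: TissueMaterial, positions: np.ndarray | None = None
) -> MechanicsState:
    """Evaluate strain, stress, energy and nodal forces on the whole mesh."""
    x = mesh.vertices if positions is None else positions
    c = _core(mesh, mat, x)
    t, rk, th = c["t"], c["rk"], c["th"]
    d1, d2 = c["d1"], c["d2"]
    E00, E01, E11 = c["E"]
    S00, S01, S11 = c["S"]
    n_t = len(t)

    # current local frame and in-plane deformation gradient
    cr = np.cross(d1, d2)
    area2 = np.linalg.norm(cr, axis=1)
    if np.any(area2 <= 1e-12):
        raise ElementInversionError(int(np.argmin(area2)))
    nc = cr / area2[:, None]
    l1 = np.linalg.norm(d1, axis=1)
    e1c = d1 / l1[:, None]
    e2c = np.cross(nc, e1c)
    dq00 = l1
    dq01 = (d2 * e1c).sum(1)
    dq11 = (d2 * e2c).sum(1)
    m00 = rk.dm_inv[:, 0, 0]
    m01 = rk.dm_inv[:, 0, 1]
    m10 = rk.dm_inv[:, 1, 0]
    m11 = rk.dm_inv[:, 1, 1]
    f00 = dq00 * m00 + dq01 * m10
    f01 = dq00 * m01 + dq01 * m11
    f10 = dq11 * m10
    f11 = dq11 * m11
    J = f00 * f11 - f01 * f10
    if np.any(J <= 1e-9):
        raise ElementInversionError(int(np.argmin(J)))

    # thickness-integrated Cauchy stress (th/J) F2 S F2^T in current frame
    g00 = f00 * S00 + f01 * S01
    g01 = f00 * S01 + f01 * S11
    g10 = f10 * S00 + f11 * S01
    g11 = f10 * S01 + f11 * S11
    s = th / J
    cauchy = np.empty((n_t, 2, 2))
    cauchy[:, 0, 0] = (g00 * f00 + g01 * f01) * s
    cauchy[:, 0, 1] = cauchy[:, 1, 0] = (g00 * f10 + g01 * f11) * s
    cauchy[:, 1, 1] = (g10 * f10 + g11 * f11) * s

    # Almansi strain (I - B^-1)/2, B = F2 F2^T, in current frame
    B00 = f00 * f00 + f01 * f01
    B01 = f00 * f10 + f01 * f11
    B11 = f10 * f10 + f11 * f11
    detB = B00 * B11 - B01 * B01
    almansi = np.empty((n_t, 2, 2))
    almansi[:, 0, 0] = 0.5 * (1.0 - B11 / detB)
    almansi[:, 0, 1] = almansi[:, 1, 0] = 0.5 * (B01 / detB)
    almansi[:, 1, 1] = 0.5 * (1.0 - B00 / detB)

    green = np.empty((n_t, 2, 2))
    green[:, 0, 0] = E00
    green[:, 0, 1] = green[:, 1, 0] = E01
    green[:, 1, 1] = E11
    spk = np.empty((n_t, 2, 2))
    spk[:, 0, 0] = S00
    spk[:, 0, 1] = spk[:, 1, 0] = S01
    spk[:, 1, 1] = S11

    return MechanicsState(
        energy=c["energy"],
        W=c["W"],
        green=green,
        spk=spk,
        cauchy=cauchy,
        almansi=almansi,
        forces=c["forces"],
        area_ratio=J,
        cur_e1=e1c,
        cur_e2=e2c,
    )


def nodal_forces(
    mesh: SurfaceMesh, mat: TissueMaterial, positions: np.ndarray | None = None
) -> np.ndarray:
    """Elastic nodal forces −∂(total energy)/∂(vertex positions), (V,3) µN."""
    return evaluate_mechanics(mesh, mat, positions).forces


def total_elastic_energy(
    mesh: SurfaceMesh, mat: TissueMaterial, positions: np.ndarray | None = None
) -> float:
    return evaluate_mechanics(mesh, mat, positions).energy


def principal_fields(tensors: np.ndarray, degeneracy_tol: float = 1e-3):
    """Batched principal decomposition of (N,2,2) symmetric tensors.

    Returns s1, s2 (N,), dir1 (N,2) and a degeneracy mask.
    """
    a = tensors[:, 0, 0]
    b = tensors[:, 0, 1]
    c = tensors[:, 1, 1]
    mval = 0.5 * (a + c)
    r = np.sqrt((0.5 * (a - c)) ** 2 + b**2)
    s1, s2 = mval + r, mval - r
    theta = 0.5 * np.arctan2(2.0 * b, a - c)
    d1 = np.stack([np.cos(theta), np.sin(theta)], axis=1)
    scale = np.maximum(np.maximum(np.abs(s1), np.abs(s2)), np.finfo(float).eps)
    degenerate = (s1 - s2) / scale < degeneracy_tol
    return s1, s2, d1, degenerate
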