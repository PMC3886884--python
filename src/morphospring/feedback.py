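"""Anisotropy measures, the fiber (material-redistribution) model and
the direction-update rules.

Two feedback hypotheses for cellulose-fiber orientation are modeled:

* **MSD** (maximal stress direction): the cell's fiber axis relaxes
  toward the direction of the largest principal Cauchy stress.
* **OsD** (orthogonal to maximal strain): the fiber axis relaxes toward
  the in-plane perpendicular of the largest principal Almansi strain
  direction.

In the baseline model the *degree* of material anisotropy is regulated
by the stress anisotropy under both direction rules; driving it by the
strain anisotropy instead is available as ``measure_source='strain'``
(a supplementary variant).

The fiber model converts an anisotropy measure a ∈ [0,1] into
longitudinal/transverse Young moduli through a saturating Hill
response α(a) = aⁿ/(aⁿ + Kⁿ),

    E_L = E_matrix + E_fiber (1+α)/2,
    E_T = E_matrix + E_fiber (1−α)/2,

so the overall elasticity E_L + E_T = 2 E_matrix + E_fiber is conserved
for every a: fibers are redistributed between directions, not added.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .mechanics import principal_fields
from .mesh import SurfaceMesh


@dataclass
class FeedbackConfig:
    """Parameters of the fiber model and the direction-update rule."""

    mode: str = "msd"  # msd | osd
    measure: str = "relative"  # relative | absolute (template-wide s_max)
    measure_source: str = "stress"  # tensor driving the fiber model (stress | strain)
    K: float = 0.4  # half-saturation of the Hill response
    n: float = 2.0  # Hill exponent
    response: str = "hill"  # hill | hill_odds (see hill_response)
    k_dir: float = 0.1  # direction update rate per outer iteration
    k_mat: float = 0.01  # moduli update rate per outer iteration
    E_matrix: float = 50.0  # MPa, isotropic matrix modulus
    E_fiber: float = 120.0  # MPa, fiber contribution to be distributed
    update_moduli: bool = True  # False: direction-only dynamics
    update_direction: bool = True  # False: static (prealigned) fibers, fiber model only
    degeneracy_tol: float = 1e-3  # isotropic-tensor tolerance (skip update)
    boundary_margin: float = 2.0  # cell diameters excluded from s_max

    def __post_init__(self):
        if self.mode not in ("msd", "osd"):
            raise ValueError(f"unknown feedback mode {self.mode!r}")
        if self.measure not in ("relative", "absolute"):
            raise ValueError(f"unknown anisotropy measure {self.measure!r}")
        if self.measure_source not in ("stress", "strain"):
            raise ValueError(f"unknown measure source {self.measure_source!r}")
        if self.K <= 0 or self.n < 1:
            raise ValueError("K must be > 0 and n >= 1")
        if not (0 < self.k_dir <= 1 and 0 < self.k_mat <= 1):
            raise ValueError("update rates must lie in (0, 1]")


# ----------------------------------------------------------------------
# cell averaging
def cell_tangent_frames(mesh: SurfaceMesh, rest: bool = False):
    """Orthonormal tangent frame (u, v) per cell, built from the cell's
    area-weighted mean normal."""
    n = mesh.cell_normals(rest)
    a0 = np.tile([1.0, 0.0, 0.0], (len(n), 1))
    swap = np.abs(np.einsum("ij,ij->i", n, a0)) > 0.9
    a0[swap] = [0.0, 1.0, 0.0]
    u = np.cross(n, a0)
    u /= np.linalg.norm(u, axis=1, keepdims=True)
    v = np.cross(n, u)
    return u, v, n


def cell_average_tensor(
    mesh: SurfaceMesh,
    tri_tensors: np.ndarray,
    tri_e1: np.ndarray,
    tri_e2: np.ndarray,
    rest: bool = False,
):
    """Area-weighted per-cell average of per-triangle 2x2 tensors.

    Each triangle tensor (given in its local frame ``tri_e1``/``tri_e2``)
    is promoted to 3D, averaged over the cell with current triangle
    areas as weights, and projected into the cell's shared tangent
    frame.  Eigen-decomposition is meant to be applied *after* this
    averaging.  Returns (C,2,2) tensors plus the cell frames (u, v, n).
    """
    T = tri_tensors
    outer11 = np.einsum("ti,tj->tij", tri_e1, tri_e1)
    outer22 = np.einsum("ti,tj->tij", tri_e2, tri_e2)
    outer12 = np.einsum("ti,tj->tij", tri_e1, tri_e2)
    T3 = (
        T[:, 0, 0, None, None] * outer11
        + T[:, 1, 1, None, None] * outer22
        + T[:, 0, 1, None, None] * (outer12 + np.swapaxes(outer12, 1, 2))
    )
    w = mesh.triangle_areas(rest)
    cid = mesh.cell_of_triangle
    C = mesh.n_cells
    acc = np.zeros((C, 3, 3))
    np.add.at(acc, cid, T3 * w[:, None, None])
    tot = np.bincount(cid, weights=w, minlength=C)
    acc /= tot[:, None, None]
    u, v, n = cell_tangent_frames(mesh, rest)
    out = np.empty((C, 2, 2))
    out[:, 0, 0] = np.einsum("ci,cij,cj->c", u, acc, u)
    out[:, 1, 1] = np.einsum("ci,cij,cj->c", v, acc, v)
    out[:, 0, 1] = out[:, 1, 0] = np.einsum("ci,cij,cj->c", u, acc, v)
    return out, (u, v, n)


# ----------------------------------------------------------------------
# anisotropy measures (tension-clamped, per the model: only tensile
# principal values are biologically relevant)
def anisotropy_relative(s1, s2):
    """(s1' − s2')/s1' with s' = max(s, 0); 0 where s1' = 0."""
    s1c = np.maximum(np.asarray(s1, dtype=float), 0.0)
    s2c = np.maximum(np.asarray(s2, dtype=float), 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        a = np.where(s1c > 0, (s1c - s2c) / np.where(s1c > 0, s1c, 1.0), 0.0)
    return np.clip(a, 0.0, 1.0)


def anisotropy_absolute(s1, s2, s_max):
    """(s1' − s2')/s_max clipped to [0,1]; s_max is the template-wide
    largest tensile principal value (boundary regions excluded)."""
    if s_max <= 0:
        return np.zeros_like(np.asarray(s1, dtype=float))
    s1c = np.maximum(np.asarray(s1, dtype=float), 0.0)
    s2c = np.maximum(np.asarray(s2, dtype=float), 0.0)
    return np.clip((s1c - s2c) / s_max, 0.0, 1.0)


def hill_response(a, K, n, form: str = "hill"):
    """Saturating response α(a) ∈ [0,1] of the fiber model.

    ``form='hill'``: α = aⁿ/(aⁿ + Kⁿ), half-saturation at a=K, reaching
    α(1) = 1/(1+Kⁿ) < 1.  ``form='hill_odds'``: the same Hill function
    applied to the odds ratio a/(1−a), i.e. α = aⁿ/(aⁿ + Kⁿ(1−a)ⁿ);
    saturates exactly at a=1 and is already near its maximum
    (α(0.5) = 1/(1+Kⁿ) = 0.86 for K=0.4, n=2) at anisotropy 0.5.
    """
    a = np.asarray(a, dtype=float)
    if form == "hill":
        return a**n / (a**n + K**n)
    if form == "hill_odds":
        return a**n / (a**n + K**n * (1.0 - a) ** n)
    raise ValueError(f"unknown response form {form!r}")


def fiber_targets(a, E_matrix, E_fiber, K=0.4, n=2.0, form: str = "hill"):
    """Target (E_L, E_T) for anisotropy measure ``a`` ∈ [0,1].

    Conserves E_L + E_T = 2 E_matrix + E_fiber for every a.
    """
    a = np.asarray(a, dtype=float)
    if np.any(a < -1e-12) or np.any(a > 1 + 1e-12):
        warnings.warn("anisotropy measure outside [0,1]; clipping", stacklevel=2)
    a = np.clip(a, 0.0, 1.0)
    alpha = hill_response(a, K, n, form)
    E_L = E_matrix + E_fiber * (1.0 + alpha) / 2.0
    E_T = E_matrix + E_fiber * (1.0 - alpha) / 2.0
    return E_L, E_T


def update_moduli(current, target, k_mat):
    """Relaxation (Euler) step X ← X + k·(X_target − X), per component."""
    cur = np.asarray(current, dtype=float)
    tgt = np.asarray(target, dtype=float)
    return cur + k_mat * (tgt - cur)


def update_direction(fiber, signal_dir, k_dir, tangent_normal=None):
    """Rotate the axial fiber vector toward the (axial) signal direction.

    The signal is sign-flipped into the fiber's hemisphere, blended with
    rate ``k_dir``, optionally projected onto the cell tangent plane,
    and renormalized.  Works on single vectors or (C,3) stacks.
    """
    f = np.atleast_2d(np.asarray(fiber, dtype=float))
    s = np.atleast_2d(np.asarray(signal_dir, dtype=float)).copy()
    dots = np.einsum("ij,ij->i", f, s)
    s[dots < 0] *= -1.0
    new = f + k_dir * (s - f)
    if tangent_normal is not None:
        nrm = np.atleast_2d(np.asarray(tangent_normal, dtype=float))
        new = new - np.einsum("ij,ij->i", new, nrm)[:, None] * nrm
    norm = np.linalg.norm(new, axis=1, keepdims=True)
    bad = norm[:, 0] < 1e-12
    new[bad] = f[bad]
    norm[bad] = 1.0
    new = new / norm
    if np.asarray(fiber).ndim == 1:
        return new[0]
    return new


def axial_angle(u, v):
    """Angle in [0, π/2] between axial (sign-free) vectors."""
    u = np.atleast_2d(u)
    v = np.atleast_2d(v)
    c = np.abs(np.einsum("ij,ij->i", u, v) / (np.linalg.norm(u, axis=1) * np.linalg.norm(v, axis=1)))
    ang = np.arccos(np.clip(c, 0.0, 1.0))
    return ang if ang.size > 1 else float(ang[0])
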