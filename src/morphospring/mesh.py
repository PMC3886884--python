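"""Triangulated-surface container used throughout the simulator.

A tissue template is a surface mesh whose triangles are grouped into
polygonal *cells* (one biological cell = a fan of triangles around the
cell's centroid vertex).  The mesh carries two configurations: the
resting one, frozen at construction time and defining per-triangle
resting edge lengths/areas and local 2D frames, and the current one,
which the solvers move.  All lengths are in µm.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np


class RestKinematics(NamedTuple):
    """Per-triangle resting-frame data needed by the mechanics core.

    e1, e2 : (T, 3) orthonormal in-plane axes of the resting triangle
             (e1 along the first edge, e1 x e2 = outward normal).
    dm_inv : (T, 2, 2) inverse of the resting edge matrix; maps resting
             local coordinates to barycentric gradients.
    area   : (T,) resting triangle areas.
    """

    e1: np.ndarray
    e2: np.ndarray
    dm_inv: np.ndarray
    area: np.ndarray


@dataclass
class SurfaceMesh:
    """Oriented triangulated surface partitioned into polygonal cells.

    Parameters
    ----------
    vertices : (V, 3) float array
        Current vertex positions (µm).  At construction these are also
        copied into ``rest_vertices``.
    triangles : (T, 3) int array
        Vertex index triples, counter-clockwise seen from outside (the
        outward normal points away from the pressurized interior).
    cell_of_triangle : (T,) int array
        Owning cell id of each triangle.
    centroid_vertex : (C,) int array, optional
        The centroid vertex of each cell fan (used by writers only).
    info : dict
        Free-form template metadata (kind, axis, dimensions, seed ...).
    """

    vertices: np.ndarray
    triangles: np.ndarray
    cell_of_triangle: np.ndarray
    centroid_vertex: np.ndarray | None = None
    info: dict = field(default_factory=dict)
    rest_vertices: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self):
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.triangles = np.asarray(self.triangles, dtype=np.int64)
        self.cell_of_triangle = np.asarray(self.cell_of_triangle, dtype=np.int64)
        if self.rest_vertices is None:
            self.rest_vertices = self.vertices.copy()
        else:
            self.rest_vertices = np.asarray(self.rest_vertices, dtype=float)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise ValueError("vertices must be (V, 3)")
        if self.triangles.ndim != 2 or self.triangles.shape[1] != 3:
            raise ValueError("triangles must be (T, 3)")
        if len(self.cell_of_triangle) != len(self.triangles):
            raise ValueError("cell_of_triangle must have one entry per triangle")
        self._rest_cache: RestKinematics | None = None
        self._boundary_cache: np.ndarray | None = None

    # ------------------------------------------------------------------
    # basic counts
    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_triangles(self) -> int:
        return len(self.triangles)

    @property
    def n_cells(self) -> int:
        return int(self.cell_of_triangle.max()) + 1

    # ------------------------------------------------------------------
    # topology
    def _edge_counts(self):
        t = self.triangles
        edges = np.concatenate([t[:, [0, 1]], t[:, [1, 2]], t[:, [2, 0]]])
        und = np.sort(edges, axis=1)
        uniq, counts = np.unique(und, axis=0, return_counts=True)
        return edges, uniq, counts

    @property
    def boundary_vertices(self) -> np.ndarray:
        """Vertex ids on open (single-sided) edges; empty for closed surfaces."""
        if self._boundary_cache is None:
            _, uniq, counts = self._edge_counts()
            open_edges = uniq[counts == 1]
            self._boundary_cache = np.unique(open_edges)
        return self._boundary_cache

    @property
    def is_closed(self) -> bool:
        return len(self.boundary_vertices) == 0

    def euler_characteristic(self) -> int:
        _, uniq, _ = self._edge_counts()
        return self.n_vertices - len(uniq) + self.n_triangles

    def check_orientation(self) -> bool:
        """True iff every interior edge is traversed once in each direction."""
        edges, _, _ = self._edge_counts()
        directed = {}
        for a, b in edges:
            key = (int(a), int(b))
            directed[key] = directed.get(key, 0) + 1
        for (a, b), c in directed.items():
            if c > 1:
                return False
            rev = directed.get((b, a), 0)
            if rev > 1:
                return False
        return True

    # ------------------------------------------------------------------
    # geometry (current configuration unless stated otherwise)
    def triangle_cross(self, rest: bool = False) -> np.ndarray:
        x = self.rest_vertices if rest else self.vertices
        a, b, c = (x[self.triangles[:, i]] for i in range(3))
        return np.cross(b - a, c - a)

    def triangle_areas(self, rest: bool = False) -> np.ndarray:
        return 0.5 * np.linalg.norm(self.triangle_cross(rest), axis=1)

    def triangle_normals(self, rest: bool = False) -> np.ndarray:
        cr = self.triangle_cross(rest)
        n = np.linalg.norm(cr, axis=1, keepdims=True)
        return cr / np.where(n == 0, 1.0, n)

    def rest_edge_lengths(self) -> np.ndarray:
        """(T, 3) resting lengths of edges (v0v1, v1v2, v2v0)."""
        x = self.rest_vertices
        t = self.triangles
        return np.stack(
            [
                np.linalg.norm(x[t[:, 1]] - x[t[:, 0]], axis=1),
                np.linalg.norm(x[t[:, 2]] - x[t[:, 1]], axis=1),
                np.linalg.norm(x[t[:, 0]] - x[t[:, 2]], axis=1),
            ],
            axis=1,
        )

    def cell_areas(self, rest: bool = False) -> np.ndarray:
        areas = self.triangle_areas(rest)
        return np.bincount(self.cell_of_triangle, weights=areas, minlength=self.n_cells)

    def cell_centroids(self, rest: bool = False) -> np.ndarray:
        """Area-weighted centroids of cells."""
        x = self.rest_vertices if rest else self.vertices
        tri_c = x[self.triangles].mean(axis=1)
        areas = self.triangle_areas(rest)
        w = np.zeros((self.n_cells, 3))
        for k in range(3):
            w[:, k] = np.bincount(
                self.cell_of_triangle, weights=areas * tri_c[:, k], minlength=self.n_cells
            )
        tot = np.bincount(self.cell_of_triangle, weights=areas, minlength=self.n_cells)
        return w / tot[:, None]

    def cell_normals(self, rest: bool = False) -> np.ndarray:
        """Area-weighted mean triangle normal per cell, renormalized."""
        nrm = self.triangle_normals(rest)
        areas = self.triangle_areas(rest)
        acc = np.zeros((self.n_cells, 3))
        for k in range(3):
            acc[:, k] = np.bincount(
                self.cell_of_triangle, weights=areas * nrm[:, k], minlength=self.n_cells
            )
        n = np.linalg.norm(acc, axis=1, keepdims=True)
        return acc / np.where(n == 0, 1.0, n)

    def mean_cell_diameter(self, rest: bool = True) -> float:
        """Diameter of the circle with the mean cell area."""
        return float(np.sqrt(4.0 * self.cell_areas(rest).mean() / np.pi))

    def interior_cells(self, margin_diameters: float = 2.0) -> np.ndarray:
        """Cell ids farther than ``margin_diameters`` mean cell diameters
        from every clamped/boundary vertex.

        Clamped boundaries distort nearby stresses, so analyses exclude a
        margin around them; for closed surfaces all cells are interior.
        """
        bv = self.boundary_vertices
        if len(bv) == 0:
            return np.arange(self.n_cells)
        margin = margin_diameters * self.mean_cell_diameter()
        cen = self.cell_centroids(rest=True)
        bpos = self.rest_vertices[bv]
        # min distance cell-centroid -> boundary vertex
        d = np.sqrt(((cen[:, None, :] - bpos[None, :, :]) ** 2).sum(-1)).min(axis=1)
        return np.nonzero(d > margin)[0]

    # ------------------------------------------------------------------
    # resting-frame kinematics for the mechanics core
    def rest_kinematics(self) -> RestKinematics:
        if self._rest_cache is None:
            x = self.rest_vertices
            t = self.triangles
            d1 = x[t[:, 1]] - x[t[:, 0]]
            d2 = x[t[:, 2]] - x[t[:, 0]]
            nrm = np.cross(d1, d2)
            area = 0.5 * np.linalg.norm(nrm, axis=1)
            if np.any(area <= 1e-12):
                bad = int(np.argmin(area))
                raise ValueError(f"degenerate resting triangle {bad}")
            nhat = nrm / (2.0 * area)[:, None]
            e1 = d1 / np.linalg.norm(d1, axis=1, keepdims=True)
            e2 = np.cross(nhat, e1)
            # resting local coordinates of v1, v2 relative to v0
            dm = np.empty((len(t), 2, 2))
            dm[:, 0, 0] = np.einsum("ij,ij->i", d1, e1)
            dm[:, 1, 0] = np.einsum("ij,ij->i", d1, e2)
            dm[:, 0, 1] = np.einsum("ij,ij->i", d2, e1)
            dm[:, 1, 1] = np.einsum("ij,ij->i", d2, e2)
            det = dm[:, 0, 0] * dm[:, 1, 1] - dm[:, 0, 1] * dm[:, 1, 0]
            dm_inv = np.empty_like(dm)
            dm_inv[:, 0, 0] = dm[:, 1, 1]
            dm_inv[:, 1, 1] = dm[:, 0, 0]
            dm_inv[:, 0, 1] = -dm[:, 0, 1]
            dm_inv[:, 1, 0] = -dm[:, 1, 0]
            dm_inv /= det[:, None, None]
            self._rest_cache = RestKinematics(e1=e1, e2=e2, dm_inv=dm_inv, area=area)
        return self._rest_cache

    # ------------------------------------------------------------------
    def copy(self) -> "SurfaceMesh":
        return SurfaceMesh(
            vertices=self.vertices.copy(),
            triangles=self.triangles.copy(),
            cell_of_triangle=self.cell_of_triangle.copy(),
            centroid_vertex=None if self.centroid_vertex is None else self.centroid_vertex.copy(),
            info=dict(self.info),
            rest_vertices=self.rest_vertices.copy(),
        )


def estimate_principal_curvatures(mesh: SurfaceMesh, vertex: int, rings: int = 2):
    """Estimate principal curvatures at a vertex by local quadric fit.

    Fits z = (a x^2 + 2 b x y + c y^2)/2 over the vertex's ``rings``-ring
    neighborhood expressed in the vertex tangent frame; returns the
    eigenvalues (k1 >= k2) of the shape operator [[a, b], [b, c]].  Sign
    convention: positive curvature bends away from the outward normal
    (a sphere seen from outside has two positive curvatures).
    """
    t = mesh.triangles
    # adjacency
    nbrs = {vertex}
    for _ in range(rings):
        mask = np.isin(t, list(nbrs)).any(axis=1)
        nbrs.update(np.unique(t[mask]))
    nbrs.discard(vertex)
    nbrs = np.array(sorted(nbrs))
    # outward normal at the vertex: mean of incident triangle normals
    inc = np.nonzero((t == vertex).any(axis=1))[0]
    nrm = mesh.triangle_normals()[inc].mean(axis=0)
    nrm /= np.linalg.norm(nrm)
    # tangent frame
    a0 = np.array([1.0, 0.0, 0.0])
    if abs(nrm @ a0) > 0.9:
        a0 = np.array([0.0, 1.0, 0.0])
    u = np.cross(nrm, a0)
    u /= np.linalg.norm(u)
    v = np.cross(nrm, u)
    rel = mesh.vertices[nbrs] - mesh.vertices[vertex]
    x, y, z = rel @ u, rel @ v, rel @ (-nrm)  # z along inward => sphere positive
    A = np.column_stack([0.5 * x * x, x * y, 0.5 * y * y, x, y])
    coef, *_ = np.linalg.lstsq(A, z, rcond=None)
    a, b, c = coef[0], coef[1], coef[2]
    shape_op = np.array([[a, b], [b, c]])
    k = np.sort(np.linalg.eigvalsh(shape_op))[::-1]
    return float(k[0]), float(k[1])
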