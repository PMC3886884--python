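"""Procedural tissue templates.

Every generator returns a :class:`~morphospring.mesh.SurfaceMesh` whose
polygonal cells are triangulated through the cell centroid.  Cells are
seeded on the parametric domain of each surface as a jittered hexagonal
lattice with one Lloyd relaxation step, then converted to Voronoi
polygons and lifted onto the surface; this yields reproducible, roughly
isotropic cells whose center spacing is the requested ``cell_size``
(plant epidermal cells are of order 10–20 µm).  All generators are
deterministic given their arguments and seed.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial import SphericalVoronoi, Voronoi

from .mesh import SurfaceMesh

_JITTER = 0.15  # lattice jitter amplitude, in units of the lattice spacing


# ----------------------------------------------------------------------
# generic plane-Voronoi machinery
def _hex_lattice(width: float, height: float, spacing: float, rng, periodic_u: bool):
    """Jittered hexagonal point lattice on [0,width) x [0,height]."""
    dy = spacing * np.sqrt(3.0) / 2.0
    n_rows = max(2, int(round(height / dy)))
    dy = height / n_rows
    if periodic_u:
        n_u = max(3, int(round(width / spacing)))
        du = width / n_u
    else:
        n_u = max(2, int(round(width / spacing)))
        du = width / n_u
    pts = []
    for i in range(n_rows):
        v = (i + 0.5) * dy
        off = 0.5 * du if (i % 2) else 0.0
        for j in range(n_u):
            u = (j + 0.5) * du + off
            pts.append((u, v))
    pts = np.array(pts, dtype=float)
    pts[:, 0] += rng.uniform(-_JITTER, _JITTER, len(pts)) * spacing
    pts[:, 1] += rng.uniform(-_JITTER, _JITTER, len(pts)) * spacing
    pts[:, 1] = np.clip(pts[:, 1], 0.1 * dy, height - 0.1 * dy)
    if periodic_u:
        pts[:, 0] %= width
    return pts


def _extend_periodic_strip(seeds, width, height):
    """Mirror seeds across v=0 and v=height, replicate u by +-width."""
    s = seeds
    mirror_lo = s * [1, -1]
    mirror_hi = np.column_stack([s[:, 0], 2 * height - s[:, 1]])
    base = np.vstack([s, mirror_lo, mirror_hi])
    return np.vstack([base, base + [width, 0], base - [width, 0]])


def _extend_disk(seeds, r_max):
    """Reflect seeds near the rim radially across the circle r=r_max."""
    r = np.linalg.norm(seeds, axis=1)
    # reflect every seed (cheap, robust): rho -> 2 r_max - rho along its ray
    with np.errstate(invalid="ignore", divide="ignore"):
        scale = (2 * r_max - r) / r
    mirror = seeds * scale[:, None]
    return np.vstack([seeds, mirror])


def _voronoi_polygons(extended, n_keep):
    """Finite Voronoi polygons of the first ``n_keep`` seeds, each sorted
    counter-clockwise around its seed."""
    vor = Voronoi(extended)
    polys = []
    for i in range(n_keep):
        region = vor.regions[vor.point_region[i]]
        if -1 in region or len(region) < 3:
            raise RuntimeError(
                "unbounded Voronoi cell: seed spacing too coarse for the domain"
            )
        poly = vor.vertices[region]
        ang = np.arctan2(poly[:, 1] - extended[i, 1], poly[:, 0] - extended[i, 0])
        polys.append(poly[np.argsort(ang)])
    return polys


def _lloyd_step(polys):
    """Area centroids of polygons (one Lloyd relaxation step)."""
    out = []
    for p in polys:
        x, y = p[:, 0], p[:, 1]
        xn, yn = np.roll(x, -1), np.roll(y, -1)
        cr = x * yn - xn * y
        a = cr.sum() / 2.0
        cx = ((x + xn) * cr).sum() / (6 * a)
        cy = ((y + yn) * cr).sum() / (6 * a)
        out.append((cx, cy))
    return np.array(out)


def _merge_polygons(polys, key_fn):
    """Merge duplicated polygon corners into a shared vertex table."""
    table: dict = {}
    coords = []
    cells = []
    for p in polys:
        idx = []
        for q in p:
            k = key_fn(q)
            j = table.get(k)
            if j is None:
                j = len(coords)
                table[k] = j
                coords.append(k)
            idx.append(j)
        # drop accidental duplicates of consecutive corners
        dedup = [idx[0]]
        for j in idx[1:]:
            if j != dedup[-1]:
                dedup.append(j)
        if dedup[-1] == dedup[0]:
            dedup.pop()
        if len(dedup) < 3:
            raise RuntimeError("degenerate Voronoi cell after merging")
        cells.append(dedup)
    return np.array(coords, dtype=float), cells


def _fan_mesh(uv_vertices, cells, raw_polys, lift, flip: bool, info: dict) -> SurfaceMesh:
    """Lift 2D vertices to the surface and fan-triangulate each cell
    through its (parametric) centroid.

    Centroids are computed from ``raw_polys`` (the unwrapped polygon
    coordinates), so cells straddling a periodic seam stay intact.
    """
    n_shared = len(uv_vertices)
    verts3 = [lift(uv_vertices)]
    centroid_ids = []
    tris = []
    cell_ids = []
    extra = []
    for c, poly in enumerate(cells):
        extra.append(_lloyd_step([raw_polys[c]])[0])
        cid = n_shared + len(extra) - 1
        centroid_ids.append(cid)
        order = poly if not flip else poly[::-1]
        m = len(order)
        for k in range(m):
            tris.append((cid, order[k], order[(k + 1) % m]))
            cell_ids.append(c)
    verts3.append(lift(np.array(extra)))
    vertices = np.vstack(verts3)
    return SurfaceMesh(
        vertices=vertices,
        triangles=np.array(tris, dtype=np.int64),
        cell_of_triangle=np.array(cell_ids, dtype=np.int64),
        centroid_vertex=np.array(centroid_ids, dtype=np.int64),
        info=info,
    )


# ----------------------------------------------------------------------
# templates
def make_square_patch(side: float, n_divisions: int) -> SurfaceMesh:
    """Flat square patch in the z=0 plane, ``n_divisions`` x ``n_divisions``
    quadrilateral cells, each split into 4 triangles via its centroid."""
    if side <= 0 or n_divisions < 1:
        raise ValueError("side must be > 0 and n_divisions >= 1")
    n = n_divisions
    h = side / n
    xs = np.arange(n + 1) * h
    gx, gy = np.meshgrid(xs, xs, indexing="ij")
    grid = np.column_stack([gx.ravel(), gy.ravel(), np.zeros((n + 1) ** 2)])

    def vid(i, j):
        return i * (n + 1) + j

    verts = [grid]
    tris, cell_ids, centroid_ids = [], [], []
    extra = []
    c = 0
    for i in range(n):
        for j in range(n):
            corners = [vid(i, j), vid(i + 1, j), vid(i + 1, j + 1), vid(i, j + 1)]
            cen = (n + 1) ** 2 + len(extra)
            extra.append([(i + 0.5) * h, (j + 0.5) * h, 0.0])
            centroid_ids.append(cen)
            for k in range(4):
                tris.append((cen, corners[k], corners[(k + 1) % 4]))
                cell_ids.append(c)
            c += 1
    verts.append(np.array(extra))
    return SurfaceMesh(
        vertices=np.vstack(verts),
        triangles=np.array(tris, dtype=np.int64),
        cell_of_triangle=np.array(cell_ids, dtype=np.int64),
        centroid_vertex=np.array(centroid_ids, dtype=np.int64),
        info={"kind": "square_patch", "side": side, "n_divisions": n},
    )


def make_cylinder(radius: float, length: float, cell_size: float, seed: int = 0) -> SurfaceMesh:
    """Open-ended cylindrical tube of polygonal cells, axis along z.

    Both rims (z=0 and z=length) are open boundary rings, marked as
    boundary (and hence clamped in the pressure simulations).  The axis
    direction is stored in ``info`` so analyses can define the
    circumferential and longitudinal directions.
    """
    if radius <= 0 or length <= 0 or cell_size <= 0:
        raise ValueError("radius, length and cell_size must be positive")
    if cell_size >= radius:
        raise ValueError("cell_size must be smaller than the cylinder radius")
    width = 2 * np.pi * radius
    rng = np.random.default_rng(seed)
    seeds = _hex_lattice(width, length, cell_size, rng, periodic_u=True)
    for _ in range(2):  # first pass + one Lloyd step
        polys = _voronoi_polygons(_extend_periodic_strip(seeds, width, length), len(seeds))
        new = _lloyd_step(polys)
        new[:, 0] %= width
        new[:, 1] = np.clip(new[:, 1], 1e-3 * length, (1 - 1e-3) * length)
        seeds, polys_final = new, polys
    polys = polys_final

    def key_fn(q):
        u = round(q[0] % width, 6)
        if u >= round(width, 6):
            u = 0.0
        return (u, round(q[1], 6))

    uv, cells = _merge_polygons(polys, key_fn)
    if np.any(uv[:, 1] < -1e-6) or np.any(uv[:, 1] > length + 1e-6):
        raise RuntimeError("tessellation produced vertices outside the strip")
    uv[:, 1] = np.clip(uv[:, 1], 0.0, length)

    def lift(p):
        th = p[:, 0] / radius
        return np.column_stack([radius * np.cos(th), radius * np.sin(th), p[:, 1]])

    info = {
        "kind": "cylinder",
        "radius": radius,
        "length": length,
        "cell_size": cell_size,
        "seed": seed,
        "axis": [0.0, 0.0, 1.0],
    }
    return _fan_mesh(uv, cells, polys, lift, flip=False, info=info)


def _disk_template(r_max, lift, cell_size, seed, info, flip=True) -> SurfaceMesh:
    rng = np.random.default_rng(seed)
    box = 2 * r_max
    pts = _hex_lattice(box, box, cell_size, rng, periodic_u=False) - r_max
    pts = pts[np.linalg.norm(pts, axis=1) < r_max - 0.35 * cell_size]
    seeds = pts
    for _ in range(2):
        polys = _voronoi_polygons(_extend_disk(seeds, r_max), len(seeds))
        new = _lloyd_step(polys)
        r = np.linalg.norm(new, axis=1)
        pull = r > r_max - 0.3 * cell_size
        new[pull] *= ((r_max - 0.3 * cell_size) / r[pull])[:, None]
        seeds, polys_final = new, polys
    polys = polys_final

    def key_fn(q):
        return (round(q[0], 6), round(q[1], 6))

    uv, cells = _merge_polygons(polys, key_fn)
    # rim vertices sit on tangent lines at r >= r_max: snap them onto the circle
    r = np.linalg.norm(uv, axis=1)
    rim = r > r_max - 1e-6 * r_max
    uv[rim] *= (r_max / r[rim])[:, None]
    return _fan_mesh(uv, cells, polys, lift, flip=flip, info=info)


def make_paraboloid(
    apex_curvature_radius: float, height: float, cell_size: float, seed: int = 0
) -> SurfaceMesh:
    """Paraboloid of revolution z = r^2 / (2 R0), capped at ``height``.

    The apex (r=0, z=0) has isotropic curvature 1/R0; the rim circle at
    z=height is the clamped boundary.  A proxy for a naked meristem.
    """
    if apex_curvature_radius <= 0 or height <= 0 or cell_size <= 0:
        raise ValueError("all dimensions must be positive")
    r0 = apex_curvature_radius
    r_max = np.sqrt(2.0 * r0 * height)

    def lift(p):
        r2 = p[:, 0] ** 2 + p[:, 1] ** 2
        return np.column_stack([p[:, 0], p[:, 1], r2 / (2 * r0)])

    info = {
        "kind": "paraboloid",
        "apex_curvature_radius": r0,
        "height": height,
        "cell_size": cell_size,
        "seed": seed,
        "apex": [0.0, 0.0, 0.0],
        "axis": [0.0, 0.0, 1.0],
    }
    return _disk_template(r_max, lift, cell_size, seed, info)


def make_meristem(
    dome_radius: float,
    primordium_radius: float,
    primordium_offset: float = 55.0,
    cell_size: float = 10.0,
    seed: int = 0,
    height: float = 90.0,
) -> SurfaceMesh:
    """Meristem-like dome with a primordium bump on its flank.

    The base is the paraboloid z = r^2/(2 dome_radius); the primordium
    is a Gaussian bump of width 0.8*primordium_radius displaced along
    the base outward normal, with amplitude chosen so the bump apex
    curvature radius is about ``primordium_radius``.  Between the two
    apices the surface forms a saddle-shaped valley.  With
    ``primordium_radius=0`` the construction reduces exactly to
    :func:`make_paraboloid`.
    """
    if dome_radius <= 0 or cell_size <= 0 or height <= 0 or primordium_radius < 0:
        raise ValueError("dimensions must be positive (primordium_radius >= 0)")
    r0 = dome_radius
    r_max = np.sqrt(2.0 * r0 * height)
    sig = 0.8 * primordium_radius
    amp = sig**2 / primordium_radius if primordium_radius > 0 else 0.0
    cx = primordium_offset

    def lift(p):
        x, y = p[:, 0], p[:, 1]
        z = (x**2 + y**2) / (2 * r0)
        base = np.column_stack([x, y, z])
        if amp == 0.0:
            return base
        # outward unit normal of the base paraboloid (pressurized side is above)
        gx, gy = x / r0, y / r0
        nrm = np.column_stack([gx, gy, -np.ones_like(x)])
        nrm /= np.linalg.norm(nrm, axis=1, keepdims=True)
        # bump width measured as 3D distance on the base surface, so the
        # primordium stays compact on the steep flank
        center = np.array([cx, 0.0, cx**2 / (2 * r0)])
        d2 = ((base - center) ** 2).sum(axis=1)
        g = amp * np.exp(-d2 / (2 * sig**2))
        return base + g[:, None] * nrm

    info = {
        "kind": "meristem",
        "dome_radius": r0,
        "primordium_radius": primordium_radius,
        "primordium_offset": primordium_offset,
        "cell_size": cell_size,
        "seed": seed,
        "height": height,
        "apex": [0.0, 0.0, 0.0],
        "primordium_center": [cx, 0.0],
        "axis": [0.0, 0.0, 1.0],
    }
    return _disk_template(r_max, lift, cell_size, seed, info)


def make_ellipsoid(semi_axes, cell_size: float, seed: int = 0) -> SurfaceMesh:
    """Closed ellipsoidal surface (no boundary), cells from a spherical
    Voronoi diagram of jittered Fibonacci points mapped to the ellipsoid."""
    a, b, c = (float(s) for s in semi_axes)
    if min(a, b, c) <= 0 or cell_size <= 0:
        raise ValueError("semi-axes and cell_size must be positive")
    # Thomsen approximation of the ellipsoid area
    p = 1.6075
    area = 4 * np.pi * (((a * b) ** p + (a * c) ** p + (b * c) ** p) / 3) ** (1 / p)
    n = max(16, int(round(area / (0.866 * cell_size**2))))
    rng = np.random.default_rng(seed)
    i = np.arange(n)
    z = 1.0 - 2.0 * (i + 0.5) / n
    phi = i * np.pi * (3.0 - np.sqrt(5.0))
    r = np.sqrt(1.0 - z**2)
    pts = np.column_stack([r * np.cos(phi), r * np.sin(phi), z])
    pts += 0.15 * (2 * np.pi / np.sqrt(n)) * rng.normal(size=(n, 3)) * 0.5
    pts /= np.linalg.norm(pts, axis=1, keepdims=True)
    sv = SphericalVoronoi(pts, radius=1.0)
    sv.sort_vertices_of_regions()
    sverts = sv.vertices * [a, b, c]
    scale = np.array([a, b, c])

    tris, cell_ids, centroid_ids = [], [], []
    extra = []
    n_shared = len(sverts)
    for ci, region in enumerate(sv.regions):
        poly_sphere = sv.vertices[region]
        # enforce counter-clockwise orientation about the outward direction
        order = list(region)
        normal_sum = np.zeros(3)
        ps = poly_sphere
        for k in range(len(ps)):
            normal_sum += np.cross(ps[k], ps[(k + 1) % len(ps)])
        if normal_sum @ pts[ci] < 0:
            order = order[::-1]
        cen = sverts[order].mean(axis=0) / scale
        cen /= np.linalg.norm(cen)
        cen *= scale
        cid = n_shared + len(extra)
        extra.append(cen)
        centroid_ids.append(cid)
        m = len(order)
        for k in range(m):
            tris.append((cid, order[k], order[(k + 1) % m]))
            cell_ids.append(ci)
    vertices = np.vstack([sverts, np.array(extra)])
    mesh = SurfaceMesh(
        vertices=vertices,
        triangles=np.array(tris, dtype=np.int64),
        cell_of_triangle=np.array(cell_ids, dtype=np.int64),
        centroid_vertex=np.array(centroid_ids, dtype=np.int64),
        info={"kind": "ellipsoid", "semi_axes": [a, b, c], "cell_size": cell_size, "seed": seed},
    )
    return mesh
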