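"""Mesh and field I/O: VTK legacy (ASCII) with per-triangle/per-cell
fields, PLY for bare geometry, and the per-cell TSV report."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .feedback import anisotropy_relative
from .mechanics import TissueMaterial, principal_fields
from .mesh import SurfaceMesh


# ----------------------------------------------------------------------
# VTK legacy unstructured grid
def write_vtk(mesh: SurfaceMesh, path, cell_data=None, point_data=None):
    """Write the current configuration as a VTK legacy ASCII
    unstructured grid.

    ``cell_data``/``point_data`` map field names to arrays of length
    n_triangles (scalars or 3-vectors) / n_vertices.  The cell grouping
    is stored as a triangle field ``cell_id`` so that reading the file
    back reconstructs the full SurfaceMesh.
    """
    cell_data = dict(cell_data or {})
    point_data = dict(point_data or {})
    cell_data.setdefault("cell_id", mesh.cell_of_triangle.astype(float))
    for name, arr in cell_data.items():
        if len(arr) != mesh.n_triangles:
            raise ValueError(f"cell field {name!r} has length {len(arr)}, "
                             f"expected {mesh.n_triangles}")
    for name, arr in point_data.items():
        if len(arr) != mesh.n_vertices:
            raise ValueError(f"point field {name!r} has length {len(arr)}, "
                             f"expected {mesh.n_vertices}")
    lines = [
        "# vtk DataFile Version 3.0",
        "morphospring surface mesh",
        "ASCII",
        "DATASET UNSTRUCTURED_GRID",
        f"POINTS {mesh.n_vertices} double",
    ]
    for p in mesh.vertices:
        lines.append("%.17g %.17g %.17g" % tuple(p))
    lines.append(f"CELLS {mesh.n_triangles} {4 * mesh.n_triangles}")
    for tri in mesh.triangles:
        lines.append("3 %d %d %d" % tuple(tri))
    lines.append(f"CELL_TYPES {mesh.n_triangles}")
    lines.extend(["5"] * mesh.n_triangles)

    def emit_fields(data, n, header):
        lines.append(f"{header} {n}")
        for name, arr in data.items():
            arr = np.asarray(arr, dtype=float)
            if arr.ndim == 1:
                lines.append(f"SCALARS {name} double 1")
                lines.append("LOOKUP_TABLE default")
                lines.extend("%.17g" % v for v in arr)
            elif arr.ndim == 2 and arr.shape[1] == 3:
                lines.append(f"VECTORS {name} double")
                lines.extend("%.17g %.17g %.17g" % tuple(v) for v in arr)
            else:
                raise ValueError(f"field {name!r} must be scalar or 3-vector")

    if cell_data:
        emit_fields(cell_data, mesh.n_triangles, "CELL_DATA")
    if point_data:
        emit_fields(point_data, mesh.n_vertices, "POINT_DATA")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_vtk(path):
    """Read a VTK legacy ASCII unstructured grid written by
    :func:`write_vtk`.  Returns (SurfaceMesh, cell_data, point_data)."""
    with open(path) as fh:
        tokens = fh.read().split("\n")
    i = 0

    def next_line():
        nonlocal i
        while i < len(tokens) and not tokens[i].strip():
            i += 1
        line = tokens[i]
        i += 1
        return line

    for _ in range(3):
        next_line()
    if "UNSTRUCTURED_GRID" not in next_line():
        raise ValueError("not a VTK unstructured grid")
    n_pts = int(next_line().split()[1])
    pts = np.array([[float(v) for v in next_line().split()] for _ in range(n_pts)])
    n_cells = int(next_line().split()[1])
    tris = []
    for _ in range(n_cells):
        parts = next_line().split()
        if parts[0] != "3":
            raise ValueError("only triangle cells are supported")
        tris.append([int(v) for v in parts[1:]])
    next_line()  # CELL_TYPES
    for _ in range(n_cells):
        next_line()

    cell_data, point_data = {}, {}
    current, n_current = None, 0
    while i < len(tokens):
        line = tokens[i].strip()
        i += 1
        if not line:
            continue
        if line.startswith("CELL_DATA"):
            current, n_current = cell_data, int(line.split()[1])
        elif line.startswith("POINT_DATA"):
            current, n_current = point_data, int(line.split()[1])
        elif line.startswith("SCALARS"):
            name = line.split()[1]
            next_line()  # lookup table
            vals = [float(next_line()) for _ in range(n_current)]
            current[name] = np.array(vals)
        elif line.startswith("VECTORS"):
            name = line.split()[1]
            vals = [[float(v) for v in next_line().split()] for _ in range(n_current)]
            current[name] = np.array(vals)
    cid = cell_data.pop("cell_id", None)
    if cid is None:
        cid = np.arange(n_cells)
    mesh = SurfaceMesh(
        vertices=pts,
        triangles=np.array(tris, dtype=np.int64),
        cell_of_triangle=np.asarray(cid, dtype=np.int64),
    )
    return mesh, cell_data, point_data


# ----------------------------------------------------------------------
# PLY (bare geometry) via trimesh
def write_ply(mesh: SurfaceMesh, path):
    import trimesh

    tm = trimesh.Trimesh(vertices=mesh.vertices, faces=mesh.triangles, process=False)
    with open(path, "wb") as fh:
        fh.write(trimesh.exchange.ply.export_ply(tm, encoding="ascii"))


def read_ply(path):
    """Read bare triangulated geometry; with no cell grouping stored,
    each triangle becomes its own cell."""
    import trimesh

    tm = trimesh.load(path, process=False)
    tris = np.asarray(tm.faces, dtype=np.int64)
    return SurfaceMesh(
        vertices=np.asarray(tm.vertices, dtype=float),
        triangles=tris,
        cell_of_triangle=np.arange(len(tris)),
    )


def write_mesh(mesh: SurfaceMesh, path, fields=None, format: str | None = None):
    """Write a mesh; format 'vtk' or 'ply' (inferred from the suffix).

    ``fields`` are per-triangle arrays (VTK only).
    """
    fmt = format or str(path).rsplit(".", 1)[-1].lower()
    if fmt == "vtk":
        write_vtk(mesh, path, cell_data=fields)
    elif fmt == "ply":
        if fields:
            raise ValueError("PLY output carries bare geometry only")
        write_ply(mesh, path)
    else:
        raise ValueError(f"unknown mesh format {fmt!r}")


def read_mesh(path, format: str | None = None) -> SurfaceMesh:
    fmt = format or str(path).rsplit(".", 1)[-1].lower()
    if fmt == "vtk":
        return read_vtk(path)[0]
    if fmt == "ply":
        return read_ply(path)
    raise ValueError(f"unknown mesh format {fmt!r}")


# ----------------------------------------------------------------------
# per-cell report
def cell_report(mesh: SurfaceMesh, mat: TissueMaterial, result) -> pd.DataFrame:
    """Tabulate the per-cell state of a finished simulation.

    Columns: cell_id, area_rest, area_cur, E_L, E_T, fiber_x/y/z,
    s1, s2 (principal thickness-integrated Cauchy stress), e1, e2
    (principal Almansi strain), aniso_stress, aniso_strain (relative,
    tension-clamped), cos_angle (max stress vs max strain direction).
    """
    s1, s2, ds, _ = principal_fields(result.cell_stress)
    e1, e2, de, _ = principal_fields(result.cell_strain)
    cos = np.abs(np.einsum("ci,ci->c", ds, de))
    return pd.DataFrame(
        {
            "cell_id": np.arange(mesh.n_cells),
            "area_rest": mesh.cell_areas(rest=True),
            "area_cur": mesh.cell_areas(),
            "E_L": mat.E_L,
            "E_T": mat.E_T,
            "fiber_x": mat.fiber[:, 0],
            "fiber_y": mat.fiber[:, 1],
            "fiber_z": mat.fiber[:, 2],
            "s1": s1,
            "s2": s2,
            "e1": e1,
            "e2": e2,
            "aniso_stress": anisotropy_relative(s1, s2),
            "aniso_strain": anisotropy_relative(e1, e2),
            "cos_angle": cos,
        }
    )


def write_cell_report(df: pd.DataFrame, path):
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")
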