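"""Canned, reproducible experiment recipes.

Each recipe bundles a template, printed material parameters and a
feedback mode into one named run; ``run_recipe`` executes it and writes
VTK + TSV outputs, a plain-text log and the fully resolved
configuration into the output directory.  Numeric defaults follow the
published parameter set (pressures 0.05–0.2 MPa, matrix moduli
40–50 MPa, fiber moduli 100–150 MPa, ν = 0.2, wall thickness 1 µm,
fiber model K = 0.4, n = 2); geometric dimensions and update rates are
package defaults documented in the methods note.
"""

from __future__ import annotations

import copy
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import analysis
from .config import SimulationConfig, config_from_dict, run_simulation
from .dynamics import LoadSpec, relax_to_equilibrium
from .io import cell_report, write_cell_report, write_vtk
from .mechanics import TissueMaterial, evaluate_mechanics, principal_fields
from .templates import make_square_patch

# cylinder runs are desk-scaled (length 300 µm, cell size 20 µm) and the
# update rates sit in the rate-insensitive regime at these problem sizes
_CYL = {
    "template": {"kind": "cylinder", "radius": 100.0, "length": 300.0, "cell_size": 20.0},
    "pressure": 0.1,
    "thickness": 1.0,
    "E_matrix": 50.0,
    "E_fiber": 120.0,
    "nu": 0.2,
    "feedback": {"mode": "msd", "K": 0.4, "n": 2.0, "k_dir": 0.2, "k_mat": 0.1},
    "max_outer": 150,
    "seed": 1,
}

RECIPES: dict[str, dict] = {
    "cylinder-static": {
        **copy.deepcopy(_CYL),
        "initial_fiber": "circumferential",
        "feedback": {**_CYL["feedback"], "update_direction": False},
    },
    "cylinder-msd": copy.deepcopy(_CYL),
    "cylinder-osd": {
        **copy.deepcopy(_CYL),
        "initial_fiber": "circumferential",
        "feedback": {**_CYL["feedback"], "mode": "osd"},
    },
    "paraboloid-msd": {
        "template": {"kind": "paraboloid", "apex_curvature_radius": 50.0, "height": 90.0,
                     "cell_size": 10.0},
        "pressure": 0.05,
        "thickness": 1.0,
        "E_matrix": 40.0,
        "E_fiber": 100.0,
        "nu": 0.2,
        "feedback": {"mode": "msd", "measure": "absolute", "response": "hill_odds",
                     "K": 0.4, "n": 2.0, "k_dir": 0.2, "k_mat": 0.1},
        "max_outer": 250,
        "seed": 1,
    },
    "meristem-msd": {
        "template": {"kind": "meristem", "dome_radius": 50.0, "primordium_radius": 20.0,
                     "primordium_offset": 55.0, "meristem_height": 90.0, "cell_size": 10.0},
        "pressure": 0.08,
        "thickness": 1.0,
        "E_matrix": 50.0,
        "E_fiber": 150.0,
        "nu": 0.2,
        "feedback": {"mode": "msd", "measure": "absolute", "response": "hill_odds",
                     "K": 0.4, "n": 2.0, "k_dir": 0.2, "k_mat": 0.1},
        "max_outer": 250,
        "seed": 1,
    },
    "axial-load": {
        **copy.deepcopy(_CYL),
        "axial_load": {"force_total": 16000.0, "band": (100.0, 200.0)},
    },
}
# the orthogonal-strain meristem variant also drives the fiber model by
# the strain anisotropy (the supplementary form of the study)
RECIPES["meristem-osd"] = {
    **copy.deepcopy(RECIPES["meristem-msd"]),
    "feedback": {**RECIPES["meristem-msd"]["feedback"], "mode": "osd",
                 "measure_source": "strain"},
}

# analysis-type recipes are parameterized function calls, not simulations
ANALYSIS_RECIPES = {
    "phase-static": {"mode": "static", "n_fa": 11, "n_er": 11, "nu": 0.2},
    "phase-msd": {"mode": "msd", "n_fa": 7, "n_er": 7, "nu": 0.2},
    "phase-osd": {"mode": "osd", "n_fa": 7, "n_er": 7, "nu": 0.2},
    "poisson-sweep": {"nus": [0.2, 0.3, 0.4], "n_fa": 9, "n_er": 9},
    "K-sweep": {"Ks": [0.2, 0.4, 0.6]},
    "shapes": {"aspect_ratios": [1.0, 1.5, 2.0], "seed": 1},
    "stability": {"angles_deg": [2.0, 5.0, 10.0, 20.0, 45.0]},
    "patch-uniaxial": {"forces": [1.0, 2.0, 4.0, 6.0, 8.0], "nus": [0.2, 0.4]},
    "patch-biaxial-aniso": {"n_angles": 13},
}


def available_recipes():
    return sorted(list(RECIPES) + list(ANALYSIS_RECIPES))


def _apply_overrides(d: dict, sets: dict):
    for key, value in (sets or {}).items():
        parts = key.split(".")
        node = d
        for p in parts[:-1]:
            if p not in node or not isinstance(node[p], dict):
                node[p] = {}
            node = node[p]
        node[parts[-1]] = value


def _log(lines, msg):
    stamp = time.strftime("%Y-%m-%d %H:%M:%S")
    lines.append(f"[{stamp}] {msg}")


# ----------------------------------------------------------------------
# special patch experiments
def patch_uniaxial_curve(forces, nus, E=400.0, thickness=0.01, side=1.0, n_divisions=10):
    """Uniaxial stretching of the clamped-edge square patch: principal
    (thickness-integrated, per-thickness) stress and area ratio versus
    corner deflection, for each Poisson ratio."""
    rows = []
    for nu in nus:
        for f in forces:
            mesh = make_square_patch(side, n_divisions)
            x = mesh.rest_vertices
            left = np.nonzero(x[:, 0] < 1e-9)[0]
            right = np.nonzero(x[:, 0] > side - 1e-9)[0]
            loads_f = np.zeros_like(x)
            loads_f[right, 0] = f / len(right)
            fixed = np.zeros((mesh.n_vertices, 3), dtype=bool)
            fixed[:, 2] = True
            mat = TissueMaterial.isotropic(mesh.n_cells, E, nu, thickness)
            loads = LoadSpec(vertex_forces=loads_f, clamped=left, fixed_dofs=fixed)
            relax_to_equilibrium(mesh, mat, loads)
            st = evaluate_mechanics(mesh, mat)
            s1, _, _, _ = principal_fields(st.cauchy)
            w = mesh.triangle_areas()
            corner = int(np.argmin(np.linalg.norm(x - [side, side, 0.0], axis=1)))
            rows.append(
                {
                    "nu": nu,
                    "force": f,
                    "deflection": float(mesh.vertices[corner, 0] - side),
                    "principal_stress": float((s1 * w).sum() / w.sum() / thickness),
                    "area_ratio": float(mesh.triangle_areas().sum()
                                        / mesh.triangle_areas(rest=True).sum()),
                }
            )
    return pd.DataFrame(rows)


def patch_biaxial_anisotropy_curve(
    n_angles=13, E_T=400.0, E_L=800.0, nu=0.2, tractions=(0.8, 0.2), thickness=0.01
):
    """First/second principal stress of the anisotropic patch as the
    fiber direction is rotated from the maximal load direction."""
    rows = []
    for ang in np.linspace(0.0, 180.0, n_angles):
        th = np.radians(ang)
        mesh = make_square_patch(1.0, 4)
        loads = analysis.patch_biaxial_loads(mesh, tractions[0], tractions[1])
        mat = TissueMaterial.uniform(
            mesh.n_cells, E_L=E_L, E_T=E_T, fiber=[np.cos(th), np.sin(th), 0.0],
            nu=nu, thickness=thickness,
        )
        relax_to_equilibrium(mesh, mat, loads)
        st = evaluate_mechanics(mesh, mat)
        s1, s2, _, _ = principal_fields(st.cauchy)
        w = mesh.triangle_areas()
        rows.append(
            {
                "fiber_angle_deg": float(ang),
                "s1": float((s1 * w).sum() / w.sum()),
                "s2": float((s2 * w).sum() / w.sum()),
            }
        )
    return pd.DataFrame(rows)


# ----------------------------------------------------------------------
def run_recipe(name_or_path, out_dir, sets: dict | None = None, seed: int | None = None) -> Path:
    """Run a named recipe (or a YAML config file) and write results.

    Writes: resolved ``config.yaml``, ``run.log``, and per-recipe TSV
    (plus VTK snapshots for simulation recipes) into ``out_dir``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log: list[str] = []
    name = str(name_or_path)

    if name in ANALYSIS_RECIPES:
        params = copy.deepcopy(ANALYSIS_RECIPES[name])
        for k in sets or {}:
            if k not in params:
                raise ValueError(f"unknown option {k!r} for recipe {name!r}")
        params.update(sets or {})
        if seed is not None and "seed" in params:
            params["seed"] = seed
        _log(log, f"recipe {name}: {params}")
        df = _run_analysis_recipe(name, params, log)
        df.to_csv(out / f"{name}.tsv", sep="\t", index=False, float_format="%.10g")
        (out / "config.yaml").write_text(yaml.safe_dump({"recipe": name, **params}))
    else:
        if name in RECIPES:
            raw = copy.deepcopy(RECIPES[name])
        else:
            p = Path(name)
            if not p.exists():
                raise ValueError(
                    f"unknown recipe or missing config file {name!r}; "
                    f"available: {', '.join(available_recipes())}"
                )
            raw = yaml.safe_load(p.read_text())
            name = p.stem
        _apply_overrides(raw, sets or {})
        if seed is not None:
            raw["seed"] = seed
        cfg = config_from_dict(raw)
        _log(log, f"recipe {name}: template={cfg.template.kind} "
                  f"p={cfg.pressure} mode={cfg.feedback.mode} seed={cfg.seed}")
        t0 = time.time()
        mesh, mat, res = run_simulation(cfg)
        _log(log, f"stationary={res.converged} outer_iterations={res.n_outer} "
                  f"elapsed={time.time() - t0:.1f}s")
        for h in res.history[-5:]:
            _log(log, f"  outer {h['iter']}: dangle={h['dangle_deg']:.4f} deg "
                      f"dmod={h['dmod']:.2e} mean_a={h['mean_a']:.3f}")
        df = cell_report(mesh, mat, res)
        write_cell_report(df, out / "cells.tsv")
        s1, s2, d1, _ = principal_fields(res.cell_stress)
        e1, e2, de1, _ = principal_fields(res.cell_strain)
        cid = mesh.cell_of_triangle
        write_vtk(
            mesh, out / "mesh.vtk",
            cell_data={
                "s1": s1[cid], "s2": s2[cid], "e1": e1[cid], "e2": e2[cid],
                "E_L": mat.E_L[cid], "E_T": mat.E_T[cid], "fiber": mat.fiber[cid],
            },
        )
        (out / "config.yaml").write_text(yaml.safe_dump(cfg.model_dump()))
    (out / "run.log").write_text("\n".join(log) + "\n")
    return out


def _run_analysis_recipe(name, params, log) -> pd.DataFrame:
    if name.startswith("phase-"):
        fas = np.linspace(0, 1, params["n_fa"])
        ers = np.linspace(1, 5, params["n_er"])
        return analysis.phase_diagram(fas, ers, mode=params["mode"], nu=params["nu"])
    if name == "poisson-sweep":
        frames = []
        for nu in params["nus"]:
            df = analysis.phase_diagram(
                np.linspace(0, 1, params["n_fa"]),
                np.linspace(1, 5, params["n_er"]),
                mode="static", nu=nu,
            )
            df["nu"] = nu
            frames.append(df)
        return pd.concat(frames, ignore_index=True)
    if name == "K-sweep":
        frames = []
        for K in params["Ks"]:
            raw = copy.deepcopy(RECIPES["paraboloid-msd"])
            raw["feedback"]["K"] = K
            cfg = config_from_dict(raw)
            mesh, mat, res = run_simulation(cfg)
            df = analysis.zonation_map(mesh, res, mat)
            df["K"] = K
            frames.append(df)
            _log(log, f"K={K}: zones "
                      f"{df[df.interior].zone.value_counts().to_dict()}")
        return pd.concat(frames, ignore_index=True)
    if name == "shapes":
        return analysis.feedback_shape_comparison(
            aspect_ratios=params["aspect_ratios"], seed=params["seed"]
        )
    if name == "stability":
        rows = []
        for ang in params["angles_deg"]:
            msd, osd = analysis.fixed_point_response(ang)
            rows.append({"fiber_angle_deg": ang, "msd_signal_deg": msd,
                         "osd_signal_deg": osd})
        return pd.DataFrame(rows)
    if name == "patch-uniaxial":
        return patch_uniaxial_curve(params["forces"], params["nus"])
    if name == "patch-biaxial-aniso":
        return patch_biaxial_anisotropy_curve(params["n_angles"])
    raise ValueError(f"unknown analysis recipe {name!r}")
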