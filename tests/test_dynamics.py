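"""Loads, boundary conditions and relaxation solvers."""

import numpy as np
import pytest

from morphospring import (
    ElementInversionError,
    LoadSpec,
    SolverConfig,
    TissueMaterial,
    boundary_loops,
    enclosed_volume,
    evaluate_mechanics,
    make_cylinder,
    make_ellipsoid,
    make_square_patch,
    pressure_forces,
    relax_to_equilibrium,
    run_feedback_simulation,
    total_elastic_energy,
)
from morphospring.dynamics import total_forces

from conftest import fresh_cylinder_setup, isotropic_material


class TestPressureForces:
    def test_zero_pressure(self, small_patch):
        assert np.abs(pressure_forces(small_patch, 0.0)).max() == 0.0

    def test_closed_surface_net_force_vanishes(self):
        m = make_ellipsoid((1.0, 1.0, 1.0), 0.4, seed=1)
        f = pressure_forces(m, 0.7)
        assert np.abs(f.sum(axis=0)).max() < 1e-9 * np.abs(f).max()

    def test_flat_patch_total_force(self):
        m = make_square_patch(2.0, 3)
        f = pressure_forces(m, 0.25)
        total = np.linalg.norm(f.sum(axis=0))
        assert total == pytest.approx(0.25 * 4.0, rel=1e-12)

    def test_capped_tube_volume(self):
        m = make_cylinder(50.0, 100.0, 16.0, seed=3)
        loops = boundary_loops(m)
        vol = enclosed_volume(m, cap_loops=loops)
        assert vol == pytest.approx(np.pi * 50.0**2 * 100.0, rel=0.01)

    def test_cap_load_is_volume_gradient(self, small_cylinder, rng):
        mesh, loads = small_cylinder
        x = mesh.rest_vertices.copy()
        f = pressure_forces(mesh, 0.1, x, loads.cap_loops)
        free = loads.dof_mask(mesh)
        eps = 1e-4
        for _ in range(6):
            i, k = int(rng.integers(mesh.n_vertices)), int(rng.integers(3))
            if not free[i, k]:
                continue
            xp = x.copy(); xp[i, k] += eps
            xm = x.copy(); xm[i, k] -= eps
            fd = 0.1 * (enclosed_volume(mesh, xp, loads.cap_loops)
                        - enclosed_volume(mesh, xm, loads.cap_loops)) / (2 * eps)
            assert fd == pytest.approx(f[i, k], rel=1e-3, abs=1e-6)


class TestRelaxation:
    def test_no_load_immediate_convergence(self, small_patch):
        mesh = small_patch.copy()
        mat = isotropic_material(mesh, E=400.0, thickness=0.01)
        res = relax_to_equilibrium(mesh, mat, LoadSpec(pressure=0.0))
        assert res.converged
        assert np.abs(res.positions - mesh.rest_vertices).max() < 1e-9

    def test_uniaxial_patch_matches_minimizer_oracle(self):
        """Damped-dynamics equilibrium equals a direct scipy minimization
        of the same potential (independent route) within 0.5%."""
        from scipy.optimize import minimize

        mesh = make_square_patch(1.0, 3)
        x0 = mesh.rest_vertices
        left = np.nonzero(x0[:, 0] < 1e-9)[0]
        right = np.nonzero(x0[:, 0] > 1 - 1e-9)[0]
        dead = np.zeros_like(x0)
        dead[right, 0] = 8.0 / len(right)
        fixed = np.zeros((mesh.n_vertices, 3), dtype=bool)
        fixed[:, 2] = True
        mat = isotropic_material(mesh, E=400.0, nu=0.2, thickness=0.01)
        loads = LoadSpec(vertex_forces=dead, clamped=left, fixed_dofs=fixed)

        free = loads.dof_mask(mesh)
        idx = np.nonzero(free.ravel())[0]
        base = x0.ravel()

        def fun(q):
            x = base.copy()
            x[idx] = q
            x = x.reshape(-1, 3)
            return (total_elastic_energy(mesh, mat, x)
                    - float(np.einsum("ij,ij->", dead, x)))

        oracle = minimize(fun, base[idx], method="L-BFGS-B",
                          options={"maxiter": 20000, "ftol": 1e-14})
        x_oracle = base.copy()
        x_oracle[idx] = oracle.x
        x_oracle = x_oracle.reshape(-1, 3)

        mesh2 = mesh.copy()
        res = relax_to_equilibrium(
            mesh2, mat, loads,
            SolverConfig(method="rk45_adaptive", dt=1e-4, max_steps=20000, tol=2e-4),
        )
        defl_oracle = x_oracle[:, 0].max() - 1.0
        defl = res.positions[:, 0].max() - 1.0
        assert defl == pytest.approx(defl_oracle, rel=0.005)

    def test_integrator_agreement(self):
        """Equilibria are integrator- and damping-independent: the damped
        RK flows return a perturbed pressurized patch to the same
        equilibrium the minimizer finds."""
        base = make_square_patch(10.0, 3)
        loads = LoadSpec(pressure=0.05)
        ref_mesh = base.copy()
        mat = isotropic_material(ref_mesh, E=20.0, thickness=0.1)
        relax_to_equilibrium(ref_mesh, mat, loads)
        bulge = np.abs(ref_mesh.vertices[:, 2]).max()
        assert bulge > 0.1  # the patch really inflated
        rng = np.random.default_rng(0)
        for method, damping in [("rk45_adaptive", 1.0), ("rk45_adaptive", 5.0),
                                ("rk4_fixed", 1.0)]:
            m = base.copy()
            m.vertices = ref_mesh.vertices + 0.03 * bulge * rng.normal(
                size=ref_mesh.vertices.shape)
            m.vertices[m.boundary_vertices] = base.rest_vertices[m.boundary_vertices]
            cfg = SolverConfig(method=method, damping=damping, dt=2e-3 * damping,
                               max_steps=40000, tol=3e-4)
            res = relax_to_equilibrium(m, isotropic_material(m, E=20.0, thickness=0.1),
                                       loads, cfg)
            assert res.converged, (method, damping)
            assert np.abs(res.positions - ref_mesh.vertices).max() < 0.01 * bulge

    def test_energy_decreases_along_damped_flow(self, small_cylinder):
        mesh, loads = small_cylinder
        m = mesh.copy()
        mat = isotropic_material(m, E=110.0)
        x = m.rest_vertices.copy()
        free = loads.dof_mask(m)
        dt = 2e-3

        def potential(x):
            return (total_elastic_energy(m, mat, x)
                    - loads.pressure * enclosed_volume(m, x, loads.cap_loops))

        energies = [potential(x)]
        for _ in range(50):
            f = total_forces(m, mat, loads, x)
            f[~free] = 0.0
            x = x + dt * f
            energies.append(potential(x))
        assert all(b <= a + 1e-9 for a, b in zip(energies, energies[1:]))

    def test_element_inversion_detected(self, small_patch):
        mesh = small_patch.copy()
        mat = isotropic_material(mesh, E=400.0, thickness=0.01)
        x = mesh.rest_vertices.copy()
        tri = mesh.triangles[0]
        x[tri[2]] = 0.5 * (x[tri[0]] + x[tri[1]])  # collapse one triangle
        with pytest.raises(ElementInversionError):
            evaluate_mechanics(mesh, mat, x)

    def test_nonconvergence_reported_not_silent(self, small_cylinder):
        mesh, loads = small_cylinder
        m = mesh.copy()
        mat = isotropic_material(m, E=110.0)
        res = relax_to_equilibrium(
            m, mat, loads, SolverConfig(method="rk4_fixed", dt=1e-4, max_steps=50)
        )
        assert not res.converged
        assert res.residual > 0

    def test_feedback_none_equals_plain_relax(self, small_cylinder):
        mesh, loads = small_cylinder
        m1, m2 = mesh.copy(), mesh.copy()
        mat1 = isotropic_material(m1, E=110.0)
        mat2 = isotropic_material(m2, E=110.0)
        relax_to_equilibrium(m1, mat1, loads)
        res = run_feedback_simulation(m2, mat2, loads, None)
        assert np.abs(m1.vertices - m2.vertices).max() < 1e-6


class TestDiscretizationConvergence:
    def test_midsection_stress_mesh_independent(self):
        """Refining the tessellation changes midsection equilibrium
        stresses by only a few percent."""
        stresses = {}
        for cs in (24.0, 16.0):
            mesh, loads = fresh_cylinder_setup(radius=60.0, length=180.0,
                                               cell_size=cs, seed=2)
            mat = isotropic_material(mesh, E=110.0)
            relax_to_equilibrium(mesh, mat, loads)
            st = evaluate_mechanics(mesh, mat)
            z = mesh.vertices[mesh.triangles].mean(1)[:, 2]
            mid = (z > 60) & (z < 120)
            from morphospring import principal_fields
            s1, *_ = principal_fields(st.cauchy)
            stresses[cs] = s1[mid].mean()
        assert stresses[24.0] == pytest.approx(stresses[16.0], rel=0.03)
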