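"""Mechanics core: strain measures, constitutive law, forces, spectra."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from morphospring import (
    MaterialState,
    TissueMaterial,
    almansi_from_edges,
    cauchy_stress,
    evaluate_mechanics,
    green_lagrange_from_edges,
    lame_plane_stress,
    mises_equivalent_strain,
    principal_decomposition,
    second_piola_kirchhoff,
    strain_energy_density,
    total_elastic_energy,
)


class TestLame:
    @pytest.mark.parametrize(
        "E,nu,lam,mu",
        [
            (400.0, 0.2, 83.3333333, 166.6666667),
            (50.0, 0.2, 10.4166667, 20.8333333),
            (123.0, 0.0, 0.0, 61.5),
        ],
    )
    def test_plane_stress_values(self, E, nu, lam, mu):
        got = lame_plane_stress(E, nu)
        assert got.lam == pytest.approx(lam, rel=1e-6)
        assert got.mu == pytest.approx(mu, rel=1e-6)

    def test_invalid(self):
        with pytest.raises(ValueError):
            lame_plane_stress(400.0, 1.0)
        with pytest.raises(ValueError):
            lame_plane_stress(-1.0, 0.2)


class TestGreenLagrange:
    def test_identity_deformation(self):
        E = green_lagrange_from_edges([1.0, 1.2, 0.9], [1.0, 1.2, 0.9])
        assert np.abs(E).max() < 1e-12

    def test_uniform_scaling(self):
        E = green_lagrange_from_edges([1, 1, 1], np.array([1, 1, 1]) * 1.1)
        assert E == pytest.approx(0.5 * (1.1**2 - 1) * np.eye(2), abs=1e-12)

    def test_matches_explicit_embedding(self, rng):
        """Brute-force oracle: build an explicit affine map between two
        embedded triangles and compare strain invariants."""
        for _ in range(20):
            P = rng.normal(size=(3, 2))
            while abs(np.linalg.det(np.stack([P[1] - P[0], P[2] - P[0]]))) < 0.1:
                P = rng.normal(size=(3, 2))
            F = rng.normal(size=(2, 2)) * 0.3 + np.eye(2)
            if np.linalg.det(F) < 0.2:
                continue
            Q = P @ F.T
            rest = [np.linalg.norm(P[1] - P[0]), np.linalg.norm(P[2] - P[1]),
                    np.linalg.norm(P[0] - P[2])]
            cur = [np.linalg.norm(Q[1] - Q[0]), np.linalg.norm(Q[2] - Q[1]),
                   np.linalg.norm(Q[0] - Q[2])]
            E = green_lagrange_from_edges(rest, cur)
            E_oracle = 0.5 * (F.T @ F - np.eye(2))
            # frames differ by a rotation: compare invariants
            assert np.trace(E) == pytest.approx(np.trace(E_oracle), rel=1e-8, abs=1e-10)
            assert np.linalg.det(E) == pytest.approx(np.linalg.det(E_oracle), rel=1e-7, abs=1e-10)

    def test_degenerate_rejected(self):
        with pytest.raises(ValueError):
            green_lagrange_from_edges([1.0, 1.0, 2.0], [1, 1, 1])


class TestAlmansi:
    def test_uniform_stretch_closed_form(self):
        s = 1.17
        e = almansi_from_edges([1, 1, 1], np.array([1, 1, 1]) * s)
        assert e == pytest.approx(0.5 * (1 - s**-2) * np.eye(2), abs=1e-12)

    def test_small_strain_agrees_with_green(self):
        rest = [1.0, 1.1, 0.95]
        cur = [1.002, 1.1015, 0.9507]
        E = green_lagrange_from_edges(rest, cur)
        e = almansi_from_edges(rest, cur)
        assert np.abs(E - e).max() < 5 * np.abs(E).max() ** 2 + 1e-12


class TestEnergyAndStress:
    def _mat(self, E_L=800.0, E_T=400.0, nu=0.2, fiber=(1, 0, 0)):
        return MaterialState(E_T=E_T, E_L=E_L, nu=nu, fiber=np.array(fiber, float),
                             thickness=0.01)

    def test_zero_strain_zero_energy_stress(self):
        m = self._mat()
        assert strain_energy_density(np.zeros((2, 2)), m) == 0.0
        assert np.abs(second_piola_kirchhoff(np.zeros((2, 2)), m)).max() == 0.0

    def test_isotropic_limit_fiber_free(self, rng):
        """With E_L = E_T the anisotropic part vanishes for every strain
        and fiber direction."""
        m0 = self._mat(E_L=400.0, E_T=400.0)
        for _ in range(10):
            A = rng.normal(size=(2, 2)) * 0.1
            E = 0.5 * (A + A.T)
            th = rng.uniform(0, np.pi)
            w1 = strain_energy_density(E, m0, fiber2=[np.cos(th), np.sin(th)])
            w2 = strain_energy_density(E, m0, fiber2=[1.0, 0.0])
            assert w1 == pytest.approx(w2, rel=1e-12, abs=1e-15)

    def test_isotropic_strain_fiber_free(self, rng):
        m = self._mat()
        E = 0.03 * np.eye(2)
        vals = [
            strain_energy_density(E, m, fiber2=[np.cos(t), np.sin(t)])
            for t in rng.uniform(0, np.pi, 8)
        ]
        assert np.ptp(vals) < 1e-14

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(
        e11=st.floats(-0.12, 0.12),
        e22=st.floats(-0.12, 0.12),
        e12=st.floats(-0.12, 0.12),
        ratio=st.floats(1.0, 4.0),
        theta=st.floats(0, np.pi),
        nu=st.floats(0.0, 0.45),
    )
    def test_energy_nonnegative_small_strains(self, e11, e22, e12, ratio, theta, nu):
        """St.V-K energy with E_L >= E_T is positive semidefinite for
        moderate strains."""
        E = np.array([[e11, e12], [e12, e22]])
        m = MaterialState(E_T=100.0, E_L=100.0 * ratio, nu=nu,
                          fiber=np.array([np.cos(theta), np.sin(theta), 0.0]))
        assert strain_energy_density(E, m) >= -1e-12

    def test_spk_is_energy_gradient(self, rng):
        m = self._mat()
        A = rng.normal(size=(2, 2)) * 0.05
        E = 0.5 * (A + A.T)
        S = second_piola_kirchhoff(E, m)
        eps = 1e-7
        for i in range(2):
            for j in range(2):
                dE = np.zeros((2, 2))
                dE[i, j] += 0.5 * eps
                dE[j, i] += 0.5 * eps
                fd = (strain_energy_density(E + dE, m) - strain_energy_density(E - dE, m)) / (2 * eps)
                assert fd == pytest.approx(S[i, j], rel=1e-5, abs=1e-9)

    def test_cauchy_zero_at_rest(self):
        m = self._mat()
        s = cauchy_stress([1, 1.2, 0.9], [1, 1.2, 0.9], m)
        assert np.abs(s).max() < 1e-12


class TestNodalForces:
    def test_forces_are_minus_energy_gradient(self, small_patch, rng):
        mesh = small_patch
        mat = TissueMaterial.uniform(mesh.n_cells, E_L=800, E_T=400,
                                     fiber=[1, 0.4, 0], nu=0.2, thickness=0.01)
        x = mesh.rest_vertices + 0.04 * rng.normal(size=(mesh.n_vertices, 3))
        forces = evaluate_mechanics(mesh, mat, x).forces
        eps = 1e-6
        idx = rng.choice(mesh.n_vertices, 8, replace=False)
        for i in idx:
            for k in range(3):
                xp = x.copy(); xp[i, k] += eps
                xm = x.copy(); xm[i, k] -= eps
                fd = (total_elastic_energy(mesh, mat, xp)
                      - total_elastic_energy(mesh, mat, xm)) / (2 * eps)
                assert -fd == pytest.approx(forces[i, k], rel=1e-5, abs=1e-8)

    def test_self_equilibrated_and_frame_indifferent(self, small_patch, rng):
        mesh = small_patch
        mat = TissueMaterial.uniform(mesh.n_cells, E_L=800, E_T=400,
                                     fiber=[1, 0.3, 0], nu=0.3, thickness=0.01)
        x = mesh.rest_vertices + 0.05 * rng.normal(size=(mesh.n_vertices, 3))
        st_ = evaluate_mechanics(mesh, mat, x)
        assert np.abs(st_.forces.sum(axis=0)).max() < 1e-10  # translation
        # rotation equivariance + energy invariance
        th = 0.7
        R = np.array([[np.cos(th), -np.sin(th), 0], [np.sin(th), np.cos(th), 0], [0, 0, 1.0]])
        st2 = evaluate_mechanics(mesh, mat, x @ R.T)
        assert st2.energy == pytest.approx(st_.energy, rel=1e-12)
        assert np.abs(st2.forces - st_.forces @ R.T).max() < 1e-10

    def test_undeformed_forces_zero(self, small_patch):
        mat = TissueMaterial.isotropic(small_patch.n_cells, 400.0, 0.2, 0.01)
        f = evaluate_mechanics(small_patch, mat, small_patch.rest_vertices).forces
        assert np.abs(f).max() < 1e-12


class TestPrincipal:
    def test_diag(self):
        s1, s2, d1, d2, deg = principal_decomposition(np.diag([2.0, 1.0]))
        assert (s1, s2) == (2.0, 1.0)
        assert abs(abs(d1 @ [1, 0]) - 1) < 1e-12
        assert not deg

    def test_isotropic_degenerate(self):
        *_, deg = principal_decomposition(np.eye(2) * 3.0)
        assert deg

    def test_reconstruction(self, rng):
        for _ in range(30):
            A = rng.normal(size=(2, 2))
            T = 0.5 * (A + A.T)
            s1, s2, d1, d2, _ = principal_decomposition(T)
            R = s1 * np.outer(d1, d1) + s2 * np.outer(d2, d2)
            assert np.abs(R - T).max() < 1e-12
            assert s1 >= s2
            assert abs(d1 @ d2) < 1e-12


class TestMises:
    @pytest.mark.parametrize(
        "tensor,expected",
        [
            (0.04 * np.eye(2), 0.04),  # isotropic
            (np.diag([0.05, 0.0]), 0.05),  # uniaxial
            (np.diag([0.03, -0.03]), np.sqrt(3) * 0.03),  # pure shear
        ],
    )
    def test_closed_forms(self, tensor, expected):
        assert mises_equivalent_strain(tensor) == pytest.approx(expected, rel=1e-12)


class TestSmallStrainRecovery:
    """The anisotropic law recovers E_L along the fiber and E_T across it
    (the contract pinning the equipartitioned energy form)."""

    @pytest.mark.parametrize("direction,expected", [("x", 800.0), ("y", 400.0)])
    def test_uniaxial_stiffness(self, direction, expected):
        from morphospring import LoadSpec, relax_to_equilibrium
        from morphospring.analysis import patch_biaxial_loads
        from morphospring.mechanics import principal_fields
        from morphospring import make_square_patch

        mesh = make_square_patch(1.0, 4)
        tr = 1e-3 * expected * 0.01
        loads = patch_biaxial_loads(mesh, tr if direction == "x" else 0.0,
                                    tr if direction == "y" else 0.0)
        mat = TissueMaterial.uniform(mesh.n_cells, E_L=800.0, E_T=400.0,
                                     fiber=[1, 0, 0], nu=0.2, thickness=0.01)
        relax_to_equilibrium(mesh, mat, loads)
        st_ = evaluate_mechanics(mesh, mat)
        s1, *_ = principal_fields(st_.almansi)
        stiffness = (tr / 0.01) / s1.mean()
        assert stiffness == pytest.approx(expected, rel=0.01)
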