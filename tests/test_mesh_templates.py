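"""Template generators: counts, geometry, orientation, determinism."""

import numpy as np
import pytest

from morphospring import (
    estimate_principal_curvatures,
    make_cylinder,
    make_ellipsoid,
    make_meristem,
    make_paraboloid,
    make_square_patch,
    shape_anisotropy,
)


class TestSquarePatch:
    def test_minimal_centroid_fan(self):
        m = make_square_patch(1.0, 1)
        assert m.n_cells == 1
        assert m.n_vertices == 5  # 4 corners + centroid
        assert m.n_triangles == 4

    def test_counts_and_area(self):
        m = make_square_patch(1.0, 10)
        assert m.n_cells == 100
        assert m.n_triangles == 400
        assert m.triangle_areas(rest=True).sum() == pytest.approx(1.0, rel=1e-12)

    def test_boundary_and_orientation(self):
        m = make_square_patch(2.0, 4)
        assert m.check_orientation()
        x = m.rest_vertices[m.boundary_vertices]
        on_edge = (
            (np.abs(x[:, 0]) < 1e-12) | (np.abs(x[:, 0] - 2) < 1e-12)
            | (np.abs(x[:, 1]) < 1e-12) | (np.abs(x[:, 1] - 2) < 1e-12)
        )
        assert on_edge.all()

    @pytest.mark.parametrize("args", [(-1.0, 2), (1.0, 0)])
    def test_invalid_arguments(self, args):
        with pytest.raises(ValueError):
            make_square_patch(*args)


class TestCylinder:
    def test_on_surface_and_area(self):
        m = make_cylinder(100.0, 400.0, 15.0, seed=1)
        r = np.linalg.norm(m.rest_vertices[:, :2], axis=1)
        assert np.abs(r - 100.0).max() < 1e-9
        lateral = 2 * np.pi * 100.0 * 400.0
        assert m.triangle_areas(rest=True).sum() == pytest.approx(lateral, rel=0.02)
        assert m.check_orientation()

    def test_outward_orientation(self):
        m = make_cylinder(60.0, 150.0, 15.0, seed=2)
        n = m.triangle_normals(rest=True)
        c = m.rest_vertices[m.triangles].mean(axis=1)
        radial = np.column_stack([c[:, 0], c[:, 1], np.zeros(len(c))])
        assert (np.einsum("ij,ij->i", n, radial) > 0).all()

    def test_two_boundary_rims(self):
        m = make_cylinder(60.0, 150.0, 15.0, seed=2)
        z = m.rest_vertices[m.boundary_vertices, 2]
        assert set(np.round(z, 6)) == {0.0, 150.0}

    def test_determinism(self):
        a = make_cylinder(100.0, 200.0, 18.0, seed=7)
        b = make_cylinder(100.0, 200.0, 18.0, seed=7)
        assert np.array_equal(a.vertices, b.vertices)
        assert np.array_equal(a.triangles, b.triangles)
        c = make_cylinder(100.0, 200.0, 18.0, seed=8)
        assert not np.array_equal(a.vertices, c.vertices)

    def test_cell_size_error(self):
        with pytest.raises(ValueError):
            make_cylinder(10.0, 100.0, 12.0, seed=0)

    def test_centroid_fan_structure(self):
        m = make_cylinder(60.0, 120.0, 15.0, seed=1)
        # every triangle of a cell shares the cell's centroid vertex
        for c in range(0, m.n_cells, 17):
            tris = m.triangles[m.cell_of_triangle == c]
            assert (tris[:, 0] == m.centroid_vertex[c]).all()

    def test_triangle_inequality_strict(self):
        m = make_cylinder(60.0, 120.0, 15.0, seed=1)
        l = m.rest_edge_lengths()
        s = np.sort(l, axis=1)
        assert (s[:, 0] + s[:, 1] > s[:, 2] * (1 + 1e-9)).all()


class TestParaboloid:
    def test_rim_at_height(self):
        m = make_paraboloid(50.0, 40.0, 10.0, seed=1)
        z = m.rest_vertices[m.boundary_vertices, 2]
        assert np.abs(z - 40.0).max() < 1e-9

    def test_apex_curvature_isotropic(self):
        m = make_paraboloid(50.0, 40.0, 10.0, seed=1)
        apex = int(np.argmin(m.rest_vertices[:, 2]))
        k1, k2 = estimate_principal_curvatures(m, apex)
        assert k1 == pytest.approx(1 / 50.0, rel=0.05)
        assert k2 == pytest.approx(1 / 50.0, rel=0.05)

    def test_cell_count_scale(self):
        m = make_paraboloid(50.0, 40.0, 10.0, seed=1)
        planar = np.pi * 2 * 50.0 * 40.0  # disk r^2 = 2 R0 h
        assert 0.7 * planar / 100.0 < m.n_cells < 1.4 * planar / 100.0

    def test_surface_equation(self):
        m = make_paraboloid(50.0, 40.0, 10.0, seed=1)
        x = m.rest_vertices
        r2 = x[:, 0] ** 2 + x[:, 1] ** 2
        assert np.abs(x[:, 2] - r2 / 100.0).max() < 1e-9


class TestMeristem:
    def test_valley_is_saddle(self):
        m = make_meristem(50.0, 20.0, seed=1)
        # somewhere on the path between the two apices the surface is a
        # saddle: principal curvatures of opposite sign
        cx = m.info["primordium_center"][0]
        x = m.rest_vertices
        cand = np.nonzero((np.abs(x[:, 1]) < 8) & (x[:, 0] > 0.3 * cx)
                          & (x[:, 0] < 0.8 * cx))[0]
        curvs = [estimate_principal_curvatures(m, int(v)) for v in cand]
        assert any(k1 > 0 > k2 for k1, k2 in curvs)

    def test_primordium_apex_isotropic_curvature(self):
        m = make_meristem(50.0, 20.0, seed=1)
        cx = m.info["primordium_center"][0]
        d = np.linalg.norm(m.rest_vertices[:, :2] - [cx, 0.0], axis=1)
        k1, k2 = estimate_principal_curvatures(m, int(np.argmin(d)))
        assert k1 > 0 and k2 > 0
        assert k2 / k1 > 0.5  # roughly isotropic cap

    def test_degenerate_reduces_to_paraboloid(self):
        p = make_paraboloid(50.0, 40.0, 10.0, seed=4)
        m = make_meristem(50.0, 0.0, 55.0, 10.0, seed=4, height=40.0)
        assert np.array_equal(p.triangles, m.triangles)
        assert np.allclose(p.vertices, m.vertices)

    def test_determinism(self):
        a = make_meristem(50.0, 20.0, seed=5)
        b = make_meristem(50.0, 20.0, seed=5)
        assert np.array_equal(a.vertices, b.vertices)


class TestEllipsoid:
    def test_closed_euler_characteristic(self):
        m = make_ellipsoid((1.0, 1.0, 1.0), 0.35, seed=1)
        assert m.is_closed
        assert m.euler_characteristic() == 2
        assert m.check_orientation()

    def test_sphere_shape_anisotropy(self):
        m = make_ellipsoid((1.0, 1.0, 1.0), 0.35, seed=1)
        assert shape_anisotropy(m, rest=True) == pytest.approx(1.0, abs=0.02)

    def test_elongated_principal_axis_ratio(self):
        m = make_ellipsoid((2.0, 1.0, 1.0), 0.4, seed=1)
        # covariance-based axis ratio of the sampled surface
        assert shape_anisotropy(m, rest=True) == pytest.approx(2.0, rel=0.05)

    def test_outward_normals(self):
        m = make_ellipsoid((1.5, 1.0, 1.0), 0.4, seed=2)
        n = m.triangle_normals(rest=True)
        c = m.rest_vertices[m.triangles].mean(axis=1)
        assert (np.einsum("ij,ij->i", n, c - c.mean(0)) > 0).all()
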