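import numpy as np
import pytest

from morphospring import (
    LoadSpec,
    TissueMaterial,
    boundary_loops,
    make_cylinder,
    make_square_patch,
)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_patch():
    return make_square_patch(1.0, 3)


@pytest.fixture(scope="session")
def small_cylinder():
    """Coarse capped-tube setup shared by solver-level tests."""
    mesh = make_cylinder(50.0, 100.0, 16.0, seed=3)
    loops = boundary_loops(mesh)
    zm = [mesh.rest_vertices[l, 2].mean() for l in loops]
    bot = loops[int(np.argmin(zm))]
    top = loops[int(np.argmax(zm))]
    loads = LoadSpec(pressure=0.1, clamped=bot, cap_loops=[top])
    return mesh, loads


def fresh_cylinder_setup(radius=100.0, length=300.0, cell_size=20.0, seed=1, pressure=0.1):
    """Standard stem setup: base rim clamped, tip rim capped."""
    mesh = make_cylinder(radius, length, cell_size, seed=seed)
    loops = boundary_loops(mesh)
    zm = [mesh.rest_vertices[l, 2].mean() for l in loops]
    bot = loops[int(np.argmin(zm))]
    top = loops[int(np.argmax(zm))]
    return mesh, LoadSpec(pressure=pressure, clamped=bot, cap_loops=[top])


def isotropic_material(mesh, E=110.0, nu=0.2, thickness=1.0):
    return TissueMaterial.isotropic(mesh.n_cells, E, nu, thickness)
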