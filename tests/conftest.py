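import numpy as np
import pytest

from vesselflow import geometry as geo
from vesselflow import membrane as mb


@pytest.fixture(scope="session")
def small_sphere():
    """42-vertex icosphere, diameter 2 (cheap FD-oracle workhorse)."""
    return geo.make_sphere_mesh(2.0, 42)


@pytest.fixture(scope="session")
def small_material(small_sphere):
    return mb.calibrate_from_moduli(100.0, 10.0, 5000.0, small_sphere)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def fd_gradient(energy_fn, mesh, rng, n_checks=10, h=1.0e-6):
    """Central finite difference of a mesh energy at random components.

    Returns (indices, fd_values): the oracle every analytic membrane /
    interaction force is checked against.
    """
    picks, vals = [], []
    for _ in range(n_checks):
        k = int(rng.integers(0, mesh.n_vertices))
        d = int(rng.integers(0, 3))
        vp = mesh.transformed()
        vm = mesh.transformed()
        vp.vertices = vp.vertices.copy()
        vm.vertices = vm.vertices.copy()
        vp.vertices[k, d] += h
        vm.vertices[k, d] -= h
        vals.append(-(energy_fn(vp) - energy_fn(vm)) / (2 * h))
        picks.append((k, d))
    return picks, np.array(vals)
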