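"""Membrane elasticity: calibration, analytic forces vs finite differences."""

import math

import numpy as np
import pytest

from conftest import fd_gradient
from vesselflow import geometry as geo
from vesselflow import membrane as mb
from vesselflow.units import ConfigurationError


def _perturbed(mesh, rng, scale=0.02):
    p = mesh.transformed()
    p.vertices = p.vertices + scale * rng.normal(size=p.vertices.shape)
    return p


def test_calibration_round_trip(small_sphere, small_material):
    assert mb.recompute_shear_modulus(
        small_material, small_sphere
    ) == pytest.approx(100.0, rel=1e-10)
    # macroscopic identities: E_B = (2/sqrt(3)) K_B, E_D = 2 E_S + K_AG + K_AL
    assert 2 / math.sqrt(3) * small_material.K_B == pytest.approx(10.0)
    assert (2 * 100.0 + small_material.K_AG
            + small_material.K_AL) == pytest.approx(5000.0)
    # default split of the area constants is 2:1
    assert small_material.K_AG == pytest.approx(2 * small_material.K_AL)


def test_bending_coefficient_from_bending_modulus(small_sphere):
    mat = mb.calibrate_from_moduli(100.0, 50.0, 5000.0, small_sphere)
    assert mat.K_B == pytest.approx(math.sqrt(3) / 2 * 50.0)


def test_calibration_input_validation(small_sphere):
    with pytest.raises(ConfigurationError):
        mb.calibrate_from_moduli(-1.0, 1.0, 10.0, small_sphere)
    with pytest.raises(ConfigurationError, match="E_D"):
        mb.calibrate_from_moduli(100.0, 1.0, 100.0, small_sphere)


def test_reference_state_is_force_free(small_sphere, small_material):
    f = mb.deformation_force(small_sphere, small_material)
    assert np.abs(f).max() < 1e-9


@pytest.mark.parametrize("family", ["inplane", "bending", "area_volume",
                                    "total"])
def test_forces_match_finite_difference_of_energy(
        small_sphere, small_material, rng, family):
    """The master oracle: every analytic force equals -dU/dX."""
    force_fn = {
        "inplane": mb.inplane_force,
        "bending": mb.bending_force,
        "area_volume": mb.area_volume_forces,
        "total": mb.deformation_force,
    }[family]
    mesh = _perturbed(small_sphere, rng)
    f = force_fn(mesh, small_material)

    def energy(m):
        return force_fn(m, small_material, return_energy=True)[1]

    picks, fd = fd_gradient(energy, mesh, rng, n_checks=10)
    for (k, d), want in zip(picks, fd):
        assert f[k, d] == pytest.approx(want, rel=1e-6, abs=1e-8)


def test_total_force_translation_and_rotation_invariant(
        small_sphere, small_material, rng):
    mesh = _perturbed(small_sphere, rng)
    f = mb.deformation_force(mesh, small_material)
    assert np.abs(f.sum(axis=0)).max() < 1e-10
    torque = np.cross(mesh.vertices, f).sum(axis=0)
    assert np.abs(torque).max() < 1e-9


def test_energy_decreases_along_gradient(small_sphere, small_material, rng):
    mesh = _perturbed(small_sphere, rng)
    f, e0 = mb.deformation_force(mesh, small_material, return_energy=True)
    step = mesh.transformed()
    step.vertices = mesh.vertices + 1e-6 * f / max(np.abs(f).max(), 1.0)
    e1 = mb.deformation_energy(step, small_material)
    assert e1 < e0


def test_inflated_sphere_is_pulled_back(small_sphere, small_material):
    inflated = small_sphere.transformed()
    inflated.vertices = inflated.vertices * 1.01
    f = mb.area_volume_forces(inflated, small_material)
    # restoring force points inward at every vertex
    radial = np.einsum("ij,ij->i", f, inflated.vertices)
    assert (radial < 0).all()


def test_overstretched_edge_raises_with_edge_name(small_sphere,
                                                  small_material):
    bad = small_sphere.transformed()
    bad.vertices = bad.vertices.copy()
    i, j = small_sphere.edges[0]
    direction = bad.vertices[i] - bad.vertices[j]
    bad.vertices[i] = bad.vertices[j] + direction * (
        small_material.l_max[0] / np.linalg.norm(direction) * 1.05
    )
    with pytest.raises(mb.OverstretchedEdgeError, match="edge"):
        mb.inplane_force(bad, small_material)
    # the non-strict path returns finite restoring forces instead
    f = mb.inplane_force(bad, small_material, strict=False)
    assert np.isfinite(f).all()


def test_network_is_strain_hardening(small_sphere, small_material):
    """Incremental stiffness grows with extension (WLC network)."""
    tensions = []
    for scale in (1.05, 1.10, 1.15):
        stretched = small_sphere.transformed()
        stretched.vertices = stretched.vertices * scale
        f = mb.inplane_force(stretched, small_material)
        # inward pull magnitude grows superlinearly with stretch
        radial = -np.einsum(
            "ij,ij->i", f, stretched.vertices
        ) / np.linalg.norm(stretched.vertices, axis=1)
        tensions.append(radial.mean())
    assert tensions[1] - tensions[0] < tensions[2] - tensions[1]


def test_flat_reference_bending_is_zero():
    """A mesh at its own reference dihedrals has zero bending force."""
    mesh = geo.make_biconcave_mesh(3.91, 42)
    mat = mb.calibrate_from_moduli(100.0, 10.0, 5000.0, mesh)
    f = mb.bending_force(mesh, mat)
    assert np.abs(f).max() < 1e-10
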