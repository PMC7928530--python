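"""Morse surface aggregation: potential, grid vs brute force, gradients."""

import numpy as np
import pytest

from vesselflow import aggregation as ag
from vesselflow import geometry as geo
from vesselflow.units import ConfigurationError


@pytest.fixture(scope="module")
def params():
    return ag.AggregationParams(E_I=5.0, r0=0.245, beta=7.68, cutoff=1.0)


@pytest.fixture(scope="module")
def sphere_pair():
    a = geo.make_sphere_mesh(2.0, 42)
    b = a.transformed(translation=[2.0 + 0.245, 0.1, 0.05])
    return [a, b]


def test_morse_minimum_at_zero_force_distance(params):
    assert ag.morse_potential(params.r0, params) == pytest.approx(-params.E_I)
    assert ag.morse_potential(50.0, params) == pytest.approx(0.0, abs=1e-12)
    assert ag.morse_potential(50.0, params) <= 0.0  # approaches zero from below


def test_morse_force_changes_sign_at_r0(params):
    # repulsive inside r0, attractive outside; derivative oracle
    assert ag.morse_force_magnitude(params.r0 * 0.8, params) > 0
    assert ag.morse_force_magnitude(params.r0 * 1.2, params) < 0
    h = 1e-7
    for r in (0.2, 0.245, 0.4):
        fd = -(ag.morse_potential(r + h, params)
               - ag.morse_potential(r - h, params)) / (2 * h)
        assert ag.morse_force_magnitude(r, params) == pytest.approx(
            fd, rel=1e-6, abs=1e-7
        )


def test_invalid_parameters_rejected():
    with pytest.raises(ConfigurationError):
        ag.AggregationParams(E_I=1.0, r0=0.5, beta=1.0, cutoff=0.4)
    with pytest.raises(ConfigurationError):
        ag.morse_potential(-0.1, ag.AggregationParams())


def test_grid_energy_equals_brute_force(sphere_pair, params):
    _, energy = ag.aggregation_forces(sphere_pair, params, return_energy=True)
    brute = ag.aggregation_energy_brute_force(sphere_pair, params)
    assert energy == pytest.approx(brute, rel=1e-12)


def test_single_cell_has_no_aggregation(params):
    cell = geo.make_sphere_mesh(2.0, 42)
    forces, energy = ag.aggregation_forces([cell], params, return_energy=True)
    assert energy == 0.0
    assert np.abs(forces[0]).max() == 0.0


def test_action_reaction_and_momentum(sphere_pair, params):
    forces, cell_f = ag.aggregation_forces(
        sphere_pair, params, return_cell_forces=True
    )
    assert np.allclose(cell_f[0], -cell_f[1], atol=1e-12)
    total = forces[0].sum(axis=0) + forces[1].sum(axis=0)
    assert np.abs(total).max() < 1e-10
    # net force on each cell matches the sum of its vertex forces
    assert np.allclose(forces[0].sum(axis=0), cell_f[0], atol=1e-10)


def test_energy_invariant_under_joint_translation(sphere_pair, params):
    _, e0 = ag.aggregation_forces(sphere_pair, params, return_energy=True)
    moved = [c.transformed(translation=[0.7, -0.3, 0.2]) for c in sphere_pair]
    _, e1 = ag.aggregation_forces(moved, params, return_energy=True)
    assert e1 == pytest.approx(e0, rel=1e-12)


def test_vertex_forces_match_finite_difference(sphere_pair, params, rng):
    """FD oracle with the cell-center projection direction held fixed."""
    forces = ag.aggregation_forces(sphere_pair, params)
    a, b = sphere_pair
    k = b.centroid() - a.centroid()
    k /= np.linalg.norm(k)

    def frozen_k_energy(cells):
        ca, na, Aa = (cells[0].face_centroids(), cells[0].face_normals(),
                      cells[0].face_areas())
        cb, nb, Ab = (cells[1].face_centroids(), cells[1].face_normals(),
                      cells[1].face_areas())
        total = 0.0
        for m in range(len(ca)):
            d = cb - ca[m]
            r = np.linalg.norm(d, axis=1)
            sel = (r < params.cutoff) & (r > 1e-12)
            if not sel.any():
                continue
            w = (na[m] @ k) * (-(nb[sel] @ k))
            eb = np.exp(params.beta * (params.r0 - r[sel]))
            phi = params.E_I * (eb * eb - 2 * eb)
            total += float((phi * w * 0.5 * (Aa[m] + Ab[sel])).sum())
        return total

    h = 1e-6
    for _ in range(8):
        ci = int(rng.integers(0, 2))
        vi = int(rng.integers(0, 42))
        d = int(rng.integers(0, 3))
        plus = [c.transformed() for c in sphere_pair]
        minus = [c.transformed() for c in sphere_pair]
        plus[ci].vertices = plus[ci].vertices.copy()
        minus[ci].vertices = minus[ci].vertices.copy()
        plus[ci].vertices[vi, d] += h
        minus[ci].vertices[vi, d] -= h
        fd = -(frozen_k_energy(plus) - frozen_k_energy(minus)) / (2 * h)
        if abs(fd) > 1e-7:
            assert forces[ci][vi, d] == pytest.approx(fd, rel=1e-6)


def test_clamped_projection_drops_back_facing_pairs(params):
    a = geo.make_sphere_mesh(2.0, 42)
    b = a.transformed(translation=[2.1, 0.0, 0.0])
    clamped = ag.AggregationParams(
        E_I=params.E_I, r0=params.r0, beta=params.beta, cutoff=params.cutoff,
        clamp_negative_projection=True,
    )
    _, e_cl = ag.aggregation_forces([a, b], clamped, return_energy=True)
    assert e_cl == pytest.approx(
        ag.aggregation_energy_brute_force([a, b], clamped), rel=1e-12
    )
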