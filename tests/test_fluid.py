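"""SDPD fluid: kernel properties, density sums, the three pair forces."""

import math

import numpy as np
import pytest
from scipy.integrate import quad

from vesselflow import fluid as fl
from vesselflow.units import ConfigurationError


@pytest.fixture(scope="module")
def kernel():
    return fl.KernelSpec(cutoff=1.0)


def _lattice_box(L=4.0, h=0.5):
    ax = (np.arange(int(L / h)) + 0.5) * h
    gx, gy, gz = np.meshgrid(ax, ax, ax, indexing="ij")
    pos = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])
    n = len(pos)
    return fl.ParticleSystem(
        positions=pos, velocities=np.zeros((n, 3)), masses=np.ones(n),
        types=np.zeros(n, np.int64), box_lo=np.zeros(3), box_hi=np.full(3, L),
        periodic=np.ones(3, bool),
    )


def test_kernel_normalization_and_support(kernel):
    integral = quad(lambda r: 4 * math.pi * r**2 * kernel.w(r), 0, 1)[0]
    assert integral == pytest.approx(1.0, abs=1e-6)
    assert kernel.w(1.0) == 0.0
    assert kernel.w(1.5) == 0.0
    assert (kernel.w(np.linspace(0, 1, 20)) >= 0).all()


def test_kernel_gradient_antisymmetric_and_zero_at_origin(kernel):
    r = np.array([0.3, -0.2, 0.1])
    g1 = kernel.grad_w(r)
    g2 = kernel.grad_w(-r)
    assert np.allclose(g1, -g2)
    assert np.allclose(kernel.grad_w(np.zeros(3)), 0.0)


def test_unknown_kernel_family_rejected():
    with pytest.raises(ConfigurationError):
        fl.KernelSpec(family="gaussian")


def test_density_on_uniform_lattice_matches_direct_summation(kernel):
    ps = _lattice_box()
    rho = fl.compute_density(ps, kernel)
    # direct summation oracle around one interior particle
    i = len(ps.positions) // 2
    d = ps.positions - ps.positions[i]
    L = 4.0
    d -= L * np.round(d / L)
    want = kernel.w(np.linalg.norm(d, axis=1)).sum()
    assert rho[i] == pytest.approx(want, rel=1e-10)
    # within a few percent of nominal number density x mass
    assert np.allclose(rho, 8.0, rtol=0.05)


def test_isolated_particle_density_is_self_term(kernel):
    ps = fl.ParticleSystem(
        positions=np.array([[5.0, 5.0, 5.0]]),
        velocities=np.zeros((1, 3)), masses=np.array([2.0]),
        types=np.zeros(1, np.int64), box_lo=np.zeros(3),
        box_hi=np.full(3, 10.0), periodic=np.zeros(3, bool),
    )
    rho = fl.compute_density(ps, fl.KernelSpec())
    assert rho[0] == pytest.approx(2.0 * fl.KernelSpec().w(0.0))


def test_density_translation_invariant(kernel):
    ps = _lattice_box()
    rho0 = fl.compute_density(ps, kernel)
    ps2 = _lattice_box()
    ps2.positions = (ps2.positions + 0.19) % 4.0
    rho1 = fl.compute_density(ps2, kernel)
    assert np.allclose(np.sort(rho0), np.sort(rho1), rtol=1e-9)


def test_conservative_force_equilibrium_and_momentum(kernel):
    params = fl.FluidParams(eta=10.0, rho0=None or 8.0, sound_speed=10.0,
                            kBT=0.0)
    ps = _lattice_box()
    f = fl.conservative_force(ps, kernel, params)
    # perfect lattice at rest density: near-zero net force per particle
    assert np.abs(f).max() < 1e-8
    # compressed pair repels along the separation
    two = fl.ParticleSystem(
        positions=np.array([[4.8, 5.0, 5.0], [5.2, 5.0, 5.0]]),
        velocities=np.zeros((2, 3)), masses=np.ones(2),
        types=np.zeros(2, np.int64), box_lo=np.zeros(3),
        box_hi=np.full(3, 10.0), periodic=np.zeros(3, bool),
    )
    # a pair denser than the rest density repels along the separation
    sparse = fl.FluidParams(eta=10.0, rho0=2.5, sound_speed=10.0, kBT=0.0)
    fpair = fl.conservative_force(two, kernel, sparse)
    assert fpair[0, 0] < 0 < fpair[1, 0]
    assert np.allclose(fpair.sum(axis=0), 0.0, atol=1e-12)
    # and one rarer than rest density attracts (negative EOS pressure)
    dense = fl.FluidParams(eta=10.0, rho0=8.0, sound_speed=10.0, kBT=0.0)
    two.densities = None
    gpair = fl.conservative_force(two, kernel, dense)
    assert gpair[0, 0] > 0 > gpair[1, 0]


def test_dissipative_force_galilean_invariant(kernel):
    params = fl.FluidParams(eta=10.0, rho0=8.0, sound_speed=10.0, kBT=0.0)
    ps = _lattice_box()
    ps.velocities[:] = [0.7, -0.2, 0.4]  # rigid translation
    f = fl.dissipative_force(ps, kernel, params)
    assert np.abs(f).max() < 1e-12
    # random velocities: forces oppose relative motion, conserve momentum
    rng = np.random.default_rng(0)
    ps.velocities = rng.normal(size=ps.velocities.shape)
    f = fl.dissipative_force(ps, kernel, params)
    assert np.abs(f.sum(axis=0)).max() < 1e-9
    # dissipative power is strictly negative
    assert float((f * ps.velocities).sum()) < 0


def test_random_force_zero_at_zero_temperature(kernel):
    params = fl.FluidParams(eta=10.0, rho0=8.0, sound_speed=10.0, kBT=0.0)
    ps = _lattice_box()
    f = fl.random_force(ps, kernel, params, dt=1e-3, seed=1, step=0)
    assert np.abs(f).max() == 0.0


def test_random_force_conserves_momentum_each_step(kernel):
    params = fl.FluidParams(eta=10.0, rho0=8.0, sound_speed=10.0, kBT=1.0)
    ps = _lattice_box()
    for step in range(3):
        f = fl.random_force(ps, kernel, params, dt=1e-3, seed=1, step=step)
        assert np.abs(f.sum(axis=0)).max() < 1e-9
        assert np.abs(f).max() > 0.0


def test_external_force_respects_region_mask(kernel):
    ps = _lattice_box()
    g = np.array([9.79, 0.0, 0.0])
    f_all = fl.external_force(ps, g)
    assert np.allclose(f_all, ps.masses[:, None] * g)
    mask = ps.positions[:, 0] < 1.0
    f_in = fl.external_force(ps, g, region_mask=mask)
    assert np.allclose(f_in[mask, 0], g[0])
    assert np.abs(f_in[~mask]).max() == 0.0
    empty = fl.external_force(ps, g, region_mask=np.zeros(ps.n, bool))
    assert np.abs(empty).max() == 0.0
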