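"""Integration loop: velocity-Verlet scheme, walls, recycling, checkpoints."""

import math

import numpy as np
import pytest

import vesselflow as vf
from vesselflow import _kernels as K
from vesselflow.driver import Simulation, wall_repulsion


def _verlet(x0, v0, accel, dt, n):
    """The integrator pattern used by the driver (half-kick/drift/half-kick)."""
    x, v = x0, v0
    a = accel(x)
    for _ in range(n):
        v = v + 0.5 * dt * a
        x = x + dt * v
        a = accel(x)
        v = v + 0.5 * dt * a
    return x, v


def test_verlet_constant_force_is_exact_quadratic():
    dt, n, g = 1e-2, 100, 2.5
    x, v = _verlet(0.0, 0.0, lambda _: g, dt, n)
    t = n * dt
    assert x == pytest.approx(0.5 * g * t**2, rel=1e-12)
    assert v == pytest.approx(g * t, rel=1e-12)


def test_verlet_zero_forces_zero_velocity_is_fixed_point():
    x, v = _verlet(1.0, 0.0, lambda _: 0.0, 1e-2, 50)
    assert x == 1.0 and v == 0.0


@pytest.mark.parametrize("dt", [2e-3, 1e-3])
def test_verlet_oscillator_period_error_second_order(dt):
    """Harmonic oscillator: bounded energy drift, O(dt^2) period error."""
    k = 4.0
    omega = math.sqrt(k)
    period = 2 * math.pi / omega
    n = int(round(10 * period / dt))
    xs = []
    x, v = 1.0, 0.0
    a = -k * x
    emax = 0.0
    for i in range(n):
        v += 0.5 * dt * a
        x += dt * v
        a = -k * x
        v += 0.5 * dt * a
        emax = max(emax, abs(0.5 * v**2 + 0.5 * k * x**2 - 0.5 * k))
        xs.append(x)
    assert emax < 0.01  # bounded energy drift
    # measured period from zero crossings
    xs = np.array(xs)
    crossings = np.nonzero((xs[:-1] < 0) & (xs[1:] >= 0))[0]
    measured = np.diff(crossings).mean() * dt
    rel_err = abs(measured - period) / period
    assert rel_err < 0.5 * (omega * dt) ** 2 + 1e-4


@pytest.fixture(scope="module")
def tiny_tube_sim():
    cfg = vf.make_config({
        "geometry": {"kind": "tube", "diameter": 5.0, "length": 4.0},
        "fluid": {"viscosity": 10.0, "kBT": 0.5, "sound_speed": 12.0},
        "aggregation": {"enabled": False},
        "adhesion": {"enabled": False},
        "drive": {"acceleration": (0.5, 0.0, 0.0)},
        "run": {"time_step": 1e-3, "n_steps": 10, "seed": 11,
                "output_every": 5},
    })
    return cfg


def test_momentum_conservation_of_pair_forces(tiny_tube_sim):
    """Conservative+dissipative+random forces are pairwise antisymmetric:
    the total force from particle interactions vanishes to round-off."""
    sim = Simulation.from_config(tiny_tube_sim)
    nf = sim.n_fluid
    rho = sim.ps.densities
    pressure = sim.params.pressure(rho)
    force = K.sdpd_pair_forces(
        sim.ps.positions, sim.ps.velocities, sim.ps.masses, rho, pressure,
        sim._pairs, sim.ps.box_lo, sim.ps.box_hi, sim.ps.periodic,
        1.0, sim.params.eta, sim.params.kBT, sim.dt, sim.seed,
        np.uint64(0), True, True, True,
    )
    scale = np.abs(force).max()
    assert np.abs(force.sum(axis=0)).max() < 1e-9 * max(scale, 1.0)


def test_fluid_count_constant_in_closed_tube(tiny_tube_sim):
    sim = Simulation.from_config(tiny_tube_sim)
    n0 = sim.n_fluid
    sim.run(50, 25)
    assert sim.n_fluid == n0
    assert len(sim.ps.positions) == sim.ps.n
    # all fluid still inside the lumen (no wall penetration)
    inside = sim.wall.inside(sim.ps.positions[:n0], margin=-0.2)
    assert inside.all()


def test_run_is_deterministic_and_resumable(tiny_tube_sim, tmp_path):
    sim1 = Simulation.from_config(tiny_tube_sim)
    sim1.run(40, 20)
    final1 = sim1.ps.positions[: sim1.n_fluid].copy()

    sim2 = Simulation.from_config(tiny_tube_sim)
    sim2.run(20, 10)
    ck = str(tmp_path / "ck.h5")
    sim2.save_checkpoint(ck)

    sim3 = Simulation.from_config(tiny_tube_sim)
    sim3.load_checkpoint(ck)
    for _ in range(20):
        sim3.step()
    assert np.array_equal(final1, sim3.ps.positions[: sim3.n_fluid])


def test_checkpoint_seed_mismatch_rejected(tiny_tube_sim, tmp_path):
    sim = Simulation.from_config(tiny_tube_sim)
    ck = str(tmp_path / "ck.h5")
    sim.save_checkpoint(ck)
    other = vf.make_config(
        dict(tiny_tube_sim.model_dump(), run=dict(
            tiny_tube_sim.run.model_dump(), seed=99))
    )
    sim2 = Simulation.from_config(other)
    with pytest.raises(vf.ConfigurationError, match="seed"):
        sim2.load_checkpoint(ck)


def test_zero_steps_returns_initial_state_only(tiny_tube_sim):
    sim = Simulation.from_config(tiny_tube_sim)
    traj = sim.run(0, 5)
    assert len(traj) == 1
    assert traj.times[0] == 0.0


def test_wall_repulsion_zero_beyond_range_and_reverses_approach():
    rep = np.array([[0.0, 0.0, 0.0]])
    grid = K.build_grid(rep, np.array([-1.0, -1.0, -1.0]),
                        np.array([1.0, 1.0, 1.0]), 0.3)
    lo, hi = np.array([-1.0, -1.0, -1.0]), np.array([1.0, 1.0, 1.0])
    per = np.zeros(3, bool)
    far = wall_repulsion(np.array([[0.0, 0.0, 0.5]]), rep, grid, lo, hi,
                         per, 100.0, 0.3)
    assert np.abs(far).max() == 0.0
    near = wall_repulsion(np.array([[0.0, 0.0, 0.1]]), rep, grid, lo, hi,
                          per, 100.0, 0.3)
    assert near[0, 2] > 0 and abs(near[0, 0]) < 1e-12
    # 1D head-on trajectory: the particle decelerates and turns around
    # before reaching the wall particle
    z, vz = 0.28, -1.0
    dt = 1e-3
    for _ in range(2000):
        f = wall_repulsion(np.array([[0.0, 0.0, z]]), rep, grid, lo, hi,
                           per, 100.0, 0.3)[0, 2]
        vz += dt * f
        z += dt * vz
        if vz > 0:
            break
    assert z > 0.0 and vz > 0.0


def test_bifurcation_recycling_conserves_fluid_count():
    from vesselflow import experiments as ex

    sim = ex.bifurcation_flow(seed=3, n_steps=10)
    n0 = sim.n_fluid
    for _ in range(300):
        sim.step()
    assert sim.n_fluid == n0
    assert sim._recycled > 0  # outflow actually re-entered the inlet
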