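"""Trajectory analysis: deviations, projections, profiles, classification."""

import numpy as np
import pytest

from vesselflow import analysis as an
from vesselflow.driver import Trajectory
from vesselflow.geometry import make_bifurcation, make_tube
from vesselflow.units import ConfigurationError


def _traj(centroids, bonds=None, velocities=None, wall=None, kinds=None,
          times=None):
    centroids = np.asarray(centroids, float)
    T, C, _ = centroids.shape
    return Trajectory(
        times=np.arange(T, dtype=float) if times is None else times,
        centroids=centroids,
        velocities=(np.zeros((T, C, 3)) if velocities is None
                    else np.asarray(velocities, float)),
        bond_counts=(np.zeros(T) if bonds is None
                     else np.asarray(bonds, float)),
        aggregation_forces=np.zeros((T, C, 3)),
        areas=np.ones((T, C)),
        volumes=np.ones((T, C)),
        fluid_temperature=np.ones(T),
        cell_kinds=kinds or ["ctc"] * C,
        wall=wall,
    )


def test_centerline_deviation_trivial_cases():
    wall = make_tube(8.0, 10.0)
    cents = np.array([[[1.0, 0.0, 0.0]], [[2.0, 1.5, 0.0]],
                      [[3.0, 0.0, -2.0]]])
    traj = _traj(cents, wall=wall)
    x, dev = an.centerline_deviation(traj, 0)
    assert np.allclose(dev, [0.0, 1.5, 2.0])
    assert np.allclose(x, [1.0, 2.0, 3.0])


def test_centerline_deviation_matches_dense_polyline_search():
    wall = make_bifurcation(8.0, 0.5, segment_lengths=(6.0, 6.0))
    rng = np.random.default_rng(0)
    pts = rng.uniform([1, -2, -2], [10, 2, 2], size=(40, 3))
    _, dev, _ = an.nearest_centerline_point(wall, pts)
    # brute force: densely sample every centerline segment
    dense = []
    for (a, b) in wall.centerline:
        ts = np.linspace(0, 1, 4001)[:, None]
        dense.append(a + ts * (b - a))
    dense = np.concatenate(dense)
    for p, d in zip(pts, dev):
        want = np.linalg.norm(dense - p, axis=1).min()
        assert d == pytest.approx(want, abs=2e-3)


def test_radial_aggregation_force_projection():
    wall = make_tube(8.0, 10.0)
    traj = _traj(np.array([[[5.0, 2.0, 0.0]]]), wall=wall)
    traj.aggregation_forces = np.array([[[3.0, 0.0, 0.0]]])  # axial only
    _, f = an.radial_aggregation_force(traj, 0)
    assert f[0] == pytest.approx(0.0)
    traj.aggregation_forces = np.array([[[0.0, 1.7, 0.0]]])  # outward at +y
    _, f = an.radial_aggregation_force(traj, 0)
    assert f[0] == pytest.approx(1.7)
    traj.aggregation_forces = np.array([[[0.0, -0.4, 0.0]]])  # inward
    _, f = an.radial_aggregation_force(traj, 0)
    assert f[0] == pytest.approx(-0.4)


def test_radial_projection_matches_dot_product_oracle():
    wall = make_tube(6.0, 8.0)
    rng = np.random.default_rng(1)
    cents = rng.uniform([1, -2, -2], [7, 2, 2], size=(20, 1, 3))
    traj = _traj(cents, wall=wall)
    traj.aggregation_forces = rng.normal(size=(20, 1, 3))
    _, proj = an.radial_aggregation_force(traj, 0)
    for t in range(20):
        radial = cents[t, 0].copy()
        radial[0] = 0.0
        unit = radial / np.linalg.norm(radial)
        assert proj[t] == pytest.approx(
            float(traj.aggregation_forces[t, 0] @ unit), rel=1e-9
        )


def test_bond_and_retention_profiles_against_per_snapshot_oracle():
    wall = make_tube(6.0, 30.0)
    x = np.linspace(0.5, 29.5, 60)
    cents = np.zeros((60, 1, 3))
    cents[:, 0, 0] = x
    bonds = np.zeros(60)
    bonds[20:30] = np.arange(10) + 1  # bonds while stalled in one region
    traj = _traj(cents, bonds=bonds, wall=wall)
    edges = np.linspace(0.0, 30.0, 7)
    max_b, mean_b, residence = an.bond_and_retention_profiles(traj, edges)
    # brute-force per-snapshot assignment
    want_max = np.zeros(6)
    want_res = np.zeros(6)
    dt = 1.0
    for t in range(60):
        b = min(int(x[t] // 5), 5)
        want_max[b] = max(want_max[b], bonds[t])
        want_res[b] += dt
    assert np.allclose(max_b, want_max)
    assert np.allclose(residence, want_res)
    # uniform motion: equal residence everywhere
    assert np.allclose(residence, 10.0)


def test_profiles_require_covering_bins():
    wall = make_tube(6.0, 30.0)
    cents = np.zeros((10, 1, 3))
    cents[:, 0, 0] = np.linspace(0, 29, 10)
    traj = _traj(cents, wall=wall)
    with pytest.raises(ConfigurationError, match="cover"):
        an.bond_and_retention_profiles(traj, np.linspace(5, 20, 4))


def test_classify_detachment_rolling_firm_phenotypes():
    T = 90
    v_flow = 1.0
    # detachment: early bonds dissolve, velocity recovers to the flow speed
    bonds = np.concatenate([np.array([3, 5, 2, 1]), np.zeros(T - 4)])
    vel = np.concatenate([np.linspace(1, 0.2, 4),
                          np.linspace(0.3, v_flow, T - 4)])
    c = an.classify_adhesion_state(bonds, vel, v_flow)
    assert c.state == "detachment"
    # firm: persistent bonds, zero velocity
    bonds = np.concatenate([np.linspace(0, 70, 30), np.full(T - 30, 70.0)])
    vel = np.concatenate([np.linspace(1, 0, 30), np.zeros(T - 30)])
    assert an.classify_adhesion_state(bonds, vel, v_flow).state == "firm"
    # rolling: ~20 persistent bonds, fluctuating nonzero velocity
    rng = np.random.default_rng(2)
    bonds = 20 + rng.integers(-4, 5, T)
    vel = 0.3 + 0.1 * rng.normal(size=T)
    assert an.classify_adhesion_state(bonds, vel, v_flow).state == "rolling"
    # too-short window is inconclusive
    out = an.classify_adhesion_state(bonds[:3], vel[:3], v_flow)
    assert out.state == "inconclusive"


def test_analysis_is_pure_and_repeatable():
    wall = make_tube(6.0, 10.0)
    rng = np.random.default_rng(7)
    cents = rng.uniform([0, -2, -2], [10, 2, 2], size=(25, 2, 3))
    traj = _traj(cents, wall=wall, kinds=["ctc", "rbc"])
    a1 = an.centerline_deviation(traj, 0)[1]
    a2 = an.centerline_deviation(traj, 0)[1]
    assert np.array_equal(a1, a2)
    r1 = an.radial_positions(traj, kinds=("rbc",))
    r2 = an.radial_positions(traj, kinds=("rbc",))
    assert np.array_equal(r1, r2)
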