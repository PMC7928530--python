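"""Stochastic receptor-ligand kinetics and bond spring forces."""

import math

import numpy as np
import pytest

from vesselflow import adhesion as adh
from vesselflow.geometry import LigandField
from vesselflow.units import ConfigurationError


@pytest.fixture(scope="module")
def params():
    # microcirculation bond constants (dimensionless)
    return adh.AdhesionParams(
        E_A=2.897e4, lam=0.1, l_r=0.5, sigma_f=5.794e2, sigma_d=7.281e2,
        k_f0=1.205e3, k_d0=3.55e2, kBT=1.0,
    )


def test_rates_at_equilibrium_length(params):
    assert adh.formation_rate(params.lam, params) == pytest.approx(params.k_f0)
    assert adh.dissociation_rate(params.lam, params) == pytest.approx(
        params.k_d0
    )


def test_rate_scalar_oracle(params):
    # direct evaluation at 0.05 stretch
    want_f = 1.205e3 * math.exp(-5.794e2 * 0.05**2 / 2.0)
    want_d = 3.55e2 * math.exp(7.281e2 * 0.05**2 / 2.0)
    assert adh.formation_rate(0.15, params) == pytest.approx(want_f, rel=1e-12)
    assert adh.dissociation_rate(0.15, params) == pytest.approx(
        want_d, rel=1e-12
    )


def test_rate_monotonicity(params):
    x = np.linspace(params.lam, 0.5, 30)
    kf = adh.formation_rate(x, params)
    kd = adh.dissociation_rate(x, params)
    assert (np.diff(kf) < 0).all()   # decreasing away from lambda
    assert (np.diff(kd) > 0).all()   # increasing away from lambda


def test_bond_probabilities_closed_form(params):
    p_f, p_d = adh.bond_probabilities(params.lam, math.log(2) / params.k_f0,
                                      params)
    assert p_f == pytest.approx(0.5)
    p_f0, _ = adh.bond_probabilities(params.lam, 1e-300, params)
    assert p_f0 == pytest.approx(0.0)
    p_f1, _ = adh.bond_probabilities(params.lam, 1e9, params)
    assert p_f1 == pytest.approx(1.0)


def test_probabilities_always_in_unit_interval(params):
    x = np.linspace(0.0, 2.0, 50)
    p_f, p_d = adh.bond_probabilities(x, 1e-3, params)
    assert ((0 <= p_f) & (p_f <= 1)).all()
    assert ((0 <= p_d) & (p_d <= 1)).all()


def test_parameter_validation():
    with pytest.raises(ConfigurationError, match="l_r > lambda"):
        adh.AdhesionParams(E_A=1.0, lam=0.5, l_r=0.2, sigma_f=1.0,
                           sigma_d=1.0, k_f0=1.0, k_d0=1.0)


def _model(params, ligand_positions, n_receptors, seed=0):
    field = LigandField(np.asarray(ligand_positions, float), 1.0)
    return adh.AdhesionModel(field, params, n_receptors, seed=seed)


def test_no_bonds_beyond_reactive_distance(params):
    model = _model(params, [[0.0, 0.0, 0.0]], 1)
    rec = np.array([[2.0, 0.0, 0.0]])
    for step in range(50):
        model.update_bonds(rec, 1e-3, step)
    assert model.bonds.count == 0


def test_infinite_dissociation_clears_all_bonds():
    p = adh.AdhesionParams(E_A=1.0, lam=0.1, l_r=0.5, sigma_f=0.0,
                           sigma_d=0.0, k_f0=1e12, k_d0=0.0, kBT=1.0)
    model = _model(p, [[0.0, 0.0, 0.1]], 1)
    rec = np.array([[0.0, 0.0, 0.2]])
    model.update_bonds(rec, 1e-3, 0)
    assert model.bonds.count == 1
    fast = adh.AdhesionParams(E_A=1.0, lam=0.1, l_r=0.5, sigma_f=0.0,
                              sigma_d=0.0, k_f0=0.0, k_d0=1e12, kBT=1.0)
    model.params = fast
    model.update_bonds(rec, 1e-3, 1)
    assert model.bonds.count == 0


def test_forced_dissociation_at_reactive_distance(params):
    model = _model(params, [[0.0, 0.0, 0.0]], 1)
    rec = np.array([[0.0, 0.0, 0.15]])
    for step in range(200):
        model.update_bonds(rec, 1e-3, step)
        if model.bonds.count:
            break
    assert model.bonds.count == 1
    far = np.array([[0.0, 0.0, 0.6]])  # beyond l_r
    model.update_bonds(far, 1e-3, 999)
    assert model.bonds.count == 0


def test_equilibrium_occupancy_matches_two_state_markov_chain():
    """Long-run bound fraction of a static receptor equals p_f/(p_f+p_d)."""
    p = adh.AdhesionParams(E_A=1.0, lam=0.1, l_r=0.5, sigma_f=0.0,
                           sigma_d=0.0, k_f0=40.0, k_d0=20.0, kBT=1.0)
    model = _model(p, [[0.0, 0.0, 0.1]], 1, seed=5)
    rec = np.array([[0.0, 0.0, 0.2]])
    dt = 5e-3
    bound = 0
    n_steps = 40_000
    for step in range(n_steps):
        model.update_bonds(rec, dt, step)
        bound += model.bonds.count
    p_f = 1 - math.exp(-p.k_f0 * dt)
    p_d = 1 - math.exp(-p.k_d0 * dt)
    expect = p_f / (p_f + p_d)
    # 3 sigma of the stationary-chain estimate (correlated samples)
    tau = 1.0 / (p_f + p_d)
    sigma = math.sqrt(expect * (1 - expect) * 2 * tau / n_steps)
    assert abs(bound / n_steps - expect) < 3 * sigma + 1e-3


def test_monte_carlo_flip_frequency_matches_probability():
    """Bernoulli oracle: formation events over many fresh trials."""
    p = adh.AdhesionParams(E_A=1.0, lam=0.1, l_r=0.5, sigma_f=0.0,
                           sigma_d=0.0, k_f0=30.0, k_d0=0.0, kBT=1.0)
    dt = 5e-3
    p_f = 1 - math.exp(-p.k_f0 * dt)
    n = 20_000
    model = _model(p, [[0.0, 0.0, 0.1]], 1, seed=9)
    hits = 0
    for step in range(n):
        model.bonds.ligand_of[:] = -1  # fresh trial each step
        model.ligand_bound_count[:] = 0
        model.update_bonds(np.array([[0.0, 0.0, 0.2]]), dt, step)
        hits += model.bonds.count
    sigma = math.sqrt(n * p_f * (1 - p_f))
    assert abs(hits - n * p_f) < 3 * sigma


def test_bond_outcomes_bit_reproducible(params):
    """Counter-based draws keyed by (step, receptor, ligand): re-running
    the same kinetics reproduces the bond set exactly."""
    lig = [[x * 0.3, 0.0, 0.1] for x in range(5)]
    rec = np.array([[x * 0.3, 0.0, 0.25] for x in range(4)])
    m1 = _model(params, lig, 4, seed=3)
    for step in range(100):
        m1.update_bonds(rec, 1e-3, step)
    m2 = _model(params, lig, 4, seed=3)
    for step in range(100):
        m2.update_bonds(rec, 1e-3, step)
    assert (m1.bonds.ligand_of == m2.bonds.ligand_of).all()
    assert (m1.bonds.formation_step == m2.bonds.formation_step).all()
    # a different seed decorrelates the stream
    m3 = _model(params, lig, 4, seed=4)
    for step in range(100):
        m3.update_bonds(rec, 1e-3, step)
    assert not (
        (m1.bonds.ligand_of == m3.bonds.ligand_of).all()
        and (m1.bonds.formation_step == m3.bonds.formation_step).all()
    )


def test_adhesion_force_zero_at_equilibrium_and_fd(params, rng):
    lig_pos = np.array([[0.0, 0.0, 0.0], [0.5, 0.0, 0.0]])
    bonds = adh.BondSet.empty(2)
    bonds.ligand_of[:] = [0, 1]
    rec = np.array([[0.0, 0.0, params.lam], [0.5, 0.0, 0.3]])
    f_rec, f_wall, energy = adh.adhesion_force(
        bonds, rec, lig_pos, params, return_energy=True
    )
    assert np.abs(f_rec[0]).max() < 1e-9  # bond at lambda: no force
    assert np.allclose(f_rec.sum(axis=0), -f_wall.sum(axis=0))
    # finite-difference check on the stretched bond
    h = 1e-7
    for d in range(3):
        rp = rec.copy()
        rm = rec.copy()
        rp[1, d] += h
        rm[1, d] -= h
        ep = adh.adhesion_force(bonds, rp, lig_pos, params,
                                return_energy=True)[2]
        em = adh.adhesion_force(bonds, rm, lig_pos, params,
                                return_energy=True)[2]
        assert f_rec[1, d] == pytest.approx(-(ep - em) / (2 * h), rel=1e-6)


def test_bondset_no_duplicate_pairs(params):
    lig = [[0.0, 0.0, 0.1]]
    model = _model(params, lig, 3, seed=1)
    rec = np.tile([[0.0, 0.0, 0.2]], (3, 1))
    for step in range(200):
        model.update_bonds(rec, 1e-3, step)
    bound = model.bonds.ligand_of
    # a receptor holds at most one bond (one slot each, by construction),
    # and the single ligand may serve several receptors
    assert (bound <= 0).all()  # ligand index 0 or unbound
    assert model.ligand_bound_count[0] == (bound == 0).sum()
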