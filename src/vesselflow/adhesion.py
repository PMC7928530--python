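"""Stochastic receptor-ligand adhesion kinetics and bond spring forces.

Receptors live on tumor-cell membrane vertices, ligands are fixed sites on
the vessel wall.  A bond of length ``x_m`` behaves as a Hookean spring with
strength ``E_A`` and equilibrium length ``lambda``; its formation and
dissociation are Poisson processes with strain-dependent rates

    k_f = k_f0 exp( - sigma_f (x_m - lambda)^2 / (2 kBT) )
    k_d = k_d0 exp( + sigma_d (x_m - lambda)^2 / (2 kBT) )

sampled once per time step with probabilities ``p = 1 - exp(-k dt)``.
A bond may only form within the reactive distance ``l_r`` and is forcibly
dissociated the moment it stretches to ``l_r``.

A receptor holds at most one bond at a time; formation candidates are
tried nearest-first.  A ligand may bind several receptors unless
``single_bond_per_ligand`` is set.  All random draws come from a
counter-based stream keyed by (seed, step, receptor, ligand), so outcomes
are independent of iteration order and bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit

from ._kernels import event_u01
from .geometry import LigandField
from .units import ConfigurationError

_FORM_SALT = np.uint64(0xA5A5A5A5A5A5A5A5)
_DISS_SALT = np.uint64(0x5A5A5A5A5A5A5A5A)


@dataclass(frozen=True)
class AdhesionParams:
    """Bond mechanics and kinetics constants (dimensionless)."""

    E_A: float  # adhesion (spring) strength
    lam: float  # equilibrium bond length
    l_r: float  # reactive distance
    sigma_f: float  # formation strength
    sigma_d: float  # dissociation strength
    k_f0: float  # unstressed formation rate
    k_d0: float  # unstressed dissociation rate
    kBT: float = 1.0
    single_bond_per_ligand: bool = False

    def __post_init__(self) -> None:
        if not (self.l_r > self.lam > 0):
            raise ConfigurationError(
                f"adhesion requires l_r > lambda > 0, got l_r={self.l_r}, "
                f"lambda={self.lam}"
            )
        for name in ("E_A", "sigma_f", "sigma_d", "k_f0", "k_d0"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        if self.kBT <= 0:
            raise ConfigurationError("kBT must be > 0")


def formation_rate(x_m, p: AdhesionParams):
    """Strain-dependent bond formation rate k_f(x_m)."""
    x_m = np.asarray(x_m, dtype=float)
    return p.k_f0 * np.exp(-p.sigma_f * (x_m - p.lam) ** 2 / (2.0 * p.kBT))


def dissociation_rate(x_m, p: AdhesionParams):
    """Strain-dependent bond dissociation rate k_d(x_m)."""
    x_m = np.asarray(x_m, dtype=float)
    return p.k_d0 * np.exp(p.sigma_d * (x_m - p.lam) ** 2 / (2.0 * p.kBT))


def bond_probabilities(x_m, dt: float, p: AdhesionParams):
    """Per-step formation and dissociation probabilities (p_f, p_d)."""
    if dt <= 0:
        raise ConfigurationError("dt must be > 0")
    p_f = 1.0 - np.exp(-formation_rate(x_m, p) * dt)
    p_d = 1.0 - np.exp(-dissociation_rate(x_m, p) * dt)
    return p_f, p_d


@dataclass
class BondSet:
    """Live bonds: one slot per receptor (-1 = unbound)."""

    ligand_of: np.ndarray  # (n_receptors,) int64
    formation_step: np.ndarray  # (n_receptors,) int64

    @classmethod
    def empty(cls, n_receptors: int) -> "BondSet":
        return cls(
            np.full(n_receptors, -1, dtype=np.int64),
            np.full(n_receptors, -1, dtype=np.int64),
        )

    @property
    def count(self) -> int:
        return int((self.ligand_of >= 0).sum())

    def records(self, receptor_pos: np.ndarray, ligand_pos: np.ndarray):
        """(receptor, ligand, length, formation_step) for live bonds."""
        rec = np.nonzero(self.ligand_of >= 0)[0]
        lig = self.ligand_of[rec]
        length = np.linalg.norm(receptor_pos[rec] - ligand_pos[lig], axis=1)
        return rec, lig, length, self.formation_step[rec]

    def copy(self) -> "BondSet":
        return BondSet(self.ligand_of.copy(), self.formation_step.copy())


@njit(cache=True)
def _update_bonds_kernel(rec_pos, lig_pos, ligand_of, formation_step,
                         lig_bound_count, cand_idx, cand_dist,
                         lam, l_r, sigma_f, sigma_d, k_f0, k_d0, kBT,
                         dt, seed, step, single_bond_per_ligand):
    n_rec = rec_pos.shape[0]
    freed = np.zeros(n_rec, dtype=np.bool_)
    # --- dissociation of existing bonds ---
    for r in range(n_rec):
        lg = ligand_of[r]
        if lg < 0:
            continue
        dx = rec_pos[r, 0] - lig_pos[lg, 0]
        dy = rec_pos[r, 1] - lig_pos[lg, 1]
        dz = rec_pos[r, 2] - lig_pos[lg, 2]
        x = np.sqrt(dx * dx + dy * dy + dz * dz)
        broke = False
        if x >= l_r:
            broke = True
        else:
            kd = k_d0 * np.exp(sigma_d * (x - lam) ** 2 / (2.0 * kBT))
            pd = 1.0 - np.exp(-kd * dt)
            xi2 = event_u01(seed ^ _DISS_SALT, step, r, lg)
            if pd > xi2:
                broke = True
        if broke:
            ligand_of[r] = -1
            formation_step[r] = -1
            lig_bound_count[lg] -= 1
            freed[r] = True
    # --- formation for unbound receptors, nearest candidate first;
    # a receptor freed this step may rebind only next step ---
    kmax = cand_idx.shape[1]
    n_lig = lig_pos.shape[0]
    for r in range(n_rec):
        if ligand_of[r] >= 0 or freed[r]:
            continue
        for c in range(kmax):
            lg = cand_idx[r, c]
            if lg < 0 or lg >= n_lig:
                continue
            x = cand_dist[r, c]
            if x >= l_r:
                continue
            if single_bond_per_ligand and lig_bound_count[lg] > 0:
                continue
            kf = k_f0 * np.exp(-sigma_f * (x - lam) ** 2 / (2.0 * kBT))
            pf = 1.0 - np.exp(-kf * dt)
            xi1 = event_u01(seed ^ _FORM_SALT, step, r, lg)
            if pf > xi1:
                ligand_of[r] = lg
                formation_step[r] = step
                lig_bound_count[lg] += 1
                break


class AdhesionModel:
    """Bond bookkeeping for one receptor set against one ligand field."""

    def __init__(self, ligands: LigandField, params: AdhesionParams,
                 n_receptors: int, seed: int = 0,
                 max_candidates: int = 8):
        from scipy.spatial import cKDTree

        self.ligands = ligands
        self.params = params
        self.seed = np.uint64(seed & 0x7FFFFFFFFFFFFFFF)
        self.max_candidates = max_candidates
        self.bonds = BondSet.empty(n_receptors)
        self.ligand_bound_count = np.zeros(
            max(len(ligands), 1), dtype=np.int64
        )
        self._tree = (
            cKDTree(ligands.positions) if len(ligands) else None
        )

    def update_bonds(self, receptor_pos: np.ndarray, dt: float,
                     step: int) -> BondSet:
        """One kinetic step: dissociation then nearest-first formation."""
        p = self.params
        if self._tree is None:
            return self.bonds
        dist, idx = self._tree.query(
            receptor_pos, k=self.max_candidates,
            distance_upper_bound=p.l_r,
        )
        if self.max_candidates == 1:
            dist = dist[:, None]
            idx = idx[:, None]
        idx = np.where(np.isfinite(dist), idx, -1).astype(np.int64)
        dist = np.where(np.isfinite(dist), dist, np.inf)
        _update_bonds_kernel(
            np.ascontiguousarray(receptor_pos, dtype=np.float64),
            self.ligands.positions, self.bonds.ligand_of,
            self.bonds.formation_step, self.ligand_bound_count,
            idx, dist, p.lam, p.l_r, p.sigma_f, p.sigma_d,
            p.k_f0, p.k_d0, p.kBT, dt, self.seed, np.uint64(step),
            p.single_bond_per_ligand,
        )
        return self.bonds

    def adhesion_force(self, receptor_pos: np.ndarray,
                       return_energy: bool = False):
        """Spring forces on receptors (and the opposite wall-side forces)."""
        return adhesion_force(
            self.bonds, receptor_pos, self.ligands.positions, self.params,
            return_energy=return_energy,
        )


def adhesion_force(bonds: BondSet, receptor_pos: np.ndarray,
                   ligand_pos: np.ndarray, p: AdhesionParams,
                   return_energy: bool = False):
    """-dU_adh/dX for U_adh = 1/2 sum E_A (x_m - lambda)^2.

    Returns (receptor_forces, wall_forces[, energy]); wall forces are the
    exact opposites of the receptor forces, bond by bond.
    """
    f_rec = np.zeros_like(receptor_pos)
    f_wall = np.zeros((len(ligand_pos), 3))
    energy = 0.0
    rec = np.nonzero(bonds.ligand_of >= 0)[0]
    if len(rec):
        lig = bonds.ligand_of[rec]
        d = receptor_pos[rec] - ligand_pos[lig]
        x = np.linalg.norm(d, axis=1)
        x_safe = np.maximum(x, 1e-12)
        mag = p.E_A * (x - p.lam)  # tension if stretched
        f = -(mag / x_safe)[:, None] * d
        f_rec[rec] = f
        np.add.at(f_wall, lig, -f)
        energy = float(0.5 * (p.E_A * (x - p.lam) ** 2).sum())
    if return_energy:
        return f_rec, f_wall, energy
    return f_rec, f_wall
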