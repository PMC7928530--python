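"""SDPD fluid: particle container, kernel, and the three pair forces.

The plasma/cytosol is a weakly compressible SDPD fluid.  Particle i evolves
under pairwise conservative (pressure), dissipative (viscous) and random
(thermal) forces plus external driving and membrane coupling:

* conservative: ``F_C = m_i m_j (P_i/rho_i^2 + P_j/rho_j^2) F_ij r_ij``
  with the linear equation of state ``P = c_s^2 (rho - rho_0)``;
* dissipative (Espanol-Revenga shear form, continuum shear viscosity eta):
  ``F_D = -a_ij (v_ij + e (e . v_ij))``,
  ``a_ij = (5 eta / 3) F_ij m_i m_j / (rho_i rho_j)``;
* random: the exact pairwise fluctuation of the friction tensor
  ``Gamma_ij = a_ij (I + e e^T)`` at temperature kBT, with amplitudes
  ``sqrt(2 kBT) Gamma^(1/2)``, which satisfies fluctuation-dissipation
  pair by pair.

``F_ij = -W'(r)/r`` uses the Lucy kernel with compact support at the
cutoff radius (the characteristic length, 1 in dimensionless units).
All three pair forces are antisymmetric, so an isolated fluid conserves
linear momentum to round-off every step.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import _kernels as K
from .units import ConfigurationError


@dataclass(frozen=True)
class KernelSpec:
    """Smoothing kernel: family and compact-support cutoff."""

    cutoff: float = 1.0
    family: str = "lucy"

    def __post_init__(self) -> None:
        if self.cutoff <= 0:
            raise ConfigurationError("kernel cutoff must be > 0")
        if self.family != "lucy":
            raise ConfigurationError(
                f"unknown kernel family {self.family!r} (supported: lucy)"
            )

    def w(self, r):
        """Kernel value W(r); W >= 0, W(r >= cutoff) = 0, integral = 1."""
        r = np.asarray(r, dtype=float)
        q = np.minimum(r / self.cutoff, 1.0)
        s = 105.0 / (16.0 * math.pi * self.cutoff**3)
        return s * (1.0 + 3.0 * q) * (1.0 - q) ** 3

    def grad_w(self, r_vec):
        """Kernel gradient at separation vector(s) r_vec (antisymmetric)."""
        r_vec = np.atleast_2d(np.asarray(r_vec, dtype=float))
        r = np.linalg.norm(r_vec, axis=1)
        out = np.zeros_like(r_vec)
        # -F(r) * r_vec with F = -W'/r  (W' <= 0, so gradient points inward)
        f = np.array([K.lucy_f(ri, self.cutoff) for ri in r])
        out = -f[:, None] * r_vec
        return out[0] if out.shape[0] == 1 else out


@dataclass
class FluidParams:
    """Bulk fluid constants and external drive."""

    eta: float = 197.0  # dynamic viscosity
    rho0: float = 8.0  # rest mass density (number density x particle mass)
    sound_speed: float = 20.0  # EOS stiffness c_s
    kBT: float = 1.0  # 0 disables the random force
    body_acceleration: np.ndarray = field(
        default_factory=lambda: np.zeros(3)
    )

    def __post_init__(self) -> None:
        if self.eta <= 0 or self.rho0 <= 0 or self.sound_speed <= 0:
            raise ConfigurationError(
                "eta, rho0 and sound_speed must all be > 0"
            )
        if self.kBT < 0:
            raise ConfigurationError("kBT must be >= 0")
        self.body_acceleration = np.asarray(self.body_acceleration, float)

    def pressure(self, rho: np.ndarray) -> np.ndarray:
        """Linear EOS P = c_s^2 (rho - rho0)."""
        return self.sound_speed**2 * (np.asarray(rho) - self.rho0)


@dataclass
class ParticleSystem:
    """Tagged point set: fluid plus static wall (ghost/repulsive) particles."""

    positions: np.ndarray
    velocities: np.ndarray
    masses: np.ndarray
    types: np.ndarray  # 0 fluid, 1 ghost, 2 repulsive
    box_lo: np.ndarray
    box_hi: np.ndarray
    periodic: np.ndarray  # bool per axis
    densities: np.ndarray | None = None

    TYPE_FLUID = 0
    TYPE_GHOST = 1
    TYPE_REPULSIVE = 2

    def __post_init__(self) -> None:
        self.positions = np.ascontiguousarray(self.positions, float)
        self.velocities = np.ascontiguousarray(self.velocities, float)
        self.masses = np.ascontiguousarray(self.masses, float)
        self.types = np.ascontiguousarray(self.types, np.int64)
        self.box_lo = np.asarray(self.box_lo, float)
        self.box_hi = np.asarray(self.box_hi, float)
        self.periodic = np.asarray(self.periodic, bool)
        if not np.isfinite(self.positions).all():
            raise ConfigurationError("non-finite particle coordinates")

    @property
    def n(self) -> int:
        return len(self.positions)

    def neighbor_pairs(self, cutoff: float) -> np.ndarray:
        dims, start, order = K.build_grid(
            self.positions, self.box_lo, self.box_hi, cutoff
        )
        return K.self_pairs(
            self.positions, self.box_lo, self.box_hi, self.periodic,
            cutoff, dims, start, order,
        )


def compute_density(ps: ParticleSystem, kernel: KernelSpec,
                    pairs: np.ndarray | None = None) -> np.ndarray:
    """rho_i = sum_j m_j W(r_ij) including self and wall contributions."""
    if pairs is None:
        pairs = ps.neighbor_pairs(kernel.cutoff)
    rho = K.sdpd_density(
        ps.positions, ps.masses, pairs, ps.box_lo, ps.box_hi,
        ps.periodic, kernel.cutoff,
    )
    if not np.isfinite(rho).all():
        bad = int(np.nonzero(~np.isfinite(rho))[0][0])
        raise ConfigurationError(f"non-finite density at particle {bad}")
    ps.densities = rho
    return rho


def _pair_forces(ps: ParticleSystem, kernel: KernelSpec, params: FluidParams,
                 conservative: bool, dissipative: bool, random: bool,
                 dt: float = 1.0, seed: int = 0, step: int = 0,
                 pairs: np.ndarray | None = None) -> np.ndarray:
    if pairs is None:
        pairs = ps.neighbor_pairs(kernel.cutoff)
    if ps.densities is None:
        compute_density(ps, kernel, pairs)
    rho = ps.densities
    if conservative and not np.isfinite(rho).all():
        bad = int(np.nonzero(~np.isfinite(rho))[0][0])
        raise ConfigurationError(f"non-finite density at particle {bad}")
    pressure = params.pressure(rho)
    return K.sdpd_pair_forces(
        ps.positions, ps.velocities, ps.masses, rho, pressure, pairs,
        ps.box_lo, ps.box_hi, ps.periodic, kernel.cutoff, params.eta,
        params.kBT, dt, np.uint64(seed), np.uint64(step),
        conservative, dissipative, random,
    )


def conservative_force(ps, kernel, params, pairs=None) -> np.ndarray:
    """Pairwise pressure force from the weakly compressible EOS."""
    return _pair_forces(ps, kernel, params, True, False, False, pairs=pairs)


def dissipative_force(ps, kernel, params, pairs=None) -> np.ndarray:
    """Pairwise viscous force, linear in velocity differences."""
    return _pair_forces(ps, kernel, params, False, True, False, pairs=pairs)


def random_force(ps, kernel, params, dt, seed, step, pairs=None) -> np.ndarray:
    """Thermal pair force satisfying fluctuation-dissipation with F_D."""
    return _pair_forces(ps, kernel, params, False, False, True,
                        dt=dt, seed=seed, step=step, pairs=pairs)


def external_force(ps: ParticleSystem, acceleration: np.ndarray,
                   region_mask: np.ndarray | None = None) -> np.ndarray:
    """m g applied to fluid particles, optionally only inside a region."""
    f = np.zeros_like(ps.positions)
    sel = ps.types == ParticleSystem.TYPE_FLUID
    if region_mask is not None:
        sel = sel & region_mask
    f[sel] = ps.masses[sel, None] * np.asarray(acceleration, float)
    return f
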