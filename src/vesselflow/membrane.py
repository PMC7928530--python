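"""Discrete elastic membrane model and its calibration.

The membrane is a triangulated network whose total deformation energy is

    U_def = U_s + U_b + U_a + U_v

* ``U_s`` — in-plane springs on every edge: worm-like-chain (WLC)
  attraction plus an inverse-power (1/l) repulsion whose coefficient is
  fixed by force balance at the stress-free edge length, so the reference
  mesh is in equilibrium edge by edge.
* ``U_b`` — dihedral bending ``K_B sum [1 - cos(theta - theta0)]`` with the
  spontaneous angles taken from the reference mesh.
* ``U_a`` — quadratic global-area and per-triangle local-area penalties
  (the membrane area is restrained to vary by no more than ~3%).
* ``U_v`` — quadratic volume penalty (no material exchange; volume
  restrained to ~3% as well).

The network maps onto three macroscopic moduli:

* shear modulus
  ``E_S = (sqrt(3) kBT / (4 p l0)) [ x0/(2(1-x0)^3) + 1/(2(1-x0)^2)
  + 3 x0 - 1/2 ]`` with ``x0 = l0/l_max`` (WLC + power network result),
* bending modulus ``E_B = (2/sqrt(3)) K_B``,
* dilation modulus ``E_D = 2 E_S + K_AG + K_AL``.

:func:`calibrate_from_moduli` inverts these relations: given (E_S, E_B,
E_D) it solves for the persistence length p, sets ``K_B = (sqrt(3)/2) E_B``
and splits ``E_D - 2 E_S`` between the global and local area constants.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import _kernels as K
from .geometry import CellMesh
from .units import ConfigurationError

#: default maximum-extension ratio of the WLC springs, l0/l_max
DEFAULT_X0 = 1.0 / 2.2

#: default split of E_D - 2 E_S between global and local area constants
DEFAULT_KAG_KAL_RATIO = 2.0


class OverstretchedEdgeError(RuntimeError):
    """An edge reached its WLC contour length (force diverges)."""


def _wlc_bracket(x0: float) -> float:
    return (
        x0 / (2.0 * (1.0 - x0) ** 3)
        + 1.0 / (2.0 * (1.0 - x0) ** 2)
        + 3.0 * x0
        - 0.5
    )


def shear_modulus_wlc(kBT: float, p: float, l0: float,
                      x0: float = DEFAULT_X0) -> float:
    """Macroscopic shear modulus of the WLC + power triangular network."""
    return math.sqrt(3.0) * kBT / (4.0 * p * l0) * _wlc_bracket(x0)


@dataclass
class MembraneMaterial:
    """Microscopic membrane constants for one cell mesh."""

    kBT: float
    persistence_length: float  # p
    x0: float  # l0 / l_max
    l_max: np.ndarray  # per edge
    k_p: np.ndarray  # per-edge power-repulsion coefficient
    K_B: float
    theta0: np.ndarray  # per-dihedral spontaneous angle (reference mesh)
    K_AG: float
    K_AL: float
    K_V: float
    # macroscopic moduli this material was calibrated to
    E_S: float = 0.0
    E_B: float = 0.0
    E_D: float = 0.0

    def __post_init__(self) -> None:
        if not (0.0 < self.x0 < 1.0):
            raise ConfigurationError(f"x0 must lie in (0, 1), got {self.x0}")
        for name in ("kBT", "persistence_length"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be > 0")
        for name in ("K_B", "K_AG", "K_AL", "K_V"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")


def calibrate_from_moduli(E_S: float, E_B: float, E_D: float,
                          mesh: CellMesh, kBT: float = 1.0,
                          x0: float = DEFAULT_X0,
                          kag_kal_ratio: float = DEFAULT_KAG_KAL_RATIO,
                          K_V: float | None = None) -> MembraneMaterial:
    """Solve the network constants from macroscopic moduli.

    The persistence length follows from inverting the WLC network shear
    modulus at the mesh's mean stress-free edge length; each edge gets its
    own contour length ``l_max = l0/x0`` and a power-repulsion coefficient
    balancing the WLC tension at l0, so the reference mesh is stress-free.
    """
    if E_S <= 0 or E_B <= 0 or E_D <= 0:
        raise ConfigurationError("moduli must be > 0")
    if E_D < 2 * E_S:
        raise ConfigurationError(
            f"E_D = {E_D} must be >= 2 E_S = {2 * E_S} for nonnegative "
            "area constants"
        )
    l0 = mesh.rest_edge_lengths
    l0_mean = float(l0.mean())
    p = math.sqrt(3.0) * kBT * _wlc_bracket(x0) / (4.0 * l0_mean * E_S)
    if p <= 0:
        raise ConfigurationError("persistence length solved non-positive")
    l_max = l0 / x0
    # force balance at l0: k_p/l0^2 = (kBT/p)[1/(4(1-x0)^2) - 1/4 + x0]
    tension = kBT / p * (1.0 / (4.0 * (1.0 - x0) ** 2) - 0.25 + x0)
    k_p = tension * l0**2
    K_B = math.sqrt(3.0) / 2.0 * E_B
    area_total = E_D - 2.0 * E_S
    K_AG = area_total * kag_kal_ratio / (1.0 + kag_kal_ratio)
    K_AL = area_total - K_AG
    if K_V is None:
        # volume stiffness comparable (per fractional deviation) to the
        # area stiffness; keeps volume within the ~3% restraint
        K_V = (K_AG + K_AL) * mesh.rest_area / max(mesh.rest_volume, 1e-12)
    return MembraneMaterial(
        kBT=kBT,
        persistence_length=p,
        x0=x0,
        l_max=np.ascontiguousarray(l_max),
        k_p=np.ascontiguousarray(k_p),
        K_B=K_B,
        theta0=np.ascontiguousarray(mesh.rest_dihedrals),
        K_AG=K_AG,
        K_AL=K_AL,
        K_V=K_V,
        E_S=E_S,
        E_B=E_B,
        E_D=E_D,
    )


def recompute_shear_modulus(mat: MembraneMaterial, mesh: CellMesh) -> float:
    """E_S implied by a material's constants (round-trip check)."""
    return shear_modulus_wlc(
        mat.kBT, mat.persistence_length,
        float(mesh.rest_edge_lengths.mean()), mat.x0
    )


# ---------------------------------------------------------------------------
# Forces
# ---------------------------------------------------------------------------


def inplane_force(mesh: CellMesh, mat: MembraneMaterial,
                  return_energy: bool = False, strict: bool = True):
    """-dU_s/dX: WLC + power spring force per vertex.

    With ``strict`` (default) an edge at or beyond its contour length
    raises :class:`OverstretchedEdgeError`; with ``strict=False`` the
    regularized (constant-tension) continuation is returned instead,
    which is what the time-stepping loop uses so that transient extreme
    stretches relax rather than abort a run.
    """
    f, e, bad = K.inplane_forces(
        mesh.vertices, mesh.edges, mat.l_max, mat.k_p,
        mat.kBT / mat.persistence_length,
    )
    if bad >= 0 and strict:
        i, j = mesh.edges[bad]
        raise OverstretchedEdgeError(
            f"edge {bad} (vertices {i}-{j}) stretched to its contour "
            f"length l_max = {mat.l_max[bad]:.4g}"
        )
    return (f, e) if return_energy else f


def bending_force(mesh: CellMesh, mat: MembraneMaterial,
                  return_energy: bool = False):
    """-dU_b/dX: dihedral bending force per vertex."""
    f, e = K.bending_forces(
        mesh.vertices, mesh.edges, mesh.edge_opposite, mat.K_B, mat.theta0
    )
    return (f, e) if return_energy else f


def area_volume_forces(mesh: CellMesh, mat: MembraneMaterial,
                       return_energy: bool = False):
    """-d(U_a + U_v)/dX: area-restraint and volume-restraint forces."""
    f, e = K.area_volume_forces(
        mesh.vertices, mesh.faces, mat.K_AG, mesh.rest_area,
        mat.K_AL, mesh.rest_face_areas, mat.K_V, mesh.rest_volume,
    )
    return (f, e) if return_energy else f


def deformation_force(mesh: CellMesh, mat: MembraneMaterial,
                      return_energy: bool = False, strict: bool = True):
    """-dU_def/dX: total membrane deformation force per vertex."""
    f1, e1 = inplane_force(mesh, mat, return_energy=True, strict=strict)
    f2, e2 = bending_force(mesh, mat, return_energy=True)
    f3, e3 = area_volume_forces(mesh, mat, return_energy=True)
    f = f1 + f2 + f3
    return (f, e1 + e2 + e3) if return_energy else f


def deformation_energy(mesh: CellMesh, mat: MembraneMaterial) -> float:
    """Total deformation energy U_def of the current configuration."""
    return deformation_force(mesh, mat, return_energy=True)[1]
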