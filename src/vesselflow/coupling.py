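"""Two-way fluid-membrane coupling (particle-particle immersed boundary).

Membrane vertex k couples to the fluid particles i inside one kernel
cutoff through weights ``beta_ik`` proportional to the SDPD kernel
W(|x_i - X_k|) and normalized per vertex (sum_i beta_ik = 1).  Membrane
forces are spread to the fluid with the same normalized weights used to
interpolate fluid velocity back onto the membrane, which conserves the
total coupling force exactly and advects a membrane at precisely the
local flow speed in uniform flow.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _kernels as K


class CouplingError(RuntimeError):
    """A membrane vertex has no fluid particle within the kernel support."""


@dataclass
class CouplingWeights:
    """Sparse normalized weights between membrane vertices and fluid."""

    pairs: np.ndarray  # (n, 2): [vertex k, fluid particle i]
    weights: np.ndarray  # (n,)
    n_membrane: int
    n_fluid: int


def compute_weights(fluid_pos: np.ndarray, membrane_pos: np.ndarray,
                    box_lo: np.ndarray, box_hi: np.ndarray,
                    periodic: np.ndarray, cutoff: float,
                    grid=None, allow_lonely: bool = False) -> CouplingWeights:
    """Kernel-weighted, per-vertex-normalized coupling weights.

    ``grid`` may carry a prebuilt (dims, start, order) grid over
    ``fluid_pos`` to avoid rebuilding.  A vertex with no fluid particle in
    its kernel support raises :class:`CouplingError` unless
    ``allow_lonely`` is set, in which case it is left uncoupled for this
    step (zero interpolated velocity, no spread force).
    """
    if grid is None:
        grid = K.build_grid(fluid_pos, box_lo, box_hi, cutoff)
    dims, start, order = grid
    pairs = K.cross_pairs(membrane_pos, fluid_pos, box_lo, box_hi,
                          periodic, cutoff, dims, start, order)
    w, totals = K.pair_kernel_weights(
        pairs, membrane_pos, fluid_pos, box_lo, box_hi, periodic, cutoff,
        len(membrane_pos),
    )
    lonely = np.nonzero(totals <= 0.0)[0]
    if len(lonely) and not allow_lonely:
        raise CouplingError(
            f"{len(lonely)} membrane vertices have no fluid neighbor within "
            f"the kernel cutoff (first: vertex {lonely[0]} at "
            f"{membrane_pos[lonely[0]]}); the coupling is under-resolved"
        )
    return CouplingWeights(pairs, w, len(membrane_pos), len(fluid_pos))


def interpolate_velocity(w: CouplingWeights,
                         fluid_vel: np.ndarray) -> np.ndarray:
    """Per-vertex velocity: convex combination of neighbor fluid velocities."""
    _, vel = K.spread_and_interp(
        w.pairs, w.weights, np.zeros((w.n_membrane, 3)), fluid_vel,
        w.n_fluid, w.n_membrane,
    )
    return vel


def spread_force(w: CouplingWeights, membrane_force: np.ndarray) -> np.ndarray:
    """Per-fluid-particle force; total equals total membrane force exactly."""
    force, _ = K.spread_and_interp(
        w.pairs, w.weights, membrane_force,
        np.zeros((w.n_fluid, 3)), w.n_fluid, w.n_membrane,
    )
    return force
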