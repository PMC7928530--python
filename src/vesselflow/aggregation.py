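"""Cell-cell aggregation via a Morse potential between surface elements.

Each pair of facing triangle elements (one on each cell) within a cutoff
contributes

    phi(r) = E_I [ exp(2 beta (r0 - r)) - 2 exp(beta (r0 - r)) ]

weighted by the normal projections (n_m . k_m)(n_m' . k_m') and the element
areas, where k is the unit vector along the line connecting the two cell
centroids.  The potential is weakly attractive beyond the zero-force
distance r0 and strongly repulsive inside it, giving both the
aggregation-driven wall-directed push on a marginating tumor cell and the
short-range excluded-volume interaction between cells.

The numeric strength/range constants are not uniquely pinned by a single
experiment; defaults follow the weak-aggregation calibration of the Morse
cell-interaction literature (De = 0.3 uJ/m^2, r0 = 0.49 um,
beta = 3.84 um^-1) and are exposed in the configuration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from . import _kernels as K
from .geometry import CellMesh
from .units import ConfigurationError


@dataclass(frozen=True)
class AggregationParams:
    """Morse surface-interaction constants (dimensionless)."""

    E_I: float = 289.7  # surface energy strength (energy / area)
    r0: float = 0.245  # zero-force distance
    beta: float = 7.68  # inverse decay length
    cutoff: float = 1.0  # element-pair interaction cutoff
    clamp_negative_projection: bool = False

    def __post_init__(self) -> None:
        if self.E_I < 0 or self.r0 <= 0 or self.beta <= 0:
            raise ConfigurationError("aggregation constants must be positive")
        if self.cutoff <= self.r0:
            raise ConfigurationError("aggregation cutoff must exceed r0")


def morse_potential(r: np.ndarray | float, p: AggregationParams):
    """Morse pair energy phi(r); minimum -E_I at r = r0."""
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0):
        raise ConfigurationError("Morse potential requires r > 0")
    eb = np.exp(p.beta * (p.r0 - r))
    return p.E_I * (eb * eb - 2.0 * eb)


def morse_force_magnitude(r: np.ndarray | float, p: AggregationParams):
    """-dphi/dr: positive = repulsive (r < r0), negative = attractive."""
    r = np.asarray(r, dtype=float)
    eb = np.exp(p.beta * (p.r0 - r))
    return 2.0 * p.beta * p.E_I * (eb * eb - eb)


def _concat_cells(cells: Sequence[CellMesh]):
    verts = np.concatenate([c.vertices for c in cells])
    offsets = np.cumsum([0] + [c.n_vertices for c in cells])
    faces = np.concatenate(
        [c.faces + offsets[i] for i, c in enumerate(cells)]
    )
    face_cell = np.concatenate(
        [np.full(len(c.faces), i, dtype=np.int64) for i, c in enumerate(cells)]
    )
    return verts, faces, face_cell, offsets


def aggregation_forces(cells: Sequence[CellMesh], p: AggregationParams,
                       return_energy: bool = False,
                       return_cell_forces: bool = False):
    """Per-vertex aggregation forces over all inter-cell element pairs.

    Candidate element pairs come from a uniform grid over triangle
    centroids (same pairs as the brute-force double loop, found in
    O(N) instead of O(N^2)).  Returns forces as a list of per-cell arrays;
    optionally also the net force on each cell and the total energy.
    """
    if len(cells) == 0:
        out = ([], np.zeros((0, 3)), 0.0)
    else:
        verts, faces, face_cell, offsets = _concat_cells(cells)
        centroids = verts[faces].mean(axis=1)
        lo = centroids.min(axis=0) - 2 * p.cutoff
        hi = centroids.max(axis=0) + 2 * p.cutoff
        periodic = np.zeros(3, dtype=np.bool_)
        dims, start, order = K.build_grid(centroids, lo, hi, p.cutoff)
        pairs = K.self_pairs(centroids, lo, hi, periodic, p.cutoff,
                             dims, start, order)
        cell_centroids = np.array([c.centroid() for c in cells])
        force, cell_force, energy = K.morse_element_forces(
            verts, faces, face_cell, cell_centroids, pairs,
            p.E_I, p.r0, p.beta, p.cutoff, p.clamp_negative_projection,
        )
        per_cell = [
            force[offsets[i]:offsets[i + 1]] for i in range(len(cells))
        ]
        out = (per_cell, cell_force, energy)
    result = [out[0]]
    if return_cell_forces:
        result.append(out[1])
    if return_energy:
        result.append(out[2])
    return result[0] if len(result) == 1 else tuple(result)


def aggregation_energy_brute_force(cells: Sequence[CellMesh],
                                   p: AggregationParams) -> float:
    """O(N^2) double-loop reference energy (oracle for the grid version)."""
    total = 0.0
    metas = []
    for c in cells:
        metas.append(
            (c.face_centroids(), c.face_normals(), c.face_areas(), c.centroid())
        )
    for a in range(len(cells)):
        for b in range(a + 1, len(cells)):
            ca, na, Aa, Ca = metas[a]
            cb, nb, Ab, Cb = metas[b]
            k = Cb - Ca
            k = k / np.linalg.norm(k)
            for m in range(len(ca)):
                d = cb - ca[m]
                r = np.linalg.norm(d, axis=1)
                sel = (r < p.cutoff) & (r > 1e-12)
                if not sel.any():
                    continue
                w = (na[m] @ k) * (-(nb[sel] @ k))
                if p.clamp_negative_projection:
                    w = np.maximum(w, 0.0)
                eb = np.exp(p.beta * (p.r0 - r[sel]))
                phi = p.E_I * (eb * eb - 2.0 * eb)
                total += float(
                    (phi * w * 0.5 * (Aa[m] + Ab[sel])).sum()
                )
    return total
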