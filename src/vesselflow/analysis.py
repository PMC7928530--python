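"""Trajectory analysis: margination deviation, radial aggregation force,
bond/retention profiles, adhesion-state classification.

All operations are pure functions of a recorded :class:`~vesselflow.driver.
Trajectory` — re-running the analysis is bit-identical.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .driver import Trajectory
from .geometry import WallGeometry
from .units import ConfigurationError


def nearest_centerline_point(geometry: WallGeometry,
                             points: np.ndarray):
    """Closest centerline point and outward radial unit vector per point.

    Works on the polyline-segment centerline every wall geometry carries;
    for a straight tube this reduces to projecting onto the axis.
    """
    p = np.atleast_2d(points)
    best_d = np.full(len(p), np.inf)
    best_pt = np.zeros_like(p)
    for (a, b) in geometry.centerline:
        ab = b - a
        t = np.clip((p - a) @ ab / (ab @ ab), 0.0, 1.0)
        proj = a + t[:, None] * ab
        d = np.linalg.norm(p - proj, axis=1)
        upd = d < best_d
        best_d[upd] = d[upd]
        best_pt[upd] = proj[upd]
    radial = p - best_pt
    norm = np.linalg.norm(radial, axis=1)
    with np.errstate(invalid="ignore"):
        unit = np.where(norm[:, None] > 1e-12, radial / norm[:, None], 0.0)
    return best_pt, best_d, unit


def centerline_deviation(traj: Trajectory, cell: int,
                         geometry: WallGeometry | None = None):
    """(x-position, radial deviation) of a cell centroid per snapshot."""
    geometry = geometry or traj.wall
    cents = traj.centroids[:, cell, :]
    # deviation is measured in the wrapped (geometric) frame
    wrapped = cents.copy()
    if geometry.periodic[0]:
        L = geometry.box_hi[0] - geometry.box_lo[0]
        wrapped[:, 0] = geometry.box_lo[0] + (
            (wrapped[:, 0] - geometry.box_lo[0]) % L
        )
    _, dev, _ = nearest_centerline_point(geometry, wrapped)
    return cents[:, 0], dev


def radial_aggregation_force(traj: Trajectory, cell: int,
                             geometry: WallGeometry | None = None):
    """(x-position, outward radial aggregation force) per snapshot.

    Positive values push the cell toward the wall, negative toward the
    centerline.
    """
    geometry = geometry or traj.wall
    cents = traj.centroids[:, cell, :]
    wrapped = cents.copy()
    if geometry.periodic[0]:
        L = geometry.box_hi[0] - geometry.box_lo[0]
        wrapped[:, 0] = geometry.box_lo[0] + (
            (wrapped[:, 0] - geometry.box_lo[0]) % L
        )
    _, _, outward = nearest_centerline_point(geometry, wrapped)
    f = traj.aggregation_forces[:, cell, :]
    return cents[:, 0], np.einsum("ij,ij->i", f, outward)


def bond_and_retention_profiles(traj: Trajectory, x_bins: np.ndarray,
                                cell: int = 0):
    """Per-x-bin maximum/mean bond count and residence time.

    Residence time of a bin is the sum of snapshot intervals whose cell
    centroid falls inside it.
    """
    x_bins = np.asarray(x_bins, float)
    if len(x_bins) < 2 or np.any(np.diff(x_bins) <= 0):
        raise ConfigurationError("x_bins must be increasing with >= 2 edges")
    x = traj.centroids[:, cell, 0]
    if x.min() < x_bins[0] or x.max() > x_bins[-1]:
        raise ConfigurationError(
            f"x_bins [{x_bins[0]}, {x_bins[-1]}] do not cover the "
            f"traversed range [{x.min():.3g}, {x.max():.3g}]"
        )
    nb = len(x_bins) - 1
    which = np.clip(np.digitize(x, x_bins) - 1, 0, nb - 1)
    dt_snap = np.empty(len(x))
    dt_snap[1:] = np.diff(traj.times)
    dt_snap[0] = dt_snap[1] if len(x) > 1 else 0.0
    bonds = traj.bond_counts
    max_bonds = np.zeros(nb)
    mean_bonds = np.zeros(nb)
    residence = np.zeros(nb)
    for b in range(nb):
        sel = which == b
        if sel.any():
            max_bonds[b] = bonds[sel].max()
            mean_bonds[b] = bonds[sel].mean()
            residence[b] = dt_snap[sel].sum()
    return max_bonds, mean_bonds, residence


@dataclass(frozen=True)
class AdhesionClassification:
    state: str  # "detachment" | "rolling" | "firm" | "inconclusive"
    mean_velocity: float
    mean_bonds: float
    bond_persistence: float
    velocity_threshold: float

    def __str__(self) -> str:
        return (
            f"{self.state} (|v| = {self.mean_velocity:.3g}, "
            f"<N_b> = {self.mean_bonds:.1f}, "
            f"persistence = {self.bond_persistence:.0%}, "
            f"firm threshold = {self.velocity_threshold:.3g})"
        )


def classify_adhesion_state(bond_series: np.ndarray,
                            velocity_series: np.ndarray,
                            free_velocity: float,
                            steady_fraction: float = 1.0 / 3.0,
                            firm_velocity_fraction: float = 0.05,
                            persistence_threshold: float = 0.9,
                            min_window: int = 5) -> AdhesionClassification:
    """Classify detachment / rolling / firm adhesion from steady-window
    statistics.

    Over the final ``steady_fraction`` of the series:

    * **firm** — bonds persist (bound in >= ``persistence_threshold`` of
      snapshots) and the mean translational speed is below
      ``firm_velocity_fraction`` of the cell-free flow speed;
    * **detachment** — bonds are gone at the end and the velocity has
      recovered toward the unbound value;
    * **rolling** — otherwise: persistent bond turnover with a nonzero,
      fluctuating translational velocity.
    """
    bonds = np.asarray(bond_series, float)
    vel = np.asarray(velocity_series, float)
    if len(bonds) != len(vel):
        raise ConfigurationError("bond and velocity series lengths differ")
    n = len(bonds)
    w = max(int(round(n * steady_fraction)), 1)
    if n < min_window or w < 2:
        return AdhesionClassification(
            "inconclusive", float("nan"), float("nan"), float("nan"),
            firm_velocity_fraction * free_velocity,
        )
    bw = bonds[-w:]
    vw = vel[-w:]
    # magnitude of the windowed mean velocity: an arrested cell's
    # fluctuating drift averages to ~zero, a rolling cell's does not
    mean_v = float(abs(vw.mean()))
    mean_b = float(bw.mean())
    persistence = float((bw > 0).mean())
    vthresh = firm_velocity_fraction * abs(free_velocity)
    if persistence >= persistence_threshold and mean_v <= vthresh:
        state = "firm"
    elif bw[-max(w // 4, 1):].mean() < 0.5 and mean_v > vthresh:
        state = "detachment"
    else:
        state = "rolling"
    return AdhesionClassification(
        state, mean_v, mean_b, persistence, vthresh
    )


def classify_trajectory(traj: Trajectory, cell: int = 0,
                        free_velocity: float | None = None,
                        **kwargs) -> AdhesionClassification:
    """Classify a recorded run.

    The translational velocity is the centroid drift rate (finite
    differences of the axially unwrapped centroid track), which averages
    out the thermal velocity fluctuations of the membrane that would
    otherwise mask an arrested cell.
    """
    if free_velocity is None:
        w = traj.wall
        if w is not None and w.kind == "couette":
            # cell-free Couette speed at the cell's mean height
            gap = w.dims["gap"]
            z = traj.centroids[:, cell, 2].mean()
            free_velocity = w.dims["shear_rate"] * z
        else:
            raise ConfigurationError(
                "free_velocity must be given for this geometry"
            )
    drift = np.gradient(traj.centroids[:, cell, 0], traj.times)
    return classify_adhesion_state(
        traj.bond_counts, drift, free_velocity, **kwargs,
    )


def radial_positions(traj: Trajectory, kinds: tuple[str, ...] = ("rbc",)):
    """Per-snapshot mean radial distance of cells of the given kinds."""
    geometry = traj.wall
    sel = [i for i, k in enumerate(traj.cell_kinds) if k in kinds]
    if not sel:
        return np.zeros((len(traj.times), 0))
    out = np.empty((len(traj.times), len(sel)))
    for t in range(len(traj.times)):
        pts = traj.centroids[t, sel, :].copy()
        if geometry.periodic[0]:
            L = geometry.box_hi[0] - geometry.box_lo[0]
            pts[:, 0] = geometry.box_lo[0] + (
                (pts[:, 0] - geometry.box_lo[0]) % L
            )
        _, d, _ = nearest_centerline_point(geometry, pts)
        out[t] = d
    return out
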