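"""Plain-text output writers: legacy VTK, OFF and CSV.

Snapshots are written in formats any standard visualization tool reads
(ParaView, meshlab):  membrane meshes as VTK polydata or OFF, particle
sets as VTK point clouds or CSV, bonds as VTK line segments.  Lengths are
dimensionless (characteristic-length units); pass a
:class:`~vesselflow.units.UnitSystem` to also emit SI coordinates.
"""

from __future__ import annotations

import os
from typing import Sequence

import numpy as np

from .geometry import CellMesh
from .units import UnitSystem


def _header(fh, title: str) -> None:
    fh.write("# vtk DataFile Version 3.0\n")
    fh.write(f"{title}\n")
    fh.write("ASCII\n")


def write_vtk_points(path: str, positions: np.ndarray,
                     scalars: dict[str, np.ndarray] | None = None,
                     title: str = "particles") -> None:
    """Point cloud with optional per-point scalar arrays (legacy VTK)."""
    positions = np.asarray(positions, float)
    with open(path, "w") as fh:
        _header(fh, title)
        fh.write("DATASET POLYDATA\n")
        fh.write(f"POINTS {len(positions)} float\n")
        for p in positions:
            fh.write(f"{p[0]:.6g} {p[1]:.6g} {p[2]:.6g}\n")
        if scalars:
            fh.write(f"POINT_DATA {len(positions)}\n")
            for name, vals in scalars.items():
                vals = np.asarray(vals)
                fh.write(f"SCALARS {name} float 1\nLOOKUP_TABLE default\n")
                for v in vals:
                    fh.write(f"{float(v):.6g}\n")


def write_vtk_mesh(path: str, mesh: CellMesh,
                   point_scalars: dict[str, np.ndarray] | None = None,
                   title: str = "membrane") -> None:
    """Triangulated membrane as VTK polydata."""
    v, f = mesh.vertices, mesh.faces
    with open(path, "w") as fh:
        _header(fh, title)
        fh.write("DATASET POLYDATA\n")
        fh.write(f"POINTS {len(v)} float\n")
        for p in v:
            fh.write(f"{p[0]:.6g} {p[1]:.6g} {p[2]:.6g}\n")
        fh.write(f"POLYGONS {len(f)} {4 * len(f)}\n")
        for a, b, c in f:
            fh.write(f"3 {a} {b} {c}\n")
        if point_scalars:
            fh.write(f"POINT_DATA {len(v)}\n")
            for name, vals in point_scalars.items():
                fh.write(f"SCALARS {name} float 1\nLOOKUP_TABLE default\n")
                for val in np.asarray(vals):
                    fh.write(f"{float(val):.6g}\n")


def write_vtk_bonds(path: str, receptor_pos: np.ndarray,
                    ligand_pos: np.ndarray, title: str = "bonds") -> None:
    """Live bonds as VTK line segments (receptor end to ligand end)."""
    n = len(receptor_pos)
    with open(path, "w") as fh:
        _header(fh, title)
        fh.write("DATASET POLYDATA\n")
        fh.write(f"POINTS {2 * n} float\n")
        for p in receptor_pos:
            fh.write(f"{p[0]:.6g} {p[1]:.6g} {p[2]:.6g}\n")
        for p in ligand_pos:
            fh.write(f"{p[0]:.6g} {p[1]:.6g} {p[2]:.6g}\n")
        fh.write(f"LINES {n} {3 * n}\n")
        for i in range(n):
            fh.write(f"2 {i} {n + i}\n")


def write_off(path: str, mesh: CellMesh) -> None:
    """Membrane mesh in OFF format."""
    v, f = mesh.vertices, mesh.faces
    with open(path, "w") as fh:
        fh.write("OFF\n")
        fh.write(f"{len(v)} {len(f)} 0\n")
        for p in v:
            fh.write(f"{p[0]:.6g} {p[1]:.6g} {p[2]:.6g}\n")
        for a, b, c in f:
            fh.write(f"3 {a} {b} {c}\n")


def write_particles_csv(path: str, positions: np.ndarray,
                        types: Sequence[str] | np.ndarray,
                        units: UnitSystem | None = None) -> None:
    """(x, y, z, type) table, optionally with SI columns appended."""
    with open(path, "w") as fh:
        cols = "x,y,z,type"
        if units is not None:
            cols += ",x_m,y_m,z_m"
        fh.write(cols + "\n")
        for p, t in zip(np.asarray(positions, float), types):
            row = f"{p[0]:.8g},{p[1]:.8g},{p[2]:.8g},{t}"
            if units is not None:
                si = p * units.l_ref
                row += f",{si[0]:.8g},{si[1]:.8g},{si[2]:.8g}"
            fh.write(row + "\n")


def write_trajectory_csv(path: str, traj) -> None:
    """Per-snapshot diagnostics table (time, cells, bonds, temperature)."""
    import pandas as pd

    rows = []
    for t in range(len(traj.times)):
        row = {
            "time": traj.times[t],
            "bond_count": traj.bond_counts[t],
            "fluid_temperature": traj.fluid_temperature[t],
        }
        for c in range(traj.centroids.shape[1]):
            row[f"cell{c}_x"] = traj.centroids[t, c, 0]
            row[f"cell{c}_y"] = traj.centroids[t, c, 1]
            row[f"cell{c}_z"] = traj.centroids[t, c, 2]
            row[f"cell{c}_vx"] = traj.velocities[t, c, 0]
            row[f"cell{c}_area"] = traj.areas[t, c]
            row[f"cell{c}_volume"] = traj.volumes[t, c]
            row[f"cell{c}_fagg_x"] = traj.aggregation_forces[t, c, 0]
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def write_geometry_bundle(outdir: str, wall, ligands=None,
                          fluid_positions=None, cells=()) -> None:
    """Write a geometry bundle directory (walls, ligands, fluid, meshes)."""
    os.makedirs(outdir, exist_ok=True)
    write_vtk_points(os.path.join(outdir, "repulsive.vtk"), wall.repulsive)
    write_vtk_points(os.path.join(outdir, "ghost.vtk"), wall.ghost)
    pos = np.concatenate([wall.repulsive, wall.ghost])
    types = ["repulsive"] * len(wall.repulsive) + ["ghost"] * len(wall.ghost)
    if ligands is not None and len(ligands):
        write_vtk_points(os.path.join(outdir, "ligands.vtk"),
                         ligands.positions)
        pos = np.concatenate([pos, ligands.positions])
        types += ["ligand"] * len(ligands)
    if fluid_positions is not None and len(fluid_positions):
        write_vtk_points(os.path.join(outdir, "fluid.vtk"), fluid_positions)
        pos = np.concatenate([pos, fluid_positions])
        types += ["fluid"] * len(fluid_positions)
    write_particles_csv(os.path.join(outdir, "particles.csv"), pos, types)
    for i, mesh in enumerate(cells):
        write_vtk_mesh(os.path.join(outdir, f"cell_{i:03d}.vtk"), mesh)
        write_off(os.path.join(outdir, f"cell_{i:03d}.off"), mesh)
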