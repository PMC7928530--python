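"""Run orchestration: velocity-Verlet integration, wall enforcement,
inflow/outflow recycling, checkpointing.

One time step (velocity-Verlet with the membrane advected kinematically by
the interpolated fluid velocity):

1. half-kick fluid velocities;
2. drift fluid positions and membrane vertices; wrap periodic images and
   recycle outflow;
3. recompute everything: densities -> SDPD pair forces -> membrane
   deformation -> aggregation -> adhesion kinetics + forces -> wall
   repulsion -> spread membrane forces to the fluid -> external drive;
4. half-kick with the new forces;
5. interpolate the new fluid velocities onto the membrane for the next
   drift.

Wall no-slip and no-penetration come from three ingredients: ghost
particles outside the lumen carrying the wall velocity (entering the
density and viscous sums), repulsive particles on the wall surface, and a
short-range quadratic repulsion acting on any fluid or membrane particle
that approaches the surface closer than its interaction range.

All randomness is counter-based and keyed by (seed, step, pair), so a run
is bit-reproducible and a resumed checkpoint continues identically.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from . import _kernels as K
from . import adhesion as adh
from . import aggregation as agg
from . import coupling as cpl
from . import membrane as mb
from .config import SimulationConfig
from .fluid import FluidParams, KernelSpec, ParticleSystem
from .geometry import (
    CellMesh,
    LigandField,
    WallGeometry,
    _clamp_to_lumen,
    fill_fluid,
    make_biconcave_mesh,
    make_bifurcation,
    make_couette_box,
    make_sphere_mesh,
    make_tube,
    place_rbcs_tube,
    points_inside_mesh,
    seed_ligands,
)
from .units import ConfigurationError


@dataclass
class Trajectory:
    """Recorded time series of the quantities the analysis layer consumes."""

    times: np.ndarray  # (T,)
    centroids: np.ndarray  # (T, n_cells, 3), axially unwrapped
    velocities: np.ndarray  # (T, n_cells, 3)
    bond_counts: np.ndarray  # (T,)
    aggregation_forces: np.ndarray  # (T, n_cells, 3)
    areas: np.ndarray  # (T, n_cells)
    volumes: np.ndarray  # (T, n_cells)
    fluid_temperature: np.ndarray  # (T,)
    cell_kinds: list[str] = field(default_factory=list)
    wall: WallGeometry | None = None

    def __len__(self) -> int:
        return len(self.times)


def wall_repulsion(targets: np.ndarray, rep_pos: np.ndarray, grid,
                   box_lo, box_hi, periodic, strength: float,
                   rng_range: float) -> np.ndarray:
    """Short-range quadratic repulsion from wall surface particles.

    F = strength * (1 - r / range)^2 e_away for r < range, zero beyond.
    """
    dims, start, order = grid
    pairs = K.cross_pairs(targets, rep_pos, box_lo, box_hi, periodic,
                          rng_range, dims, start, order)
    if len(pairs) == 0:
        return np.zeros_like(targets)
    f, _ = K.soft_repulsion_cross(
        pairs, targets, rep_pos, box_lo, box_hi, periodic,
        strength, rng_range,
    )
    return f


class Simulation:
    """Assembled run state and the velocity-Verlet loop."""

    def __init__(self, config: SimulationConfig, wall: WallGeometry,
                 cells: list[CellMesh], materials: list[mb.MembraneMaterial],
                 ligands: LigandField | None = None,
                 fluid_positions: np.ndarray | None = None):
        self.config = config
        self.wall = wall
        self.cells = cells
        self.materials = materials
        self.templates = [c.transformed() for c in cells]
        fl = config.fluid
        self.kernel = KernelSpec(cutoff=1.0)
        cs = fl.sound_speed
        if cs <= 0:
            cs = 20.0
        self.params = FluidParams(
            eta=fl.viscosity, rho0=fl.number_density * fl.particle_mass,
            sound_speed=cs, kBT=fl.kBT,
            body_acceleration=np.asarray(config.drive.acceleration),
        )
        self.seed = np.uint64(config.run.seed & 0x7FFFFFFF)
        self.dt = config.run.time_step
        self.step_index = 0

        if fluid_positions is None:
            fluid_positions = fill_fluid(wall, fl.number_density)
        nf = len(fluid_positions)
        rep, gho = wall.repulsive, wall.ghost
        rep_vel = np.zeros_like(rep)
        if wall.kind == "couette":
            nb = wall.dims["n_bottom_repulsive"]
            rep_vel[nb:, 0] = wall.dims["top_speed"]
        pos = np.concatenate([fluid_positions, rep, gho])
        vel = np.concatenate(
            [np.zeros((nf, 3)), rep_vel, wall.ghost_velocity]
        )
        types = np.concatenate([
            np.zeros(nf, np.int64),
            np.full(len(rep), ParticleSystem.TYPE_REPULSIVE, np.int64),
            np.full(len(gho), ParticleSystem.TYPE_GHOST, np.int64),
        ])
        self.ps = ParticleSystem(
            positions=pos, velocities=vel,
            masses=np.full(len(pos), fl.particle_mass),
            types=types, box_lo=wall.box_lo, box_hi=wall.box_hi,
            periodic=np.array(wall.periodic, bool),
        )
        self.n_fluid = nf
        self._wall_slice = slice(nf, len(pos))

        # static wall-wall density contribution (walls never move)
        wall_pos = pos[nf:]
        if len(wall_pos):
            dims, start, order = K.build_grid(
                wall_pos, wall.box_lo, wall.box_hi, self.kernel.cutoff
            )
            wpairs = K.self_pairs(
                wall_pos, wall.box_lo, wall.box_hi, self.ps.periodic,
                self.kernel.cutoff, dims, start, order,
            )
            wrho = K.sdpd_density(
                wall_pos, self.ps.masses[nf:], wpairs, wall.box_lo,
                wall.box_hi, self.ps.periodic, self.kernel.cutoff,
            )
            self._wall_rho_static = wrho - self.ps.masses[nf:] * K.lucy_w(
                0.0, self.kernel.cutoff
            )
        else:
            self._wall_rho_static = np.zeros(0)

        # static grid over repulsive particles for short-range wall repulsion
        self._rep_pos = rep
        self._rep_grid = (
            K.build_grid(rep, wall.box_lo, wall.box_hi,
                         max(config.wall.repulsion_range, 0.1))
            if len(rep) else None
        )

        # membrane bookkeeping
        self._cell_offsets = np.cumsum(
            [0] + [c.n_vertices for c in cells]
        )
        self.n_membrane = self._cell_offsets[-1]
        self._mem_owner = np.concatenate(
            [np.full(c.n_vertices, i, np.int64) for i in range(len(cells))
             for c in [cells[i]]]
        ) if cells else np.zeros(0, np.int64)
        self._wrap_offsets = np.zeros((len(cells), 3))
        self._receptor_cells = [
            i for i, c in enumerate(cells) if c.has_receptors
        ]
        self._receptor_index = np.concatenate(
            [
                np.arange(self._cell_offsets[i], self._cell_offsets[i + 1])
                for i in self._receptor_cells
            ]
        ) if self._receptor_cells else np.zeros(0, np.int64)

        self.ligands = ligands
        self.adhesion_model = None
        if (
            config.adhesion.enabled
            and ligands is not None
            and len(ligands)
            and len(self._receptor_index)
        ):
            a = config.adhesion
            self.adhesion_model = adh.AdhesionModel(
                ligands,
                adh.AdhesionParams(
                    E_A=a.adhesion_strength, lam=a.equilibrium_length,
                    l_r=a.reactive_distance, sigma_f=a.formation_strength,
                    sigma_d=a.dissociation_strength, k_f0=a.formation_rate,
                    k_d0=a.dissociation_rate,
                    kBT=a.kBT if a.kBT is not None else fl.kBT,
                    single_bond_per_ligand=not a.allow_multibond_ligand,
                ),
                n_receptors=len(self._receptor_index),
                seed=int(self.seed) ^ 0x5EED,
            )
        self.agg_params = None
        if config.aggregation.enabled and len(cells) >= 2:
            g = config.aggregation
            self.agg_params = agg.AggregationParams(
                E_I=g.strength, r0=g.zero_force_distance, beta=g.beta,
                cutoff=g.cutoff,
                clamp_negative_projection=g.clamp_negative_projection,
            )

        # neighbor list with skin
        self.skin = 0.2
        self._pairs = None
        self._pos_at_build = None
        self._recycled = 0

        # diagnostics
        self._records: list[dict] = []
        self._accel = np.zeros((nf, 3))
        self._mem_vel = np.zeros((self.n_membrane, 3))
        self._cell_agg_force = np.zeros((len(cells), 3))
        self._compute_forces()

    # ------------------------------------------------------------------
    @classmethod
    def from_config(cls, config: SimulationConfig) -> "Simulation":
        """Build geometry, cells, ligands and fluid from a configuration."""
        g = config.geometry
        rng = np.random.default_rng(config.run.seed)
        if g.kind == "tube":
            wall = make_tube(g.diameter, g.length, g.spacing)
        elif g.kind == "couette":
            wall = make_couette_box(g.couette_R, g.spacing, g.shear_rate,
                                    box_factors=g.couette_box)
        elif g.kind == "bifurcation":
            wall = make_bifurcation(
                g.diameter, g.daughter_ratio, g.angle,
                segment_lengths=(g.length / 2, g.length / 2),
                spacing=g.spacing,
            )
        else:  # pragma: no cover - config validation forbids
            raise ConfigurationError(f"unknown geometry kind {g.kind!r}")

        cells: list[CellMesh] = []
        materials: list[mb.MembraneMaterial] = []
        for spec in config.cells:
            if spec.count == 0:
                continue
            if spec.kind == "rbc":
                template = make_biconcave_mesh(
                    spec.diameter, spec.n_vertices,
                    has_receptors=spec.has_receptors, kind=spec.kind,
                )
            else:
                template = make_sphere_mesh(
                    spec.diameter, spec.n_vertices,
                    has_receptors=spec.has_receptors, kind=spec.kind,
                )
            mat = mb.calibrate_from_moduli(
                spec.shear_modulus, spec.bending_modulus,
                spec.dilation_modulus, template, kBT=config.fluid.kBT,
            )
            if g.kind == "couette":
                R = g.couette_R
                lam = config.adhesion.equilibrium_length
                # grazing start: the lowest receptors just inside the
                # reactive distance, so capture must be won by the first
                # bonds (the adhesion-state discriminator)
                lr = config.adhesion.reactive_distance
                z0 = R + max(0.9 * lr, 0.05)
                center = np.array([
                    wall.box_hi[0] * 0.25,
                    (wall.box_lo[1] + wall.box_hi[1]) / 2.0,
                    z0,
                ])
                for _ in range(spec.count):
                    cells.append(template.transformed(
                        translation=center - template.centroid()
                    ))
                    materials.append(mat)
            elif g.kind == "tube" and spec.kind in ("ctc", "capsule"):
                center = np.array([g.length / 2.0, 0.0, 0.0])
                for _ in range(spec.count):
                    cells.append(template.transformed(
                        translation=center - template.centroid()
                    ))
                    materials.append(mat)
            elif g.kind == "tube":
                # keep initial surface gaps outside the Morse repulsive core
                gap = (
                    config.aggregation.zero_force_distance + 0.05
                    if config.aggregation.enabled else 0.15
                )
                placed = place_rbcs_tube(
                    wall, template, spec.count, rng, avoid=cells,
                    min_gap=gap, prefer_outer=bool(cells),
                )
                cells.extend(placed)
                materials.extend([mat] * len(placed))
            else:  # bifurcation: queue cells near the inlet on-axis
                x0 = spec.diameter / 2 + 0.6
                for ci in range(spec.count):
                    center = np.array([x0 + ci * (spec.diameter + 0.4),
                                       0.0, 0.0])
                    cells.append(template.transformed(
                        translation=center - template.centroid()
                    ))
                    materials.append(mat)

        ligands = None
        if config.adhesion.enabled and config.adhesion.ligand_density > 0:
            ligands = seed_ligands(
                wall, config.adhesion.ligand_density,
                np.random.default_rng(config.run.seed ^ 0xC0FFEE),
            )
        fluid_pos = fill_fluid(wall, config.fluid.number_density)
        # fluid fills cell interiors too (it models the cytosol); only a
        # thin shell around each membrane is cleared so no fluid particle
        # starts on top of a vertex
        if cells:
            from scipy.spatial import cKDTree

            allv = np.concatenate([c.vertices for c in cells])
            d, _ = cKDTree(allv).query(fluid_pos, k=1,
                                       distance_upper_bound=0.25)
            fluid_pos = fluid_pos[np.isinf(d)]
        return cls(config, wall, cells, materials, ligands, fluid_pos)

    # ------------------------------------------------------------------
    @property
    def membrane_positions(self) -> np.ndarray:
        return np.concatenate([c.vertices for c in self.cells]) if self.cells \
            else np.zeros((0, 3))

    def _set_membrane_positions(self, mem: np.ndarray) -> None:
        for i, c in enumerate(self.cells):
            c.vertices = np.ascontiguousarray(
                mem[self._cell_offsets[i]:self._cell_offsets[i + 1]]
            )

    def _maybe_rebuild_pairs(self) -> None:
        pos = self.ps.positions
        # a runaway velocity collapses particles onto each other within a
        # step and makes the pair list quadratic; abort early instead
        if self.n_fluid:
            vmax = float(np.abs(self.ps.velocities[: self.n_fluid]).max())
            if vmax > 20.0 * self.params.sound_speed:
                raise RuntimeError(
                    f"fluid velocity {vmax:.3g} exceeds 20x the sound speed "
                    f"at step {self.step_index}; reduce the time step"
                )
        if self._pairs is not None:
            if self.n_fluid:
                d = pos[: self.n_fluid] - self._pos_at_build
                box = self.ps.box_hi - self.ps.box_lo
                for ax in range(3):
                    if self.ps.periodic[ax]:
                        d[:, ax] -= box[ax] * np.round(d[:, ax] / box[ax])
                disp = float(np.linalg.norm(d, axis=1).max())
            else:
                disp = 0.0
            if disp < self.skin / 2:
                return
        dims, start, order = K.build_grid(
            pos, self.ps.box_lo, self.ps.box_hi,
            self.kernel.cutoff + self.skin,
        )
        pairs = K.self_pairs(
            pos, self.ps.box_lo, self.ps.box_hi, self.ps.periodic,
            self.kernel.cutoff + self.skin, dims, start, order,
        )
        # drop wall-wall pairs (static; their density part is precomputed)
        keep = (pairs[:, 0] < self.n_fluid) | (pairs[:, 1] < self.n_fluid)
        pairs = pairs[keep]
        # canonical order: summation order then depends only on the pair
        # set, so a resumed run accumulates forces bit-identically (pairs
        # beyond the cutoff contribute exact zeros)
        order = np.lexsort((pairs[:, 1], pairs[:, 0]))
        self._pairs = np.ascontiguousarray(pairs[order])
        self._pos_at_build = pos[: self.n_fluid].copy()

    def _intercell_contact_forces(self, mem: np.ndarray) -> np.ndarray:
        """Excluded-volume repulsion between vertices of different cells."""
        cfg = self.config.aggregation
        rc = cfg.contact_range
        lo = mem.min(axis=0) - 2 * rc
        hi = mem.max(axis=0) + 2 * rc
        grid = K.build_grid(mem, lo, hi, rc)
        pairs = K.self_pairs(mem, lo, hi, np.zeros(3, bool), rc, *grid)
        if len(pairs) == 0:
            return np.zeros_like(mem)
        return K.soft_repulsion_pairs(
            pairs, mem, self._mem_owner, lo, hi, np.zeros(3, bool),
            cfg.contact_strength, rc,
        )

    def _update_ghost_velocities(self, fluid_grid) -> None:
        """No-slip boundary: v_ghost = 2 v_wall - v_fluid(mirror point)."""
        wall = self.wall
        if (
            not self.config.wall.morris_ghosts
            or wall.ghost_mirror is None
            or len(wall.ghost) == 0
        ):
            return
        nf = self.n_fluid
        mirrors = wall.ghost_mirror
        dims, start, order = fluid_grid
        pairs = K.cross_pairs(
            mirrors, self.ps.positions[:nf], self.ps.box_lo, self.ps.box_hi,
            self.ps.periodic, self.kernel.cutoff, dims, start, order,
        )
        vsm = np.zeros((len(mirrors), 3))
        if len(pairs):
            box = self.ps.box_hi - self.ps.box_lo
            d = mirrors[pairs[:, 0]] - self.ps.positions[pairs[:, 1]]
            for ax in range(3):
                if self.ps.periodic[ax]:
                    d[:, ax] -= box[ax] * np.round(d[:, ax] / box[ax])
            q = np.minimum(
                np.linalg.norm(d, axis=1) / self.kernel.cutoff, 1.0
            )
            w = (1 + 3 * q) * (1 - q) ** 3
            tot = np.bincount(pairs[:, 0], weights=w, minlength=len(mirrors))
            num = np.zeros((len(mirrors), 3))
            for ax in range(3):
                num[:, ax] = np.bincount(
                    pairs[:, 0],
                    weights=w * self.ps.velocities[pairs[:, 1], ax],
                    minlength=len(mirrors),
                )
            ok = tot > 1e-12
            vsm[ok] = num[ok] / tot[ok, None]
        ghost0 = self.ps.n - len(wall.ghost)
        self.ps.velocities[ghost0:] = 2.0 * wall.ghost_velocity - vsm

    def _compute_forces(self) -> None:
        cfg = self.config
        nf = self.n_fluid
        fluid_grid = K.build_grid(
            self.ps.positions[:nf], self.ps.box_lo, self.ps.box_hi,
            self.kernel.cutoff,
        )
        self._update_ghost_velocities(fluid_grid)
        self._maybe_rebuild_pairs()
        rho = K.sdpd_density(
            self.ps.positions, self.ps.masses, self._pairs,
            self.ps.box_lo, self.ps.box_hi, self.ps.periodic,
            self.kernel.cutoff,
        )
        rho[nf:] += self._wall_rho_static
        self.ps.densities = rho
        pressure = self.params.pressure(rho)
        force = K.sdpd_pair_forces(
            self.ps.positions, self.ps.velocities, self.ps.masses, rho,
            pressure, self._pairs, self.ps.box_lo, self.ps.box_hi,
            self.ps.periodic, self.kernel.cutoff, self.params.eta,
            self.params.kBT, self.dt, self.seed,
            np.uint64(self.step_index), True, True, True,
            nf, self.config.wall.viscosity_factor,
        )

        mem = self.membrane_positions
        mem_force = np.zeros_like(mem)
        self._cell_agg_force[:] = 0.0
        if self.cells:
            for i, (c, mat) in enumerate(zip(self.cells, self.materials)):
                mem_force[
                    self._cell_offsets[i]:self._cell_offsets[i + 1]
                ] += mb.deformation_force(c, mat, strict=False)
            if self.agg_params is not None:
                per_cell, cell_f, _ = agg.aggregation_forces(
                    self.cells, self.agg_params,
                    return_energy=True, return_cell_forces=True,
                )
                self._cell_agg_force[:] = cell_f
                for i, f in enumerate(per_cell):
                    mem_force[
                        self._cell_offsets[i]:self._cell_offsets[i + 1]
                    ] += f
            if len(self.cells) >= 2 and cfg.aggregation.contact_strength > 0:
                mem_force += self._intercell_contact_forces(mem)
            if self.adhesion_model is not None:
                rec_pos = mem[self._receptor_index]
                self.adhesion_model.update_bonds(
                    rec_pos, self.dt, self.step_index
                )
                f_rec, _ = self.adhesion_model.adhesion_force(rec_pos)
                mem_force[self._receptor_index] += f_rec
        if self._rep_grid is not None:
            # wall repulsion: membrane vertices and near-wall fluid, one pass
            near = ~self.wall.inside(
                self.ps.positions[:nf],
                margin=cfg.wall.repulsion_range + 0.1,
            )
            idx = np.nonzero(near)[0]
            targets = (
                np.concatenate([mem, self.ps.positions[idx]])
                if self.n_membrane else self.ps.positions[idx]
            )
            if len(targets):
                f = wall_repulsion(
                    targets, self._rep_pos, self._rep_grid,
                    self.ps.box_lo, self.ps.box_hi, self.ps.periodic,
                    cfg.wall.repulsion_strength, cfg.wall.repulsion_range,
                )
                if self.n_membrane:
                    mem_force += f[: self.n_membrane]
                    force[idx] += f[self.n_membrane:]
                else:
                    force[idx] += f

        # fluid-membrane coupling + impermeability barrier (one grid scan)
        self._weights = None
        if self.n_membrane:
            wpairs, wts, totals, fm, ff = K.coupling_scan(
                mem, self.ps.positions[:nf], self.ps.box_lo,
                self.ps.box_hi, self.ps.periodic, self.kernel.cutoff,
                *fluid_grid, cfg.fluid.membrane_barrier_strength,
                cfg.fluid.membrane_barrier_range,
            )
            mem_force += fm
            force[:nf] += ff
            self._weights = cpl.CouplingWeights(
                wpairs, wts, self.n_membrane, nf
            )
            fl_force, _ = K.spread_and_interp(
                wpairs, wts, mem_force,
                self.ps.velocities[:nf], nf, self.n_membrane,
            )
            force[:nf] += fl_force

        # external drive
        drive = cfg.drive
        g = np.asarray(drive.acceleration, float)
        if np.any(g != 0.0):
            if drive.region == "inlet" and drive.inlet_length > 0:
                mask = self.ps.positions[:nf, 0] < (
                    self.ps.box_lo[0] + drive.inlet_length
                )
                force[:nf][mask] += self.ps.masses[:nf][mask, None] * g
            else:
                force[:nf] += self.ps.masses[:nf, None] * g

        self._accel = force[:nf] / self.ps.masses[:nf, None]
        self._mem_force = mem_force

    def _advect_and_wrap(self) -> None:
        nf = self.n_fluid
        dt = self.dt
        self.ps.positions[:nf] += dt * self.ps.velocities[:nf]
        if self.n_membrane:
            mem = self.membrane_positions + dt * self._mem_vel
            if not np.isfinite(mem).all():
                bad = int(np.nonzero(~np.isfinite(mem).all(axis=1))[0][0])
                raise RuntimeError(
                    f"non-finite membrane vertex {bad} at step "
                    f"{self.step_index}; reduce the time step"
                )
            # hard no-penetration constraint: a hard-pressed membrane must
            # not leak between the discrete wall particles (the soft wall
            # repulsion sets the actual standoff)
            mem = _clamp_to_lumen(self.wall, mem, 0.02)
            self._set_membrane_positions(mem)
        box = self.ps.box_hi - self.ps.box_lo
        for ax in range(3):
            if self.ps.periodic[ax]:
                p = self.ps.positions[:nf, ax]
                self.ps.positions[:nf, ax] = (
                    self.ps.box_lo[ax] + (p - self.ps.box_lo[ax]) % box[ax]
                )
        # wrap whole cells across periodic axes
        for i, c in enumerate(self.cells):
            for ax in range(3):
                if not self.ps.periodic[ax]:
                    continue
                cx = c.vertices[:, ax].mean()
                if cx < self.ps.box_lo[ax]:
                    c.vertices[:, ax] += box[ax]
                    self._wrap_offsets[i, ax] -= box[ax]
                elif cx >= self.ps.box_hi[ax]:
                    c.vertices[:, ax] -= box[ax]
                    self._wrap_offsets[i, ax] += box[ax]
        if self.wall.kind == "bifurcation":
            self._recycle_outflow()

    def _recycle_outflow(self) -> None:
        """Teleport fluid leaving the outlet back into the inlet disk."""
        nf = self.n_fluid
        wall = self.wall
        out_x = wall.outlet_x
        in_x = wall.inlet_x
        x = self.ps.positions[:nf, 0]
        crossed = np.nonzero(x > out_x)[0]
        if len(crossed) == 0:
            return
        rng = np.random.default_rng(
            int(self.seed) + 7919 * (self.step_index + 1)
        )
        r_in = wall.centerline_radius[0] - 0.3
        for idx in crossed:
            th = rng.uniform(0, 2 * math.pi)
            rr = r_in * math.sqrt(rng.uniform())
            self.ps.positions[idx, 0] = in_x + (
                self.ps.positions[idx, 0] - out_x
            ) % 1.0
            self.ps.positions[idx, 1] = rr * math.cos(th)
            self.ps.positions[idx, 2] = rr * math.sin(th)
        self._recycled += len(crossed)
        # re-inject cells that fully left the outlet
        for i, c in enumerate(self.cells):
            if c.vertices[:, 0].min() > out_x - 0.2:
                template = self.templates[i]
                r = np.linalg.norm(
                    template.vertices - template.centroid(), axis=1
                ).max()
                target = np.array([in_x + r + 0.4, 0.0, 0.0])
                c.vertices = np.ascontiguousarray(
                    template.vertices - template.centroid() + target
                )
                off = self._cell_offsets[i]
                self._mem_vel[off:off + c.n_vertices] = 0.0
                if self.adhesion_model is not None and c.has_receptors:
                    sel = (
                        (self._receptor_index >= off)
                        & (self._receptor_index < off + c.n_vertices)
                    )
                    self.adhesion_model.bonds.ligand_of[sel] = -1

    def step(self) -> None:
        """Advance the state by one velocity-Verlet step."""
        nf = self.n_fluid
        dt = self.dt
        self.ps.velocities[:nf] += 0.5 * dt * self._accel
        self._advect_and_wrap()
        self.step_index += 1
        self._compute_forces()
        self.ps.velocities[:nf] += 0.5 * dt * self._accel
        if self._weights is not None:
            self._mem_vel = cpl.interpolate_velocity(
                self._weights, self.ps.velocities[:nf]
            )
        if not np.isfinite(self.ps.velocities[:nf]).all():
            bad = int(
                np.nonzero(~np.isfinite(self.ps.velocities[:nf]).all(axis=1))[0][0]
            )
            raise RuntimeError(
                f"non-finite state at step {self.step_index}, fluid "
                f"particle {bad}; reduce the time step"
            )

    # ------------------------------------------------------------------
    def _record(self) -> None:
        nc = len(self.cells)
        cents = np.zeros((nc, 3))
        vels = np.zeros((nc, 3))
        areas = np.zeros(nc)
        vols = np.zeros(nc)
        for i, c in enumerate(self.cells):
            cents[i] = c.centroid() + self._wrap_offsets[i]
            off = self._cell_offsets[i]
            vels[i] = self._mem_vel[off:off + c.n_vertices].mean(axis=0)
            areas[i] = c.area()
            vols[i] = c.volume()
        vf = self.ps.velocities[: self.n_fluid]
        vmean = vf.mean(axis=0) if len(vf) else np.zeros(3)
        temp = (
            float(
                (self.ps.masses[: self.n_fluid, None]
                 * (vf - vmean) ** 2).sum() / (3.0 * max(self.n_fluid, 1))
            )
        )
        self._records.append(
            dict(
                time=self.step_index * self.dt,
                centroids=cents,
                velocities=vels,
                bonds=(
                    self.adhesion_model.bonds.count
                    if self.adhesion_model else 0
                ),
                agg=self._cell_agg_force.copy(),
                areas=areas,
                volumes=vols,
                temperature=temp,
            )
        )

    def run(self, n_steps: int | None = None,
            record_every: int | None = None,
            progress: bool = False) -> Trajectory:
        """Integrate ``n_steps`` and return the recorded trajectory."""
        n_steps = self.config.run.n_steps if n_steps is None else n_steps
        record_every = (
            self.config.run.output_every if record_every is None
            else record_every
        )
        self._records = []
        self._record()
        for s in range(n_steps):
            self.step()
            if (s + 1) % record_every == 0:
                self._record()
        return self.trajectory()

    def trajectory(self) -> Trajectory:
        recs = self._records
        return Trajectory(
            times=np.array([r["time"] for r in recs]),
            centroids=np.array([r["centroids"] for r in recs]),
            velocities=np.array([r["velocities"] for r in recs]),
            bond_counts=np.array([r["bonds"] for r in recs]),
            aggregation_forces=np.array([r["agg"] for r in recs]),
            areas=np.array([r["areas"] for r in recs]),
            volumes=np.array([r["volumes"] for r in recs]),
            fluid_temperature=np.array([r["temperature"] for r in recs]),
            cell_kinds=[c.kind for c in self.cells],
            wall=self.wall,
        )

    # ------------------------------------------------------------------
    def timestep_bounds(self) -> dict[str, float]:
        """Stability-motivated upper bounds on the time step."""
        h = self.config.fluid.number_density ** (-1.0 / 3.0)
        bounds = {
            "acoustic_cfl": 0.25 * h / self.params.sound_speed,
            "viscous": h**2 * self.params.rho0 / (8.0 * self.params.eta),
        }
        if self.adhesion_model is not None:
            p = self.adhesion_model.params
            kmax = max(p.k_f0, p.k_d0, 1e-12)
            bounds["bond_kinetics"] = 0.1 / kmax
        return bounds

    def save_checkpoint(self, path: str) -> None:
        import h5py

        with h5py.File(path, "w") as f:
            f.attrs["step"] = self.step_index
            f.attrs["seed"] = int(self.seed)
            f["positions"] = self.ps.positions
            f["velocities"] = self.ps.velocities
            f["accel"] = self._accel
            f["mem_vel"] = self._mem_vel
            f["wrap_offsets"] = self._wrap_offsets
            for i, c in enumerate(self.cells):
                f[f"cell_{i}"] = c.vertices
            if self.adhesion_model is not None:
                f["bond_ligand"] = self.adhesion_model.bonds.ligand_of
                f["bond_step"] = self.adhesion_model.bonds.formation_step
                f["ligand_count"] = self.adhesion_model.ligand_bound_count

    def load_checkpoint(self, path: str) -> None:
        import h5py

        with h5py.File(path, "r") as f:
            if int(f.attrs["seed"]) != int(self.seed):
                raise ConfigurationError(
                    f"checkpoint seed {int(f.attrs['seed'])} does not match "
                    f"configured seed {int(self.seed)}"
                )
            self.step_index = int(f.attrs["step"])
            self.ps.positions[:] = f["positions"][:]
            self.ps.velocities[:] = f["velocities"][:]
            self._accel = f["accel"][:]
            self._mem_vel = f["mem_vel"][:]
            self._wrap_offsets = f["wrap_offsets"][:]
            for i, c in enumerate(self.cells):
                c.vertices = np.ascontiguousarray(f[f"cell_{i}"][:])
            if self.adhesion_model is not None and "bond_ligand" in f:
                self.adhesion_model.bonds.ligand_of[:] = f["bond_ligand"][:]
                self.adhesion_model.bonds.formation_step[:] = f["bond_step"][:]
                self.adhesion_model.ligand_bound_count[:] = f["ligand_count"][:]
        # the saved acceleration was evaluated at the half-step velocities
        # of the checkpointed step; it is restored rather than recomputed
        # so the continuation is bit-identical
        self._pairs = None


def run_simulation(config: SimulationConfig) -> Trajectory:
    """Build everything from the configuration and run it to completion."""
    sim = Simulation.from_config(config)
    return sim.run()
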