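"""Procedural geometry: cell membrane meshes, vessel walls, ligand fields.

Everything the simulator runs on is generated here, in dimensionless units
(lengths in multiples of the kernel cut-off radius):

* closed triangulated cell membranes — icosphere tessellations for spherical
  cells (tumor cells, capsules) and an Evans–Fung biconcave discocyte for
  red blood cells;
* wall particle scaffolds (repulsive particles on the wall surface, ghost
  particles outside it) for a Couette channel, a straight cylindrical tube,
  and a Y-bifurcation whose daughter diameters follow Murray's law
  d_p^3 = d_1^3 + d_2^3;
* ligand site fields on the wall surface at a prescribed number density;
* fluid particle lattice fills of the lumen;
* non-overlapping cell placements at a target hematocrit.

The flow axis is x; coordinates are right-handed.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .units import ConfigurationError

# Evans–Fung biconcave discocyte coefficients: the resting red-cell shape
# z(rho) = +/- (R0/2) sqrt(1 - (rho/R0)^2) [c0 + c1 (rho/R0)^2 + c2 (rho/R0)^4]
EVANS_FUNG_C0 = 0.207161
EVANS_FUNG_C1 = 2.002558
EVANS_FUNG_C2 = -1.122762


# ---------------------------------------------------------------------------
# Cell meshes
# ---------------------------------------------------------------------------


@dataclass
class CellMesh:
    """Closed triangulated membrane with its stress-free reference state."""

    vertices: np.ndarray  # (V, 3)
    faces: np.ndarray  # (F, 3) int
    kind: str = "sphere"
    has_receptors: bool = False
    material: object | None = None

    # reference (stress-free) state, filled by freeze_reference()
    edges: np.ndarray = field(default=None, repr=False)  # (E, 2)
    edge_opposite: np.ndarray = field(default=None, repr=False)  # (E, 2)
    rest_edge_lengths: np.ndarray = field(default=None, repr=False)
    rest_dihedrals: np.ndarray = field(default=None, repr=False)
    rest_face_areas: np.ndarray = field(default=None, repr=False)
    rest_area: float = 0.0
    rest_volume: float = 0.0

    def __post_init__(self) -> None:
        self.vertices = np.ascontiguousarray(self.vertices, dtype=np.float64)
        self.faces = np.ascontiguousarray(self.faces, dtype=np.int64)
        if self.volume() < 0.0:
            self.faces = self.faces[:, ::-1].copy()
        if self.edges is None:
            self._build_topology()
            self.freeze_reference()

    # -- topology -----------------------------------------------------------
    def _build_topology(self) -> None:
        edge_map: dict[tuple[int, int], list[int]] = {}
        for fi, (a, b, c) in enumerate(self.faces):
            for u, v, w in ((a, b, c), (b, c, a), (c, a, b)):
                key = (min(u, v), max(u, v))
                edge_map.setdefault(key, []).append(w)
        bad = [k for k, opp in edge_map.items() if len(opp) != 2]
        if bad:
            raise ConfigurationError(
                f"mesh is not a closed 2-manifold: {len(bad)} edges not shared "
                f"by exactly two triangles (e.g. {bad[0]})"
            )
        self.edges = np.array(sorted(edge_map), dtype=np.int64)
        self.edge_opposite = np.array(
            [edge_map[(a, b)] for a, b in self.edges], dtype=np.int64
        )

    def freeze_reference(self) -> None:
        """Record the current configuration as the stress-free state."""
        self.rest_edge_lengths = self.edge_lengths()
        self.rest_dihedrals = self.dihedral_angles()
        self.rest_face_areas = self.face_areas()
        self.rest_area = float(self.rest_face_areas.sum())
        self.rest_volume = self.volume()

    # -- measures -----------------------------------------------------------
    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    def euler_characteristic(self) -> int:
        return self.n_vertices - len(self.edges) + len(self.faces)

    def edge_lengths(self) -> np.ndarray:
        d = self.vertices[self.edges[:, 0]] - self.vertices[self.edges[:, 1]]
        return np.linalg.norm(d, axis=1)

    def face_areas(self) -> np.ndarray:
        v = self.vertices
        f = self.faces
        n = np.cross(v[f[:, 1]] - v[f[:, 0]], v[f[:, 2]] - v[f[:, 0]])
        return 0.5 * np.linalg.norm(n, axis=1)

    def face_normals(self) -> np.ndarray:
        v = self.vertices
        f = self.faces
        n = np.cross(v[f[:, 1]] - v[f[:, 0]], v[f[:, 2]] - v[f[:, 0]])
        return n / np.linalg.norm(n, axis=1)[:, None]

    def face_centroids(self) -> np.ndarray:
        return self.vertices[self.faces].mean(axis=1)

    def area(self) -> float:
        return float(self.face_areas().sum())

    def volume(self) -> float:
        """Signed enclosed volume by the divergence theorem."""
        v = self.vertices
        f = self.faces
        return float(
            np.einsum(
                "ij,ij->i", v[f[:, 0]], np.cross(v[f[:, 1]], v[f[:, 2]])
            ).sum()
            / 6.0
        )

    def dihedral_angles(self) -> np.ndarray:
        """Signed angle between face normals across each edge.

        Positive for a convex edge of an outward-oriented mesh.
        """
        v = self.vertices
        a = v[self.edges[:, 0]]
        b = v[self.edges[:, 1]]
        c = v[self.edge_opposite[:, 0]]
        d = v[self.edge_opposite[:, 1]]
        n1 = np.cross(b - a, c - a)
        n2 = np.cross(d - a, b - a)
        n1n = np.linalg.norm(n1, axis=1)
        n2n = np.linalg.norm(n2, axis=1)
        cosang = np.clip(
            np.einsum("ij,ij->i", n1, n2) / (n1n * n2n), -1.0, 1.0
        )
        sin_sign = np.einsum("ij,ij->i", np.cross(n1, n2), b - a)
        return np.arctan2(np.sign(sin_sign) * np.sqrt(1 - cosang**2), cosang)

    def centroid(self) -> np.ndarray:
        return self.vertices.mean(axis=0)

    # -- transforms ---------------------------------------------------------
    def transformed(self, rotation: np.ndarray | None = None,
                    translation: np.ndarray | None = None) -> "CellMesh":
        """A placed copy sharing topology and reference state."""
        verts = self.vertices
        if rotation is not None:
            verts = verts @ np.asarray(rotation).T
        if translation is not None:
            verts = verts + np.asarray(translation)
        placed = CellMesh.__new__(CellMesh)
        placed.__dict__.update(self.__dict__)
        placed.vertices = np.ascontiguousarray(verts)
        return placed


def _icosahedron() -> tuple[np.ndarray, np.ndarray]:
    phi = (1.0 + math.sqrt(5.0)) / 2.0
    verts = np.array(
        [
            (-1, phi, 0), (1, phi, 0), (-1, -phi, 0), (1, -phi, 0),
            (0, -1, phi), (0, 1, phi), (0, -1, -phi), (0, 1, -phi),
            (phi, 0, -1), (phi, 0, 1), (-phi, 0, -1), (-phi, 0, 1),
        ],
        dtype=np.float64,
    )
    verts /= np.linalg.norm(verts, axis=1)[:, None]
    faces = np.array(
        [
            (0, 11, 5), (0, 5, 1), (0, 1, 7), (0, 7, 10), (0, 10, 11),
            (1, 5, 9), (5, 11, 4), (11, 10, 2), (10, 7, 6), (7, 1, 8),
            (3, 9, 4), (3, 4, 2), (3, 2, 6), (3, 6, 8), (3, 8, 9),
            (4, 9, 5), (2, 4, 11), (6, 2, 10), (8, 6, 7), (9, 8, 1),
        ],
        dtype=np.int64,
    )
    return verts, faces


def _subdivide(verts: np.ndarray, faces: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    cache: dict[tuple[int, int], int] = {}
    verts = list(verts)

    def midpoint(i: int, j: int) -> int:
        key = (min(i, j), max(i, j))
        if key not in cache:
            m = (verts[i] + verts[j]) / 2.0
            m /= np.linalg.norm(m)
            cache[key] = len(verts)
            verts.append(m)
        return cache[key]

    new_faces = []
    for a, b, c in faces:
        ab, bc, ca = midpoint(a, b), midpoint(b, c), midpoint(c, a)
        new_faces += [(a, ab, ca), (b, bc, ab), (c, ca, bc), (ab, bc, ca)]
    return np.array(verts), np.array(new_faces, dtype=np.int64)


def _unit_icosphere(target_vertices: int) -> tuple[np.ndarray, np.ndarray, int]:
    """Subdivided icosahedron with vertex count closest to the target.

    Pure icosahedral subdivision reaches 12, 42, 162, 642, 2562, ... vertices;
    the generator returns the nearest achievable level (resolution, not the
    exact count, is what the discrete mechanics depend on).
    """
    verts, faces = _icosahedron()
    count = 12
    while True:
        next_count = 4 * count - 6  # V' = V + E, E = 3V - 6 for genus 0
        if abs(next_count - target_vertices) >= abs(count - target_vertices):
            break
        verts, faces = _subdivide(verts, faces)
        count = next_count
    if count != target_vertices:
        warnings.warn(
            f"icosphere tessellation cannot reach exactly {target_vertices} "
            f"vertices; using nearest subdivision level with {count}",
            stacklevel=3,
        )
    return verts, faces, count


def _balance_scale(v_ratio: float) -> float:
    """Scale factor balancing volume deficit against diameter excess.

    A polyhedral tessellation inscribed in its target surface underestimates
    the enclosed volume.  Inflating by the root of s + s^3 * v = 2 (v = mesh
    volume / analytic volume) splits the discretization error evenly between
    the volume (-e) and the max diameter (+e), keeping both within tolerance
    at practical resolutions.
    """
    s = 1.0
    for _ in range(50):
        f = s + s**3 * v_ratio - 2.0
        s -= f / (1.0 + 3.0 * s**2 * v_ratio)
    return s


def make_sphere_mesh(diameter: float, target_vertices: int = 642,
                     **mesh_kwargs) -> CellMesh:
    """Icosphere membrane mesh of the given diameter."""
    if diameter <= 0:
        raise ConfigurationError(f"sphere diameter must be > 0, got {diameter}")
    if target_vertices < 12:
        raise ConfigurationError("target_vertices must be >= 12")
    verts, faces, _ = _unit_icosphere(target_vertices)
    mesh = CellMesh(verts * (diameter / 2.0), faces)
    s = _balance_scale(mesh.volume() / (math.pi * diameter**3 / 6.0))
    mesh_kwargs.setdefault("kind", "sphere")
    return CellMesh(mesh.vertices * s, faces, **mesh_kwargs)


def biconcave_profile(rho: np.ndarray | float, max_diameter: float) -> np.ndarray:
    """Half-thickness z(rho) of the Evans–Fung discocyte (rho = axial radius)."""
    R0 = max_diameter / 2.0
    x2 = np.clip(np.square(np.asarray(rho, dtype=float) / R0), 0.0, 1.0)
    return (
        0.5
        * R0
        * np.sqrt(1.0 - x2)
        * (EVANS_FUNG_C0 + EVANS_FUNG_C1 * x2 + EVANS_FUNG_C2 * x2**2)
    )


def make_biconcave_mesh(max_diameter: float, target_vertices: int = 162,
                        **mesh_kwargs) -> CellMesh:
    """Biconcave discocyte membrane (resting red-cell shape), axis = z."""
    if max_diameter <= 0:
        raise ConfigurationError(f"max_diameter must be > 0, got {max_diameter}")
    verts, faces, _ = _unit_icosphere(target_vertices)
    R0 = max_diameter / 2.0
    rho_unit = np.minimum(np.linalg.norm(verts[:, :2], axis=1), 1.0)
    z = np.sign(verts[:, 2]) * biconcave_profile(rho_unit * R0, max_diameter)
    out = np.column_stack([R0 * verts[:, 0], R0 * verts[:, 1], z])
    mesh = CellMesh(out, faces)
    from scipy.integrate import quad

    v_exact = quad(
        lambda r: 4 * math.pi * r * biconcave_profile(r, max_diameter), 0.0, R0
    )[0]
    s = _balance_scale(mesh.volume() / v_exact)
    mesh_kwargs.setdefault("kind", "biconcave")
    return CellMesh(mesh.vertices * s, faces, **mesh_kwargs)


# ---------------------------------------------------------------------------
# Wall geometry
# ---------------------------------------------------------------------------


@dataclass
class WallGeometry:
    """Wall particle scaffold plus the analytic description of the lumen."""

    kind: str  # couette | tube | bifurcation
    repulsive: np.ndarray  # (Nr, 3) on the wall surface
    ghost: np.ndarray  # (Ng, 3) outside the lumen
    ghost_velocity: np.ndarray  # (Ng, 3) prescribed wall velocity per ghost
    spacing: float
    ghost_mirror: np.ndarray | None = None  # (Ng, 3) in-lumen mirror points
    # axis-aligned simulation box and per-axis periodicity
    box_lo: np.ndarray = field(default_factory=lambda: np.zeros(3))
    box_hi: np.ndarray = field(default_factory=lambda: np.ones(3))
    periodic: tuple[bool, bool, bool] = (False, False, False)
    # centerline polyline segments: (nseg, 2, 3) endpoints + radius per segment
    centerline: np.ndarray | None = None
    centerline_radius: np.ndarray | None = None
    dims: dict = field(default_factory=dict)
    inlet_x: float | None = None
    outlet_x: float | None = None

    # -- analytic lumen queries --------------------------------------------
    def inside(self, points: np.ndarray, margin: float = 0.0) -> np.ndarray:
        p = np.atleast_2d(points)
        if self.kind == "tube":
            R = self.dims["diameter"] / 2.0 - margin
            return np.hypot(p[:, 1], p[:, 2]) <= R
        if self.kind == "couette":
            Lz = self.dims["gap"]
            return (p[:, 2] >= margin) & (p[:, 2] <= Lz - margin)
        if self.kind == "bifurcation":
            ok = np.zeros(len(p), dtype=bool)
            for (a, b), r in zip(self.centerline, self.centerline_radius):
                ok |= _dist_to_segment(p, a, b) <= r - margin
            return ok
        raise ConfigurationError(f"unknown wall kind {self.kind!r}")

    def lumen_volume(self) -> float:
        if self.kind == "tube":
            D, L = self.dims["diameter"], self.dims["length"]
            return math.pi * D**2 / 4.0 * L
        if self.kind == "couette":
            return float(np.prod(self.box_hi - self.box_lo))
        if self.kind == "bifurcation":
            # Monte-Carlo estimate of the union of the branch cylinders.
            rng = np.random.default_rng(0)
            n = 200_000
            pts = rng.uniform(self.box_lo, self.box_hi, size=(n, 3))
            frac = float(self.inside(pts).mean())
            return frac * float(np.prod(self.box_hi - self.box_lo))
        raise ConfigurationError(f"unknown wall kind {self.kind!r}")

    def ligand_surface_area(self) -> float:
        """Area of the adhesive (ligand-bearing) wall surface."""
        if self.kind == "tube":
            return math.pi * self.dims["diameter"] * self.dims["length"]
        if self.kind == "couette":
            Lx = self.box_hi[0] - self.box_lo[0]
            Ly = self.box_hi[1] - self.box_lo[1]
            return float(Lx * Ly)  # bottom (static) wall only
        if self.kind == "bifurcation":
            return float(self._bifurcation_surface_area())
        raise ConfigurationError(f"unknown wall kind {self.kind!r}")

    def _bifurcation_surface_area(self, n: int = 40_000) -> float:
        # Monte-Carlo: sample each branch's lateral surface, reject points
        # strictly inside another branch.
        rng = np.random.default_rng(1)
        total = 0.0
        for i, ((a, b), r) in enumerate(zip(self.centerline, self.centerline_radius)):
            L = np.linalg.norm(b - a)
            pts = _sample_cylinder_surface(rng, a, b, r, n)
            keep = ~_inside_other_branches(self, pts, i)
            total += 2 * math.pi * r * L * keep.mean()
        return total

    def surface_points(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """Uniform random points on the ligand-bearing wall surface."""
        if self.kind == "tube":
            D, L = self.dims["diameter"], self.dims["length"]
            x = rng.uniform(0.0, L, n)
            th = rng.uniform(0.0, 2 * math.pi, n)
            return np.column_stack(
                [x, D / 2 * np.cos(th), D / 2 * np.sin(th)]
            )
        if self.kind == "couette":
            x = rng.uniform(self.box_lo[0], self.box_hi[0], n)
            y = rng.uniform(self.box_lo[1], self.box_hi[1], n)
            return np.column_stack([x, y, np.zeros(n)])
        if self.kind == "bifurcation":
            areas = np.array(
                [
                    2 * math.pi * r * np.linalg.norm(b - a)
                    for (a, b), r in zip(self.centerline, self.centerline_radius)
                ]
            )
            out: list[np.ndarray] = []
            need = n
            while need > 0:
                seg = rng.choice(len(areas), p=areas / areas.sum())
                a, b = self.centerline[seg]
                r = self.centerline_radius[seg]
                pts = _sample_cylinder_surface(rng, a, b, r, max(need * 2, 64))
                pts = pts[~_inside_other_branches(self, pts, seg)]
                out.append(pts[:need])
                need -= len(pts[:need])
            return np.concatenate(out)[:n]
        raise ConfigurationError(f"unknown wall kind {self.kind!r}")


def _dist_to_segment(p: np.ndarray, a: np.ndarray, b: np.ndarray) -> np.ndarray:
    ab = b - a
    t = np.clip((p - a) @ ab / (ab @ ab), 0.0, 1.0)
    return np.linalg.norm(p - (a + t[:, None] * ab), axis=1)


def _inside_other_branches(wall: WallGeometry, pts: np.ndarray, seg: int,
                           shrink: float = 1.0e-9) -> np.ndarray:
    mask = np.zeros(len(pts), dtype=bool)
    for j, ((a, b), r) in enumerate(zip(wall.centerline, wall.centerline_radius)):
        if j == seg:
            continue
        mask |= _dist_to_segment(pts, a, b) < r - shrink
    return mask


def _sample_cylinder_surface(rng, a, b, r, n) -> np.ndarray:
    axis = (b - a) / np.linalg.norm(b - a)
    u = np.cross(axis, [0.0, 0.0, 1.0])
    if np.linalg.norm(u) < 1e-12:
        u = np.cross(axis, [0.0, 1.0, 0.0])
    u /= np.linalg.norm(u)
    w = np.cross(axis, u)
    t = rng.uniform(0.0, 1.0, n)
    th = rng.uniform(0.0, 2 * math.pi, n)
    return (
        a
        + t[:, None] * (b - a)
        + r * (np.cos(th)[:, None] * u + np.sin(th)[:, None] * w)
    )


def compute_ghost_mirrors(wall: WallGeometry) -> np.ndarray:
    """In-lumen mirror point of every ghost particle.

    Used for the no-slip boundary condition: each ghost is assigned the
    velocity ``2 v_wall - v_fluid(mirror)``, which makes the interpolated
    velocity field antisymmetric about the nominal wall surface, pinning
    the no-slip plane there.
    """
    g = wall.ghost
    if len(g) == 0:
        return np.zeros((0, 3))
    if wall.kind == "tube":
        R = wall.dims["diameter"] / 2.0
        r = np.hypot(g[:, 1], g[:, 2])
        scale = np.maximum(2.0 * R - r, 0.1 * R) / np.maximum(r, 1e-12)
        return np.column_stack([g[:, 0], g[:, 1] * scale, g[:, 2] * scale])
    if wall.kind == "couette":
        Lz = wall.dims["gap"]
        z = g[:, 2]
        zm = np.where(z < Lz / 2.0, -z, 2.0 * Lz - z)
        return np.column_stack([g[:, 0], g[:, 1], zm])
    if wall.kind == "bifurcation":
        # mirror through the branch whose surface is nearest
        best_out = np.full(len(g), np.inf)
        mirror = g.copy()
        for (a, b), r in zip(wall.centerline, wall.centerline_radius):
            ab = b - a
            t = np.clip((g - a) @ ab / (ab @ ab), 0.0, 1.0)
            axis_pt = a + t[:, None] * ab
            vec = g - axis_pt
            d = np.maximum(np.linalg.norm(vec, axis=1), 1e-12)
            outside = d - r
            upd = outside < best_out
            scale = np.maximum(2.0 * r - d[upd], 0.1 * r) / d[upd]
            mirror[upd] = axis_pt[upd] + vec[upd] * scale[:, None]
            best_out[upd] = outside[upd]
        return mirror
    raise ConfigurationError(f"unknown wall kind {wall.kind!r}")


def _circle_ring(radius: float, spacing: float) -> np.ndarray:
    n = max(int(round(2 * math.pi * radius / spacing)), 6)
    th = np.linspace(0.0, 2 * math.pi, n, endpoint=False)
    return np.column_stack([np.cos(th), np.sin(th)]) * radius


#: Outward offset of the ghost layers relative to the nominal surface, in
#: units of the wall particle spacing.  The no-slip plane of a discrete
#: particle wall sits inside the outermost wall layer; shifting the ghost
#: scaffold outward by half a spacing (with repulsive particles kept on the
#: nominal surface and a short-range wall friction enhancement) puts the
#: hydrodynamic boundary at the nominal wall position, calibrated once
#: against the analytic Poiseuille profile.
WALL_HYDRO_OFFSET = 0.5


def make_tube(diameter: float, length: float, spacing: float = 0.5,
              cutoff: float = 1.0, n_ghost_layers: int = 2,
              periodic: bool = True,
              hydro_offset: float | None = None) -> WallGeometry:
    """Cylindrical vessel wall along x with surface repulsive particles and
    ghost layers outside the lumen."""
    if diameter <= 0 or length <= 0:
        raise ConfigurationError("tube diameter and length must be > 0")
    if spacing > cutoff:
        raise ConfigurationError(
            f"wall spacing {spacing} is coarser than the kernel cutoff {cutoff}"
        )
    delta = spacing * WALL_HYDRO_OFFSET if hydro_offset is None else hydro_offset
    R = diameter / 2.0
    xs = np.arange(0.0, length, spacing)

    def rings(radius: float, stagger: float = 0.0) -> np.ndarray:
        pts = []
        for i, x in enumerate(xs):
            ring = _circle_ring(radius, spacing)
            if stagger and i % 2:
                ang = spacing / (2 * radius)
                c, s = math.cos(ang), math.sin(ang)
                ring = ring @ np.array([[c, -s], [s, c]])
            pts.append(np.column_stack([np.full(len(ring), x), ring]))
        return np.concatenate(pts)

    # repulsive particles on the nominal surface; ghost layers slightly
    # further out (hydrodynamic offset) so the no-slip plane lands at R
    repulsive = rings(R, stagger=0.5)
    ghost = np.concatenate(
        [rings(R + delta + k * spacing, stagger=0.5)
         for k in range(1, n_ghost_layers + 1)]
    )
    pad = n_ghost_layers * spacing + 1e-9
    wall = WallGeometry(
        kind="tube",
        repulsive=repulsive,
        ghost=ghost,
        ghost_velocity=np.zeros_like(ghost),
        spacing=spacing,
        box_lo=np.array([0.0, -R - pad, -R - pad]),
        box_hi=np.array([length, R + pad, R + pad]),
        periodic=(periodic, False, False),
        centerline=np.array([[[0.0, 0.0, 0.0], [length, 0.0, 0.0]]]),
        centerline_radius=np.array([diameter / 2.0]),
        dims={"diameter": diameter, "length": length},
        inlet_x=0.0,
        outlet_x=length,
    )
    wall.ghost_mirror = compute_ghost_mirrors(wall)
    return wall


def make_couette_box(R: float, spacing: float = 0.5, shear_rate: float = 0.0,
                     cutoff: float = 1.0, n_ghost_layers: int = 2,
                     hydro_offset: float | None = None,
                     box_factors: tuple[float, float, float] = (10.0, 6.0, 6.0),
                     ) -> WallGeometry:
    """Couette channel of size 10R x 6R x 6R (x, y periodic; z walls).

    The bottom wall (z = 0) is static and ligand-bearing; the top wall
    translates in +x with speed ``shear_rate * gap``.  ``box_factors``
    rescales the channel (in units of R) for reduced-cost runs.
    """
    if R <= 0:
        raise ConfigurationError("couette R must be > 0")
    delta = spacing * WALL_HYDRO_OFFSET if hydro_offset is None else hydro_offset
    Lx, Ly, Lz = (f * R for f in box_factors)
    xs = np.arange(0.0, Lx, spacing)
    ys = np.arange(0.0, Ly, spacing)
    gx, gy = np.meshgrid(xs, ys, indexing="ij")
    plane = np.column_stack([gx.ravel(), gy.ravel()])

    def layer(z: float) -> np.ndarray:
        return np.column_stack([plane, np.full(len(plane), z)])

    repulsive = np.concatenate([layer(0.0), layer(Lz)])
    ghosts, gvel = [], []
    top_speed = shear_rate * Lz
    for k in range(1, n_ghost_layers + 1):
        ghosts.append(layer(-delta - k * spacing))
        gvel.append(np.zeros((len(plane), 3)))
        ghosts.append(layer(Lz + delta + k * spacing))
        v = np.zeros((len(plane), 3))
        v[:, 0] = top_speed
        gvel.append(v)
    wall = WallGeometry(
        kind="couette",
        repulsive=repulsive,
        ghost=np.concatenate(ghosts),
        ghost_velocity=np.concatenate(gvel),
        spacing=spacing,
        box_lo=np.array([0.0, 0.0, 0.0]),
        box_hi=np.array([Lx, Ly, Lz]),
        periodic=(True, True, False),
        centerline=np.array([[[0.0, Ly / 2, Lz / 2], [Lx, Ly / 2, Lz / 2]]]),
        centerline_radius=np.array([Lz / 2]),
        dims={"R": R, "gap": Lz, "shear_rate": shear_rate,
              "top_speed": top_speed},
    )
    # top repulsive particles share the top-wall velocity; encode by index
    wall.dims["n_bottom_repulsive"] = len(plane)
    wall.ghost_mirror = compute_ghost_mirrors(wall)
    return wall


def murray_daughters(parent_diameter: float, daughter_ratio: float) -> tuple[float, float]:
    """Daughter diameters from Murray's law, d_p^3 = d_1^3 + d_2^3.

    ``daughter_ratio`` is the fraction of the parent's cubed diameter carried
    by the first daughter.
    """
    if not (0.0 < daughter_ratio <= 1.0):
        raise ConfigurationError("daughter_ratio must lie in (0, 1]")
    d1 = parent_diameter * daughter_ratio ** (1.0 / 3.0)
    d2 = parent_diameter * (1.0 - daughter_ratio) ** (1.0 / 3.0)
    return d1, d2


def make_bifurcation(parent_diameter: float, daughter_ratio: float = 0.5,
                     angle: float = math.pi / 3.0,
                     segment_lengths: tuple[float, float] = (8.0, 8.0),
                     spacing: float = 0.5, cutoff: float = 1.0,
                     n_ghost_layers: int = 2,
                     hydro_offset: float | None = None) -> WallGeometry:
    """Y-bifurcation: parent tube along x splitting into two daughters.

    Daughter diameters satisfy Murray's law for the given split ratio;
    ``angle`` is the full opening angle between the daughters (in the
    xy-plane).
    """
    if spacing > cutoff:
        raise ConfigurationError("wall spacing coarser than kernel cutoff")
    d1, d2 = murray_daughters(parent_diameter, daughter_ratio)
    Lp, Ld = segment_lengths
    j = np.array([Lp, 0.0, 0.0])
    half = angle / 2.0
    dir1 = np.array([math.cos(half), math.sin(half), 0.0])
    dir2 = np.array([math.cos(half), -math.sin(half), 0.0])
    segments = [
        (np.zeros(3), j, parent_diameter / 2.0),
        (j, j + dir1 * Ld, d1 / 2.0),
    ]
    if daughter_ratio < 1.0:
        segments.append((j, j + dir2 * Ld, d2 / 2.0))
    centerline = np.array([[a, b] for a, b, _ in segments])
    radii = np.array([r for _, _, r in segments])

    wall = WallGeometry(
        kind="bifurcation",
        repulsive=np.zeros((0, 3)),
        ghost=np.zeros((0, 3)),
        ghost_velocity=np.zeros((0, 3)),
        spacing=spacing,
        centerline=centerline,
        centerline_radius=radii,
        dims={
            "parent_diameter": parent_diameter,
            "daughter_diameters": (d1, d2),
            "angle": angle,
            "segment_lengths": segment_lengths,
        },
        inlet_x=0.0,
        outlet_x=float((j + dir1 * Ld)[0]),
        periodic=(False, False, False),
    )

    def branch_particles(seg_idx: int, radius_offset: float) -> np.ndarray:
        a, b, r = segments[seg_idx]
        axis = (b - a) / np.linalg.norm(b - a)
        u = np.cross(axis, [0.0, 0.0, 1.0])
        if np.linalg.norm(u) < 1e-12:
            u = np.cross(axis, [0.0, 1.0, 0.0])
        u /= np.linalg.norm(u)
        w = np.cross(axis, u)
        L = np.linalg.norm(b - a)
        pts = []
        delta = spacing * WALL_HYDRO_OFFSET if hydro_offset is None \
            else hydro_offset
        radius = segments[seg_idx][2] + delta + radius_offset
        for i, t in enumerate(np.arange(0.0, L, spacing)):
            ring = _circle_ring(radius, spacing)
            if i % 2:
                ang = spacing / (2 * radius)
                c, s = math.cos(ang), math.sin(ang)
                ring = ring @ np.array([[c, -s], [s, c]])
            center = a + t * axis
            pts.append(center + ring[:, :1] * u + ring[:, 1:] * w)
        return np.concatenate(pts)

    rep, gho = [], []
    for i in range(len(segments)):
        surf = branch_particles(i, 0.0)
        rep.append(surf[~_inside_other_branches(wall, surf, i)])
        for k in range(1, n_ghost_layers + 1):
            g = branch_particles(i, k * spacing)
            keep = ~wall.inside(g)  # ghosts must sit outside the lumen
            gho.append(g[keep])
    wall.repulsive = np.concatenate(rep)
    wall.ghost = np.concatenate(gho)
    wall.ghost_velocity = np.zeros_like(wall.ghost)

    all_pts = np.concatenate([wall.repulsive, wall.ghost])
    pad = n_ghost_layers * spacing
    wall.box_lo = all_pts.min(axis=0) - pad
    wall.box_hi = all_pts.max(axis=0) + pad
    wall.box_lo[0] = 0.0
    wall.box_hi[0] = wall.outlet_x
    wall.ghost_mirror = compute_ghost_mirrors(wall)
    return wall


# ---------------------------------------------------------------------------
# Ligand fields and fluid fills
# ---------------------------------------------------------------------------


@dataclass
class LigandField:
    """Fixed ligand binding sites scattered on the wall surface."""

    positions: np.ndarray  # (N, 3)
    density: float  # sites per dimensionless area
    wall: WallGeometry | None = None

    def __len__(self) -> int:
        return len(self.positions)


def seed_ligands(wall: WallGeometry, density: float,
                 rng: np.random.Generator | int | None = None) -> LigandField:
    """Scatter ligand sites uniformly on the adhesive wall surface."""
    if density < 0:
        raise ConfigurationError("ligand density must be >= 0")
    rng = np.random.default_rng(rng)
    if density == 0:
        return LigandField(np.zeros((0, 3)), 0.0, wall)
    area = wall.ligand_surface_area()
    n = int(round(area * density))
    return LigandField(wall.surface_points(n, rng), density, wall)


def _clamp_to_lumen(wall: WallGeometry, pts: np.ndarray,
                    margin: float) -> np.ndarray:
    """Pull points within ``margin`` of the wall surface back to that margin."""
    p = pts.copy()
    if wall.kind == "tube":
        R = wall.dims["diameter"] / 2.0 - margin
        r = np.hypot(p[:, 1], p[:, 2])
        over = r > R
        scale = np.where(over, R / np.maximum(r, 1e-300), 1.0)
        p[:, 1] *= scale
        p[:, 2] *= scale
    elif wall.kind == "couette":
        Lz = wall.dims["gap"]
        p[:, 2] = np.clip(p[:, 2], margin, Lz - margin)
    elif wall.kind == "bifurcation":
        # project toward the axis of the branch the point is deepest inside
        depth = np.full(len(p), -np.inf)
        best = np.zeros(len(p), dtype=int)
        for i, ((a, b), r) in enumerate(zip(wall.centerline, wall.centerline_radius)):
            d = r - _dist_to_segment(p, a, b)
            upd = d > depth
            depth[upd] = d[upd]
            best[upd] = i
        for i, ((a, b), r) in enumerate(zip(wall.centerline, wall.centerline_radius)):
            sel = (best == i) & (depth < margin)
            if not sel.any():
                continue
            ab = b - a
            t = np.clip((p[sel] - a) @ ab / (ab @ ab), 0.0, 1.0)
            axis_pt = a + t[:, None] * ab
            vec = p[sel] - axis_pt
            norm = np.maximum(np.linalg.norm(vec, axis=1), 1e-300)
            p[sel] = axis_pt + vec / norm[:, None] * (r - margin)
    return p


def fill_fluid(wall: WallGeometry, number_density: float,
               margin: float | None = None) -> np.ndarray:
    """Simple-cubic lattice fill of the lumen at the requested number density.

    The lattice covers the whole lumen so the particle count matches
    lumen volume x density; particles that land within half a lattice
    spacing of the wall surface are pulled back to that clearance (the
    slight local compression relaxes within a few SDPD steps).
    """
    if number_density <= 0:
        raise ConfigurationError("fluid number density must be > 0")
    h = number_density ** (-1.0 / 3.0)
    if margin is None:
        margin = h / 2.0
    lo, hi = wall.box_lo, wall.box_hi
    axes = []
    for d in range(3):
        if wall.periodic[d]:
            n = max(int(round((hi[d] - lo[d]) / h)), 1)
            axes.append(lo[d] + (np.arange(n) + 0.5) * (hi[d] - lo[d]) / n)
        else:
            # lattice centered on the box midpoint, so circular lumina are
            # sampled symmetrically (unbiased counts)
            n = int((hi[d] - lo[d]) / h)
            mid = 0.5 * (lo[d] + hi[d])
            axes.append(mid + (np.arange(n) - (n - 1) / 2.0) * h)
    gx, gy, gz = np.meshgrid(*axes, indexing="ij")
    pts = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])
    pts = pts[wall.inside(pts, margin=0.0)]
    # trim lattice-quantization excess so the count matches volume x density
    n_target = int(round(number_density * wall.lumen_volume()))
    if len(pts) > n_target:
        keep = np.random.default_rng(len(pts)).permutation(len(pts))
        pts = pts[np.sort(keep[:n_target])]
    return _clamp_to_lumen(wall, pts, margin)


# ---------------------------------------------------------------------------
# Cell placement
# ---------------------------------------------------------------------------


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - z * w), 2 * (x * z + y * w)],
            [2 * (x * y + z * w), 1 - 2 * (x * x + z * z), 2 * (y * z - x * w)],
            [2 * (x * z - y * w), 2 * (y * z + x * w), 1 - 2 * (x * x + y * y)],
        ]
    )


def points_inside_mesh(points: np.ndarray, mesh: CellMesh,
                       shrink: float = 0.0) -> np.ndarray:
    """Approximate inside test: signed distance along nearest-vertex normal."""
    from scipy.spatial import cKDTree

    vnorm = np.zeros_like(mesh.vertices)
    fn = mesh.face_normals()
    for k in range(3):
        np.add.at(vnorm, mesh.faces[:, k], fn)
    vnorm /= np.maximum(np.linalg.norm(vnorm, axis=1), 1e-12)[:, None]
    _, idx = cKDTree(mesh.vertices).query(points, k=1)
    to_point = points - mesh.vertices[idx]
    signed = np.einsum("ij,ij->i", to_point, vnorm[idx])
    return signed < -shrink


def _meshes_separated(a: CellMesh, b: CellMesh, min_gap: float) -> bool:
    """Surface separation: no close vertices and no surface crossing."""
    ca, cb = a.centroid(), b.centroid()
    ra = np.linalg.norm(a.vertices - ca, axis=1).max()
    rb = np.linalg.norm(b.vertices - cb, axis=1).max()
    if np.linalg.norm(ca - cb) > ra + rb + min_gap:
        return True
    from scipy.spatial import cKDTree

    d, _ = cKDTree(b.vertices).query(a.vertices, k=1,
                                     distance_upper_bound=min_gap)
    if not np.isinf(d).all():
        return False
    # vertex clouds are clear of each other; reject interpenetration
    if points_inside_mesh(a.vertices, b).any():
        return False
    if points_inside_mesh(b.vertices, a).any():
        return False
    return True


def place_cells(wall: WallGeometry, templates: Sequence[tuple[CellMesh, int]],
                rng: np.random.Generator | int | None = None,
                min_gap: float = 0.3, wall_margin: float = 0.35,
                max_attempts: int = 2000,
                fixed_positions: Optional[Sequence[np.ndarray]] = None,
                ) -> list[CellMesh]:
    """Place cells into the lumen without overlap (greedy random insertion).

    ``templates`` is a list of (reference mesh, count) pairs, placed in
    order.  ``fixed_positions`` optionally pins the first placed cells
    (e.g. a tumor cell on the tube axis) before random insertion begins.

    Raises a :class:`ConfigurationError` naming the failing cell if a
    non-overlapping position cannot be found within ``max_attempts``.
    """
    rng = np.random.default_rng(rng)
    placed: list[CellMesh] = []
    fixed = list(fixed_positions or [])
    idx = 0
    for template, count in templates:
        radius = np.linalg.norm(
            template.vertices - template.centroid(), axis=1
        ).max()
        for c in range(count):
            ok = False
            for attempt in range(max_attempts):
                if fixed:
                    pos = np.asarray(fixed.pop(0), dtype=float)
                    rot = np.eye(3)
                else:
                    pos = _sample_interior_point(wall, radius + wall_margin, rng)
                    rot = _random_rotation(rng)
                cand = template.transformed(rotation=rot,
                                            translation=pos - template.centroid())
                if not wall.inside(cand.vertices, margin=wall_margin).all():
                    continue
                if all(_meshes_separated(cand, p, min_gap) for p in placed):
                    placed.append(cand)
                    ok = True
                    break
            if not ok:
                raise ConfigurationError(
                    f"could not place cell #{idx} (kind={template.kind!r}, "
                    f"copy {c + 1}/{count}) without overlap after "
                    f"{max_attempts} attempts"
                )
            idx += 1
    return placed


def _sample_interior_point(wall: WallGeometry, margin: float,
                           rng: np.random.Generator) -> np.ndarray:
    for _ in range(10_000):
        p = rng.uniform(wall.box_lo, wall.box_hi)
        if wall.inside(p[None, :], margin=margin)[0]:
            return p
    raise ConfigurationError(
        f"lumen too narrow: no interior point at margin {margin}"
    )


def tube_disc_slots(wall: WallGeometry, cell_radius: float,
                    cell_thickness: float, wall_margin: float = 0.35,
                    axial_gap: float = 0.35) -> list[tuple[np.ndarray, np.ndarray]]:
    """Candidate (position, rotation) slots for disc-shaped cells in a tube.

    Cells are arranged as axial columns of face-on discs (normal along the
    flow axis), columns helically staggered so neighboring rims interleave —
    the arrangement that admits physiological hematocrits which random
    insertion cannot reach.  Slots are candidates only; the caller re-checks
    surface separation before accepting one.
    """
    if wall.kind != "tube":
        raise ConfigurationError("disc slots are defined for tube geometry")
    R = wall.dims["diameter"] / 2.0
    L = wall.dims["length"]
    r_max = R - wall_margin - cell_radius
    if r_max < 0:
        raise ConfigurationError(
            f"tube radius {R} too small for cells of radius {cell_radius}"
        )
    dz = cell_thickness + axial_gap
    slots: list[tuple[np.ndarray, np.ndarray]] = []
    # nested shells of wall-tangent discs (disc normal radial — the
    # orientation red cells adopt near a wall), thickness-limited radially
    shell_r = R - wall_margin - cell_thickness / 2.0
    shell_step = cell_thickness + 0.35
    dz_t = 2.0 * cell_radius + axial_gap
    innermost = shell_r
    while shell_r > 1.2 * cell_radius:
        innermost = shell_r
        n = max(int(2 * math.pi * shell_r // (2.0 * cell_radius + 0.5)), 1)
        chord = 2.0 * shell_r * math.sin(math.pi / max(n, 2))
        stagger = chord < 2.0 * cell_radius + 0.3
        if stagger and n % 2 and n > 1:
            n -= 1  # even count so axial stagger alternates cleanly
        for k in range(n):
            th = 2 * math.pi * k / n
            ct, st = math.cos(th), math.sin(th)
            radial = np.array([0.0, ct, st])
            axis = np.cross([0.0, 0.0, 1.0], radial)
            rot = (
                _rotation_about(axis, math.acos(np.clip(radial[2], -1, 1)))
                if np.linalg.norm(axis) > 1e-12 else np.eye(3)
            )
            phase = (k % 2) * dz_t / 2.0 if stagger else 0.0
            x = cell_radius + axial_gap / 2.0 + phase
            while x < L - cell_radius:
                slots.append((
                    np.array([x, shell_r * ct, shell_r * st]), rot,
                ))
                x += dz_t
        shell_r -= shell_step
    # face-on columns (disc normal along flow) in the core left open by
    # the innermost shell
    core = innermost - cell_thickness / 2.0 - 0.5 * axial_gap
    face_rot = np.array([[0.0, 0.0, 1.0], [0.0, 1.0, 0.0], [-1.0, 0.0, 0.0]])
    ring_radii = []
    if core >= cell_radius:
        ring_radii.append(0.0)
        r = 1.7 * cell_radius
        while r <= core - cell_radius + 1e-9:
            ring_radii.append(r)
            r += 1.7 * cell_radius
    ci = 0
    for rr in ring_radii:
        angles = [0.0]
        if rr > 0:
            n = max(int(2 * math.pi * rr // (2.1 * cell_radius)), 1)
            angles = [2 * math.pi * k / n for k in range(n)]
        for th in angles:
            phase = (ci % 2) * dz / 2.0
            ci += 1
            x = cell_thickness / 2.0 + axial_gap / 2.0 + phase
            while x < L - cell_thickness / 2.0:
                slots.append((
                    np.array([x, rr * math.cos(th), rr * math.sin(th)]),
                    face_rot,
                ))
                x += dz
    return slots


def _rotation_about(axis: np.ndarray, angle: float) -> np.ndarray:
    axis = axis / max(np.linalg.norm(axis), 1e-300)
    K = np.array([[0, -axis[2], axis[1]],
                  [axis[2], 0, -axis[0]],
                  [-axis[1], axis[0], 0]])
    return np.eye(3) + math.sin(angle) * K + (1 - math.cos(angle)) * K @ K


def relax_cell_overlaps(cells: list[CellMesh], wall: WallGeometry,
                        target_gap: float = 0.1, wall_margin: float = 0.3,
                        max_iterations: int = 600, step: float = 0.05,
                        mobile: Sequence[bool] | None = None) -> list[CellMesh]:
    """Resolve inter-cell overlaps by rigid-body steepest descent.

    Cells are moved and rotated as rigid bodies under short-range repulsive
    forces between nearby vertices of different cells and an inward push on
    vertices violating the wall clearance.  Deformation-free, deterministic,
    and the standard way to initialize suspensions at hematocrits random
    insertion cannot reach.
    """
    from scipy.spatial import cKDTree

    if mobile is None:
        mobile = [True] * len(cells)
    verts = [c.vertices.copy() for c in cells]
    owner = np.concatenate([np.full(len(v), i) for i, v in enumerate(verts)])
    n_axial_periodic = wall.periodic[0]
    Lx = wall.box_hi[0] - wall.box_lo[0]
    for it in range(max_iterations):
        allv = np.concatenate(verts)
        tree = cKDTree(allv)
        pairs = tree.query_pairs(target_gap, output_type="ndarray")
        if len(pairs):
            pairs = pairs[owner[pairs[:, 0]] != owner[pairs[:, 1]]]
        forces = np.zeros((len(cells), 3))
        torques = np.zeros((len(cells), 3))
        centroids = np.array([v.mean(axis=0) for v in verts])
        moved = False
        if len(pairs):
            moved = True
            d = allv[pairs[:, 0]] - allv[pairs[:, 1]]
            dist = np.maximum(np.linalg.norm(d, axis=1), 1e-9)
            push = (target_gap - dist) / dist
            f = d * push[:, None]
            for (i, j), fij, pi, pj in zip(pairs, f, allv[pairs[:, 0]],
                                           allv[pairs[:, 1]]):
                ci, cj = owner[i], owner[j]
                forces[ci] += fij
                forces[cj] -= fij
                torques[ci] += np.cross(pi - centroids[ci], fij)
                torques[cj] += np.cross(pj - centroids[cj], -fij)
        # eject interpenetrating cells (surfaces can cross between vertex
        # samples; push the intruder out along the line of centroids)
        if it % 10 == 0:
            radii = [
                np.linalg.norm(v - centroids[ci], axis=1).max()
                for ci, v in enumerate(verts)
            ]
            for a in range(len(cells)):
                for b in range(len(cells)):
                    if a == b or not (mobile[a] or mobile[b]):
                        continue
                    cc = centroids[b] - centroids[a]
                    dist = np.linalg.norm(cc)
                    if dist > radii[a] + radii[b]:
                        continue
                    mesh_b = cells[b].transformed()
                    mesh_b.vertices = np.ascontiguousarray(verts[b])
                    inside = points_inside_mesh(verts[a], mesh_b)
                    if inside.any():
                        moved = True
                        push = -cc / max(dist, 1e-9) * inside.sum()
                        if mobile[a]:
                            forces[a] += push * 2.0
                        if mobile[b]:
                            forces[b] -= push * 2.0
        # wall clearance
        for ci, v in enumerate(verts):
            if not mobile[ci]:
                continue
            clamped = _clamp_to_lumen(wall, v, wall_margin)
            dv = clamped - v
            bad = np.linalg.norm(dv, axis=1) > 1e-12
            if bad.any():
                moved = True
                forces[ci] += dv[bad].sum(axis=0)
                torques[ci] += np.cross(v[bad] - centroids[ci], dv[bad]).sum(axis=0)
        if not moved:
            break
        for ci in range(len(cells)):
            if not mobile[ci]:
                continue
            nf = np.linalg.norm(forces[ci])
            if nf > 1e-12:
                verts[ci] = verts[ci] + forces[ci] / nf * min(step, step * nf)
            nt = np.linalg.norm(torques[ci])
            if nt > 1e-12:
                ang = min(0.02, 0.02 * nt)
                R = _rotation_about(torques[ci], ang)
                verts[ci] = (verts[ci] - centroids[ci]) @ R.T + centroids[ci]
            if n_axial_periodic:
                # keep centroids inside the periodic box
                cx = verts[ci][:, 0].mean()
                if cx < wall.box_lo[0]:
                    verts[ci][:, 0] += Lx
                elif cx >= wall.box_hi[0]:
                    verts[ci][:, 0] -= Lx
    out = []
    for c, v in zip(cells, verts):
        nc = c.transformed()
        nc.vertices = np.ascontiguousarray(v)
        out.append(nc)
    return out


def place_rbcs_tube(wall: WallGeometry, template: CellMesh, count: int,
                    rng: np.random.Generator | int | None = None,
                    min_gap: float = 0.05, wall_margin: float = 0.3,
                    jitter: float = 0.1, avoid: Sequence[CellMesh] = (),
                    prefer_outer: bool = False) -> list[CellMesh]:
    """Place ``count`` disc-shaped cells into a tube at high volume fraction.

    Cells start on a helically staggered column lattice (face-on discs) and
    residual overlaps are resolved by rigid-body relaxation.  ``avoid``
    holds already-placed cells (e.g. a tumor cell pinned on the axis) the
    new ones must keep clear of.  Raises if the lattice has too few slots
    or relaxation cannot reach positive surface separation.
    """
    rng = np.random.default_rng(rng)
    radius = np.linalg.norm(template.vertices - template.centroid(), axis=1).max()
    thickness = 2.0 * np.abs(template.vertices[:, 2] - template.centroid()[2]).max()
    slots = tube_disc_slots(wall, radius, thickness, wall_margin=wall_margin)
    if len(slots) < count:
        raise ConfigurationError(
            f"tube lattice has only {len(slots)} slots for {count} cells "
            f"(kind={template.kind!r})"
        )
    # keep slots far from pinned cells, then sample
    keep = []
    avoid_centroids = [c.centroid() for c in avoid]
    avoid_radii = [
        np.linalg.norm(c.vertices - c.centroid(), axis=1).max() for c in avoid
    ]
    # loose prefilter; the vertex-separation test and relaxation decide
    for pos, rot in slots:
        if all(
            np.linalg.norm(pos - ac) > ar + radius * 0.2
            for ac, ar in zip(avoid_centroids, avoid_radii)
        ):
            keep.append((pos, rot))
    if len(keep) < count:
        raise ConfigurationError(
            f"only {len(keep)} lattice slots clear of pinned cells, "
            f"need {count}"
        )
    # phase 1: greedy insertion on the slot lattice (several jitter rounds)
    placed: list[CellMesh] = list(avoid)
    new: list[CellMesh] = []
    for round_ in range(3):
        if prefer_outer:
            # outer slots first (area-uniform seeding), random tie-break
            radii = np.array([np.hypot(p[1], p[2]) for p, _ in keep])
            order = np.argsort(-(radii + rng.uniform(0, 0.3, len(keep))))
        else:
            order = rng.permutation(len(keep))
        for si in order:
            if len(new) >= count:
                break
            pos, rot = keep[si]
            pos = pos + rng.uniform(-jitter, jitter, 3)
            tilt = _rotation_about(rng.normal(size=3),
                                   rng.uniform(-0.15, 0.15))
            cand = template.transformed(
                rotation=tilt @ rot, translation=pos - template.centroid()
            )
            if not wall.inside(cand.vertices, margin=wall_margin * 0.8).all():
                continue
            if all(_meshes_separated(cand, p, min_gap) for p in placed):
                placed.append(cand)
                new.append(cand)
        if len(new) >= count:
            return new
    # phase 2: admit the remaining cells with overlaps, relax them out;
    # retried with fresh draws if relaxation leaves contacts
    for attempt in range(4):
        extras: list[CellMesh] = []
        for si in rng.permutation(len(keep)):
            if len(new) + len(extras) >= count:
                break
            pos, rot = keep[si]
            pos = pos + rng.uniform(-jitter, jitter, 3)
            cand = template.transformed(
                rotation=rot, translation=pos - template.centroid()
            )
            if any(
                np.linalg.norm(cand.centroid() - p.centroid()) < 0.4
                for p in placed + extras
            ):
                continue
            extras.append(cand)
        if len(new) + len(extras) < count:
            raise ConfigurationError(
                f"tube lattice exhausted: {len(new) + len(extras)} of "
                f"{count} cells (kind={template.kind!r})"
            )
        all_cells = placed + extras
        mobile = [False] * len(placed) + [True] * len(extras)
        relaxed = relax_cell_overlaps(all_cells, wall, target_gap=min_gap,
                                      wall_margin=wall_margin, mobile=mobile)
        result = new + relaxed[len(placed):]
        # full pairwise verification (vertex gaps and interpenetration)
        every = list(avoid) + result
        ok = True
        for a in range(len(every)):
            for b in range(a + 1, len(every)):
                if not _meshes_separated(every[a], every[b], min_gap * 0.2):
                    ok = False
                    break
            if not ok:
                break
        if ok:
            return result
    raise ConfigurationError(
        "relaxation could not produce positively separated cells after "
        "4 attempts; reduce count or enlarge tube"
    )


def compute_hematocrit(cells: Sequence[CellMesh], lumen_volume: float) -> float:
    """Volume fraction occupied by the given cells (divergence-theorem volumes)."""
    if lumen_volume <= 0:
        raise ConfigurationError("lumen volume must be > 0")
    return float(sum(abs(c.volume()) for c in cells)) / lumen_volume
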