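"""Numba-compiled inner loops: neighbor search, SDPD pair forces, membrane
network forces, Morse element forces.

All functions are deterministic.  Pairwise thermal noise uses a
counter-based hash RNG keyed by (seed, step, i, j), so results do not
depend on pair iteration order and runs are bit-reproducible.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

# Lucy kernel, 3D normalization: W(r) = 105/(16 pi rc^3) (1 + 3q)(1 - q)^3
_LUCY_SIGMA = 105.0 / (16.0 * math.pi)


@njit(cache=True, inline="always")
def lucy_w(r, rc):
    q = r / rc
    if q >= 1.0:
        return 0.0
    s = _LUCY_SIGMA / rc**3
    return s * (1.0 + 3.0 * q) * (1.0 - q) ** 3


@njit(cache=True, inline="always")
def lucy_f(r, rc):
    """-W'(r)/r, finite at r = 0 (Lucy kernel property)."""
    q = r / rc
    if q >= 1.0:
        return 0.0
    s = _LUCY_SIGMA / rc**3
    return 12.0 * s * (1.0 - q) ** 2 / rc**2


# ---------------------------------------------------------------------------
# Counter-based RNG (splitmix64 -> Box-Muller)
# ---------------------------------------------------------------------------


@njit(cache=True, inline="always")
def _splitmix(z):
    z = (z + np.uint64(0x9E3779B97F4A7C15)) & np.uint64(0xFFFFFFFFFFFFFFFF)
    z = (z ^ (z >> np.uint64(30))) * np.uint64(0xBF58476D1CE4E5B9)
    z = (z ^ (z >> np.uint64(27))) * np.uint64(0x94D049BB133111EB)
    return z ^ (z >> np.uint64(31))


@njit(cache=True, inline="always")
def _u01(h):
    # uniform in (0, 1]
    return (float(h >> np.uint64(11)) + 1.0) * (1.0 / 9007199254740992.0)


_SQRT3 = math.sqrt(3.0)


@njit(cache=True, inline="always")
def pair_noise3(seed, step, i, j):
    """Three zero-mean unit-variance symmetric variates keyed by
    (seed, step, unordered pair).

    Uniform variates scaled to unit variance; for pairwise-thermostat
    forces the noise distribution shape is immaterial (only the first two
    moments enter), and uniforms cost far less than Gaussians.
    """
    a = np.uint64(min(i, j))
    b = np.uint64(max(i, j))
    h = _splitmix(np.uint64(seed) ^ _splitmix(np.uint64(step)))
    h = _splitmix(h ^ (a * np.uint64(0x9E3779B97F4A7C15) + b))
    h2 = _splitmix(h)
    mask = np.uint64(0xFFFFFFFF)
    inv = 1.0 / 4294967296.0
    u1 = float(h & mask) * inv
    u2 = float(h >> np.uint64(32)) * inv
    u3 = float(h2 & mask) * inv
    g1 = _SQRT3 * (2.0 * u1 - 1.0)
    g2 = _SQRT3 * (2.0 * u2 - 1.0)
    g3 = _SQRT3 * (2.0 * u3 - 1.0)
    return g1, g2, g3


@njit(cache=True, inline="always")
def event_u01(seed, step, a, b):
    """Uniform (0,1] keyed by (seed, step, a, b) — bond kinetics draws."""
    h = _splitmix(np.uint64(seed) ^ _splitmix(np.uint64(step)))
    h = _splitmix(
        h ^ (np.uint64(a) * np.uint64(0x9E3779B97F4A7C15) + np.uint64(b))
    )
    return _u01(h)


# ---------------------------------------------------------------------------
# Linked-cell neighbor search
# ---------------------------------------------------------------------------


@njit(cache=True)
def build_grid(pos, box_lo, box_hi, cutoff):
    """Bin particles into a uniform grid of cell size >= cutoff."""
    n = pos.shape[0]
    dims = np.empty(3, dtype=np.int64)
    for d in range(3):
        dims[d] = max(int((box_hi[d] - box_lo[d]) / cutoff), 1)
    ncell = dims[0] * dims[1] * dims[2]
    cell_of = np.empty(n, dtype=np.int64)
    for i in range(n):
        cx = int((pos[i, 0] - box_lo[0]) / (box_hi[0] - box_lo[0]) * dims[0])
        cy = int((pos[i, 1] - box_lo[1]) / (box_hi[1] - box_lo[1]) * dims[1])
        cz = int((pos[i, 2] - box_lo[2]) / (box_hi[2] - box_lo[2]) * dims[2])
        cx = min(max(cx, 0), dims[0] - 1)
        cy = min(max(cy, 0), dims[1] - 1)
        cz = min(max(cz, 0), dims[2] - 1)
        cell_of[i] = (cx * dims[1] + cy) * dims[2] + cz
    count = np.zeros(ncell + 1, dtype=np.int64)
    for i in range(n):
        count[cell_of[i] + 1] += 1
    for c in range(ncell):
        count[c + 1] += count[c]
    order = np.empty(n, dtype=np.int64)
    fill = count[:-1].copy()
    for i in range(n):
        c = cell_of[i]
        order[fill[c]] = i
        fill[c] += 1
    return dims, count, order


@njit(cache=True, inline="always")
def _min_image(dx, box, periodic):
    for d in range(3):
        if periodic[d]:
            if dx[d] > 0.5 * box[d]:
                dx[d] -= box[d]
            elif dx[d] < -0.5 * box[d]:
                dx[d] += box[d]


@njit(cache=True)
def self_pairs(pos, box_lo, box_hi, periodic, cutoff, dims, start, order):
    """Half list of (i, j) pairs with |r_ij| < cutoff (minimum image)."""
    n = pos.shape[0]
    box = box_hi - box_lo
    cap = max(n * 64, 1024)
    out = np.empty((cap, 2), dtype=np.int64)
    m = 0
    c2 = cutoff * cutoff
    dx = np.empty(3)
    # wrapped neighbor cells can coincide only if a periodic dim has < 3
    # cells; only then is the dedupe scan needed
    check_dup = (
        (periodic[0] and dims[0] < 3)
        or (periodic[1] and dims[1] < 3)
        or (periodic[2] and dims[2] < 3)
    )
    seen = np.empty(27, dtype=np.int64)
    inv = np.empty(3)
    for d in range(3):
        inv[d] = dims[d] / box[d]
    for i in range(n):
        cx = min(max(int((pos[i, 0] - box_lo[0]) * inv[0]), 0), dims[0] - 1)
        cy = min(max(int((pos[i, 1] - box_lo[1]) * inv[1]), 0), dims[1] - 1)
        cz = min(max(int((pos[i, 2] - box_lo[2]) * inv[2]), 0), dims[2] - 1)
        nseen = 0
        for ox in range(-1, 2):
            nx = cx + ox
            if periodic[0]:
                nx %= dims[0]
            elif nx < 0 or nx >= dims[0]:
                continue
            for oy in range(-1, 2):
                ny = cy + oy
                if periodic[1]:
                    ny %= dims[1]
                elif ny < 0 or ny >= dims[1]:
                    continue
                for oz in range(-1, 2):
                    nz = cz + oz
                    if periodic[2]:
                        nz %= dims[2]
                    elif nz < 0 or nz >= dims[2]:
                        continue
                    nc = (nx * dims[1] + ny) * dims[2] + nz
                    if check_dup:
                        dup = False
                        for q in range(nseen):
                            if seen[q] == nc:
                                dup = True
                                break
                        if dup:
                            continue
                        seen[nseen] = nc
                        nseen += 1
                    for jj in range(start[nc], start[nc + 1]):
                        j = order[jj]
                        if j <= i:
                            continue
                        for d in range(3):
                            dx[d] = pos[i, d] - pos[j, d]
                        _min_image(dx, box, periodic)
                        r2 = dx[0] ** 2 + dx[1] ** 2 + dx[2] ** 2
                        if r2 < c2:
                            if m >= cap:
                                cap *= 2
                                new = np.empty((cap, 2), dtype=np.int64)
                                new[:m] = out[:m]
                                out = new
                            out[m, 0] = i
                            out[m, 1] = j
                            m += 1
    return out[:m]


@njit(cache=True)
def cross_pairs(query, pos, box_lo, box_hi, periodic, cutoff,
                dims, start, order):
    """Pairs (qi, pj) with |query_qi - pos_pj| < cutoff, grid built on pos."""
    box = box_hi - box_lo
    nq = query.shape[0]
    cap = max(nq * 48, 1024)
    out = np.empty((cap, 2), dtype=np.int64)
    m = 0
    c2 = cutoff * cutoff
    dx = np.empty(3)
    check_dup = (
        (periodic[0] and dims[0] < 3)
        or (periodic[1] and dims[1] < 3)
        or (periodic[2] and dims[2] < 3)
    )
    seen = np.empty(27, dtype=np.int64)
    for qi in range(nq):
        cx = int((query[qi, 0] - box_lo[0]) / box[0] * dims[0])
        cy = int((query[qi, 1] - box_lo[1]) / box[1] * dims[1])
        cz = int((query[qi, 2] - box_lo[2]) / box[2] * dims[2])
        cx = min(max(cx, 0), dims[0] - 1)
        cy = min(max(cy, 0), dims[1] - 1)
        cz = min(max(cz, 0), dims[2] - 1)
        nseen = 0
        for ox in range(-1, 2):
            nx = cx + ox
            if periodic[0]:
                nx %= dims[0]
            elif nx < 0 or nx >= dims[0]:
                continue
            for oy in range(-1, 2):
                ny = cy + oy
                if periodic[1]:
                    ny %= dims[1]
                elif ny < 0 or ny >= dims[1]:
                    continue
                for oz in range(-1, 2):
                    nz = cz + oz
                    if periodic[2]:
                        nz %= dims[2]
                    elif nz < 0 or nz >= dims[2]:
                        continue
                    nc = (nx * dims[1] + ny) * dims[2] + nz
                    if check_dup:
                        dup = False
                        for q in range(nseen):
                            if seen[q] == nc:
                                dup = True
                                break
                        if dup:
                            continue
                        seen[nseen] = nc
                        nseen += 1
                    for jj in range(start[nc], start[nc + 1]):
                        j = order[jj]
                        for d in range(3):
                            dx[d] = query[qi, d] - pos[j, d]
                        _min_image(dx, box, periodic)
                        r2 = dx[0] ** 2 + dx[1] ** 2 + dx[2] ** 2
                        if r2 < c2:
                            if m >= cap:
                                cap *= 2
                                new = np.empty((cap, 2), dtype=np.int64)
                                new[:m] = out[:m]
                                out = new
                            out[m, 0] = qi
                            out[m, 1] = j
                            m += 1
    return out[:m]


# ---------------------------------------------------------------------------
# SDPD fluid
# ---------------------------------------------------------------------------


@njit(cache=True)
def sdpd_density(pos, mass, pairs, box_lo, box_hi, periodic, cutoff):
    """rho_i = sum_j m_j W(r_ij), including the self contribution."""
    n = pos.shape[0]
    box = box_hi - box_lo
    rho = np.empty(n)
    w0 = lucy_w(0.0, cutoff)
    for i in range(n):
        rho[i] = mass[i] * w0
    dx = np.empty(3)
    for p in range(pairs.shape[0]):
        i = pairs[p, 0]
        j = pairs[p, 1]
        for d in range(3):
            dx[d] = pos[i, d] - pos[j, d]
        _min_image(dx, box, periodic)
        r = math.sqrt(dx[0] ** 2 + dx[1] ** 2 + dx[2] ** 2)
        w = lucy_w(r, cutoff)
        rho[i] += mass[j] * w
        rho[j] += mass[i] * w
    return rho


@njit(cache=True)
def sdpd_pair_forces(pos, vel, mass, rho, pressure, pairs, box_lo, box_hi,
                     periodic, cutoff, eta, kBT, dt, seed, step,
                     conservative, dissipative, random,
                     n_mobile=-1, wall_visc_factor=1.0):
    """Conservative + dissipative + random SDPD pair forces.

    The dissipative force is the Espanol–Revenga shear form
    F_D = -a_ij (v_ij + e (e . v_ij)), a_ij = (5 eta / 3) F_ij m_i m_j /
    (rho_i rho_j), whose continuum limit has shear viscosity eta.  The
    random force is the matched fluctuation of that pairwise friction
    tensor Gamma = a (I + e e^T): amplitude sqrt(2 kBT) Gamma^{1/2} with
    Gamma^{1/2} = sqrt(a) (I + (sqrt(2)-1) e e^T).
    """
    n = pos.shape[0]
    box = box_hi - box_lo
    force = np.zeros((n, 3))
    sq2m1 = math.sqrt(2.0) - 1.0
    dx = np.empty(3)
    dv = np.empty(3)
    e = np.empty(3)
    for p in range(pairs.shape[0]):
        i = pairs[p, 0]
        j = pairs[p, 1]
        for d in range(3):
            dx[d] = pos[i, d] - pos[j, d]
        _min_image(dx, box, periodic)
        r = math.sqrt(dx[0] ** 2 + dx[1] ** 2 + dx[2] ** 2)
        if r >= cutoff:
            continue
        fl = lucy_f(r, cutoff)
        if r > 1e-12:
            for d in range(3):
                e[d] = dx[d] / r
        else:
            e[0] = 1.0
            e[1] = 0.0
            e[2] = 0.0
        mm = mass[i] * mass[j]
        fx = 0.0
        fy = 0.0
        fz = 0.0
        if conservative:
            pc = mm * (
                pressure[i] / rho[i] ** 2 + pressure[j] / rho[j] ** 2
            ) * fl
            fx += pc * dx[0]
            fy += pc * dx[1]
            fz += pc * dx[2]
        a_ij = (5.0 * eta / 3.0) * fl * mm / (rho[i] * rho[j])
        if n_mobile >= 0 and (i >= n_mobile or j >= n_mobile):
            # fluid-wall pair: short-range friction enhancement pins the
            # boundary layer to the wall velocity without adding bulk drag
            # (no-slip calibration; reach 0.5 cutoff)
            if r < 0.5 * cutoff:
                a_ij *= 1.0 + (wall_visc_factor - 1.0) * (
                    1.0 - r / (0.5 * cutoff)
                ) ** 2
        if dissipative:
            for d in range(3):
                dv[d] = vel[i, d] - vel[j, d]
            edv = e[0] * dv[0] + e[1] * dv[1] + e[2] * dv[2]
            fx += -a_ij * (dv[0] + e[0] * edv)
            fy += -a_ij * (dv[1] + e[1] * edv)
            fz += -a_ij * (dv[2] + e[2] * edv)
        if random and kBT > 0.0 and a_ij > 0.0:
            g1, g2, g3 = pair_noise3(seed, step, i, j)
            amp = math.sqrt(2.0 * kBT * a_ij / dt)
            ge = g1 * e[0] + g2 * e[1] + g3 * e[2]
            fx += amp * (g1 + sq2m1 * ge * e[0])
            fy += amp * (g2 + sq2m1 * ge * e[1])
            fz += amp * (g3 + sq2m1 * ge * e[2])
        force[i, 0] += fx
        force[i, 1] += fy
        force[i, 2] += fz
        force[j, 0] -= fx
        force[j, 1] -= fy
        force[j, 2] -= fz
    return force


# ---------------------------------------------------------------------------
# Membrane network forces
# ---------------------------------------------------------------------------


#: extension ratio beyond which the WLC tension is held constant (yield
#: regularization; the bare WLC force diverges at x = 1)
WLC_REGULARIZATION_X = 0.9


@njit(cache=True)
def inplane_forces(verts, edges, l_max, k_p, kT_over_p):
    """Worm-like-chain attraction + inverse-square repulsion springs.

    Beyond 90% of the contour length the WLC tension is held at its
    value there (a yield-like continuation), so transient extreme
    stretches produce a large finite restoring force instead of a
    singularity.  Returns (forces, energy,
    first_edge_beyond_contour_length or -1).
    """
    nv = verts.shape[0]
    force = np.zeros((nv, 3))
    energy = 0.0
    bad = -1
    xs = WLC_REGULARIZATION_X
    # WLC tension at the regularization point (per unit kT/p)
    f_s = 1.0 / (4.0 * (1.0 - xs) ** 2) - 0.25 + xs
    u_s = xs * (3.0 * xs - 2.0 * xs * xs) / (4.0 * (1.0 - xs))
    for eidx in range(edges.shape[0]):
        i = edges[eidx, 0]
        j = edges[eidx, 1]
        dx0 = verts[i, 0] - verts[j, 0]
        dx1 = verts[i, 1] - verts[j, 1]
        dx2 = verts[i, 2] - verts[j, 2]
        l = math.sqrt(dx0 * dx0 + dx1 * dx1 + dx2 * dx2)
        lm = l_max[eidx]
        x = l / lm
        if x >= 1.0 and bad < 0:
            bad = eidx
        if x < xs:
            # U_wlc = kT lm (3x^2 - 2x^3) / (4 p (1 - x))
            energy += kT_over_p * lm * (
                3.0 * x * x - 2.0 * x**3
            ) / (4.0 * (1.0 - x))
            dwlc = kT_over_p * (
                1.0 / (4.0 * (1.0 - x) ** 2) - 0.25 + x
            )
        else:
            dl = (x - xs) * lm
            energy += kT_over_p * (lm * u_s + f_s * dl)
            dwlc = kT_over_p * f_s
        energy += k_p[eidx] / l
        dpow = -k_p[eidx] / (l * l)
        du = dwlc + dpow
        g = du / l
        force[i, 0] -= g * dx0
        force[i, 1] -= g * dx1
        force[i, 2] -= g * dx2
        force[j, 0] += g * dx0
        force[j, 1] += g * dx1
        force[j, 2] += g * dx2
    return force, energy, bad


@njit(cache=True)
def bending_forces(verts, edges, edge_opp, K_B, theta0):
    """Dihedral bending U = K_B sum [1 - cos(theta - theta0)].

    theta is the signed angle between the normals of the two triangles
    sharing each edge (positive convex for outward orientation).
    """
    nv = verts.shape[0]
    force = np.zeros((nv, 3))
    energy = 0.0
    for eidx in range(edges.shape[0]):
        i = edges[eidx, 0]
        j = edges[eidx, 1]
        k = edge_opp[eidx, 0]
        l = edge_opp[eidx, 1]
        # triangles (i, j, k) and (j, i, l); shared edge i-j
        ex = verts[j, 0] - verts[i, 0]
        ey = verts[j, 1] - verts[i, 1]
        ez = verts[j, 2] - verts[i, 2]
        en = math.sqrt(ex * ex + ey * ey + ez * ez)
        # n1 = (j - i) x (k - i); n2 = (l - i) x (j - i)
        ax = verts[k, 0] - verts[i, 0]
        ay = verts[k, 1] - verts[i, 1]
        az = verts[k, 2] - verts[i, 2]
        bx = verts[l, 0] - verts[i, 0]
        by = verts[l, 1] - verts[i, 1]
        bz = verts[l, 2] - verts[i, 2]
        n1x = ey * az - ez * ay
        n1y = ez * ax - ex * az
        n1z = ex * ay - ey * ax
        n2x = by * ez - bz * ey
        n2y = bz * ex - bx * ez
        n2z = bx * ey - by * ex
        n1sq = n1x * n1x + n1y * n1y + n1z * n1z
        n2sq = n2x * n2x + n2y * n2y + n2z * n2z
        if n1sq < 1e-30 or n2sq < 1e-30 or en < 1e-15:
            continue
        n1n = math.sqrt(n1sq)
        n2n = math.sqrt(n2sq)
        cosq = (n1x * n2x + n1y * n2y + n1z * n2z) / (n1n * n2n)
        if cosq > 1.0:
            cosq = 1.0
        elif cosq < -1.0:
            cosq = -1.0
        # sign: (n1 x n2) . e
        cx = n1y * n2z - n1z * n2y
        cy = n1z * n2x - n1x * n2z
        cz = n1x * n2y - n1y * n2x
        sinq = (cx * ex + cy * ey + cz * ez) / (n1n * n2n * en)
        theta = math.atan2(sinq, cosq)
        dth = theta - theta0[eidx]
        energy += K_B * (1.0 - math.cos(dth))
        dU = K_B * math.sin(dth)
        # gradients of the torsion angle (standard formulas):
        # dtheta/dx_k = -|e| n1 / |n1|^2 ; dtheta/dx_l = -|e| n2 / |n2|^2
        gk = -en / n1sq
        gl = -en / n2sq
        gkx = gk * n1x
        gky = gk * n1y
        gkz = gk * n1z
        glx = gl * n2x
        gly = gl * n2y
        glz = gl * n2z
        # projections of the wing vectors on the shared edge
        # (k - i).e / |e|^2 and (l - i).e / |e|^2
        pk = (ax * ex + ay * ey + az * ez) / (en * en)
        pl = (bx * ex + by * ey + bz * ez) / (en * en)
        # dtheta/dx_i = -(1 - pk) gk_vec - (1 - pl) gl_vec
        # dtheta/dx_j = -pk gk_vec - pl gl_vec   (with overall signs below)
        gix = (pk - 1.0) * gkx + (pl - 1.0) * glx
        giy = (pk - 1.0) * gky + (pl - 1.0) * gly
        giz = (pk - 1.0) * gkz + (pl - 1.0) * glz
        gjx = -pk * gkx - pl * glx
        gjy = -pk * gky - pl * gly
        gjz = -pk * gkz - pl * glz
        force[k, 0] -= dU * gkx
        force[k, 1] -= dU * gky
        force[k, 2] -= dU * gkz
        force[l, 0] -= dU * glx
        force[l, 1] -= dU * gly
        force[l, 2] -= dU * glz
        force[i, 0] -= dU * gix
        force[i, 1] -= dU * giy
        force[i, 2] -= dU * giz
        force[j, 0] -= dU * gjx
        force[j, 1] -= dU * gjy
        force[j, 2] -= dU * gjz
    return force, energy


@njit(cache=True)
def area_volume_forces(verts, faces, K_AG, A0, K_AL, a0, K_V, V0):
    """Quadratic global-area, local-area and volume penalty forces."""
    nv = verts.shape[0]
    force = np.zeros((nv, 3))
    nf = faces.shape[0]
    areas = np.empty(nf)
    nhat = np.empty((nf, 3))
    A = 0.0
    V = 0.0
    for f in range(nf):
        a = faces[f, 0]
        b = faces[f, 1]
        c = faces[f, 2]
        ux = verts[b, 0] - verts[a, 0]
        uy = verts[b, 1] - verts[a, 1]
        uz = verts[b, 2] - verts[a, 2]
        vx = verts[c, 0] - verts[a, 0]
        vy = verts[c, 1] - verts[a, 1]
        vz = verts[c, 2] - verts[a, 2]
        nx = uy * vz - uz * vy
        ny = uz * vx - ux * vz
        nz = ux * vy - uy * vx
        nn = math.sqrt(nx * nx + ny * ny + nz * nz)
        areas[f] = 0.5 * nn
        if nn > 1e-30:
            nhat[f, 0] = nx / nn
            nhat[f, 1] = ny / nn
            nhat[f, 2] = nz / nn
        else:
            nhat[f, 0] = 0.0
            nhat[f, 1] = 0.0
            nhat[f, 2] = 0.0
        A += areas[f]
        V += (
            verts[a, 0] * (verts[b, 1] * verts[c, 2] - verts[b, 2] * verts[c, 1])
            + verts[a, 1] * (verts[b, 2] * verts[c, 0] - verts[b, 0] * verts[c, 2])
            + verts[a, 2] * (verts[b, 0] * verts[c, 1] - verts[b, 1] * verts[c, 0])
        ) / 6.0
    energy = K_AG * (A - A0) ** 2 / (2.0 * A0) + K_V * (V - V0) ** 2 / (2.0 * V0)
    cG = K_AG * (A - A0) / A0
    cV = K_V * (V - V0) / V0
    for f in range(nf):
        a = faces[f, 0]
        b = faces[f, 1]
        c = faces[f, 2]
        cL = K_AL * (areas[f] - a0[f]) / a0[f]
        energy += K_AL * (areas[f] - a0[f]) ** 2 / (2.0 * a0[f])
        cA = cG + cL
        # dA_f/dx_a = 0.5 * nhat x (c - b), cyclic
        for (p, q, s) in ((a, b, c), (b, c, a), (c, a, b)):
            wx = verts[s, 0] - verts[q, 0]
            wy = verts[s, 1] - verts[q, 1]
            wz = verts[s, 2] - verts[q, 2]
            gx = 0.5 * (nhat[f, 1] * wz - nhat[f, 2] * wy)
            gy = 0.5 * (nhat[f, 2] * wx - nhat[f, 0] * wz)
            gz = 0.5 * (nhat[f, 0] * wy - nhat[f, 1] * wx)
            force[p, 0] -= cA * gx
            force[p, 1] -= cA * gy
            force[p, 2] -= cA * gz
            # dV/dx_p = (x_q x x_s) / 6
            hx = (verts[q, 1] * verts[s, 2] - verts[q, 2] * verts[s, 1]) / 6.0
            hy = (verts[q, 2] * verts[s, 0] - verts[q, 0] * verts[s, 2]) / 6.0
            hz = (verts[q, 0] * verts[s, 1] - verts[q, 1] * verts[s, 0]) / 6.0
            force[p, 0] -= cV * hx
            force[p, 1] -= cV * hy
            force[p, 2] -= cV * hz
    return force, energy


# ---------------------------------------------------------------------------
# Morse surface aggregation
# ---------------------------------------------------------------------------


@njit(cache=True)
def morse_element_forces(verts, faces, face_cell, cell_centroids, face_pairs,
                         E_I, r0, beta, cutoff, clamp_negative):
    """Morse interaction between facing surface elements of different cells.

    Energy per unordered element pair (f, g):
        phi(r_fg) (n_f . k_f)(n_g . k_g) (A_f + A_g) / 2
    with r_fg the centroid distance, n the outward unit normals and
    k_f the unit vector from cell(f)'s centroid to cell(g)'s centroid
    (k_g = -k_f).  The projection direction k is held fixed during
    differentiation (it varies on the cell scale, not the element scale);
    gradients through r, the areas and the normals are analytic.

    Returns (per-vertex forces, per-cell force totals, energy).
    """
    nv = verts.shape[0]
    nc = cell_centroids.shape[0]
    force = np.zeros((nv, 3))
    cell_force = np.zeros((nc, 3))
    energy = 0.0
    for pidx in range(face_pairs.shape[0]):
        f = face_pairs[pidx, 0]
        g = face_pairs[pidx, 1]
        ca = face_cell[f]
        cb = face_cell[g]
        if ca == cb:
            continue
        # element geometry
        fa = faces[f, 0]
        fb = faces[f, 1]
        fc = faces[f, 2]
        ga = faces[g, 0]
        gb = faces[g, 1]
        gc = faces[g, 2]
        # centroids
        cfx = (verts[fa, 0] + verts[fb, 0] + verts[fc, 0]) / 3.0
        cfy = (verts[fa, 1] + verts[fb, 1] + verts[fc, 1]) / 3.0
        cfz = (verts[fa, 2] + verts[fb, 2] + verts[fc, 2]) / 3.0
        cgx = (verts[ga, 0] + verts[gb, 0] + verts[gc, 0]) / 3.0
        cgy = (verts[ga, 1] + verts[gb, 1] + verts[gc, 1]) / 3.0
        cgz = (verts[ga, 2] + verts[gb, 2] + verts[gc, 2]) / 3.0
        rx = cfx - cgx
        ry = cfy - cgy
        rz = cfz - cgz
        r = math.sqrt(rx * rx + ry * ry + rz * rz)
        if r >= cutoff or r < 1e-12:
            continue
        # normals and areas
        u1x = verts[fb, 0] - verts[fa, 0]
        u1y = verts[fb, 1] - verts[fa, 1]
        u1z = verts[fb, 2] - verts[fa, 2]
        v1x = verts[fc, 0] - verts[fa, 0]
        v1y = verts[fc, 1] - verts[fa, 1]
        v1z = verts[fc, 2] - verts[fa, 2]
        N1x = u1y * v1z - u1z * v1y
        N1y = u1z * v1x - u1x * v1z
        N1z = u1x * v1y - u1y * v1x
        N1n = math.sqrt(N1x * N1x + N1y * N1y + N1z * N1z)
        u2x = verts[gb, 0] - verts[ga, 0]
        u2y = verts[gb, 1] - verts[ga, 1]
        u2z = verts[gb, 2] - verts[ga, 2]
        v2x = verts[gc, 0] - verts[ga, 0]
        v2y = verts[gc, 1] - verts[ga, 1]
        v2z = verts[gc, 2] - verts[ga, 2]
        N2x = u2y * v2z - u2z * v2y
        N2y = u2z * v2x - u2x * v2z
        N2z = u2x * v2y - u2y * v2x
        N2n = math.sqrt(N2x * N2x + N2y * N2y + N2z * N2z)
        if N1n < 1e-30 or N2n < 1e-30:
            continue
        A1 = 0.5 * N1n
        A2 = 0.5 * N2n
        n1x = N1x / N1n
        n1y = N1y / N1n
        n1z = N1z / N1n
        n2x = N2x / N2n
        n2y = N2y / N2n
        n2z = N2z / N2n
        # projection direction: cell(f) centroid -> cell(g) centroid
        kx = cell_centroids[cb, 0] - cell_centroids[ca, 0]
        ky = cell_centroids[cb, 1] - cell_centroids[ca, 1]
        kz = cell_centroids[cb, 2] - cell_centroids[ca, 2]
        kn = math.sqrt(kx * kx + ky * ky + kz * kz)
        if kn < 1e-12:
            continue
        kx /= kn
        ky /= kn
        kz /= kn
        w1 = n1x * kx + n1y * ky + n1z * kz
        w2 = -(n2x * kx + n2y * ky + n2z * kz)
        w = w1 * w2
        if clamp_negative and w < 0.0:
            continue
        # phi and phi'
        eb = math.exp(beta * (r0 - r))
        phi = E_I * (eb * eb - 2.0 * eb)
        dphi = E_I * (-2.0 * beta * eb * eb + 2.0 * beta * eb)
        Asum = 0.5 * (A1 + A2)
        energy += phi * w * Asum
        # --- gradient through r (centroid distance) ---
        cr = dphi * w * Asum / r / 3.0
        fxr = cr * rx
        fyr = cr * ry
        fzr = cr * rz
        for vv in (fa, fb, fc):
            force[vv, 0] -= fxr
            force[vv, 1] -= fyr
            force[vv, 2] -= fzr
        for vv in (ga, gb, gc):
            force[vv, 0] += fxr
            force[vv, 1] += fyr
            force[vv, 2] += fzr
        cell_force[ca, 0] -= 3.0 * fxr
        cell_force[ca, 1] -= 3.0 * fyr
        cell_force[ca, 2] -= 3.0 * fzr
        cell_force[cb, 0] += 3.0 * fxr
        cell_force[cb, 1] += 3.0 * fyr
        cell_force[cb, 2] += 3.0 * fzr
        # --- gradient through A1, n1 (vertices of f) ---
        # dU/dN1 = phi*w2*[w1 * n1/2 (area part, dA = n.dN/2)
        #          + Asum * (k - w1 n1)/N1n (normal part)]
        c_area = phi * w1 * w2 * 0.5 * 0.5  # d(Asum)/dA1 = 1/2, dA1 = n.dN/2
        c_norm = phi * w2 * Asum / N1n
        g1x = c_area * n1x + c_norm * (kx - w1 * n1x)
        g1y = c_area * n1y + c_norm * (ky - w1 * n1y)
        g1z = c_area * n1z + c_norm * (kz - w1 * n1z)
        # map dN gradient to vertices: dN = d(u x v);
        # grad_b = v x g, grad_c = g x u, grad_a = -(grad_b + grad_c)
        gbx = v1y * g1z - v1z * g1y
        gby = v1z * g1x - v1x * g1z
        gbz = v1x * g1y - v1y * g1x
        gcx = g1y * u1z - g1z * u1y
        gcy = g1z * u1x - g1x * u1z
        gcz = g1x * u1y - g1y * u1x
        force[fb, 0] -= gbx
        force[fb, 1] -= gby
        force[fb, 2] -= gbz
        force[fc, 0] -= gcx
        force[fc, 1] -= gcy
        force[fc, 2] -= gcz
        force[fa, 0] += gbx + gcx
        force[fa, 1] += gby + gcy
        force[fa, 2] += gbz + gcz
        # (these internal-shape gradients sum to zero over the cell's
        # vertices, so they do not contribute to cell_force)
        # --- gradient through A2, n2 (vertices of g) ---
        c_area2 = phi * w1 * w2 * 0.5 * 0.5
        c_norm2 = phi * w1 * Asum / N2n
        # w2 = -(n2 . k) => dw2/dn2 = -k
        g2x = c_area2 * n2x + c_norm2 * (-kx - w2 * n2x)
        g2y = c_area2 * n2y + c_norm2 * (-ky - w2 * n2y)
        g2z = c_area2 * n2z + c_norm2 * (-kz - w2 * n2z)
        gbx = v2y * g2z - v2z * g2y
        gby = v2z * g2x - v2x * g2z
        gbz = v2x * g2y - v2y * g2x
        gcx = g2y * u2z - g2z * u2y
        gcy = g2z * u2x - g2x * u2z
        gcz = g2x * u2y - g2y * u2x
        force[gb, 0] -= gbx
        force[gb, 1] -= gby
        force[gb, 2] -= gbz
        force[gc, 0] -= gcx
        force[gc, 1] -= gcy
        force[gc, 2] -= gcz
        force[ga, 0] += gbx + gcx
        force[ga, 1] += gby + gcy
        force[ga, 2] += gbz + gcz
    return force, cell_force, energy


@njit(cache=True)
def coupling_scan(mem, fluid, box_lo, box_hi, periodic, cutoff,
                  dims, start, order, barrier_strength, barrier_range):
    """One grid scan producing coupling pairs, kernel weights (normalized
    per membrane vertex) and the short-range fluid-membrane barrier forces.

    Returns (pairs, weights, totals, f_mem, f_fluid).
    """
    box = box_hi - box_lo
    nm = mem.shape[0]
    cap = max(nm * 40, 1024)
    out = np.empty((cap, 2), dtype=np.int64)
    w = np.empty(cap)
    m = 0
    totals = np.zeros(nm)
    f_mem = np.zeros((nm, 3))
    f_fluid = np.zeros((fluid.shape[0], 3))
    c2 = cutoff * cutoff
    dx = np.empty(3)
    for qi in range(nm):
        cx = min(max(int((mem[qi, 0] - box_lo[0]) / box[0] * dims[0]), 0),
                 dims[0] - 1)
        cy = min(max(int((mem[qi, 1] - box_lo[1]) / box[1] * dims[1]), 0),
                 dims[1] - 1)
        cz = min(max(int((mem[qi, 2] - box_lo[2]) / box[2] * dims[2]), 0),
                 dims[2] - 1)
        for ox in range(-1, 2):
            nx = cx + ox
            if periodic[0]:
                nx %= dims[0]
            elif nx < 0 or nx >= dims[0]:
                continue
            for oy in range(-1, 2):
                ny = cy + oy
                if periodic[1]:
                    ny %= dims[1]
                elif ny < 0 or ny >= dims[1]:
                    continue
                for oz in range(-1, 2):
                    nz = cz + oz
                    if periodic[2]:
                        nz %= dims[2]
                    elif nz < 0 or nz >= dims[2]:
                        continue
                    nc = (nx * dims[1] + ny) * dims[2] + nz
                    for jj in range(start[nc], start[nc + 1]):
                        j = order[jj]
                        for d in range(3):
                            dx[d] = mem[qi, d] - fluid[j, d]
                        _min_image(dx, box, periodic)
                        r2 = dx[0] ** 2 + dx[1] ** 2 + dx[2] ** 2
                        if r2 >= c2:
                            continue
                        r = math.sqrt(r2)
                        if m >= cap:
                            cap *= 2
                            new = np.empty((cap, 2), dtype=np.int64)
                            new[:m] = out[:m]
                            out = new
                            nw = np.empty(cap)
                            nw[:m] = w[:m]
                            w = nw
                        out[m, 0] = qi
                        out[m, 1] = j
                        wk = lucy_w(r, cutoff)
                        w[m] = wk
                        totals[qi] += wk
                        m += 1
                        if barrier_strength > 0.0 and r < barrier_range \
                                and r > 1e-12:
                            mag = barrier_strength * (
                                1.0 - r / barrier_range
                            ) ** 2 / r
                            for d in range(3):
                                f_mem[qi, d] += mag * dx[d]
                                f_fluid[j, d] -= mag * dx[d]
    for p in range(m):
        t = totals[out[p, 0]]
        if t > 0.0:
            w[p] /= t
    return out[:m], w[:m], totals, f_mem, f_fluid


@njit(cache=True)
def pair_kernel_weights(pairs, query, pos, box_lo, box_hi, periodic,
                        cutoff, n_query):
    """Lucy kernel weights for cross pairs, normalized per query point."""
    box = box_hi - box_lo
    m = pairs.shape[0]
    w = np.empty(m)
    totals = np.zeros(n_query)
    dx = np.empty(3)
    for p in range(m):
        qi = pairs[p, 0]
        j = pairs[p, 1]
        for d in range(3):
            dx[d] = query[qi, d] - pos[j, d]
        _min_image(dx, box, periodic)
        r = math.sqrt(dx[0] ** 2 + dx[1] ** 2 + dx[2] ** 2)
        w[p] = lucy_w(r, cutoff)
        totals[qi] += w[p]
    for p in range(m):
        t = totals[pairs[p, 0]]
        if t > 0.0:
            w[p] /= t
    return w, totals


@njit(cache=True)
def soft_repulsion_cross(pairs, pos_a, pos_b, box_lo, box_hi, periodic,
                         strength, rng_range):
    """Quadratic soft repulsion F = A (1 - r/rc)^2 along the pair axis.

    Returns (force on A points, force on B points); antisymmetric.
    """
    box = box_hi - box_lo
    fa = np.zeros_like(pos_a)
    fb = np.zeros_like(pos_b)
    dx = np.empty(3)
    for p in range(pairs.shape[0]):
        i = pairs[p, 0]
        j = pairs[p, 1]
        for d in range(3):
            dx[d] = pos_a[i, d] - pos_b[j, d]
        _min_image(dx, box, periodic)
        r = math.sqrt(dx[0] ** 2 + dx[1] ** 2 + dx[2] ** 2)
        if r >= rng_range or r < 1e-12:
            continue
        mag = strength * (1.0 - r / rng_range) ** 2 / r
        for d in range(3):
            fa[i, d] += mag * dx[d]
            fb[j, d] -= mag * dx[d]
    return fa, fb


@njit(cache=True)
def soft_repulsion_pairs(pairs, pos, owner, box_lo, box_hi, periodic,
                         strength, rng_range):
    """Soft repulsion between points of *different* owners (self pairs)."""
    box = box_hi - box_lo
    f = np.zeros_like(pos)
    dx = np.empty(3)
    for p in range(pairs.shape[0]):
        i = pairs[p, 0]
        j = pairs[p, 1]
        if owner[i] == owner[j]:
            continue
        for d in range(3):
            dx[d] = pos[i, d] - pos[j, d]
        _min_image(dx, box, periodic)
        r = math.sqrt(dx[0] ** 2 + dx[1] ** 2 + dx[2] ** 2)
        if r >= rng_range or r < 1e-12:
            continue
        mag = strength * (1.0 - r / rng_range) ** 2 / r
        for d in range(3):
            f[i, d] += mag * dx[d]
            f[j, d] -= mag * dx[d]
    return f


@njit(cache=True)
def spread_and_interp(weights_pairs, weights, mem_force, fluid_vel,
                      n_fluid, n_mem):
    """Spread membrane forces to fluid and interpolate fluid velocities.

    weights_pairs[(p, 0)] = membrane vertex k, [(p, 1)] = fluid particle i;
    weights are normalized per vertex (sum_i beta_ik = 1).
    """
    fluid_force = np.zeros((n_fluid, 3))
    mem_vel = np.zeros((n_mem, 3))
    for p in range(weights_pairs.shape[0]):
        k = weights_pairs[p, 0]
        i = weights_pairs[p, 1]
        b = weights[p]
        for d in range(3):
            fluid_force[i, d] += b * mem_force[k, d]
            mem_vel[k, d] += b * fluid_vel[i, d]
    return fluid_force, mem_vel
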