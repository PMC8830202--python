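"""Numba kernels: cell-list neighbor search, force evaluation, Langevin steps.

The integrator is velocity Verlet with a per-monomer Langevin term in the
LAMMPS convention: at every force evaluation the total force is
F_cons(x) - m * gamma * v + xi, where xi is pre-scaled Gaussian noise with
per-component variance 2 m gamma k_B T_i / dt at the monomer's own bath
temperature.  Status codes returned by :func:`run_chunk`:

0 ok | 1 bond broke (r >= r_max) | 2 monomer escaped the sphere
3 neighbor-list capacity overflow (caller enlarges and retries)
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

WCA_CUTOFF = 2.0 ** (1.0 / 6.0)

STATUS_OK = 0
STATUS_BOND_BROKEN = 1
STATUS_ESCAPED = 2
STATUS_NLIST_OVERFLOW = 3

PAIR_WCA = 0
PAIR_SOFT = 1
PAIR_SOFT_INTRA = 2  # soft within a ring, full WCA between rings

BOND_FENE = 0
BOND_HARMONIC = 1  # unbreakable spring for the push-off stages
HARMONIC_K = 300.0
HARMONIC_R0 = 0.9


@njit(cache=True)
def build_neighbor_list(pos, cutoff, R, pair_i, pair_j):
    """Half neighbor list (i < j) within ``cutoff`` via a linked-cell grid.

    Returns the number of pairs, or -1 if the capacity of pair_i/pair_j is
    exceeded.
    """
    n = pos.shape[0]
    L = R + 1.0
    ncell = int(2.0 * L / cutoff)
    if ncell < 1:
        ncell = 1
    if ncell > 64:
        ncell = 64
    cellsize = 2.0 * L / ncell
    head = -np.ones(ncell * ncell * ncell, dtype=np.int64)
    nxt = -np.ones(n, dtype=np.int64)
    cx = np.empty(n, dtype=np.int64)
    cy = np.empty(n, dtype=np.int64)
    cz = np.empty(n, dtype=np.int64)
    for i in range(n):
        a = int((pos[i, 0] + L) / cellsize)
        b = int((pos[i, 1] + L) / cellsize)
        c = int((pos[i, 2] + L) / cellsize)
        if a < 0:
            a = 0
        if a >= ncell:
            a = ncell - 1
        if b < 0:
            b = 0
        if b >= ncell:
            b = ncell - 1
        if c < 0:
            c = 0
        if c >= ncell:
            c = ncell - 1
        cx[i], cy[i], cz[i] = a, b, c
        idx = (a * ncell + b) * ncell + c
        nxt[i] = head[idx]
        head[idx] = i
    cap = pair_i.shape[0]
    cut2 = cutoff * cutoff
    cnt = 0
    for i in range(n):
        for da in range(-1, 2):
            a = cx[i] + da
            if a < 0 or a >= ncell:
                continue
            for db in range(-1, 2):
                b = cy[i] + db
                if b < 0 or b >= ncell:
                    continue
                for dc in range(-1, 2):
                    c = cz[i] + dc
                    if c < 0 or c >= ncell:
                        continue
                    j = head[(a * ncell + b) * ncell + c]
                    while j != -1:
                        if j > i:
                            dx = pos[i, 0] - pos[j, 0]
                            dy = pos[i, 1] - pos[j, 1]
                            dz = pos[i, 2] - pos[j, 2]
                            if dx * dx + dy * dy + dz * dz < cut2:
                                if cnt >= cap:
                                    return -1
                                pair_i[cnt] = i
                                pair_j[cnt] = j
                                cnt += 1
                        j = nxt[j]
    return cnt


@njit(cache=True, fastmath=True)
def compute_forces(pos, f, pair_i, pair_j, npairs, bonds, angles, ring_of,
                   R, eps, sig, K_fene, r_max, k_theta,
                   use_pair, use_bond, use_angle, use_wall,
                   pair_style, soft_A, f_cap, bond_style):
    """Conservative forces into ``f``; returns (status, potential_energy)."""
    n = pos.shape[0]
    for i in range(n):
        f[i, 0] = 0.0
        f[i, 1] = 0.0
        f[i, 2] = 0.0
    pe = 0.0
    rc = WCA_CUTOFF * sig
    rc2 = rc * rc
    if use_pair:
        for k in range(npairs):
            i = pair_i[k]
            j = pair_j[k]
            dx = pos[i, 0] - pos[j, 0]
            dy = pos[i, 1] - pos[j, 1]
            dz = pos[i, 2] - pos[j, 2]
            r2 = dx * dx + dy * dy + dz * dz
            if r2 >= rc2 or r2 <= 0.0:
                continue
            style = pair_style
            if style == PAIR_SOFT_INTRA:
                style = PAIR_SOFT if ring_of[i] == ring_of[j] else PAIR_WCA
            if style == PAIR_WCA:
                sr2 = sig * sig / r2
                sr6 = sr2 * sr2 * sr2
                sr12 = sr6 * sr6
                pe += 4.0 * eps * (sr12 - sr6) + eps
                fpr = 24.0 * eps * (2.0 * sr12 - sr6) / r2  # (F/r)
            else:
                r = math.sqrt(r2)
                pe += soft_A * (1.0 + math.cos(math.pi * r / rc))
                fpr = soft_A * math.pi / rc * math.sin(math.pi * r / rc) / r
            f[i, 0] += fpr * dx
            f[i, 1] += fpr * dy
            f[i, 2] += fpr * dz
            f[j, 0] -= fpr * dx
            f[j, 1] -= fpr * dy
            f[j, 2] -= fpr * dz
        if f_cap > 0.0:
            # cap the net pair force per bead (push-off stability); bonded
            # and wall restoring forces stay uncapped
            for i in range(n):
                fn = math.sqrt(f[i, 0] ** 2 + f[i, 1] ** 2 + f[i, 2] ** 2)
                if fn > f_cap:
                    sc = f_cap / fn
                    f[i, 0] *= sc
                    f[i, 1] *= sc
                    f[i, 2] *= sc
    if use_bond:
        rmax2 = r_max * r_max
        for k in range(bonds.shape[0]):
            i = bonds[k, 0]
            j = bonds[k, 1]
            dx = pos[i, 0] - pos[j, 0]
            dy = pos[i, 1] - pos[j, 1]
            dz = pos[i, 2] - pos[j, 2]
            r2 = dx * dx + dy * dy + dz * dz
            if bond_style == BOND_HARMONIC:
                r = math.sqrt(r2)
                dr = r - HARMONIC_R0
                pe += 0.5 * HARMONIC_K * dr * dr
                m = -HARMONIC_K * dr / r if r > 0.0 else 0.0
            else:
                if r2 >= rmax2:
                    return STATUS_BOND_BROKEN, pe
                x = 1.0 - r2 / rmax2
                pe += -0.5 * K_fene * rmax2 * math.log(x)
                m = -K_fene / x  # attractive toward the partner
            f[i, 0] += m * dx
            f[i, 1] += m * dy
            f[i, 2] += m * dz
            f[j, 0] -= m * dx
            f[j, 1] -= m * dy
            f[j, 2] -= m * dz
    if use_angle:
        for k in range(angles.shape[0]):
            ia = angles[k, 0]
            ib = angles[k, 1]
            ic = angles[k, 2]
            ux = pos[ia, 0] - pos[ib, 0]
            uy = pos[ia, 1] - pos[ib, 1]
            uz = pos[ia, 2] - pos[ib, 2]
            vx = pos[ic, 0] - pos[ib, 0]
            vy = pos[ic, 1] - pos[ib, 1]
            vz = pos[ic, 2] - pos[ib, 2]
            lu = math.sqrt(ux * ux + uy * uy + uz * uz)
            lv = math.sqrt(vx * vx + vy * vy + vz * vz)
            if lu <= 0.0 or lv <= 0.0:
                continue
            cth = (ux * vx + uy * vy + uz * vz) / (lu * lv)
            if cth > 1.0:
                cth = 1.0
            elif cth < -1.0:
                cth = -1.0
            pe += k_theta * (1.0 + cth)
            # F_a = -k dcos/da, dcos/da = (v/lv - cth*u/lu)/lu
            gax = (vx / lv - cth * ux / lu) / lu
            gay = (vy / lv - cth * uy / lu) / lu
            gaz = (vz / lv - cth * uz / lu) / lu
            gcx = (ux / lu - cth * vx / lv) / lv
            gcy = (uy / lu - cth * vy / lv) / lv
            gcz = (uz / lu - cth * vz / lv) / lv
            f[ia, 0] -= k_theta * gax
            f[ia, 1] -= k_theta * gay
            f[ia, 2] -= k_theta * gaz
            f[ic, 0] -= k_theta * gcx
            f[ic, 1] -= k_theta * gcy
            f[ic, 2] -= k_theta * gcz
            f[ib, 0] += k_theta * (gax + gcx)
            f[ib, 1] += k_theta * (gay + gcy)
            f[ib, 2] += k_theta * (gaz + gcz)
    if use_wall:
        for i in range(n):
            rn2 = pos[i, 0] ** 2 + pos[i, 1] ** 2 + pos[i, 2] ** 2
            rn = math.sqrt(rn2)
            if rn >= R:
                return STATUS_ESCAPED, pe
            d = R - rn
            if d < rc and rn > 0.0:
                sr2 = sig * sig / (d * d)
                sr6 = sr2 * sr2 * sr2
                sr12 = sr6 * sr6
                pe += 4.0 * eps * (sr12 - sr6) + eps
                fmag = 24.0 * eps * (2.0 * sr12 - sr6) / d
                f[i, 0] -= fmag * pos[i, 0] / rn
                f[i, 1] -= fmag * pos[i, 1] / rn
                f[i, 2] -= fmag * pos[i, 2] / rn
    return STATUS_OK, pe


@njit(cache=True, fastmath=True)
def run_chunk(pos, vel, f, nsteps, dt, mass, gamma, noise,
              bonds, angles, ring_of, pair_i, pair_j, ref_pos,
              R, eps, sig, K_fene, r_max, k_theta,
              use_pair, use_bond, use_angle, use_wall,
              pair_style, soft_A0, soft_A1, skin, f_cap, bond_style):
    """Integrate ``nsteps`` velocity-Verlet Langevin steps in place.

    ``noise`` is (nsteps, n, 3) pre-scaled random force; ``soft_A`` ramps
    linearly from soft_A0 to soft_A1 across the chunk (soft pair style only).
    Returns (status, steps_completed).
    """
    n = pos.shape[0]
    cutoff = WCA_CUTOFF * sig + skin
    half_skin2 = 0.25 * skin * skin
    npairs = 0
    if use_pair:
        npairs = build_neighbor_list(pos, cutoff, R, pair_i, pair_j)
        if npairs < 0:
            return STATUS_NLIST_OVERFLOW, 0
        for i in range(n):
            ref_pos[i, 0] = pos[i, 0]
            ref_pos[i, 1] = pos[i, 1]
            ref_pos[i, 2] = pos[i, 2]
    status, pe = compute_forces(pos, f, pair_i, pair_j, npairs, bonds, angles,
                                ring_of, R, eps, sig, K_fene, r_max, k_theta,
                                use_pair, use_bond, use_angle, use_wall,
                                pair_style, soft_A0, f_cap, bond_style)
    if status != STATUS_OK:
        return status, 0
    # entry total force: conservative + friction (no fresh noise before step 0)
    for i in range(n):
        f[i, 0] -= mass * gamma * vel[i, 0]
        f[i, 1] -= mass * gamma * vel[i, 1]
        f[i, 2] -= mass * gamma * vel[i, 2]
    half = 0.5 * dt / mass
    for step in range(nsteps):
        for i in range(n):
            vel[i, 0] += half * f[i, 0]
            vel[i, 1] += half * f[i, 1]
            vel[i, 2] += half * f[i, 2]
            pos[i, 0] += dt * vel[i, 0]
            pos[i, 1] += dt * vel[i, 1]
            pos[i, 2] += dt * vel[i, 2]
        if use_pair:
            maxd2 = 0.0
            for i in range(n):
                ddx = pos[i, 0] - ref_pos[i, 0]
                ddy = pos[i, 1] - ref_pos[i, 1]
                ddz = pos[i, 2] - ref_pos[i, 2]
                d2 = ddx * ddx + ddy * ddy + ddz * ddz
                if d2 > maxd2:
                    maxd2 = d2
            if maxd2 > half_skin2:
                npairs = build_neighbor_list(pos, cutoff, R, pair_i, pair_j)
                if npairs < 0:
                    return STATUS_NLIST_OVERFLOW, step
                for i in range(n):
                    ref_pos[i, 0] = pos[i, 0]
                    ref_pos[i, 1] = pos[i, 1]
                    ref_pos[i, 2] = pos[i, 2]
        if nsteps > 1:
            soft_A = soft_A0 + (soft_A1 - soft_A0) * step / (nsteps - 1.0)
        else:
            soft_A = soft_A1
        status, pe = compute_forces(pos, f, pair_i, pair_j, npairs, bonds, angles,
                                    ring_of, R, eps, sig, K_fene, r_max, k_theta,
                                    use_pair, use_bond, use_angle, use_wall,
                                    pair_style, soft_A, f_cap, bond_style)
        if status != STATUS_OK:
            return status, step
        if gamma > 0.0:
            for i in range(n):
                f[i, 0] += -mass * gamma * vel[i, 0] + noise[step, i, 0]
                f[i, 1] += -mass * gamma * vel[i, 1] + noise[step, i, 1]
                f[i, 2] += -mass * gamma * vel[i, 2] + noise[step, i, 2]
        for i in range(n):
            vel[i, 0] += half * f[i, 0]
            vel[i, 1] += half * f[i, 1]
            vel[i, 2] += half * f[i, 2]
    return STATUS_OK, nsteps


@njit(cache=True, fastmath=True)
def linking_number_sum(a, b):
    """Discrete Gauss linking integral of two closed polygonal curves.

    Sums the signed solid angles of all segment pairs (Klenin & Langowski
    convention); divide by 4*pi for the linking number.
    """
    na = a.shape[0]
    nb = b.shape[0]
    total = 0.0
    for i in range(na):
        i2 = (i + 1) % na
        p1x, p1y, p1z = a[i, 0], a[i, 1], a[i, 2]
        p2x, p2y, p2z = a[i2, 0], a[i2, 1], a[i2, 2]
        for j in range(nb):
            j2 = (j + 1) % nb
            q1x, q1y, q1z = b[j, 0], b[j, 1], b[j, 2]
            q2x, q2y, q2z = b[j2, 0], b[j2, 1], b[j2, 2]
            r13x, r13y, r13z = q1x - p1x, q1y - p1y, q1z - p1z
            r14x, r14y, r14z = q2x - p1x, q2y - p1y, q2z - p1z
            r23x, r23y, r23z = q1x - p2x, q1y - p2y, q1z - p2z
            r24x, r24y, r24z = q2x - p2x, q2y - p2y, q2z - p2z
            # normals of the spherical quadrilateral faces
            n1x = r13y * r14z - r13z * r14y
            n1y = r13z * r14x - r13x * r14z
            n1z = r13x * r14y - r13y * r14x
            n2x = r14y * r24z - r14z * r24y
            n2y = r14z * r24x - r14x * r24z
            n2z = r14x * r24y - r14y * r24x
            n3x = r24y * r23z - r24z * r23y
            n3y = r24z * r23x - r24x * r23z
            n3z = r24x * r23y - r24y * r23x
            n4x = r23y * r13z - r23z * r13y
            n4y = r23z * r13x - r23x * r13z
            n4z = r23x * r13y - r23y * r13x
            l1 = math.sqrt(n1x * n1x + n1y * n1y + n1z * n1z)
            l2 = math.sqrt(n2x * n2x + n2y * n2y + n2z * n2z)
            l3 = math.sqrt(n3x * n3x + n3y * n3y + n3z * n3z)
            l4 = math.sqrt(n4x * n4x + n4y * n4y + n4z * n4z)
            if l1 == 0.0 or l2 == 0.0 or l3 == 0.0 or l4 == 0.0:
                continue
            d12 = (n1x * n2x + n1y * n2y + n1z * n2z) / (l1 * l2)
            d23 = (n2x * n3x + n2y * n3y + n2z * n3z) / (l2 * l3)
            d34 = (n3x * n4x + n3y * n4y + n3z * n4z) / (l3 * l4)
            d41 = (n4x * n1x + n4y * n1y + n4z * n1z) / (l4 * l1)
            if d12 > 1.0:
                d12 = 1.0
            elif d12 < -1.0:
                d12 = -1.0
            if d23 > 1.0:
                d23 = 1.0
            elif d23 < -1.0:
                d23 = -1.0
            if d34 > 1.0:
                d34 = 1.0
            elif d34 < -1.0:
                d34 = -1.0
            if d41 > 1.0:
                d41 = 1.0
            elif d41 < -1.0:
                d41 = -1.0
            s = math.asin(d12) + math.asin(d23) + math.asin(d34) + math.asin(d41)
            # sign from (q2-q1) x (p2-p1) . r13
            ax = q2x - q1x
            ay = q2y - q1y
            az = q2z - q1z
            bx = p2x - p1x
            by = p2y - p1y
            bz = p2z - p1z
            cxx = ay * bz - az * by
            cyy = az * bx - ax * bz
            czz = ax * by - ay * bx
            sign = cxx * r13x + cyy * r13y + czz * r13z
            if sign > 0.0:
                total += s
            elif sign < 0.0:
                total -= s
    return total


@njit(cache=True, fastmath=True)
def count_segment_triangle_crossings(verts, tris, seg_a, seg_b, eps_par):
    """Count transversal segment-triangle intersections (Moeller-Trumbore).

    Returns (count, degenerate_flag); degenerate_flag is 1 when any candidate
    intersection fell within eps_par of a boundary of the valid parameter
    domain, signalling the caller to jitter and retry.
    """
    ntri = tris.shape[0]
    nseg = seg_a.shape[0]
    count = 0
    degen = 0
    for s in range(nseg):
        ox, oy, oz = seg_a[s, 0], seg_a[s, 1], seg_a[s, 2]
        dx = seg_b[s, 0] - ox
        dy = seg_b[s, 1] - oy
        dz = seg_b[s, 2] - oz
        for t in range(ntri):
            i0, i1, i2 = tris[t, 0], tris[t, 1], tris[t, 2]
            e1x = verts[i1, 0] - verts[i0, 0]
            e1y = verts[i1, 1] - verts[i0, 1]
            e1z = verts[i1, 2] - verts[i0, 2]
            e2x = verts[i2, 0] - verts[i0, 0]
            e2y = verts[i2, 1] - verts[i0, 1]
            e2z = verts[i2, 2] - verts[i0, 2]
            px = dy * e2z - dz * e2y
            py = dz * e2x - dx * e2z
            pz = dx * e2y - dy * e2x
            det = e1x * px + e1y * py + e1z * pz
            if -1e-14 < det < 1e-14:
                continue
            inv = 1.0 / det
            tx = ox - verts[i0, 0]
            ty = oy - verts[i0, 1]
            tz = oz - verts[i0, 2]
            u = (tx * px + ty * py + tz * pz) * inv
            if u < -eps_par or u > 1.0 + eps_par:
                continue
            qx = ty * e1z - tz * e1y
            qy = tz * e1x - tx * e1z
            qz = tx * e1y - ty * e1x
            v = (dx * qx + dy * qy + dz * qz) * inv
            if v < -eps_par or u + v > 1.0 + eps_par:
                continue
            lam = (e2x * qx + e2y * qy + e2z * qz) * inv
            if lam < -eps_par or lam > 1.0 + eps_par:
                continue
            near = (abs(u) < eps_par or abs(v) < eps_par or
                    abs(1.0 - u - v) < eps_par or
                    abs(lam) < eps_par or abs(1.0 - lam) < eps_par)
            if near:
                degen = 1
                continue
            if 0.0 < lam < 1.0 and u > 0.0 and v > 0.0 and u + v < 1.0:
                count += 1
    return count, degen
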