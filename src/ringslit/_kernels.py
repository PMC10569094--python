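"""Numba kernels for the kinetic Monte Carlo engine.

Geometry is exact integer arithmetic throughout.  A structural fact of
the fcc checkerboard representation shapes the move set: the surface
swept by a nearest-neighbor monomer displacement consists of minimal
triangles whose plane normals are of (+-1,+-1,+-1) type.  Every
lattice site sits on an even level of such a plane, while one
nearest-neighbor bond changes the level by at most 2 -- so no bond can
ever pierce the swept surface transversally.  Ordinary local moves
between valid states therefore conserve topology *exactly*, with no
crossing test needed; excluded volume alone enforces the constraint.

Strand crossings are instead realized by an explicit topology-changing
move: a position swap of two monomers on nearest-neighbor sites (each
singly occupied), which passes one filament through the other.  The
proposal is symmetric (monomer + direction drawn uniformly), so
Metropolis acceptance on the bending-energy change preserves detailed
balance; the swap is attempted with probability ``crossing_rate`` per
elementary step.
"""

import numpy as np
from numba import njit

FCC = np.array(
    [
        (1, 1, 0), (1, -1, 0), (-1, 1, 0), (-1, -1, 0),
        (1, 0, 1), (1, 0, -1), (-1, 0, 1), (-1, 0, -1),
        (0, 1, 1), (0, 1, -1), (0, -1, 1), (0, -1, -1),
    ],
    dtype=np.int64,
)

# counter indices
C_ROUSE_ATT = 0
C_ROUSE_ACC = 1
C_REP_ATT = 2
C_REP_ACC = 3
C_SWAP_ATT = 4
C_SWAP_ACC = 5
C_NULL = 6
C_METRO_REJ = 7
N_COUNTERS = 8


@njit(cache=True)
def seed_rng(seed):
    np.random.seed(seed)


@njit(cache=True)
def _window_energy(pos, r, i, N, cand, kappa, transmit):
    """Bending energy of the 6-bond window around monomer i with the
    monomer placed at ``cand``.  With ``transmit`` the angle is taken
    between consecutive *nonzero* bonds (a zero bond transmits the
    angle across itself); otherwise angles involving a zero bond are
    dropped.  Zero bonds are never adjacent (three monomers on one
    site are forbidden), so all angle pairs whose energy can change
    are fully contained in the window.
    """
    e = 0.0
    lx = 0.0
    ly = 0.0
    lz = 0.0
    have_last = False
    px = 0.0
    py = 0.0
    pz = 0.0
    pzero = True
    first = True
    for k in range(-3, 3):
        ja = (i + k) % N
        jb = (i + k + 1) % N
        if ja == i:
            bx = pos[r, jb, 0] - cand[0]
            by = pos[r, jb, 1] - cand[1]
            bz = pos[r, jb, 2] - cand[2]
        elif jb == i:
            bx = cand[0] - pos[r, ja, 0]
            by = cand[1] - pos[r, ja, 1]
            bz = cand[2] - pos[r, ja, 2]
        else:
            bx = pos[r, jb, 0] - pos[r, ja, 0]
            by = pos[r, jb, 1] - pos[r, ja, 1]
            bz = pos[r, jb, 2] - pos[r, ja, 2]
        zero = bx == 0 and by == 0 and bz == 0
        if transmit:
            if zero:
                continue
            if have_last:
                e += kappa * (1.0 - (lx * bx + ly * by + lz * bz) / 2.0)
            lx = float(bx)
            ly = float(by)
            lz = float(bz)
            have_last = True
        else:
            if not first and not zero and not pzero:
                e += kappa * (1.0 - (px * bx + py * by + pz * bz) / 2.0)
            px = float(bx)
            py = float(by)
            pz = float(bz)
            pzero = zero
            first = False
    return e


@njit(cache=True)
def ring_energy(pos, r, N, kappa, transmit):
    """Full cyclic bending energy of ring r (kT units)."""
    e = 0.0
    # first bond
    lx = 0.0
    ly = 0.0
    lz = 0.0
    have_last = False
    fx = 0.0
    fy = 0.0
    fz = 0.0
    have_first = False
    px = 0.0
    py = 0.0
    pz = 0.0
    pzero = True
    first_zero = True
    for k in range(N):
        jb = k + 1 if k + 1 < N else 0
        bx = pos[r, jb, 0] - pos[r, k, 0]
        by = pos[r, jb, 1] - pos[r, k, 1]
        bz = pos[r, jb, 2] - pos[r, k, 2]
        zero = bx == 0 and by == 0 and bz == 0
        if transmit:
            if zero:
                continue
            if have_last:
                e += kappa * (1.0 - (lx * bx + ly * by + lz * bz) / 2.0)
            else:
                fx = float(bx)
                fy = float(by)
                fz = float(bz)
                have_first = True
            lx = float(bx)
            ly = float(by)
            lz = float(bz)
            have_last = True
        else:
            if k > 0 and not zero and not pzero:
                e += kappa * (1.0 - (px * bx + py * by + pz * bz) / 2.0)
            if k == 0:
                fx = float(bx)
                fy = float(by)
                fz = float(bz)
                first_zero = zero
            px = float(bx)
            py = float(by)
            pz = float(bz)
            pzero = zero
    # closing angle (cyclic)
    if transmit:
        if have_first and have_last:
            e += kappa * (1.0 - (lx * fx + ly * fy + lz * fz) / 2.0)
    else:
        if not pzero and not first_zero:
            e += kappa * (1.0 - (px * fx + py * fy + pz * fz) / 2.0)
    return e


@njit(cache=True)
def _occ_remove(occ_n, occ_r, occ_m, xi, yi, zi, r, i):
    n = occ_n[xi, yi, zi]
    for s in range(n):
        if occ_r[xi, yi, zi, s] == r and occ_m[xi, yi, zi, s] == i:
            if s == 0 and n == 2:
                occ_r[xi, yi, zi, 0] = occ_r[xi, yi, zi, 1]
                occ_m[xi, yi, zi, 0] = occ_m[xi, yi, zi, 1]
            occ_n[xi, yi, zi] = n - 1
            return


@njit(cache=True, inline="always")
def _occ_add(occ_n, occ_r, occ_m, xi, yi, zi, r, i):
    n = occ_n[xi, yi, zi]
    occ_r[xi, yi, zi, n] = r
    occ_m[xi, yi, zi, n] = i
    occ_n[xi, yi, zi] = n + 1


@njit(cache=True)
def run_chunk(pos, occ_n, occ_r, occ_m, Lx, Ly, Lzl, slab,
              kappa, p_cross, rep_frac, transmit, n_steps, counters):
    """Run n_steps elementary kMC steps (attempted monomer moves),
    mutating pos and the occupancy index in place."""
    M, N = pos.shape[0], pos.shape[1]
    m0 = np.empty(3, np.int64)
    m1 = np.empty(3, np.int64)
    jt = np.empty(3, np.int64)
    for _step in range(n_steps):
        r = np.random.randint(0, M)
        i = np.random.randint(0, N)
        for c in range(3):
            m0[c] = pos[r, i, c]
        x0 = m0[0] % Lx
        y0 = m0[1] % Ly
        z0 = m0[2] if slab else m0[2] % Lzl

        if np.random.random() < p_cross:
            # --- strand crossing: exchange the full contents of two
            # adjacent sites.  All occupants of one site share one
            # unwrapped position (double occupancy is only for
            # consecutive monomers, joined by a zero bond), so the X
            # side moves rigidly by +v and the Y side by -v.  The swap
            # is proposed with probability (occ(X)+occ(Y))/(12*M*N),
            # symmetric under the exchange: detailed balance holds. ---
            counters[C_SWAP_ATT] += 1
            kv = np.random.randint(0, 12)
            for c in range(3):
                m1[c] = m0[c] + FCC[kv, c]
            if slab and (m1[2] < 0 or m1[2] >= Lzl):
                counters[C_NULL] += 1
                continue
            x1 = m1[0] % Lx
            y1 = m1[1] % Ly
            z1 = m1[2] if slab else m1[2] % Lzl
            nX = occ_n[x0, y0, z0]
            nY = occ_n[x1, y1, z1]
            if nY == 0:
                counters[C_NULL] += 1   # nothing to pass through
                continue
            # gather movers: (ring, idx, +1) from X and (ring, idx, -1) from Y
            mv_r = np.empty(4, np.int64)
            mv_m = np.empty(4, np.int64)
            mv_s = np.empty(4, np.int64)
            nmv = 0
            for s in range(nX):
                mv_r[nmv] = occ_r[x0, y0, z0, s]
                mv_m[nmv] = occ_m[x0, y0, z0, s]
                mv_s[nmv] = 1
                nmv += 1
            for s in range(nY):
                mv_r[nmv] = occ_r[x1, y1, z1, s]
                mv_m[nmv] = occ_m[x1, y1, z1, s]
                mv_s[nmv] = -1
                nmv += 1
            # bond validity for every mover against (possibly moved) neighbors
            ok = True
            for t in range(nmv):
                ra = mv_r[t]
                ma = mv_m[t]
                for side in range(2):
                    nb = ma + 1 if side == 0 else ma - 1
                    if nb >= N:
                        nb = 0
                    if nb < 0:
                        nb = N - 1
                    shift = 0
                    for u in range(nmv):
                        if mv_r[u] == ra and mv_m[u] == nb:
                            shift = mv_s[u]
                            break
                    nsq = 0
                    for c in range(3):
                        dd = (pos[ra, nb, c] + shift * FCC[kv, c]
                              - (pos[ra, ma, c] + mv_s[t] * FCC[kv, c]))
                        nsq += dd * dd
                    if nsq != 0 and nsq != 2:
                        ok = False
                        break
                if not ok:
                    break
            if not ok:
                counters[C_NULL] += 1
                continue
            ring_a = mv_r[0]
            ring_b = mv_r[nX]  # first Y-side mover
            if ring_a == ring_b:
                e_before = ring_energy(pos, ring_a, N, kappa, transmit)
            else:
                e_before = (ring_energy(pos, ring_a, N, kappa, transmit)
                            + ring_energy(pos, ring_b, N, kappa, transmit))
            for t in range(nmv):
                for c in range(3):
                    pos[mv_r[t], mv_m[t], c] += mv_s[t] * FCC[kv, c]
            if ring_a == ring_b:
                e_after = ring_energy(pos, ring_a, N, kappa, transmit)
            else:
                e_after = (ring_energy(pos, ring_a, N, kappa, transmit)
                           + ring_energy(pos, ring_b, N, kappa, transmit))
            dE = e_after - e_before
            if dE > 0.0 and np.random.random() >= np.exp(-dE):
                for t in range(nmv):
                    for c in range(3):
                        pos[mv_r[t], mv_m[t], c] -= mv_s[t] * FCC[kv, c]
                counters[C_METRO_REJ] += 1
                continue
            # occupancy: exchange the site contents
            for s in range(nY):
                occ_r[x0, y0, z0, s] = mv_r[nX + s]
                occ_m[x0, y0, z0, s] = mv_m[nX + s]
            occ_n[x0, y0, z0] = nY
            for s in range(nX):
                occ_r[x1, y1, z1, s] = mv_r[s]
                occ_m[x1, y1, z1, s] = mv_m[s]
            occ_n[x1, y1, z1] = nX
            counters[C_SWAP_ACC] += 1
            continue

        if np.random.random() < rep_frac:
            # --- reptation-like: slide a stored-length defect ---
            counters[C_REP_ATT] += 1
            d = 1 if np.random.random() < 0.5 else -1
            j = (i + d) % N
            if (pos[r, j, 0] != m0[0] or pos[r, j, 1] != m0[1]
                    or pos[r, j, 2] != m0[2]):
                counters[C_NULL] += 1
                continue  # no defect on that side
            k = (i - d) % N
            for c in range(3):
                m1[c] = pos[r, k, c]
            x1 = m1[0] % Lx
            y1 = m1[1] % Ly
            z1 = m1[2] if slab else m1[2] % Lzl
            if occ_n[x1, y1, z1] >= 2:
                counters[C_NULL] += 1
                continue
            dE = (_window_energy(pos, r, i, N, m1, kappa, transmit)
                  - _window_energy(pos, r, i, N, m0, kappa, transmit))
            if dE > 0.0 and np.random.random() >= np.exp(-dE):
                counters[C_METRO_REJ] += 1
                continue
            _occ_remove(occ_n, occ_r, occ_m, x0, y0, z0, r, i)
            _occ_add(occ_n, occ_r, occ_m, x1, y1, z1, r, i)
            for c in range(3):
                pos[r, i, c] = m1[c]
            counters[C_REP_ACC] += 1
        else:
            # --- Rouse-like: displace one monomer by an fcc vector ---
            counters[C_ROUSE_ATT] += 1
            kv = np.random.randint(0, 12)
            for c in range(3):
                m1[c] = m0[c] + FCC[kv, c]
            if slab and (m1[2] < 0 or m1[2] >= Lzl):
                counters[C_NULL] += 1
                continue
            ip = i - 1 if i > 0 else N - 1
            iq = i + 1 if i + 1 < N else 0
            n1 = 0
            n2 = 0
            for c in range(3):
                n1 += (m1[c] - pos[r, ip, c]) ** 2
                n2 += (pos[r, iq, c] - m1[c]) ** 2
            if not ((n1 == 0 or n1 == 2) and (n2 == 0 or n2 == 2)):
                counters[C_NULL] += 1
                continue
            x1 = m1[0] % Lx
            y1 = m1[1] % Ly
            z1 = m1[2] if slab else m1[2] % Lzl
            nocc = occ_n[x1, y1, z1]
            if nocc >= 2:
                counters[C_NULL] += 1
                continue
            if nocc == 1:
                rr = occ_r[x1, y1, z1, 0]
                mm = occ_m[x1, y1, z1, 0]
                if not (rr == r and (mm == ip or mm == iq)):
                    counters[C_NULL] += 1
                    continue
            dE = (_window_energy(pos, r, i, N, m1, kappa, transmit)
                  - _window_energy(pos, r, i, N, m0, kappa, transmit))
            if dE > 0.0 and np.random.random() >= np.exp(-dE):
                counters[C_METRO_REJ] += 1
                continue
            _occ_remove(occ_n, occ_r, occ_m, x0, y0, z0, r, i)
            _occ_add(occ_n, occ_r, occ_m, x1, y1, z1, r, i)
            for c in range(3):
                pos[r, i, c] = m1[c]
            counters[C_ROUSE_ACC] += 1
    return 0
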