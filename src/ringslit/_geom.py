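"""Exact integer geometry predicates for curve simplification and
linking-number evaluation.

All curve vertices are integer triples, so orientation tests are exact
(int64 determinants of small differences).  The fast paths below
classify the generic strict cases; any test that encounters a zero
orientation returns "ambiguous" and the caller falls back to exact
rational arithmetic in Python.
"""

import numpy as np
from numba import njit

BLOCK_FREE = 0
BLOCK_HIT = 1
BLOCK_AMBIGUOUS = 2


@njit(cache=True, inline="always")
def _orient4(p, q, r, s):
    """Sign of the signed volume of tetrahedron (p, q, r, s)."""
    a0 = q[0] - p[0]
    a1 = q[1] - p[1]
    a2 = q[2] - p[2]
    b0 = r[0] - p[0]
    b1 = r[1] - p[1]
    b2 = r[2] - p[2]
    c0 = s[0] - p[0]
    c1 = s[1] - p[1]
    c2 = s[2] - p[2]
    d = (a0 * (b1 * c2 - b2 * c1)
         - a1 * (b0 * c2 - b2 * c0)
         + a2 * (b0 * c1 - b1 * c0))
    if d > 0:
        return 1
    if d < 0:
        return -1
    return 0


@njit(cache=True, inline="always")
def _eq3(p, q):
    return p[0] == q[0] and p[1] == q[1] and p[2] == q[2]


@njit(cache=True)
def _pt_in_closed_tri_onplane(p, tA, tV, tB, n0, n1, n2):
    """p known to lie in the triangle's plane; closed membership."""
    # cross(edge, p - vertex) . n, for the three edges in cyclic order
    e0 = (tV[0] - tA[0], tV[1] - tA[1], tV[2] - tA[2])
    e1 = (tB[0] - tV[0], tB[1] - tV[1], tB[2] - tV[2])
    e2 = (tA[0] - tB[0], tA[1] - tB[1], tA[2] - tB[2])
    d0 = (p[0] - tA[0], p[1] - tA[1], p[2] - tA[2])
    d1 = (p[0] - tV[0], p[1] - tV[1], p[2] - tV[2])
    d2 = (p[0] - tB[0], p[1] - tB[1], p[2] - tB[2])
    c0 = ((e0[1] * d0[2] - e0[2] * d0[1]) * n0
          + (e0[2] * d0[0] - e0[0] * d0[2]) * n1
          + (e0[0] * d0[1] - e0[1] * d0[0]) * n2)
    c1 = ((e1[1] * d1[2] - e1[2] * d1[1]) * n0
          + (e1[2] * d1[0] - e1[0] * d1[2]) * n1
          + (e1[0] * d1[1] - e1[1] * d1[0]) * n2)
    c2 = ((e2[1] * d2[2] - e2[2] * d2[1]) * n0
          + (e2[2] * d2[0] - e2[0] * d2[2]) * n1
          + (e2[0] * d2[1] - e2[1] * d2[0]) * n2)
    return (c0 >= 0 and c1 >= 0 and c2 >= 0) or (c0 <= 0 and c1 <= 0 and c2 <= 0)


@njit(cache=True, inline="always")
def _orient2(ax, ay, bx, by, cx, cy):
    d = (bx - ax) * (cy - ay) - (by - ay) * (cx - ax)
    if d > 0:
        return 1
    if d < 0:
        return -1
    return 0


@njit(cache=True, inline="always")
def _between2(px, py, qx, qy, xx, xy):
    """x collinear with p,q assumed; is x within the closed box [p,q]?"""
    return (min(px, qx) <= xx <= max(px, qx)
            and min(py, qy) <= xy <= max(py, qy))


@njit(cache=True)
def _coplanar_blocked_2d(a, b, tA, tV, tB, drop):
    """All five points coplanar: 2D closed-intersection test in the
    projection dropping axis ``drop`` (injective on the plane).
    Touching only at tA or tB is permitted."""
    if drop == 0:
        i0, i1 = 1, 2
    elif drop == 1:
        i0, i1 = 0, 2
    else:
        i0, i1 = 0, 1
    ax, ay = a[i0], a[i1]
    bx, by = b[i0], b[i1]
    Ax, Ay = tA[i0], tA[i1]
    Vx, Vy = tV[i0], tV[i1]
    Bx, By = tB[i0], tB[i1]

    # 1) segment endpoints inside the closed triangle?
    for (px, py, is_a) in ((ax, ay, True), (bx, by, False)):
        c0 = _orient2(Ax, Ay, Vx, Vy, px, py)
        c1 = _orient2(Vx, Vy, Bx, By, px, py)
        c2 = _orient2(Bx, By, Ax, Ay, px, py)
        inside = ((c0 >= 0 and c1 >= 0 and c2 >= 0)
                  or (c0 <= 0 and c1 <= 0 and c2 <= 0))
        if inside:
            if not ((px == Ax and py == Ay) or (px == Bx and py == By)):
                return True

    # 2) edge-by-edge intersection classification
    for e in range(3):
        if e == 0:
            ux, uy, vx, vy = Ax, Ay, Vx, Vy
        elif e == 1:
            ux, uy, vx, vy = Vx, Vy, Bx, By
        else:
            ux, uy, vx, vy = Bx, By, Ax, Ay
        o1 = _orient2(ax, ay, bx, by, ux, uy)
        o2 = _orient2(ax, ay, bx, by, vx, vy)
        o3 = _orient2(ux, uy, vx, vy, ax, ay)
        o4 = _orient2(ux, uy, vx, vy, bx, by)
        if o1 * o2 < 0 and o3 * o4 < 0:
            return True      # proper crossing: interior point
        if o1 == 0 and o2 == 0:
            # collinear: closed interval overlap on the common line
            lo_s = min(ax, bx) if ax != bx else min(ay, by)
            # overlap test on both coordinates (conservative exact):
            ox_lo = max(min(ax, bx), min(ux, vx))
            ox_hi = min(max(ax, bx), max(ux, vx))
            oy_lo = max(min(ay, by), min(uy, vy))
            oy_hi = min(max(ay, by), max(uy, vy))
            if ox_lo > ox_hi or oy_lo > oy_hi:
                continue
            if ox_lo == ox_hi and oy_lo == oy_hi:
                px, py = ox_lo, oy_lo
                if (px == Ax and py == Ay) or (px == Bx and py == By):
                    continue
                return True
            return True      # overlap along a stretch
        if o1 == 0 and _between2(ax, ay, bx, by, ux, uy):
            if not ((ux == Ax and uy == Ay) or (ux == Bx and uy == By)):
                return True
        if o2 == 0 and _between2(ax, ay, bx, by, vx, vy):
            if not ((vx == Ax and vy == Ay) or (vx == Bx and vy == By)):
                return True
        if o3 == 0 and _between2(ux, uy, vx, vy, ax, ay):
            if not ((ax == Ax and ay == Ay) or (ax == Bx and ay == By)):
                return True
        if o4 == 0 and _between2(ux, uy, vx, vy, bx, by):
            if not ((bx == Ax and by == Ay) or (bx == Bx and by == By)):
                return True
    return False


@njit(cache=True)
def _tri_block_one(a, b, tA, tV, tB):
    """Classify closed segment (a,b) against the closed triangle
    (tA, tV, tB) where touching exactly at tA or tB is permitted.

    Exact integer arithmetic throughout; BLOCK_AMBIGUOUS only for a
    degenerate (collinear) triangle, which the caller re-examines with
    rational arithmetic.
    """
    # triangle normal
    u0 = tV[0] - tA[0]
    u1 = tV[1] - tA[1]
    u2 = tV[2] - tA[2]
    w0 = tB[0] - tA[0]
    w1 = tB[1] - tA[1]
    w2 = tB[2] - tA[2]
    n0 = u1 * w2 - u2 * w1
    n1 = u2 * w0 - u0 * w2
    n2 = u0 * w1 - u1 * w0
    if n0 == 0 and n1 == 0 and n2 == 0:
        return BLOCK_AMBIGUOUS   # collinear triangle
    s1 = _orient4(tA, tV, tB, a)
    s2 = _orient4(tA, tV, tB, b)
    if (s1 > 0 and s2 > 0) or (s1 < 0 and s2 < 0):
        return BLOCK_FREE
    if s1 == 0 and s2 == 0:
        an0 = -n0 if n0 < 0 else n0
        an1 = -n1 if n1 < 0 else n1
        an2 = -n2 if n2 < 0 else n2
        drop = 0 if (an0 >= an1 and an0 >= an2) else (1 if an1 >= an2 else 2)
        return BLOCK_HIT if _coplanar_blocked_2d(a, b, tA, tV, tB, drop) \
            else BLOCK_FREE
    if s1 == 0 or s2 == 0:
        # one endpoint on the plane: contact possible only at that point
        p = a if s1 == 0 else b
        if not _pt_in_closed_tri_onplane(p, tA, tV, tB, n0, n1, n2):
            return BLOCK_FREE
        if _eq3(p, tA) or _eq3(p, tB):
            return BLOCK_FREE
        return BLOCK_HIT
    # strict plane crossing: unique intersection point X
    o1 = _orient4(a, b, tA, tV)
    o2 = _orient4(a, b, tV, tB)
    o3 = _orient4(a, b, tB, tA)
    if (o1 > 0 and o2 > 0 and o3 > 0) or (o1 < 0 and o2 < 0 and o3 < 0):
        return BLOCK_HIT         # strictly interior
    pos = o1 > 0 or o2 > 0 or o3 > 0
    neg = o1 < 0 or o2 < 0 or o3 < 0
    if pos and neg:
        return BLOCK_FREE        # line misses the closed triangle
    # X on the boundary: allowed only at the vertices tA or tB
    if o1 == 0 and o3 == 0:
        return BLOCK_FREE        # X == tA
    if o2 == 0 and o3 == 0:
        return BLOCK_FREE        # X == tB
    return BLOCK_HIT             # X == tV or on an open edge


@njit(cache=True)
def deletion_blocked(edges, alive_edge, skip1, skip2, tA, tV, tB, amb_out):
    """Fast scan of all alive obstacle edges against a deletion triangle.

    ``edges`` is (E, 6) int64 rows (ax, ay, az, bx, by, bz).  Returns
    -1 if some edge certainly blocks, else the number of edges needing
    the exact rational fallback, whose indices are written to
    ``amb_out``.
    """
    n_amb = 0
    a = np.empty(3, np.int64)
    b = np.empty(3, np.int64)
    # bounding box of the triangle for cheap rejection
    lo0 = min(tA[0], tV[0], tB[0])
    lo1 = min(tA[1], tV[1], tB[1])
    lo2 = min(tA[2], tV[2], tB[2])
    hi0 = max(tA[0], tV[0], tB[0])
    hi1 = max(tA[1], tV[1], tB[1])
    hi2 = max(tA[2], tV[2], tB[2])
    for e in range(edges.shape[0]):
        if not alive_edge[e] or e == skip1 or e == skip2:
            continue
        a0 = edges[e, 0]
        a1 = edges[e, 1]
        a2 = edges[e, 2]
        b0 = edges[e, 3]
        b1 = edges[e, 4]
        b2 = edges[e, 5]
        if (max(a0, b0) < lo0 or min(a0, b0) > hi0
                or max(a1, b1) < lo1 or min(a1, b1) > hi1
                or max(a2, b2) < lo2 or min(a2, b2) > hi2):
            continue
        a[0] = a0
        a[1] = a1
        a[2] = a2
        b[0] = b0
        b[1] = b1
        b[2] = b2
        res = _tri_block_one(a, b, tA, tV, tB)
        if res == BLOCK_HIT:
            return -1
        if res == BLOCK_AMBIGUOUS:
            if n_amb < amb_out.shape[0]:
                amb_out[n_amb] = e
            n_amb += 1
    return n_amb


@njit(cache=True)
def gln_pair_sum(c1, c2):
    """Gauss linking number of two closed integer polygons.

    Sum of signed solid angles of the spherical quadrilaterals spanned
    by each segment pair (van Oosterom-Strackee), divided by 4*pi.
    Returns a float; the caller rounds and checks the residual.
    """
    n1 = c1.shape[0]
    n2 = c2.shape[0]
    total = 0.0
    for i in range(n1):
        a1x = float(c1[i, 0])
        a1y = float(c1[i, 1])
        a1z = float(c1[i, 2])
        j2 = i + 1 if i + 1 < n1 else 0
        a2x = float(c1[j2, 0])
        a2y = float(c1[j2, 1])
        a2z = float(c1[j2, 2])
        if a1x == a2x and a1y == a2y and a1z == a2z:
            continue
        for j in range(n2):
            k2 = j + 1 if j + 1 < n2 else 0
            b1x = float(c2[j, 0])
            b1y = float(c2[j, 1])
            b1z = float(c2[j, 2])
            b2x = float(c2[k2, 0])
            b2y = float(c2[k2, 1])
            b2z = float(c2[k2, 2])
            if b1x == b2x and b1y == b2y and b1z == b2z:
                continue
            # the four chords
            r00x = b1x - a1x
            r00y = b1y - a1y
            r00z = b1z - a1z
            r01x = b2x - a1x
            r01y = b2y - a1y
            r01z = b2z - a1z
            r10x = b1x - a2x
            r10y = b1y - a2y
            r10z = b1z - a2z
            r11x = b2x - a2x
            r11y = b2y - a2y
            r11z = b2z - a2z
            total += _solid_tri(r00x, r00y, r00z, r01x, r01y, r01z,
                                r11x, r11y, r11z)
            total += _solid_tri(r00x, r00y, r00z, r11x, r11y, r11z,
                                r10x, r10y, r10z)
    return total / (4.0 * np.pi)


@njit(cache=True, inline="always")
def _solid_tri(ax, ay, az, bx, by, bz, cx, cy, cz):
    """Signed solid angle of the spherical triangle (a, b, c)."""
    la = np.sqrt(ax * ax + ay * ay + az * az)
    lb = np.sqrt(bx * bx + by * by + bz * bz)
    lc = np.sqrt(cx * cx + cy * cy + cz * cz)
    num = (ax * (by * cz - bz * cy)
           - ay * (bx * cz - bz * cx)
           + az * (bx * cy - by * cx))
    den = (la * lb * lc
           + (ax * bx + ay * by + az * bz) * lc
           + (bx * cx + by * cy + bz * cz) * la
           + (cx * ax + cy * ay + cz * az) * lb)
    return 2.0 * np.arctan2(num, den)
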