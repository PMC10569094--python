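"""Topological characterization of ring conformations.

Pipeline
--------
1.  **Shrinking / simplification** (`simplify_ring`,
    `simplify_system`): iterative vertex deletion.  Vertex v may be
    removed when the triangle (v-1, v, v+1) meets no other segment of
    any curve in the system, so the move is an ambient isotopy; sweeps
    repeat in seeded-random order until a fixed point.  All tests are
    exact integer predicates with a rational-arithmetic fallback for
    degenerate configurations.
2.  **Gauss linking number** (`gauss_linking_number`): exact integer
    from the analytic solid-angle sum over segment pairs.
3.  **Knot classification** (`knot_classify`): project the simplified
    ring along a random direction, read the crossing diagram, and
    compute the Alexander polynomial (exactly, by integer evaluation
    and interpolation from the arc/crossing matrix).  Knots are named
    from a lookup of Alexander polynomials of prime knots up to 7
    crossings plus composites of small knots; anything beyond is
    reported as ``complex``.  |Delta(-1)| (the knot determinant)
    separates the knots that occur with measurable frequency in these
    melts: unknot 1, trefoil 3, figure-eight 5, 5_1 5, 5_2 7, ...
4.  **Link classification** (`pair_link_classify`,
    `triplet_link_classify`): GLN != 0 means concatenated with weight
    chi = |GLN|.  GLN = 0 pairs are decided by joint simplification
    plus a separating-slab search over random orientations; inseparable
    GLN=0 pairs are classified by the two-component link determinant
    (Whitehead 5^2_1 has determinant 8, crossing number K=5, weight
    chi = K/2 = 2.5).  Three-chain links: triangles and
    poly(3)catenanes from pairwise concatenation alone; irreducible
    triples (poly(2)catenane+1-ring, Brunnian e.g. Borromean 6^3_2) by
    joint triple simplification and separability.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from fractions import Fraction

import numpy as np

from . import _geom
from .lattice import MeltState

__all__ = [
    "Polygon3D", "KnotRecord", "PairLinkRecord", "TripletLinkRecord",
    "simplify_ring", "simplify_system", "gauss_linking_number",
    "knot_classify", "pair_link_classify", "triplet_link_classify",
    "concatenation_census",
]


# ----------------------------------------------------------------------
# domain types
# ----------------------------------------------------------------------

class Polygon3D:
    """A closed polygonal space curve with integer vertices.

    Consecutive duplicate vertices are removed on construction (a
    lattice ring's stored-length doublings disappear here); closure is
    implicit.  Real-valued input is accepted when integral.
    """

    __slots__ = ("vertices",)

    def __init__(self, vertices):
        v = np.asarray(vertices)
        if v.ndim != 2 or v.shape[1] != 3:
            raise ValueError("vertices must be (N, 3)")
        if not np.issubdtype(v.dtype, np.integer):
            r = np.rint(v)
            if not np.allclose(v, r, atol=1e-9):
                raise ValueError("vertices must have integer coordinates")
            v = r
        v = v.astype(np.int64)
        keep = np.any(v != np.roll(v, -1, axis=0), axis=1)
        v = v[keep]
        if len(v) < 3:
            raise ValueError("a closed curve needs at least 3 distinct vertices")
        self.vertices = v

    def __len__(self):
        return len(self.vertices)

    def edges(self) -> np.ndarray:
        """(E, 6) array of segment endpoints (closed)."""
        a = self.vertices
        b = np.roll(a, -1, axis=0)
        return np.concatenate([a, b], axis=1)

    def reversed(self) -> "Polygon3D":
        return Polygon3D(self.vertices[::-1])

    def transformed(self, R: np.ndarray | None = None,
                    t: np.ndarray | None = None) -> np.ndarray:
        v = self.vertices.astype(np.float64)
        if R is not None:
            v = v @ np.asarray(R).T
        if t is not None:
            v = v + t
        return v


def _as_poly(obj) -> Polygon3D:
    if isinstance(obj, Polygon3D):
        return obj
    return Polygon3D(obj)


@dataclass
class KnotRecord:
    """Knot class of one ring."""
    ring_id: int
    K: int                    # irreducible crossing count (table value when known)
    det: int                  # |Alexander determinant| = |Delta(-1)|
    label: str                # unknot, 3_1, 4_1, ..., composite:..., complex(...)
    confidence: str = "exact"
    diagram_crossings: int = 0
    alexander: tuple = ()


@dataclass
class PairLinkRecord:
    """Two-chain link class of a ring pair."""
    ring_ids: tuple
    GLN: int
    K: int
    label: str                # unlinked, hopf-like|GLN|=n, whitehead, other-GLN0
    chi: float
    C: int
    det: int = 0


@dataclass
class TripletLinkRecord:
    """Three-chain link class of a ring triple."""
    ring_ids: tuple
    link_class: str           # none, poly3catenane, triangle,
    #                           poly2catenane_plus_ring, brunnian
    irreducible: bool = False


# ----------------------------------------------------------------------
# exact geometric helpers (rational fallback)
# ----------------------------------------------------------------------

def _orient_exact(p, q, r, s) -> int:
    """Exact orientation with Python integers (no overflow)."""
    a = [int(q[k]) - int(p[k]) for k in range(3)]
    b = [int(r[k]) - int(p[k]) for k in range(3)]
    c = [int(s[k]) - int(p[k]) for k in range(3)]
    d = (a[0] * (b[1] * c[2] - b[2] * c[1])
         - a[1] * (b[0] * c[2] - b[2] * c[0])
         + a[2] * (b[0] * c[1] - b[1] * c[0]))
    return (d > 0) - (d < 0)


def _cross3(u, v):
    return (u[1] * v[2] - u[2] * v[1],
            u[2] * v[0] - u[0] * v[2],
            u[0] * v[1] - u[1] * v[0])


def _sub(p, q):
    return tuple(int(p[k]) - int(q[k]) for k in range(3))


def _collinear(a, b, c) -> bool:
    return _cross3(_sub(b, a), _sub(c, a)) == (0, 0, 0)


def _seg_point_contains(a, b, p) -> bool:
    """Closed segment [a,b] contains point p (all integer/rational)."""
    if not _collinear(a, b, p):
        return False
    # p = a + t (b-a) with t in [0,1]
    d = _sub(b, a)
    for k in range(3):
        if d[k] != 0:
            t = Fraction(int(p[k]) - int(a[k]), d[k])
            break
    else:
        return tuple(int(x) for x in p) == tuple(int(x) for x in a)
    if not (0 <= t <= 1):
        return False
    return all(Fraction(int(a[k])) + t * d[k] == int(p[k]) for k in range(3))


def _segseg_intersection(a, b, c, d):
    """Exact intersection classification of closed segments in 3D.

    Returns (kind, data): kind in {"none", "point", "overlap"}; for
    "point" data is the rational intersection point.
    """
    ab = _sub(b, a)
    cd = _sub(d, c)
    ac = _sub(c, a)
    n = _cross3(ab, cd)
    if n == (0, 0, 0):
        # parallel (or degenerate): collinear overlap?
        if not _collinear(a, b, c):
            return ("none", None)
        # collinear: compare parameter intervals along ab
        axis = next((k for k in range(3) if ab[k] != 0), None)
        if axis is None:   # a == b: degenerate segment
            return ("point", tuple(Fraction(int(x)) for x in a)) \
                if _seg_point_contains(c, d, a) else ("none", None)
        ta, tb = Fraction(0), Fraction(1)
        tc = Fraction(int(c[axis]) - int(a[axis]), ab[axis])
        td = Fraction(int(d[axis]) - int(a[axis]), ab[axis])
        lo, hi = min(tc, td), max(tc, td)
        lo2, hi2 = max(ta, lo), min(tb, hi)
        if lo2 > hi2:
            return ("none", None)
        if lo2 == hi2:
            pt = tuple(Fraction(int(a[k])) + lo2 * ab[k] for k in range(3))
            return ("point", pt)
        return ("overlap", None)
    # skew or crossing: intersection requires coplanarity
    denom_v = _cross3(ab, cd)
    triple = sum(ac[k] * denom_v[k] for k in range(3))
    if triple != 0:
        return ("none", None)
    # solve a + t ab = c + s cd
    denom = sum(x * x for x in denom_v)
    t_num = sum(_cross3(ac, cd)[k] * denom_v[k] for k in range(3))
    s_num = sum(_cross3(ac, ab)[k] * denom_v[k] for k in range(3))
    t = Fraction(t_num, denom)
    s = Fraction(s_num, denom)
    if 0 <= t <= 1 and 0 <= s <= 1:
        pt = tuple(Fraction(int(a[k])) + t * ab[k] for k in range(3))
        return ("point", pt)
    return ("none", None)


def _point_in_closed_triangle(p, tA, tV, tB) -> bool:
    """p (rational 3-tuple) in the closed triangle; triangle may be
    degenerate (then its closed convex hull segment)."""
    A = tuple(Fraction(int(x)) for x in tA)
    V = tuple(Fraction(int(x)) for x in tV)
    B = tuple(Fraction(int(x)) for x in tB)
    u = tuple(V[k] - A[k] for k in range(3))
    w = tuple(B[k] - A[k] for k in range(3))
    n = _cross3(u, w)
    if n == (0, 0, 0):
        # degenerate: closed hull = segment between extreme points
        pts = [A, V, B]
        d = next((tuple(q[k] - A[k] for k in range(3)) for q in (V, B)
                  if q != A), None)
        if d is None:
            return p == A
        ts = []
        axis = next(k for k in range(3) if d[k] != 0)
        for q in pts:
            ts.append((q[axis] - A[axis]) / d[axis])
        lo, hi = min(ts), max(ts)
        if not _collinear(A, tuple(A[k] + d[k] for k in range(3)), p):
            return False
        tp = (p[axis] - A[axis]) / d[axis]
        if not (lo <= tp <= hi):
            return False
        return all(A[k] + tp * d[k] == p[k] for k in range(3))
    # on plane?
    ap = tuple(p[k] - A[k] for k in range(3))
    if sum(ap[k] * n[k] for k in range(3)) != 0:
        return False
    # barycentric via cross products
    def cr(u1, u2):
        return _cross3(u1, u2)
    vp = tuple(p[k] - V[k] for k in range(3))
    bp = tuple(p[k] - B[k] for k in range(3))
    c1 = cr(u, ap)                      # A->V vs A->p
    c2 = cr(tuple(B[k] - V[k] for k in range(3)), vp)
    c3 = cr(tuple(A[k] - B[k] for k in range(3)), bp)
    d1 = sum(c1[k] * n[k] for k in range(3))
    d2 = sum(c2[k] * n[k] for k in range(3))
    d3 = sum(c3[k] * n[k] for k in range(3))
    return d1 >= 0 and d2 >= 0 and d3 >= 0


def _tri_block_exact(a, b, tA, tV, tB, allowed) -> bool:
    """Exact check: does closed segment (a,b) touch the closed triangle
    (tA,tV,tB) anywhere outside the allowed vertex set?"""
    # triangle as three edges + interior; equivalently: intersect the
    # segment with the triangle's plane / hull and classify.
    # Strategy: collect candidate intersection points from edge-edge
    # tests and segment-plane crossing; if any is not in allowed -> hit.
    pts = []
    overlap = False
    for (u, v) in ((tA, tV), (tV, tB), (tB, tA)):
        kind, data = _segseg_intersection(a, b, u, v)
        if kind == "overlap":
            overlap = True
        elif kind == "point":
            pts.append(data)
    if overlap:
        # collinear overlap with an edge: more than a point of contact
        # unless the overlap is a single allowed vertex, which the
        # "point" branch would have reported; treat as blocking.
        return True
    # transversal interior crossing
    s1 = _orient_exact(tA, tV, tB, a)
    s2 = _orient_exact(tA, tV, tB, b)
    if s1 * s2 < 0:
        # unique plane crossing point; in closed triangle?
        A = tuple(Fraction(int(x)) for x in tA)
        n = _cross3(_sub(tV, tA), _sub(tB, tA))
        ab = _sub(b, a)
        denom = sum(ab[k] * n[k] for k in range(3))
        t = Fraction(-sum((int(a[k]) - int(tA[k])) * n[k] for k in range(3)), denom)
        pt = tuple(Fraction(int(a[k])) + t * ab[k] for k in range(3))
        if _point_in_closed_triangle(pt, tA, tV, tB):
            pts.append(pt)
    elif s1 == 0 and s2 == 0:
        # coplanar segment: endpoints inside the triangle?
        for p in (a, b):
            pf = tuple(Fraction(int(x)) for x in p)
            if _point_in_closed_triangle(pf, tA, tV, tB):
                pts.append(pf)
        # interior chords are caught by the edge tests above; but a
        # segment passing fully through the interior crosses two edges,
        # already collected.
    elif s1 == 0 or s2 == 0:
        p = a if s1 == 0 else b
        pf = tuple(Fraction(int(x)) for x in p)
        if _point_in_closed_triangle(pf, tA, tV, tB):
            pts.append(pf)
    allowed_f = {tuple(Fraction(int(x)) for x in q) for q in allowed}
    for p in pts:
        if p not in allowed_f:
            return True
    # coplanar chord fully inside without touching edges is impossible
    # for a closed region bounded by the edges; handled above.
    return False


# ----------------------------------------------------------------------
# simplification
# ----------------------------------------------------------------------

def _check_mutually_disjoint(polys: list[Polygon3D], include_self: bool = True):
    """Refuse curves that intersect each other (and, optionally,
    themselves)."""
    all_edges = [p.edges() for p in polys]
    for pi in range(len(polys)):
        for pj in range(pi if include_self else pi + 1, len(polys)):
            E1, E2 = all_edges[pi], all_edges[pj]
            for i in range(E1.shape[0]):
                jstart = i + 1 if pi == pj else 0
                for j in range(jstart, E2.shape[0]):
                    if pi == pj:
                        n = E1.shape[0]
                        if j == i or j == (i + 1) % n or i == (j + 1) % n:
                            continue  # adjacent edges share a vertex
                    kind, data = _segseg_intersection(
                        E1[i, :3], E1[i, 3:], E2[j, :3], E2[j, 3:])
                    if kind != "none":
                        raise ValueError(
                            f"curves intersect (curve {pi} edge {i} vs "
                            f"curve {pj} edge {j}); topology undefined")


def simplify_system(polys, rng=0, max_sweeps: int = 200,
                    movable=None, check: bool = True) -> list[Polygon3D]:
    """Jointly simplify a set of closed curves by isotopy-preserving
    vertex deletion; every curve is an obstacle for every other.

    ``movable`` optionally restricts which curves may shrink.
    Deterministic given ``rng`` (an int seed or Generator).
    """
    polys = [_as_poly(p) for p in polys]
    if check:
        _check_mutually_disjoint(polys)
    rng = np.random.default_rng(rng if not isinstance(rng, np.random.Generator) else rng)
    if movable is None:
        movable = [True] * len(polys)

    # flat vertex arena with per-ring cyclic linked lists; edge e runs
    # from vertex e to nxt[e] and dies with its tail vertex
    sizes = [len(p) for p in polys]
    offs = np.concatenate([[0], np.cumsum(sizes)])
    V = int(offs[-1])
    P = np.concatenate([p.vertices for p in polys], axis=0)
    ring_of = np.concatenate([np.full(s, ci) for ci, s in enumerate(sizes)])
    nxt = np.empty(V, dtype=np.int64)
    prv = np.empty(V, dtype=np.int64)
    for ci, s in enumerate(sizes):
        base = offs[ci]
        idx = np.arange(base, base + s)
        nxt[idx] = base + (np.arange(s) + 1) % s
        prv[idx] = base + (np.arange(s) - 1) % s
    alive = np.ones(V, dtype=np.bool_)
    nleft = np.array(sizes)
    edges = np.concatenate([P, P[nxt]], axis=1).astype(np.int64)
    amb = np.empty(64, dtype=np.int64)

    changed = True
    sweeps = 0
    while changed and sweeps < max_sweeps:
        changed = False
        sweeps += 1
        for v in rng.permutation(V):
            v = int(v)
            if not alive[v]:
                continue
            ci = int(ring_of[v])
            if not movable[ci] or nleft[ci] <= 3:
                continue
            a, b = int(prv[v]), int(nxt[v])
            tA, tV, tB = P[a], P[v], P[b]
            if np.array_equal(tA, tB):
                continue
            res = _geom.deletion_blocked(edges, alive, a, v, tA, tV, tB, amb)
            if res < 0:
                continue
            if res > 0:
                if res > amb.shape[0]:   # pragma: no cover
                    amb = np.empty(2 * res, dtype=np.int64)
                    res = _geom.deletion_blocked(edges, alive, a, v,
                                                 tA, tV, tB, amb)
                tAt, tBt = tuple(tA), tuple(tB)
                blocked = any(
                    _tri_block_exact(edges[e, :3], edges[e, 3:],
                                     tAt, tV, tBt, allowed=(tAt, tBt))
                    for e in amb[:res])
                if blocked:
                    continue
            # delete v: edge a now runs a -> b; edge v dies with v
            alive[v] = False
            nxt[a] = b
            prv[b] = a
            edges[a, 3:] = P[b]
            nleft[ci] -= 1
            changed = True

    out = []
    for ci, s in enumerate(sizes):
        base = int(offs[ci])
        # walk the surviving cycle in order
        start = base
        while not alive[start]:
            start += 1
        seq = [start]
        cur = int(nxt[start])
        while cur != start:
            seq.append(cur)
            cur = int(nxt[cur])
        out.append(Polygon3D(P[np.array(seq)]))
    return out


def simplify_ring(poly, obstacles=(), rng=0) -> Polygon3D:
    """Shrink one closed curve to a reduced representative that is
    ambient-isotopic to the input relative to the obstacle curves.

    The output vertex count never exceeds the input's; the operation
    is idempotent up to its fixed point and deterministic given the
    seed.  Curves that already intersect are refused.
    """
    polys = [_as_poly(poly)] + [_as_poly(o) for o in obstacles]
    movable = [True] + [False] * len(polys[1:])
    return simplify_system(polys, rng=rng, movable=movable)[0]


# ----------------------------------------------------------------------
# Gauss linking number
# ----------------------------------------------------------------------

def gauss_linking_number(c1, c2, check: bool = True) -> int:
    """Exact integer Gauss linking number of two disjoint closed
    polygons, from the analytic solid-angle sum over segment pairs.

    Antisymmetric under orientation reversal of either curve,
    invariant under rigid motions and simplification.  Curves sharing
    a point raise (the Gauss integral is singular).
    """
    p1, p2 = _as_poly(c1), _as_poly(c2)
    if check:
        # only mutual disjointness matters for the Gauss integral
        _check_mutually_disjoint([p1, p2], include_self=False)
    total = _geom.gln_pair_sum(p1.vertices, p2.vertices)
    g = int(round(total))
    if abs(total - g) > 1e-6:
        tot = _gln_longdouble(p1.vertices, p2.vertices)
        g = int(round(float(tot)))
        if abs(float(tot) - g) > 1e-4:   # pragma: no cover
            raise ArithmeticError(f"GLN failed to converge: {total}")
    return g


def _gln_longdouble(v1, v2):   # pragma: no cover - rare fallback
    import itertools as it
    total = np.longdouble(0)
    e1 = np.concatenate([v1, np.roll(v1, -1, axis=0)], axis=1).astype(np.longdouble)
    e2 = np.concatenate([v2, np.roll(v2, -1, axis=0)], axis=1).astype(np.longdouble)
    for a in e1:
        for b in e2:
            r = [b[:3] - a[:3], b[3:] - a[:3], b[3:] - a[3:], b[:3] - a[3:]]
            for tri in ((0, 1, 2), (0, 2, 3)):
                A, B, C = (r[t] for t in tri)
                la, lb, lc = (np.sqrt((x * x).sum()) for x in (A, B, C))
                num = np.dot(A, np.cross(B, C))
                den = (la * lb * lc + np.dot(A, B) * lc
                       + np.dot(B, C) * la + np.dot(C, A) * lb)
                total += 2.0 * np.arctan2(num, den)
    return total / (4 * np.pi)


# ----------------------------------------------------------------------
# planar diagrams and Alexander invariants
# ----------------------------------------------------------------------

class _DegenerateProjection(Exception):
    pass


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])


def _diagram(components: list[np.ndarray], rng: np.random.Generator,
             eps: float = 1e-9):
    """Project rotated curves to the xy plane and read the crossing
    diagram.

    Returns (crossings, n_arcs) where each crossing is a dict with the
    over/under arc indices and the sign.  Raises _DegenerateProjection
    on near-degenerate geometry (caller retries with a new rotation).
    """
    R = _random_rotation(rng)
    rot = [c.astype(np.float64) @ R.T for c in components]

    # global edge list
    edges = []           # (comp, index, P0, P1)
    for ci, v in enumerate(rot):
        n = len(v)
        for k in range(n):
            edges.append((ci, k, v[k], v[(k + 1) % n]))

    events = []          # (comp, edge_idx, t, z, partner_key, over?)
    crossings = []
    for e1 in range(len(edges)):
        c1, k1, p0, p1 = edges[e1]
        n1 = len(rot[c1])
        for e2 in range(e1 + 1, len(edges)):
            c2, k2, q0, q1 = edges[e2]
            if c1 == c2:
                n = len(rot[c1])
                if k2 == k1 or k2 == (k1 + 1) % n or k1 == (k2 + 1) % n:
                    continue
            d1 = p1[:2] - p0[:2]
            d2 = q1[:2] - q0[:2]
            den = d1[0] * d2[1] - d1[1] * d2[0]
            if abs(den) < eps:
                continue
            rhs = q0[:2] - p0[:2]
            t = (rhs[0] * d2[1] - rhs[1] * d2[0]) / den
            s = (rhs[0] * d1[1] - rhs[1] * d1[0]) / den
            if t < -eps or t > 1 + eps or s < -eps or s > 1 + eps:
                continue
            if min(t, s) < eps or max(t, s) > 1 - eps:
                raise _DegenerateProjection("crossing at segment endpoint")
            z1 = p0[2] + t * (p1[2] - p0[2])
            z2 = q0[2] + s * (q1[2] - q0[2])
            if abs(z1 - z2) < eps:
                raise _DegenerateProjection("tangent strands")
            over_first = z1 > z2
            cid = len(crossings)
            # crossing sign: with over-strand direction o and
            # under-strand direction u, sign = sign(det[o, u])
            if over_first:
                sign = 1 if (d1[0] * d2[1] - d1[1] * d2[0]) > 0 else -1
            else:
                sign = 1 if (d2[0] * d1[1] - d2[1] * d1[0]) > 0 else -1
            crossings.append({"sign": sign, "id": cid,
                              "over_comp": c1 if over_first else c2,
                              "under_comp": c2 if over_first else c1})
            events.append((c1, k1, t, cid, over_first))
            events.append((c2, k2, s, cid, not over_first))

    # order events along each component; under-events cut arcs
    per_comp: dict[int, list] = {ci: [] for ci in range(len(components))}
    for (ci, k, t, cid, over) in events:
        per_comp[ci].append((k + t, cid, over))
    arc_of_under_in = {}
    arc_of_under_out = {}
    over_events = {}     # cid -> list of (comp, position)
    arc_count = 0
    comp_arcs = {}
    for ci, evs in per_comp.items():
        evs.sort()
        unders = [e for e in evs if not e[2]]
        if not unders:
            # whole component is one arc with no cuts
            comp_arcs[ci] = [(0.0, float("inf"), arc_count)]
            arc_count += 1
            continue
        # arcs run from one under-event to the next (cyclically)
        arcs = []
        for u in range(len(unders)):
            start = unders[u][0]
            end = unders[(u + 1) % len(unders)][0]
            aid = arc_count
            arc_count += 1
            arcs.append((start, end, aid))
            cid = unders[u][0]
            arc_of_under_in[unders[u][1]] = None   # fill later
        comp_arcs[ci] = arcs
        for u in range(len(unders)):
            pos, cid, _ = unders[u]
            # incoming arc ends at this under event; outgoing starts here
            incoming = arcs[(u - 1) % len(unders)][2]
            outgoing = arcs[u][2]
            arc_of_under_in[cid] = incoming
            arc_of_under_out[cid] = outgoing

    def arc_at(ci, pos):
        arcs = comp_arcs[ci]
        if len(arcs) == 1 and arcs[0][1] == float("inf"):
            return arcs[0][2]
        for (start, end, aid) in arcs:
            if start <= end:
                if start <= pos <= end:
                    return aid
            else:   # wraps
                if pos >= start or pos <= end:
                    return aid
        return arcs[0][2]   # pragma: no cover

    for (ci, k, t, cid, over) in events:
        if over:
            crossings[cid]["over_arc"] = arc_at(ci, k + t)

    for c in crossings:
        c["under_in"] = arc_of_under_in[c["id"]]
        c["under_out"] = arc_of_under_out[c["id"]]
        if "over_arc" not in c:   # pragma: no cover
            raise _DegenerateProjection("crossing without over event")

    return crossings, arc_count


def _bareiss_det(mat: list[list[int]]) -> int:
    """Exact integer determinant (fraction-free Gaussian elimination)."""
    m = [row[:] for row in mat]
    n = len(m)
    if n == 0:
        return 1
    sign = 1
    prev = 1
    for k in range(n - 1):
        if m[k][k] == 0:
            for r in range(k + 1, n):
                if m[r][k] != 0:
                    m[k], m[r] = m[r], m[k]
                    sign = -sign
                    break
            else:
                return 0
        for i in range(k + 1, n):
            for j in range(k + 1, n):
                m[i][j] = (m[i][j] * m[k][k] - m[i][k] * m[k][j]) // prev
        prev = m[k][k]
    return sign * m[n - 1][n - 1]


def _alexander_matrix_at(crossings, n_arcs, t: int) -> list[list[int]]:
    """Alexander matrix evaluated at integer t (one row per crossing)."""
    rows = []
    for c in crossings:
        row = [0] * n_arcs
        o, ui, uo, s = c["over_arc"], c["under_in"], c["under_out"], c["sign"]
        if s > 0:
            # x_uo = t x_ui + (1-t) x_o
            row[ui] += t
            row[o] += 1 - t
            row[uo] -= 1
        else:
            # t x_uo = x_ui + (t-1) x_o
            row[ui] += 1
            row[o] += t - 1
            row[uo] -= t
        rows.append(row)
    return rows


def _alexander_det_at(crossings, n_arcs, t: int) -> int:
    """|det of the Alexander matrix with one column deleted| at t."""
    if not crossings:
        return 1
    if n_arcs != len(crossings):
        return 0   # split or reducible diagram
    rows = _alexander_matrix_at(crossings, n_arcs, t)
    minor = [row[1:] for row in rows[:-1]] if n_arcs > 1 else []
    # delete one column and one row (matrix rank is n-1; any minor works
    # up to units +-t^k which cannot change |det(-1)| parity-free value)
    minor = [row[:-1] for row in rows[:len(rows) - 1]]
    return abs(_bareiss_det(minor))


def _alexander_polynomial(crossings, n_arcs) -> tuple[int, ...]:
    """Normalized Alexander polynomial coefficients (exact).

    Evaluates the deleted-minor determinant at integer points and
    interpolates; normalizes by stripping t factors and fixing the
    sign of the leading coefficient.  Defined up to +-t^k, and the
    result is palindromic for knots.
    """
    if not crossings or n_arcs != len(crossings):
        return (1,) if not crossings else (0,)
    n = len(crossings)
    deg = n                      # generous bound on the degree
    ts = list(range(2, 2 + deg + 1))
    vals = []
    for t in ts:
        rows = _alexander_matrix_at(crossings, n_arcs, t)
        minor = [row[:-1] for row in rows[:n - 1]]
        vals.append(_bareiss_det(minor))
    # Lagrange interpolation with exact rationals
    coeffs = [Fraction(0)] * (deg + 1)
    for i, ti in enumerate(ts):
        # basis polynomial l_i(t)
        num = [Fraction(1)]
        den = Fraction(1)
        for j, tj in enumerate(ts):
            if i == j:
                continue
            num = _polymul(num, [Fraction(-tj), Fraction(1)])
            den *= (ti - tj)
        w = Fraction(vals[i]) / den
        for k in range(len(num)):
            coeffs[k] += w * num[k]
    ints = []
    for c in coeffs:
        assert c.denominator == 1, "interpolation must be integral"
        ints.append(int(c))
    # strip trailing zeros then leading t factors
    while ints and ints[-1] == 0:
        ints.pop()
    k0 = 0
    while k0 < len(ints) and ints[k0] == 0:
        k0 += 1
    ints = ints[k0:] or [0]
    if ints[0] < 0 or (ints[0] == 0 and sum(ints) < 0):
        ints = [-c for c in ints]
    # canonical orientation: palindrome for knots; for safety pick the
    # lexicographically smaller of the two readings
    rev = ints[::-1]
    if rev[0] > 0 and rev < ints:
        ints = rev
    return tuple(ints)


def _polymul(a, b):
    out = [Fraction(0)] * (len(a) + len(b) - 1)
    for i, x in enumerate(a):
        for j, y in enumerate(b):
            out[i + j] += x * y
    return out


# ----------------------------------------------------------------------
# knot classification
# ----------------------------------------------------------------------

# normalized Alexander polynomials of prime knots up to 7 crossings
# (low-to-high coefficients, positive first entry, t-power stripped)
_KNOT_TABLE = {
    (1,): ("unknot", 0),
    (1, -1, 1): ("3_1", 3),
    (1, -3, 1): ("4_1", 4),
    (1, -1, 1, -1, 1): ("5_1", 5),
    (2, -3, 2): ("5_2", 5),
    (2, -5, 2): ("6_1", 6),
    (1, -3, 3, -3, 1): ("6_2", 6),
    (1, -3, 5, -3, 1): ("6_3", 6),
    (1, -1, 1, -1, 1, -1, 1): ("7_1", 7),
    (3, -5, 3): ("7_2", 7),
    (2, -3, 3, -3, 2): ("7_3", 7),
    (4, -7, 4): ("7_4", 7),
    (2, -4, 5, -4, 2): ("7_5", 7),
    (1, -5, 7, -5, 1): ("7_6", 7),
    (1, -5, 9, -5, 1): ("7_7", 7),
}


def _poly_product(p, q):
    out = [0] * (len(p) + len(q) - 1)
    for i, a in enumerate(p):
        for j, b in enumerate(q):
            out[i + j] += a * b
    return tuple(out)


def _normalize_poly(p):
    ints = list(p)
    while ints and ints[-1] == 0:
        ints.pop()
    k0 = 0
    while k0 < len(ints) and ints[k0] == 0:
        k0 += 1
    ints = ints[k0:] or [0]
    if ints[0] < 0:
        ints = [-c for c in ints]
    rev = ints[::-1]
    if rev[0] > 0 and rev < ints:
        ints = rev
    return tuple(ints)


def _composite_table():
    """Alexander polynomials of connected sums of small prime knots."""
    primes = [(k, v) for k, v in _KNOT_TABLE.items() if v[0] != "unknot"]
    out = {}
    for (p1, (n1, k1)), (p2, (n2, k2)) in itertools.combinations_with_replacement(primes, 2):
        prod = _normalize_poly(_poly_product(p1, p2))
        name = "#".join(sorted([n1, n2]))
        out.setdefault(prod, (f"composite:{name}", k1 + k2))
    return out


_COMPOSITE_TABLE = _composite_table()


def knot_classify(ring, rng=0, n_projections: int = 10,
                  ring_id: int = -1) -> KnotRecord:
    """Classify the knot type of one closed curve.

    The ring is first simplified against itself; small reduced curves
    are certified unknots.  Otherwise the reduced curve is projected
    along random directions, the diagram with the fewest crossings is
    kept, and the exact Alexander polynomial / determinant decides the
    label via a lookup covering prime knots to 7 crossings and
    composites of them; anything else is labelled ``complex`` with the
    observed crossing count (heuristic confidence).
    """
    rng = np.random.default_rng(rng if not isinstance(rng, np.random.Generator) else rng)
    poly = _as_poly(ring)
    red = simplify_ring(poly, rng=rng)
    if len(red) <= 5:
        return KnotRecord(ring_id=ring_id, K=0, det=1, label="unknot",
                          confidence="exact", diagram_crossings=0,
                          alexander=(1,))
    best = None
    attempts = 0
    while attempts < n_projections:
        attempts += 1
        try:
            crossings, n_arcs = _diagram([red.vertices], rng)
        except _DegenerateProjection:
            continue
        if best is None or len(crossings) < len(best[0]):
            best = (crossings, n_arcs)
        if len(crossings) <= 2:
            break
    if best is None:
        raise RuntimeError("no generic projection found within retry budget")
    crossings, n_arcs = best
    if len(crossings) <= 2:
        return KnotRecord(ring_id=ring_id, K=0, det=1, label="unknot",
                          confidence="exact", diagram_crossings=len(crossings),
                          alexander=(1,))
    apoly = _alexander_polynomial(crossings, n_arcs)
    det = abs(sum(c * ((-1) ** k) for k, c in enumerate(apoly)))
    if apoly in _KNOT_TABLE:
        label, K = _KNOT_TABLE[apoly]
        conf = "exact"
    elif apoly in _COMPOSITE_TABLE:
        label, K = _COMPOSITE_TABLE[apoly]
        conf = "exact"
    elif apoly == (1,):
        # trivial Alexander polynomial on a many-crossing diagram:
        # almost surely an unsimplified unknot; label unknot but flag.
        label, K, conf = "unknot", 0, "heuristic"
    else:
        label, K, conf = f"complex(K={len(crossings)})", len(crossings), "heuristic"
    return KnotRecord(ring_id=ring_id, K=K, det=det, label=label,
                      confidence=conf, diagram_crossings=len(crossings),
                      alexander=apoly)


# ----------------------------------------------------------------------
# separability and link classification
# ----------------------------------------------------------------------

def _separable_bipartition(group1: list[np.ndarray], group2: list[np.ndarray],
                           rng: np.random.Generator, n_rot: int = 20) -> bool:
    """Axis-aligned separating-slab search over random orientations.

    Conservative: failure to find a slab declares inseparable.
    """
    for attempt in range(n_rot):
        if attempt == 0:
            R = np.eye(3)
        else:
            R = _random_rotation(rng)
        a = np.concatenate([v @ R.T for v in group1], axis=0)
        b = np.concatenate([v @ R.T for v in group2], axis=0)
        for ax in range(3):
            if a[:, ax].max() < b[:, ax].min() or b[:, ax].max() < a[:, ax].min():
                return True
    return False


def _link_determinant(curves: list[np.ndarray], rng: np.random.Generator,
                      n_projections: int = 10):
    """(min diagram crossings, |Delta(-1)|) for a multi-component link.

    Returns (0, 0) when some projection certifies splitness: a
    component that is never the under-strand at an inter-component
    crossing can be lifted clear of the others, so the link splits.
    """
    best = None
    attempts = 0
    while attempts < n_projections:
        attempts += 1
        try:
            crossings, n_arcs = _diagram(curves, rng)
        except _DegenerateProjection:
            continue
        if len(curves) >= 2:
            inter = [c for c in crossings
                     if c["over_comp"] != c["under_comp"]]
            if not inter:
                return 0, 0
            for comp in range(len(curves)):
                unders = sum(1 for c in inter if c["under_comp"] == comp)
                overs = sum(1 for c in inter if c["over_comp"] == comp)
                if (unders == 0 and overs > 0) or (overs == 0 and unders > 0):
                    return 0, 0   # one-sided component: lifts off
        if n_arcs != len(crossings):
            continue  # reducible diagram for invariants: retry
        if best is None or len(crossings) < len(best[0]):
            best = (crossings, n_arcs)
    if best is None:
        return None, None
    crossings, n_arcs = best
    det = _alexander_det_at(crossings, n_arcs, -1)
    return len(crossings), det


def pair_link_classify(ri, rj, rng=0, ids=(0, 1), check: bool = True) -> PairLinkRecord:
    """Classify the two-chain link of two disjoint rings.

    GLN is computed exactly; pairs with GLN = 0 are decided by joint
    simplification: separable pairs are unlinked, inseparable ones are
    classified by the link determinant (8 = Whitehead class, K = 5,
    chi = 2.5) or, failing recognition, by the reduced diagram
    crossing count with chi = K/2.
    """
    rng = np.random.default_rng(rng if not isinstance(rng, np.random.Generator) else rng)
    p1, p2 = _as_poly(ri), _as_poly(rj)
    gln = gauss_linking_number(p1, p2, check=check)
    if gln != 0:
        return PairLinkRecord(ring_ids=tuple(ids), GLN=gln, K=2 * abs(gln),
                              label=f"hopf-like|GLN|={abs(gln)}",
                              chi=float(abs(gln)), C=1)
    s1, s2 = simplify_system([p1, p2], rng=rng, check=False)
    if _separable_bipartition([s1.vertices.astype(float)],
                              [s2.vertices.astype(float)], rng):
        return PairLinkRecord(ring_ids=tuple(ids), GLN=0, K=0,
                              label="unlinked", chi=0.0, C=0)
    # geometrically stuck: decide by the two-component link determinant
    # (0 for a split link -- deletion-only shrinking cannot pull apart
    # interpenetrating convex curves, so the slab test alone is too
    # conservative; the determinant is an isotopy invariant).
    K, det = _link_determinant([s1.vertices, s2.vertices], rng)
    if det == 0 or (K is not None and K == 0):
        return PairLinkRecord(ring_ids=tuple(ids), GLN=0, K=0,
                              label="unlinked", chi=0.0, C=0, det=0)
    if det == 8:
        return PairLinkRecord(ring_ids=tuple(ids), GLN=0, K=5,
                              label="whitehead", chi=2.5, C=1, det=8)
    if K is None:
        # no usable diagram: conservative inseparable, unknown class
        return PairLinkRecord(ring_ids=tuple(ids), GLN=0, K=0,
                              label="other-GLN0", chi=0.0, C=1)
    return PairLinkRecord(ring_ids=tuple(ids), GLN=0, K=K,
                          label="other-GLN0", chi=K / 2.0, C=1,
                          det=int(det))


def triplet_link_classify(ri, rj, rk, pair_records, rng=0,
                          ids=(0, 1, 2)) -> TripletLinkRecord:
    """Classify a ring triple from its pairwise records plus, when at
    most one pair is concatenated, a joint triple simplification with
    a separability search."""
    recs = list(pair_records)
    if len(recs) != 3:
        raise ValueError("need the three pairwise records")
    cs = [r.C for r in recs]
    n_linked = sum(cs)
    if n_linked == 3:
        return TripletLinkRecord(ring_ids=tuple(ids), link_class="triangle")
    if n_linked == 2:
        return TripletLinkRecord(ring_ids=tuple(ids), link_class="poly3catenane")
    rng = np.random.default_rng(rng if not isinstance(rng, np.random.Generator) else rng)
    polys = [_as_poly(x) for x in (ri, rj, rk)]
    simp = simplify_system(polys, rng=rng, check=False)
    vs = [s.vertices.astype(float) for s in simp]
    separable = False
    for lone in range(3):
        rest = [vs[k] for k in range(3) if k != lone]
        if _separable_bipartition([vs[lone]], rest, rng):
            separable = True
            break
    if separable:
        return TripletLinkRecord(ring_ids=tuple(ids), link_class="none")
    # geometrically stuck triple: the three-component link determinant
    # vanishes for any split link, screening out merely interpenetrating
    # (but separable) configurations the slab search cannot resolve.
    _, det = _link_determinant([s.vertices for s in simp], rng)
    if det == 0:
        return TripletLinkRecord(ring_ids=tuple(ids), link_class="none")
    if n_linked == 1:
        return TripletLinkRecord(ring_ids=tuple(ids),
                                 link_class="poly2catenane_plus_ring",
                                 irreducible=True)
    return TripletLinkRecord(ring_ids=tuple(ids), link_class="brunnian",
                             irreducible=True)


# ----------------------------------------------------------------------
# melt-wide census
# ----------------------------------------------------------------------

def _ring_images(state: MeltState, i: int, j: int):
    """Candidate periodic images of ring j relative to ring i.

    The minimum-image shift of the centers of mass always qualifies;
    neighboring images are added when their bounding boxes overlap
    ring i's (rings comparable to the box size can link through more
    than one image)."""
    box = state.box
    vi = state.pos[i]
    vj = state.pos[j]
    cmi = vi.mean(axis=0)
    cmj = vj.mean(axis=0)
    L = np.array([box.Lx, box.Ly,
                  0 if box.is_slit else box.Lz], dtype=float)
    base = np.zeros(3)
    for ax in range(3):
        if L[ax] > 0:
            base[ax] = round((cmi[ax] - cmj[ax]) / L[ax])
    lo_i, hi_i = vi.min(axis=0), vi.max(axis=0)
    shifts = []
    rng_ax = [(-1, 0, 1) if L[ax] > 0 else (0,) for ax in range(3)]
    for dx in rng_ax[0]:
        for dy in rng_ax[1]:
            for dz in rng_ax[2]:
                s = base + np.array([dx, dy, dz])
                off = (s * L).astype(np.int64)
                lo_j = vj.min(axis=0) + off
                hi_j = vj.max(axis=0) + off
                if np.all(lo_j <= hi_i + 1) and np.all(hi_j >= lo_i - 1):
                    shifts.append(off)
    if not shifts:
        shifts.append((base * L).astype(np.int64))
    return shifts


def concatenation_census(state: MeltState, rng=0,
                         include_triplets: bool = False):
    """Full pairwise (and triplet) topological census of a melt snapshot.

    Returns ``(C, chi, pair_records, triplet_records)``: the symmetric
    concatenation matrix C, the symmetric link-weight matrix chi, the
    per-pair records for concatenated pairs, and the triplet census
    restricted to mutually proximal triples.  Pairs are pre-filtered
    by a rigorous spatial cutoff (center-of-mass distance beyond the
    sum of maximal radii cannot link).
    """
    rng = np.random.default_rng(rng if not isinstance(rng, np.random.Generator) else rng)
    M = state.M
    box = state.box
    C = np.zeros((M, M), dtype=np.int64)
    chi = np.zeros((M, M), dtype=float)
    records = {}

    cms = state.pos.mean(axis=1)
    radii = np.array([np.linalg.norm(state.pos[i] - cms[i], axis=1).max()
                      for i in range(M)])
    L = np.array([box.Lx, box.Ly, 0 if box.is_slit else box.Lz], dtype=float)

    prox_pairs = set()
    for i in range(M):
        for j in range(i + 1, M):
            d = cms[i] - cms[j]
            for ax in range(3):
                if L[ax] > 0:
                    d[ax] -= L[ax] * round(d[ax] / L[ax])
            if np.linalg.norm(d) > radii[i] + radii[j] + 2.0:
                continue
            prox_pairs.add((i, j))
            total_gln = 0
            crecs = []
            for off in _ring_images(state, i, j):
                pj = state.pos[j] + off
                # distinct rings in a valid melt never share sites and
                # nearest-neighbor segments cannot cross, so the curves
                # are guaranteed disjoint; skip the quadratic check.
                rec = pair_link_classify(state.pos[i], pj, rng=rng,
                                         ids=(i, j), check=False)
                total_gln += rec.GLN
                if rec.C:
                    crecs.append(rec)
            if crecs:
                if len(crecs) == 1:
                    best = crecs[0]
                else:
                    # the pair links through several periodic images
                    best = PairLinkRecord(
                        ring_ids=(i, j), GLN=total_gln,
                        K=sum(r.K for r in crecs), label="multi-image",
                        chi=sum(r.chi for r in crecs), C=1,
                        det=max(r.det for r in crecs))
                C[i, j] = C[j, i] = 1
                chi[i, j] = chi[j, i] = best.chi
                records[(i, j)] = best

    triplets = []
    if include_triplets:
        for (i, j, k) in itertools.combinations(range(M), 3):
            pairs = [(i, j), (i, k), (j, k)]
            if not all(p in prox_pairs for p in pairs):
                continue
            precs = []
            for p in pairs:
                if p in records:
                    precs.append(records[p])
                else:
                    precs.append(PairLinkRecord(ring_ids=p, GLN=0, K=0,
                                                label="unlinked", chi=0.0, C=0))
            trec = triplet_link_classify(state.pos[i], state.pos[j],
                                         state.pos[k], precs, rng=rng,
                                         ids=(i, j, k))
            if trec.link_class != "none":
                triplets.append(trec)
    return C, chi, list(records.values()), triplets
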