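"""Exact geometry predicates and the lattice non-crossing lemma."""

import itertools

import numpy as np
import pytest

from ringslit._geom import BLOCK_FREE, BLOCK_HIT, _tri_block_one
from ringslit.lattice import FCC_VECTORS


def test_no_bond_can_pierce_a_minimal_sweep_triangle():
    """The topology-conservation lemma, checked by enumeration: a
    nearest-neighbor displacement sweeps triangles with all-fcc sides,
    and no fcc bond placed anywhere nearby crosses their open interior
    transversally.  This is why ordinary moves conserve topology."""
    z = np.zeros(3, dtype=np.int64)
    tried = 0
    for u, v in itertools.product(FCC_VECTORS, FCC_VECTORS):
        w = u - v
        if (w ** 2).sum() != 2:
            continue  # not a minimal triangle (0, u, v)
        tri = (z, u.astype(np.int64), v.astype(np.int64))
        # every fcc bond with endpoints on the even sublattice nearby
        for ox, oy, oz in itertools.product(range(-2, 3), repeat=3):
            if (ox + oy + oz) % 2:
                continue
            a = np.array([ox, oy, oz], dtype=np.int64)
            for step in FCC_VECTORS:
                b = a + step
                # skip bonds incident to a triangle vertex (shared sites)
                if any(np.array_equal(a, t) or np.array_equal(b, t)
                       for t in tri):
                    continue
                res = _tri_block_one(a, b, *tri)
                tried += 1
                # touching cases are fine; strict transversal piercing
                # must be impossible for single fcc bonds
                s1 = _orient(tri[0], tri[1], tri[2], a)
                s2 = _orient(tri[0], tri[1], tri[2], b)
                assert not (s1 * s2 < 0 and res == BLOCK_HIT), (a, b, tri)
    assert tried > 10_000


def _orient(p, q, r, s):
    m = np.array([q - p, r - p, s - p], dtype=np.int64)
    d = int(round(np.linalg.det(m)))
    return (d > 0) - (d < 0)


def test_tri_block_detects_transversal_piercing():
    # non-minimal triangle with a segment through its interior
    tA = np.array([0, 0, 0], dtype=np.int64)
    tV = np.array([4, 0, 0], dtype=np.int64)
    tB = np.array([0, 4, 0], dtype=np.int64)
    a = np.array([1, 1, -1], dtype=np.int64)
    b = np.array([1, 1, 1], dtype=np.int64)
    assert _tri_block_one(a, b, tA, tV, tB) == BLOCK_HIT


def test_tri_block_allows_touch_at_permitted_vertices():
    tA = np.array([0, 0, 0], dtype=np.int64)
    tV = np.array([4, 0, 0], dtype=np.int64)
    tB = np.array([0, 4, 0], dtype=np.int64)
    # segment ending exactly at tA (an allowed endpoint)
    a = np.array([0, 0, 0], dtype=np.int64)
    b = np.array([-2, -2, 2], dtype=np.int64)
    assert _tri_block_one(a, b, tA, tV, tB) == BLOCK_FREE
    # but a segment ending on the open interior blocks
    c = np.array([1, 1, 0], dtype=np.int64)
    d = np.array([1, 1, 4], dtype=np.int64)
    assert _tri_block_one(c, d, tA, tV, tB) == BLOCK_HIT


def test_tri_block_coplanar_cases():
    tA = np.array([0, 0, 0], dtype=np.int64)
    tV = np.array([4, 0, 0], dtype=np.int64)
    tB = np.array([0, 4, 0], dtype=np.int64)
    # coplanar segment crossing the triangle
    a = np.array([-1, 1, 0], dtype=np.int64)
    b = np.array([3, 1, 0], dtype=np.int64)
    assert _tri_block_one(a, b, tA, tV, tB) == BLOCK_HIT
    # coplanar but fully outside
    c = np.array([6, 6, 0], dtype=np.int64)
    d = np.array([8, 6, 0], dtype=np.int64)
    assert _tri_block_one(c, d, tA, tV, tB) == BLOCK_FREE
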