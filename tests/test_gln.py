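"""Gauss linking number: exactness, symmetries, oracle agreement."""

import numpy as np
import pytest

from ringslit.fixtures import FixtureSpec, make_fixture, random_closed_walk
from ringslit.topology import Polygon3D, gauss_linking_number

from helpers import gln_projection_oracle


def _hopf():
    polys, _ = make_fixture(FixtureSpec(name="hopf"))
    return polys


def test_hopf_link_has_unit_gln():
    a, b = _hopf()
    assert abs(gauss_linking_number(a, b)) == 1


def test_far_separated_loops_unlinked():
    a, b = _hopf()
    far = Polygon3D(b.vertices + np.array([100, 0, 0]))
    assert gauss_linking_number(a, far) == 0


def test_whitehead_gln_zero():
    a, b = make_fixture(FixtureSpec(name="whitehead"))[0]
    assert gauss_linking_number(a, b) == 0


def test_orientation_reversal_antisymmetry():
    a, b = _hopf()
    g = gauss_linking_number(a, b)
    assert gauss_linking_number(a.reversed(), b) == -g
    assert gauss_linking_number(a, b.reversed()) == -g
    assert gauss_linking_number(a.reversed(), b.reversed()) == g


def test_rigid_motion_invariance():
    a, b = _hopf()
    g = gauss_linking_number(a, b)
    perm = np.array([[0, 0, 1], [1, 0, 0], [0, 1, 0]])   # proper rotation
    t = np.array([7, -3, 11])
    ra = Polygon3D(a.vertices @ perm.T + t)
    rb = Polygon3D(b.vertices @ perm.T + t)
    assert gauss_linking_number(ra, rb) == g


def test_mirror_flips_sign():
    a, b = _hopf()
    g = gauss_linking_number(a, b)
    mirror = np.array([1, 1, -1])
    assert gauss_linking_number(Polygon3D(a.vertices * mirror),
                                Polygon3D(b.vertices * mirror)) == -g


def test_subdivision_invariance():
    a, b = _hopf()
    def subdivide(p):
        v = 2 * p.vertices
        mids = (v + np.roll(v, -1, axis=0)) // 2
        out = np.empty((2 * len(v), 3), dtype=np.int64)
        out[0::2] = v
        out[1::2] = mids
        return Polygon3D(out)
    assert gauss_linking_number(subdivide(a), subdivide(b)) == \
        gauss_linking_number(a, b)


def test_touching_curves_rejected():
    a = np.array([(0, 0, 0), (4, 0, 0), (4, 4, 0), (0, 4, 0)], np.int64)
    b = a + np.array([4, 0, 0])   # shares the vertex (4,0,0)... and edge
    with pytest.raises(ValueError):
        gauss_linking_number(a, b)


def test_gln_matches_projection_oracle_on_random_pairs(rng):
    """Solid-angle GLN equals the brute-force signed-crossing count on
    entangled random closed walks, every time."""
    checked = nonzero = 0
    while checked < 40:
        c1 = random_closed_walk(40, rng)
        c2 = random_closed_walk(40, rng) + np.array([3, 1, 1])
        try:
            g = gauss_linking_number(c1, c2)
        except ValueError:
            continue
        assert gln_projection_oracle(c1, c2, rng, n_dirs=8) == g
        checked += 1
        nonzero += g != 0
    assert nonzero >= 1
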