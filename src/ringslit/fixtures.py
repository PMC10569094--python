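"""Certified topological fixtures and synthetic conformation ensembles.

Every named fixture returns integer-coordinate closed polygons together
with a certificate of ground-truth invariants (GLN matrix, knot
determinants, link classes) that the topology module must reproduce.
Lattice melts use the fcc checkerboard; where a clean published-style
polygonal realization is simpler (Whitehead clasp, Borromean
rectangles) plain integer polygons are used -- the topology module
accepts both.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .lattice import FCC_VECTORS, RunConfig, init_melt
from .topology import Polygon3D

__all__ = ["FixtureSpec", "make_fixture", "random_closed_walk",
           "gaussian_rings", "FIXTURE_NAMES"]

FIXTURE_NAMES = ("unknot", "trefoil", "figure_eight", "hopf", "whitehead",
                 "borromean", "random_ring", "flat_stack")


@dataclass(frozen=True)
class FixtureSpec:
    """Request for a named fixture.

    ``size`` scales parametric curves (vertices per ring); ``seed``
    makes stochastic fixtures reproducible.
    """
    name: str
    size: int = 60
    separation: float = 4.0
    seed: int = 0


def _torus_curve(p: int, q: int, n: int, scale: float) -> np.ndarray:
    """(p,q) torus-style closed curve rounded to integer coordinates.

    The tube radius 1 times ``scale`` dominates the rounding error of
    1/2 per coordinate, so the rounded polygon stays in the isotopy
    class of the smooth curve for scale >= 6.
    """
    t = np.linspace(0.0, 2.0 * np.pi, n + 1)[:-1]
    x = (2.0 + np.cos(q * t)) * np.cos(p * t)
    y = (2.0 + np.cos(q * t)) * np.sin(p * t)
    z = np.sin(q * t)
    return np.rint(np.stack([x, y, z], axis=1) * scale).astype(np.int64)


def _fig8_curve(n: int, scale: float) -> np.ndarray:
    t = np.linspace(0.0, 2.0 * np.pi, n + 1)[:-1]
    x = (2.0 + np.cos(2 * t)) * np.cos(3 * t)
    y = (2.0 + np.cos(2 * t)) * np.sin(3 * t)
    z = np.sin(4 * t)
    return np.rint(np.stack([x, y, z], axis=1) * scale).astype(np.int64)


# hand-built clasped bowtie (component B) threaded twice, same spatial
# direction, by component A: the Whitehead link 5^2_1
_WHITEHEAD_B = np.array(
    [(1, 0, 2), (6, 0, 2), (6, 0, -2), (1, 0, -2), (-1, 0, 2), (-6, 0, 2),
     (-6, 1, -2), (-1, 1, -2), (1, 1, 2)], dtype=np.int64)
_WHITEHEAD_A = np.array(
    [(4, -3, 0), (4, 3, 0), (4, 3, 9), (-4, -3, 9), (-4, -3, 0),
     (-4, 3, 0), (-4, 3, -9), (4, -3, -9)], dtype=np.int64)

# three mutually perpendicular 2x4 rectangles: the Borromean rings 6^3_2
_BORROMEAN = [
    np.array([(2, 4, 0), (-2, 4, 0), (-2, -4, 0), (2, -4, 0)], np.int64),
    np.array([(0, 2, 4), (0, -2, 4), (0, -2, -4), (0, 2, -4)], np.int64),
    np.array([(4, 0, 2), (4, 0, -2), (-4, 0, -2), (-4, 0, 2)], np.int64),
]

_HOPF = [
    np.array([(2, 2, 0), (-2, 2, 0), (-2, -2, 0), (2, -2, 0)], np.int64),
    np.array([(1, 0, 2), (1, 0, -2), (5, 0, -2), (5, 0, 2)], np.int64),
]


def random_closed_walk(n: int, rng: np.random.Generator) -> np.ndarray:
    """Closed random walk of n fcc steps (pair each step with its
    negation and shuffle, so the walk returns to the origin).  The
    curve may self-intersect; it is used where only inter-curve
    topology matters (e.g. linking-number oracles)."""
    if n % 2:
        raise ValueError("need an even number of steps")
    idx = rng.integers(0, 12, size=n // 2)
    steps = np.concatenate([FCC_VECTORS[idx], -FCC_VECTORS[idx]], axis=0)
    rng.shuffle(steps, axis=0)
    pts = np.concatenate([[np.zeros(3, np.int64)],
                          np.cumsum(steps[:-1], axis=0)], axis=0)
    return pts.astype(np.int64)


def gaussian_rings(n_rings: int, N: int, rng: np.random.Generator,
                   sigma: float = 1.0, compress_z: float = 1.0) -> np.ndarray:
    """Ensemble of ideal closed Gaussian rings (Brownian bridges).

    Used as an analytic oracle for shape statistics; ``compress_z``
    affinely flattens the ensemble to emulate slit confinement.
    Returns float coordinates of shape (n_rings, N, 3).
    """
    steps = rng.normal(scale=sigma, size=(n_rings, N, 3))
    steps -= steps.mean(axis=1, keepdims=True)   # exact closure
    pos = np.cumsum(steps, axis=1)
    pos[..., 2] *= compress_z
    return pos


def make_fixture(spec: FixtureSpec):
    """Build the named fixture.

    Returns ``(polygons, certificate)``; the certificate carries the
    invariants the topology module must reproduce exactly.
    """
    name = spec.name
    rng = np.random.default_rng(spec.seed)
    sep = spec.separation

    if name == "unknot":
        s = max(3, int(sep))
        poly = np.array([(0, 0, 0), (2 * s, 0, 0), (2 * s, 2 * s, 0),
                         (0, 2 * s, 0)], dtype=np.int64)
        cert = {"knots": [{"det": 1, "label": "unknot", "K": 0}],
                "gln": [[0]]}
        return [Polygon3D(poly)], cert

    if name == "trefoil":
        poly = _torus_curve(2, 3, spec.size, scale=6)
        cert = {"knots": [{"det": 3, "label": "3_1", "K": 3}], "gln": [[0]]}
        return [Polygon3D(poly)], cert

    if name == "figure_eight":
        poly = _fig8_curve(spec.size, scale=6)
        cert = {"knots": [{"det": 5, "label": "4_1", "K": 4}], "gln": [[0]]}
        return [Polygon3D(poly)], cert

    if name == "hopf":
        cert = {"knots": [{"det": 1, "label": "unknot", "K": 0}] * 2,
                "gln": [[0, 1], [1, 0]], "abs_gln": 1,
                "pair": {"C": 1, "chi": 1.0}}
        return [Polygon3D(v) for v in _HOPF], cert

    if name == "whitehead":
        cert = {"knots": [{"det": 1, "label": "unknot", "K": 0}] * 2,
                "gln": [[0, 0], [0, 0]],
                "pair": {"C": 1, "chi": 2.5, "K": 5, "det": 8,
                         "label": "whitehead"}}
        return [Polygon3D(_WHITEHEAD_A), Polygon3D(_WHITEHEAD_B)], cert

    if name == "borromean":
        cert = {"knots": [{"det": 1, "label": "unknot", "K": 0}] * 3,
                "gln": [[0, 0, 0], [0, 0, 0], [0, 0, 0]],
                "pairwise_C": 0, "triplet": "brunnian"}
        return [Polygon3D(v) for v in _BORROMEAN], cert

    if name == "random_ring":
        n = spec.size + (spec.size % 2)
        poly = random_closed_walk(n, rng)
        cert = {"note": "random closed walk; no fixed invariants"}
        return [Polygon3D(poly)], cert

    if name == "flat_stack":
        # well-separated flat lattice rings: an unlinked melt
        state = init_melt(RunConfig(N=max(8, 4 * (spec.size // 4)),
                                    M=4, rho_site=0.2, seed=spec.seed))
        polys = [Polygon3D(state.pos[i]) for i in range(state.M)]
        cert = {"gln": [[0] * state.M for _ in range(state.M)],
                "C": "zero-matrix"}
        return polys, cert

    raise ValueError(f"unknown fixture name {name!r}")
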