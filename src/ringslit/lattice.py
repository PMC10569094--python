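"""fcc lattice geometry, slit-confined simulation box and melt state.

Internal representation
-----------------------
The fcc lattice is stored on the even-parity sublattice of a simple
cubic grid ("grid units"): a site is an integer triple ``(x, y, z)``
with ``x + y + z`` even, and the 12 nearest neighbors are the
permutations of ``(+-1, +-1, 0)``.  The fcc lattice step is then
``a = sqrt(2)`` grid units; every metric observable is reported in
units of ``a``.

The box is periodic in x and y (``Lx``, ``Ly`` even so that wrapping
preserves parity).  Slit confinement places impenetrable walls at
``z = 0`` and ``z = H`` (grid units); both wall planes contain lattice
sites.  ``H_over_a = H / sqrt(2)`` reproduces the slit heights quoted
in lattice units ``a`` (e.g. a three-grid-layer gap is
``H/a = 2.12``).  In bulk mode z is periodic as well.

Monomer positions are stored *unwrapped*; bonds are direct coordinate
differences (always a nearest-neighbor vector or zero), so rings never
need minimum-image reconstruction.  Occupancy is defined on wrapped
coordinates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

#: grid units per fcc lattice step a
GRID_PER_A = math.sqrt(2.0)

#: the 12 fcc nearest-neighbor displacement vectors (grid units)
FCC_VECTORS = np.array(
    [
        (1, 1, 0), (1, -1, 0), (-1, 1, 0), (-1, -1, 0),
        (1, 0, 1), (1, 0, -1), (-1, 0, 1), (-1, 0, -1),
        (0, 1, 1), (0, 1, -1), (0, -1, 1), (0, -1, -1),
    ],
    dtype=np.int64,
)

DEFAULT_RHO_SITE = 5.0 / 6.0
DEFAULT_KAPPA = 2.0
DEFAULT_CROSSING_RATE = 1e-4


def fcc_neighbor_vectors() -> np.ndarray:
    """Return the 12 fcc nearest-neighbor displacement vectors.

    All have squared Euclidean length 2 in grid units (length ``a``),
    and the set is closed under negation.
    """
    return FCC_VECTORS.copy()


@dataclass(frozen=True)
class SlitBox:
    """Simulation box: periodic in x/y, hard walls (or periodic) in z.

    Parameters are in grid units; ``Lx`` and ``Ly`` must be even.  For
    a slit, ``H`` is the wall-to-wall distance and sites with
    ``0 <= z <= H`` are allowed (``H + 1`` layers).  For bulk, ``H``
    is ``None`` and ``Lz`` (even) is the periodic height.
    """

    Lx: int
    Ly: int
    H: int | None = None
    Lz: int | None = None

    def __post_init__(self):
        if self.Lx <= 0 or self.Ly <= 0:
            raise ValueError("box sides must be positive")
        if self.Lx % 2 or self.Ly % 2:
            raise ValueError("Lx, Ly must be even to preserve fcc parity")
        if self.H is None:
            if self.Lz is None or self.Lz <= 0 or self.Lz % 2:
                raise ValueError("bulk box needs positive even Lz")
        else:
            if self.H < 1:
                raise ValueError(
                    "slit needs at least 2 lattice layers (H >= 1 grid unit)"
                )

    # ------------------------------------------------------------------
    @property
    def is_slit(self) -> bool:
        return self.H is not None

    @property
    def n_layers(self) -> int:
        """Number of z layers holding lattice sites."""
        return (self.H + 1) if self.is_slit else self.Lz

    @property
    def site_count(self) -> int:
        """Total number of fcc sites in the box (half of all grid cells)."""
        return self.Lx * self.Ly * self.n_layers // 2

    @property
    def H_over_a(self) -> float | None:
        """Slit height in units of the fcc step a (None for bulk)."""
        return None if self.H is None else self.H / GRID_PER_A

    def wrap(self, pos: np.ndarray) -> np.ndarray:
        """Wrap positions into the primary box (x, y always; z only in bulk)."""
        w = np.array(pos, dtype=np.int64, copy=True)
        w[..., 0] %= self.Lx
        w[..., 1] %= self.Ly
        if not self.is_slit:
            w[..., 2] %= self.Lz
        return w

    def z_in_box(self, z: np.ndarray | int) -> np.ndarray | bool:
        if self.is_slit:
            return (np.asarray(z) >= 0) & (np.asarray(z) <= self.H)
        return np.ones(np.shape(z), dtype=bool) if np.ndim(z) else True


@dataclass
class RingConformation:
    """A single ring: ordered cyclic list of fcc sites.

    ``unwrapped`` carries the true (non-periodic) coordinates used for
    metric observables; ``sites`` are the wrapped coordinates.
    """

    ring_id: int
    sites: np.ndarray       # (N, 3) wrapped, int64
    unwrapped: np.ndarray   # (N, 3) unwrapped, int64

    @property
    def N(self) -> int:
        return self.sites.shape[0]

    def bonds(self) -> np.ndarray:
        """Cyclic bond vectors (unwrapped differences; exact)."""
        return np.roll(self.unwrapped, -1, axis=0) - self.unwrapped


@dataclass(frozen=True)
class RunConfig:
    """Key-value run configuration (mirrors the simulated-melt parameters).

    ``H_over_a`` of ``None`` means bulk (fully periodic).  ``N`` is the
    number of monomers per ring, ``M`` the requested chain count
    (adjusted on construction to keep the site density ``rho_site``
    fixed), ``kappa_bend`` the bending stiffness in units of kT, and
    ``crossing_rate`` the probability per elementary kMC step that the
    attempted move is allowed to cross another strand (default one
    crossing-permitted attempt per 1e4 elementary steps).
    """

    N: int
    M: int
    rho_site: float = DEFAULT_RHO_SITE
    kappa_bend: float = DEFAULT_KAPPA
    H_over_a: float | None = None
    crossing_rate: float = DEFAULT_CROSSING_RATE
    steps: int = 0
    snapshot_stride: int = 0
    seed: int = 0
    reptation_fraction: float = 0.5
    zero_bond_angle: str = "drop"   # or "transmit"

    @property
    def H_grid(self) -> int | None:
        if self.H_over_a is None:
            return None
        return int(round(self.H_over_a * GRID_PER_A))

    def to_dict(self) -> dict:
        return {
            "N": self.N, "M": self.M, "rho_site": self.rho_site,
            "kappa_bend": self.kappa_bend, "H_over_a": self.H_over_a,
            "crossing_rate": self.crossing_rate, "steps": self.steps,
            "snapshot_stride": self.snapshot_stride, "seed": self.seed,
            "reptation_fraction": self.reptation_fraction,
            "zero_bond_angle": self.zero_bond_angle,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        return cls(**{k: d[k] for k in d if k in cls.__dataclass_fields__})


@dataclass
class MeltState:
    """Full simulator state: box, all ring coordinates, parameters.

    ``pos`` is int64 of shape (M, N, 3), unwrapped grid coordinates.
    ``tau`` is the accumulated MC time in elementary steps (attempted
    moves).
    """

    box: SlitBox
    pos: np.ndarray
    config: RunConfig
    tau: int = 0

    @property
    def M(self) -> int:
        return self.pos.shape[0]

    @property
    def N(self) -> int:
        return self.pos.shape[1]

    def ring(self, i: int) -> RingConformation:
        return RingConformation(
            ring_id=i,
            sites=self.box.wrap(self.pos[i]),
            unwrapped=self.pos[i].copy(),
        )

    def rings(self) -> list[RingConformation]:
        return [self.ring(i) for i in range(self.M)]

    def occupancy(self) -> dict[tuple[int, int, int], list[tuple[int, int]]]:
        """Map wrapped site -> list of (ring_id, monomer_index)."""
        occ: dict[tuple[int, int, int], list[tuple[int, int]]] = {}
        wrapped = self.box.wrap(self.pos)
        for r in range(self.M):
            for m in range(self.N):
                occ.setdefault(tuple(int(c) for c in wrapped[r, m]), []).append((r, m))
        return occ

    @property
    def rho_site(self) -> float:
        return self.M * self.N / self.box.site_count

    def copy(self) -> "MeltState":
        return MeltState(self.box, self.pos.copy(), self.config, self.tau)


# ----------------------------------------------------------------------
# state validation
# ----------------------------------------------------------------------

def validate_state(state: MeltState) -> list[str]:
    """Check every melt-state invariant; return a list of violations.

    The validator never raises on bad geometry: each violation names
    the ring, monomer and rule.  An empty list certifies a valid state.
    """
    out: list[str] = []
    box, pos = state.box, state.pos
    M, N = state.M, state.N

    parity = (pos.sum(axis=2) % 2).astype(bool)
    for r, m in zip(*np.nonzero(parity)):
        out.append(f"ring {r} monomer {m}: odd coordinate parity (not an fcc site)")

    if box.is_slit:
        bad = (pos[:, :, 2] < 0) | (pos[:, :, 2] > box.H)
        for r, m in zip(*np.nonzero(bad)):
            out.append(f"ring {r} monomer {m}: z={pos[r, m, 2]} outside slit [0, {box.H}]")

    bonds = np.roll(pos, -1, axis=1) - pos
    nsq = (bonds ** 2).sum(axis=2)
    bad = ~((nsq == 0) | (nsq == 2))
    for r, m in zip(*np.nonzero(bad)):
        out.append(
            f"ring {r} bond {m}->{(m + 1) % N}: squared length {nsq[r, m]} "
            "is neither 0 nor a nearest-neighbor step"
        )

    # three consecutive monomers on one site = two adjacent zero bonds
    zero = nsq == 0
    triple = zero & np.roll(zero, -1, axis=1)
    for r, m in zip(*np.nonzero(triple)):
        out.append(f"ring {r} monomers {m}..{(m + 2) % N}: three consecutive on one site")

    occ = state.occupancy()
    for site, occupants in occ.items():
        if len(occupants) > 2:
            out.append(f"site {site}: occupied by {len(occupants)} monomers (max 2)")
        elif len(occupants) == 2:
            (r1, m1), (r2, m2) = occupants
            adjacent = r1 == r2 and (abs(m1 - m2) == 1 or abs(m1 - m2) == N - 1)
            if not adjacent:
                out.append(
                    f"site {site}: doubly occupied by non-consecutive monomers "
                    f"({r1},{m1}) and ({r2},{m2})"
                )
    return out


# ----------------------------------------------------------------------
# melt construction
# ----------------------------------------------------------------------

def _even_factor_pair(target: int) -> tuple[int, int] | None:
    """Even (Lx, Ly) with Lx*Ly == target and mild aspect ratio, or None."""
    if target <= 0 or target % 4:
        return None
    best = None
    lo = 4 if target >= 32 else 2
    for lx in range(lo, int(math.isqrt(target)) + 1, 2):
        if target % lx == 0 and (target // lx) % 2 == 0:
            ly = target // lx
            if best is None or abs(lx - ly) < abs(best[0] - best[1]):
                best = (lx, ly)
    if best is not None and max(best) <= 4 * min(best):
        return (min(best), max(best))
    return None


def _choose_box(N: int, M: int, rho: float, H_grid: int | None) -> SlitBox:
    """Pick box dimensions holding ~N*M/rho sites at the requested slit height."""
    site_target = N * M / rho
    if H_grid is not None:
        layers = H_grid + 1
        area2 = site_target * 2 / layers          # = Lx * Ly
        t = int(round(area2))
        for cand in range(t, t + 4 * max(t // 10, 50)):
            pair = _even_factor_pair(cand)
            if pair is not None:
                return SlitBox(Lx=pair[0], Ly=pair[1], H=H_grid)
        side = 2 * max(1, int(math.ceil(math.sqrt(area2) / 2)))
        return SlitBox(Lx=side, Ly=side, H=H_grid)
    # bulk: near-cubic even dimensions
    vol2 = site_target * 2
    best = None
    edge = max(2, int(round(vol2 ** (1 / 3))))
    for lz in range(max(2, (edge - 8) // 2 * 2), edge + 10, 2):
        t = int(round(vol2 / lz))
        pair = None
        for cand in range(t, t + 9):
            pair = _even_factor_pair(cand)
            if pair is not None:
                break
        if pair is None:
            continue
        dims = (pair[0], pair[1], lz)
        score = max(dims) / min(dims) + 50.0 * abs(pair[0] * pair[1] * lz - vol2) / vol2
        if min(dims) < 4:
            score += 100.0  # needle boxes cannot hold staples
        if best is None or score < best[0]:
            best = (score, dims)
    if best is None:
        side = 2 * max(1, int(round(vol2 ** (1 / 3) / 2)))
        dims = (side, side, side)
    else:
        dims = best[1]
    return SlitBox(Lx=dims[0], Ly=dims[1], H=None, Lz=dims[2])


def _serpentine(n: int, w: int) -> np.ndarray:
    """Self-avoiding in-layer path of n sites in local coordinates.

    Moves are in-layer fcc steps (+-1, +-1, 0).  The path snakes
    through row pairs ``y in {2r, 2r+1}``: within a pair the site is
    ``(x, 2r + x % 2)``, and the pair-to-pair transition always leaves
    from an odd x (top row), so every step is a valid diagonal.  Local
    parity x+y is even on every site.  Width w >= 4.
    """
    if w == 2:   # degenerate strip: straight diagonal zigzag
        arr = np.array([(k % 2, k) for k in range(n)], dtype=np.int64)
        return arr
    assert w >= 4
    x_hi = w - 1 if (w - 1) % 2 == 1 else w - 2   # odd turning column
    sites = [(0, 0)]
    x, r, dr = 0, 0, 1
    while len(sites) < n:
        limit = x_hi if dr > 0 else 1
        if x == limit:      # turn upward into the next row pair
            r += 1
            dr = -dr
        x += dr
        sites.append((x, 2 * r + (x % 2)))
    arr = np.array(sites, dtype=np.int64)
    d = np.diff(arr, axis=0)
    assert np.all(np.abs(d) == 1), "serpentine generator produced an invalid step"
    assert len(set(map(tuple, sites))) == n, "serpentine self-intersects"
    return arr


def _staple_ring(n_path: int, w: int, double: bool) -> np.ndarray:
    """Closed flat ring ("staple") spanning two adjacent z layers.

    The outbound path is an in-layer serpentine of ``n_path`` sites at
    local z=0; the return path is the reversed serpentine shifted by
    (1, 0, 1).  With ``double`` each site holds two consecutive
    monomers (stored length), giving 4*n_path monomers, else 2*n_path.
    """
    f = _serpentine(n_path, w)
    fwd = np.concatenate([f, np.zeros((n_path, 1), dtype=np.int64)], axis=1)
    back = fwd[::-1].copy()
    back += np.array([1, 0, 1], dtype=np.int64)
    path = np.concatenate([fwd, back], axis=0)
    if double:
        path = np.repeat(path, 2, axis=0)
    # closure check
    d = np.roll(path, -1, axis=0) - path
    nsq = (d ** 2).sum(axis=1)
    assert np.all((nsq == 0) | (nsq == 2)), "staple ring has an invalid bond"
    return path


def init_melt(config: RunConfig) -> MeltState:
    """Build a valid melt at the target density.

    Rings are laid out as flat stacked "staples" (two-layer serpentine
    rectangles, each site holding two consecutive monomers) tiling the
    box; the chain count is adjusted to hold ``rho_site`` fixed once
    the box side is chosen.  Any initial condition is acceptable
    because equilibration is certified by the g2 plateau, not the
    start state.  Deterministic given the seed.
    """
    N, M = config.N, config.M
    if N < 8 or N % 2:
        raise ValueError("N must be even and >= 8")
    if not (0 < config.rho_site <= 2):
        raise ValueError("rho_site must be in (0, 2]")
    H_grid = config.H_grid
    if config.H_over_a is not None and (H_grid is None or H_grid < 1):
        raise ValueError("slit must span at least 2 lattice layers")

    box = _choose_box(N, M, config.rho_site, H_grid)
    M_adj = max(1, int(round(config.rho_site * box.site_count / N)))

    double = N % 4 == 0
    n_path = N // 4 if double else N // 2

    # choose the staple width maximizing the number of tile slots
    best = None
    nz = box.n_layers // 2
    for w in [2] + list(range(4, min(box.Lx, n_path + 2) + 1)):
        f = _serpentine(n_path, w)
        ext_x = int(f[:, 0].max()) + 2     # sites span [0, ext_x-1] (+1 return shift)
        ext_y = int(f[:, 1].max()) + 1
        # even strides keep every tile origin on the even-parity sublattice
        sx = ext_x + (ext_x % 2)
        sy = ext_y + (ext_y % 2)
        slots = (box.Lx // sx) * (box.Ly // sy) * nz
        if best is None or slots > best[0]:
            best = (slots, w, sx, sy)
    if best is None or best[0] < M_adj:
        raise ValueError(
            f"infeasible packing: cannot place {M_adj} rings of N={N} in "
            f"box {box.Lx}x{box.Ly}x{box.n_layers} layers at density "
            f"{config.rho_site:.4f}"
        )
    _, w, sx, sy = best
    template = _staple_ring(n_path, w, double)

    nx = box.Lx // sx
    ny = box.Ly // sy
    nz = box.n_layers // 2
    pos = np.empty((M_adj, N, 3), dtype=np.int64)
    k = 0
    for iz in range(nz):
        for iy in range(ny):
            for ix in range(nx):
                if k >= M_adj:
                    break
                origin = np.array([ix * sx, iy * sy, 2 * iz], dtype=np.int64)
                assert origin.sum() % 2 == 0
                pos[k] = template + origin
                k += 1
    assert k == M_adj

    cfg = replace(config, M=M_adj)
    state = MeltState(box=box, pos=pos, config=cfg, tau=0)
    problems = validate_state(state)
    if problems:  # pragma: no cover - construction is checked
        raise RuntimeError("initial state invalid: " + "; ".join(problems[:5]))
    return state
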