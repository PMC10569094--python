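"""Kinetic Monte Carlo dynamics for ring-polymer melts.

Move set
--------
* **Rouse-like**: displace one randomly chosen monomer by one of the 12
  fcc vectors, provided both adjacent bonds remain of length 0 or a,
  site occupancy stays within the stored-length rule (at most two
  *consecutive* monomers of one chain per site), and walls are
  respected.
* **Reptation-like**: slide a stored-length defect (zero bond) one
  position along the chain.  The motion is along an existing bond, so
  it can never cross another strand.
* **Strand crossing**: with probability ``crossing_rate`` per
  elementary step (default 1e-4, i.e. one crossing attempt per 1e4
  elementary kMC steps) a topology-changing move is attempted instead:
  two monomers on nearest-neighbor sites (each the sole occupant of
  its site) exchange positions, passing one filament through the
  other.  Occupancy, wall and parity rules still hold; the proposal is
  symmetric and accepted by Metropolis on the full bending-energy
  change.  Intra-ring crossings create or destroy knots, inter-ring
  crossings catenate or decatenate.

Ordinary local moves conserve topology *exactly*: on the fcc
checkerboard the surface swept by a nearest-neighbor displacement
consists of minimal triangles whose planes no single bond can pierce
transversally (see ``_kernels``), so excluded volume alone enforces
the non-crossing constraint and with ``crossing_rate=0`` every
topological invariant is rigorously constant.

Acceptance is Metropolis on the bending Hamiltonian
``E = kappa_bend * sum_i (1 - cos theta_i)`` (kT units).  Angles
involving a stored-length (zero) bond carry no bending energy by
default (``zero_bond_angle="drop"``, the convention compatible with
the published mean bond lengths); the alternative convention in which
a zero bond transmits the angle between its nonzero neighbors is
available as ``zero_bond_angle="transmit"``.

One elementary kMC step is one attempted monomer move; one MC sweep is
N*M attempts.  Trajectories are bit-reproducible for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np

from . import _kernels
from .lattice import FCC_VECTORS, MeltState, RingConformation, RunConfig, SlitBox, validate_state

__all__ = [
    "MoveProposal", "Trajectory", "bending_energy", "metropolis_accept",
    "propose_local_move", "propose_strand_crossing", "apply_proposal",
    "run_kmc", "build_occupancy",
]


@dataclass
class MoveProposal:
    """A proposed elementary move.

    ``null`` proposals (no legal move for the drawn monomer) are
    counted as rejected attempts.  ``kind="strand_crossing"`` proposals
    are two-monomer swaps: ``swap_with`` names the partner monomer and
    ``swap_target`` its destination (the drawn monomer's old site, in
    the partner's unwrapped frame); they are the only move kind that
    can change a topological invariant.
    """

    kind: Literal["rouse", "reptation", "strand_crossing"]
    ring_id: int
    monomer_index: int
    new_site: np.ndarray | None
    dE: float = 0.0
    null: bool = False
    reason: str = ""
    swap_with: tuple[int, int] | None = None
    swap_target: np.ndarray | None = None


@dataclass
class Trajectory:
    """Sequence of melt snapshots at a fixed stride of MC time.

    ``sites`` is int64 (n_snapshots, M, N, 3), unwrapped grid
    coordinates; ``taus`` the elementary-step clock of each snapshot.
    """

    box: SlitBox
    config: RunConfig
    sites: np.ndarray
    taus: np.ndarray
    counters: dict[str, int] = field(default_factory=dict)
    seed: int = 0

    @property
    def n_snapshots(self) -> int:
        return self.sites.shape[0]

    def state_at(self, k: int) -> MeltState:
        return MeltState(box=self.box, pos=self.sites[k].copy(),
                         config=self.config, tau=int(self.taus[k]))


# ----------------------------------------------------------------------

def bending_energy(ring: RingConformation, kappa: float = 2.0,
                   zero_bond_angle: str = "drop") -> float:
    """Bending energy of one ring in kT units.

    ``kappa * sum_i (1 - cos theta_i)`` summed cyclically over all
    well-defined bond angles.  With the default "drop" convention an
    angle involving a stored-length (zero) bond contributes nothing;
    with "transmit" a zero bond transmits the angle between its
    nonzero neighbors.  Rotation- and translation-invariant, >= 0.
    """
    b = ring.bonds().astype(np.float64)
    nsq = (b ** 2).sum(axis=1)
    if zero_bond_angle == "transmit":
        nz = b[nsq > 0]
        if len(nz) < 2:
            return 0.0
        nxt = np.roll(nz, -1, axis=0)
        cos = (nz * nxt).sum(axis=1) / 2.0
        return float(kappa * (1.0 - cos).sum())
    if zero_bond_angle == "drop":
        nxt = np.roll(b, -1, axis=0)
        both = (nsq > 0) & (np.roll(nsq, -1) > 0)
        cos = (b[both] * nxt[both]).sum(axis=1) / 2.0
        return float(kappa * (1.0 - cos).sum())
    raise ValueError(f"unknown zero_bond_angle convention {zero_bond_angle!r}")


def metropolis_accept(dE: float, rng: np.random.Generator) -> bool:
    """Metropolis rule: accept with probability min(1, exp(-dE))."""
    if dE <= 0.0:
        return True
    return bool(rng.random() < np.exp(-dE))


# ----------------------------------------------------------------------

def build_occupancy(state: MeltState):
    """Dense occupancy index (counts, ring ids, monomer ids) on wrapped sites."""
    box = state.box
    Lzl = box.n_layers
    occ_n = np.zeros((box.Lx, box.Ly, Lzl), dtype=np.uint8)
    occ_r = np.full((box.Lx, box.Ly, Lzl, 2), -1, dtype=np.int32)
    occ_m = np.full((box.Lx, box.Ly, Lzl, 2), -1, dtype=np.int32)
    wrapped = box.wrap(state.pos)
    for r in range(state.M):
        for m in range(state.N):
            x, y, z = wrapped[r, m]
            n = occ_n[x, y, z]
            if n >= 2:
                raise ValueError(f"site ({x},{y},{z}) over-occupied")
            occ_r[x, y, z, n] = r
            occ_m[x, y, z, n] = m
            occ_n[x, y, z] = n + 1
    return occ_n, occ_r, occ_m


def _as_seed(rng) -> int:
    if isinstance(rng, (int, np.integer)):
        return int(rng) % (2 ** 31)
    if isinstance(rng, np.random.Generator):
        return int(rng.integers(2 ** 31))
    raise TypeError("rng must be an int seed or numpy Generator")


def _window_dE(state: MeltState, r: int, i: int, m1: np.ndarray) -> float:
    cfg = state.config
    transmit = cfg.zero_bond_angle == "transmit"
    e1 = _kernels._window_energy(state.pos, r, i, state.N,
                                 np.asarray(m1, dtype=np.int64),
                                 cfg.kappa_bend, transmit)
    e0 = _kernels._window_energy(state.pos, r, i, state.N,
                                 state.pos[r, i].copy(),
                                 cfg.kappa_bend, transmit)
    return float(e1 - e0)


def _wrap_site(box: SlitBox, s: np.ndarray) -> tuple[int, int, int]:
    z = int(s[2]) if box.is_slit else int(s[2]) % box.n_layers
    return int(s[0]) % box.Lx, int(s[1]) % box.Ly, z


def _propose(state: MeltState, rng: np.random.Generator,
             crossing: bool) -> MoveProposal:
    """Draw one move proposal (reference implementation of the kernel
    logic; used by the API and the test suite)."""
    box, N, M = state.box, state.N, state.M
    cfg = state.config
    r = int(rng.integers(M))
    i = int(rng.integers(N))
    m0 = state.pos[r, i]
    occ_n, occ_r, occ_m = build_occupancy(state)

    def null(reason, knd):
        return MoveProposal(kind=knd, ring_id=r, monomer_index=i,
                            new_site=None, null=True, reason=reason)

    if crossing:
        kind = "strand_crossing"
        x0, y0, z0 = _wrap_site(box, m0)
        if occ_n[x0, y0, z0] != 1:
            return null("own site doubly occupied", kind)
        v = FCC_VECTORS[int(rng.integers(12))]
        m1 = m0 + v
        if box.is_slit and not (0 <= m1[2] <= box.H):
            return null("outside slit walls", kind)
        x1, y1, z1 = _wrap_site(box, m1)
        if occ_n[x1, y1, z1] != 1:
            return null("partner site not singly occupied", kind)
        rr, jj = int(occ_r[x1, y1, z1, 0]), int(occ_m[x1, y1, z1, 0])
        if (rr, jj) == (r, i):
            return null("no partner", kind)
        jt = state.pos[rr, jj] - v
        p, q = state.pos[r, (i - 1) % N], state.pos[r, (i + 1) % N]
        jp, jq = state.pos[rr, (jj - 1) % N], state.pos[rr, (jj + 1) % N]
        for t, u in ((m1, p), (m1, q), (jt, jp), (jt, jq)):
            if int(((t - u) ** 2).sum()) not in (0, 2):
                return null("adjacent bond would break", kind)
        kap, transmit = cfg.kappa_bend, cfg.zero_bond_angle == "transmit"
        rings = {r, rr}
        e0 = sum(_kernels.ring_energy(state.pos, k, N, kap, transmit) for k in rings)
        old_i, old_j = state.pos[r, i].copy(), state.pos[rr, jj].copy()
        state.pos[r, i], state.pos[rr, jj] = m1, jt
        e1 = sum(_kernels.ring_energy(state.pos, k, N, kap, transmit) for k in rings)
        state.pos[r, i], state.pos[rr, jj] = old_i, old_j
        return MoveProposal(kind=kind, ring_id=r, monomer_index=i,
                            new_site=m1.copy(), dE=float(e1 - e0),
                            swap_with=(rr, jj), swap_target=jt.copy())

    reptation = rng.random() < cfg.reptation_fraction
    if reptation:
        kind = "reptation"
        d = 1 if rng.random() < 0.5 else -1
        j = (i + d) % N
        if not np.array_equal(state.pos[r, j], m0):
            return null("no stored-length defect on drawn side", kind)
        m1 = state.pos[r, (i - d) % N].copy()
        x, y, z = _wrap_site(box, m1)
        if occ_n[x, y, z] >= 2:
            return null("target site full", kind)
        return MoveProposal(kind=kind, ring_id=r, monomer_index=i,
                            new_site=m1, dE=_window_dE(state, r, i, m1))

    kind = "rouse"
    v = FCC_VECTORS[int(rng.integers(12))]
    m1 = m0 + v
    if box.is_slit and not (0 <= m1[2] <= box.H):
        return null("outside slit walls", kind)
    p = state.pos[r, (i - 1) % N]
    q = state.pos[r, (i + 1) % N]
    if (int(((m1 - p) ** 2).sum()) not in (0, 2)
            or int(((q - m1) ** 2).sum()) not in (0, 2)):
        return null("adjacent bond would break", kind)
    x, y, z = _wrap_site(box, m1)
    nocc = int(occ_n[x, y, z])
    if nocc >= 2:
        return null("target site full", kind)
    if nocc == 1:
        rr, mm = int(occ_r[x, y, z, 0]), int(occ_m[x, y, z, 0])
        if not (rr == r and mm in ((i - 1) % N, (i + 1) % N)):
            return null("double occupancy only for consecutive monomers", kind)
    return MoveProposal(kind=kind, ring_id=r, monomer_index=i, new_site=m1,
                        dE=_window_dE(state, r, i, m1))


def propose_local_move(state: MeltState, rng: np.random.Generator) -> MoveProposal:
    """Propose one topology-preserving move (Rouse-like or
    reptation-like, drawn per ``config.reptation_fraction``).  The
    returned proposal, if applied, keeps every state invariant and
    every topological invariant."""
    return _propose(state, rng, crossing=False)


def propose_strand_crossing(state: MeltState, rng: np.random.Generator) -> MoveProposal:
    """Propose one topology-changing move: a position swap of two
    monomers on nearest-neighbor sites, which passes one filament
    through another (same ring or different rings).  Null when the
    drawn monomer has no crossable geometry."""
    return _propose(state, rng, crossing=True)


def apply_proposal(state: MeltState, prop: MoveProposal) -> bool:
    """Apply a non-null proposal to the state (no Metropolis draw).
    Returns False for null proposals."""
    if prop.null or prop.new_site is None:
        return False
    state.pos[prop.ring_id, prop.monomer_index] = prop.new_site
    if prop.swap_with is not None:
        rr, jj = prop.swap_with
        state.pos[rr, jj] = prop.swap_target
    state.tau += 1
    return True


# ----------------------------------------------------------------------

def run_kmc(state: MeltState, steps: int, snapshot_stride: int | None = None,
            rng: int | np.random.Generator = 0,
            validate_snapshots: bool = False) -> Trajectory:
    """Run the kMC move mixture for ``steps`` elementary steps.

    Snapshots (including the input state) are recorded every
    ``snapshot_stride`` steps (default: only first and last).  The
    input state is mutated in place and left at the final snapshot.
    Bit-reproducible for a fixed seed.
    """
    problems = validate_state(state)
    if problems:
        raise ValueError("refusing to run from invalid state: " + problems[0])
    if steps < 0:
        raise ValueError("steps must be >= 0")
    seed = _as_seed(rng)
    cfg = state.config
    box = state.box
    if snapshot_stride is None or snapshot_stride <= 0:
        snapshot_stride = steps if steps > 0 else 1

    occ_n, occ_r, occ_m = build_occupancy(state)
    _kernels.seed_rng(seed)
    counters = np.zeros(_kernels.N_COUNTERS, dtype=np.int64)

    snaps = [state.pos.copy()]
    taus = [state.tau]
    done = 0
    transmit = cfg.zero_bond_angle == "transmit"
    while done < steps:
        chunk = min(snapshot_stride, steps - done)
        _kernels.run_chunk(state.pos, occ_n, occ_r, occ_m,
                           box.Lx, box.Ly, box.n_layers, box.is_slit,
                           cfg.kappa_bend, cfg.crossing_rate,
                           cfg.reptation_fraction, transmit, chunk, counters)
        done += chunk
        state.tau += chunk
        snaps.append(state.pos.copy())
        taus.append(state.tau)
        if validate_snapshots:
            problems = validate_state(state)
            if problems:  # pragma: no cover - kernel is invariant-preserving
                raise RuntimeError("invalid snapshot: " + problems[0])

    names = ["rouse_attempts", "rouse_accepted", "reptation_attempts",
             "reptation_accepted", "crossing_attempts", "crossing_events",
             "null_or_blocked", "metropolis_rejected"]
    return Trajectory(box=box, config=cfg,
                      sites=np.array(snaps, dtype=np.int64),
                      taus=np.array(taus, dtype=np.int64),
                      counters={n: int(c) for n, c in zip(names, counters)},
                      seed=seed)
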