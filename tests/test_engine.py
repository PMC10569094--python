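"""Kinetic Monte Carlo engine: energies, proposals, Metropolis, runs."""

import numpy as np
import pytest

from ringslit import (RingConformation, RunConfig, bending_energy, init_melt,
                      metropolis_accept, propose_local_move,
                      propose_strand_crossing, run_kmc, validate_state)
from ringslit.engine import apply_proposal
from ringslit.lattice import FCC_VECTORS


def _ring_from_sites(sites):
    s = np.asarray(sites, dtype=np.int64)
    return RingConformation(ring_id=0, sites=s, unwrapped=s.copy())


def test_bending_energy_collinear_angles_contribute_zero():
    # diamond ring: four straight (theta=0) angles and four right-angle
    # corners; only the corners carry energy -> E = 4 kappa exactly
    diamond = _ring_from_sites([(0, 0, 0), (1, 1, 0), (2, 2, 0), (3, 1, 0),
                                (4, 0, 0), (3, -1, 0), (2, -2, 0), (1, -1, 0)])
    assert bending_energy(diamond, kappa=2.0) == pytest.approx(8.0)


def test_bending_energy_right_angle_contribution():
    # evaluate kappa*(1-cos theta) for a single 90-degree angle: with
    # kappa=2 that angle contributes exactly 2.0
    ring = _ring_from_sites([(0, 0, 0), (1, 1, 0), (2, 0, 0), (1, -1, 0)])
    # square with four 90-degree angles -> 4 * kappa * (1 - 0) = 8
    assert bending_energy(ring, kappa=2.0) == pytest.approx(8.0)
    # so one angle contributes 2.0
    assert bending_energy(ring, kappa=2.0) / 4 == pytest.approx(2.0)


def test_bending_energy_rotation_invariance(rng):
    ring = _ring_from_sites([(0, 0, 0), (1, 1, 0), (1, 0, 1), (0, -1, 1)])
    e0 = bending_energy(ring)
    assert e0 > 0
    # lattice rotation: permute axes and flip signs (det +1)
    perm = np.array([[0, 1, 0], [0, 0, 1], [1, 0, 0]])
    rot = _ring_from_sites(ring.unwrapped @ perm.T)
    assert bending_energy(rot) == pytest.approx(e0)


def test_bending_energy_transmit_ignores_stored_length():
    # doubled site: zero bond between collinear nonzero bonds
    ring = _ring_from_sites([(0, 0, 0), (1, 1, 0), (1, 1, 0), (2, 0, 0)])
    e_transmit = bending_energy(ring, kappa=2.0, zero_bond_angle="transmit")
    nodouble = _ring_from_sites([(0, 0, 0), (1, 1, 0), (2, 0, 0)])
    assert e_transmit == pytest.approx(bending_energy(nodouble, kappa=2.0,
                                                      zero_bond_angle="transmit"))
    # drop convention: both angles at the doubled site carry no energy
    e_drop = bending_energy(ring, kappa=2.0, zero_bond_angle="drop")
    assert e_drop < e_transmit


def test_metropolis_zero_and_large_dE(rng):
    assert all(metropolis_accept(0.0, rng) for _ in range(100))
    assert not any(metropolis_accept(50.0, rng) for _ in range(200))


def test_metropolis_ln2_rate(rng):
    n = 40_000
    acc = sum(metropolis_accept(np.log(2.0), rng) for _ in range(n))
    # binomial check against the closed form 1/2
    assert abs(acc / n - 0.5) < 4 * 0.5 / np.sqrt(n)


def test_zero_steps_returns_input_state_only(small_melt):
    state = small_melt.copy()
    traj = run_kmc(state, 0, rng=1)
    assert traj.n_snapshots == 1
    assert np.array_equal(traj.sites[0], state.pos)


def test_run_kmc_deterministic():
    a = init_melt(RunConfig(N=40, M=6, seed=3))
    b = init_melt(RunConfig(N=40, M=6, seed=3))
    ta = run_kmc(a, 200_000, snapshot_stride=50_000, rng=9)
    tb = run_kmc(b, 200_000, snapshot_stride=50_000, rng=9)
    assert np.array_equal(ta.sites, tb.sites)
    assert ta.counters == tb.counters


def test_run_kmc_snapshots_stay_valid(small_melt):
    state = small_melt.copy()
    traj = run_kmc(state, 500_000, snapshot_stride=100_000, rng=4,
                   validate_snapshots=True)
    assert traj.n_snapshots == 6
    assert np.all(np.diff(traj.taus) > 0)


def test_run_kmc_refuses_invalid_state(small_melt):
    bad = small_melt.copy()
    bad.pos[0, 0] += np.array([7, 0, 0])   # breaks parity and bonds
    with pytest.raises(ValueError, match="invalid state"):
        run_kmc(bad, 100, rng=0)


def test_monomer_count_and_density_conserved(small_melt):
    state = small_melt.copy()
    rho0 = state.rho_site
    run_kmc(state, 300_000, rng=5)
    assert state.rho_site == rho0
    assert validate_state(state) == []


def test_local_proposals_keep_invariants(small_melt, rng):
    state = small_melt.copy()
    applied = 0
    for _ in range(400):
        prop = propose_local_move(state, rng)
        if prop.null:
            continue
        apply_proposal(state, prop)
        applied += 1
    assert applied > 0
    assert validate_state(state) == []


def test_local_proposals_are_reversible(small_melt, rng):
    """Detailed balance at the proposal level: every applied move has a
    legal inverse with the same geometric signature."""
    from ringslit.engine import _propose
    state = small_melt.copy()
    checked = 0
    for _ in range(300):
        prop = propose_local_move(state, rng)
        if prop.null:
            continue
        old = state.pos[prop.ring_id, prop.monomer_index].copy()
        apply_proposal(state, prop)
        # the reverse displacement must again be a legal proposal target
        rev = old - state.pos[prop.ring_id, prop.monomer_index]
        assert int((rev ** 2).sum()) in (0, 2)
        # moving back restores a valid state
        state.pos[prop.ring_id, prop.monomer_index] = old
        assert validate_state(state) == []
        checked += 1
    assert checked > 0


def test_strand_crossing_swap_keeps_invariants(entangled_melt, rng):
    state = entangled_melt.copy()
    applied = 0
    for _ in range(3000):
        prop = propose_strand_crossing(state, rng)
        if prop.null:
            continue
        apply_proposal(state, prop)
        assert validate_state(state) == []
        applied += 1
        if applied >= 5:
            break
    assert applied > 0


def test_crossing_events_occur_when_enabled(entangled_melt):
    state = entangled_melt.copy()
    traj = run_kmc(state, 3_000_000, rng=21)
    assert traj.counters["crossing_attempts"] > 0
    assert traj.counters["crossing_events"] > 0


def test_mean_bond_length_insensitive_to_confinement():
    """The stored-length density is a local equilibrium property: bulk
    and tight-slit values differ by only a few percent."""
    vals = {}
    for H in (None, 2.12):
        state = init_melt(RunConfig(N=80, M=12, H_over_a=H, seed=2,
                                    crossing_rate=1e-2))
        run_kmc(state, 15_000_000, rng=13)
        b = np.roll(state.pos, -1, axis=1) - state.pos
        vals[H] = ((b ** 2).sum(axis=2) > 0).mean()
    assert abs(vals[2.12] - vals[None]) / vals[None] < 0.06
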