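"""fcc geometry, box construction and state validation."""

import numpy as np
import pytest

from ringslit import (FCC_VECTORS, MeltState, RunConfig, SlitBox,
                      fcc_neighbor_vectors, init_melt, validate_state)
from ringslit.lattice import GRID_PER_A


def test_fcc_neighbor_shell():
    v = fcc_neighbor_vectors()
    assert v.shape == (12, 3)
    # all at the nearest-neighbor distance a (= sqrt(2) grid units)
    assert np.all((v ** 2).sum(axis=1) == 2)
    # closed under negation
    vset = {tuple(x) for x in v}
    assert {tuple(-x) for x in v} == vset
    # no duplicates
    assert len(vset) == 12


def test_init_melt_site_count_matches_requested_density():
    state = init_melt(RunConfig(N=320, M=10, rho_site=5 / 6, H_over_a=2.12))
    assert state.box.site_count == 3840          # N*M/rho exactly
    assert state.M == 10
    assert state.rho_site == pytest.approx(5 / 6, rel=1e-9)


def test_init_melt_rejects_degenerate_slit():
    with pytest.raises(ValueError):
        init_melt(RunConfig(N=40, M=4, H_over_a=0.3))   # below 2 layers


def test_init_melt_deterministic():
    a = init_melt(RunConfig(N=80, M=8, seed=5))
    b = init_melt(RunConfig(N=80, M=8, seed=5))
    assert np.array_equal(a.pos, b.pos)
    assert a.box == b.box


@pytest.mark.parametrize("kw", [
    dict(N=320, M=10, H_over_a=2.12),
    dict(N=320, M=10),
    dict(N=80, M=19, H_over_a=2.12),
    dict(N=40, M=24),
])
def test_initial_states_are_valid(kw):
    state = init_melt(RunConfig(seed=1, **kw))
    assert validate_state(state) == []
    # checkerboard parity everywhere
    assert np.all(state.pos.sum(axis=2) % 2 == 0)


def test_table_slit_heights_map_to_integer_grid_gaps():
    # published slit heights in units a correspond to integer grid gaps
    for h_a, grid in [(2.12, 3), (3.53, 5), (4.95, 7), (6.36, 9),
                      (7.78, 11), (10.61, 15), (20.51, 29)]:
        assert RunConfig(N=8, M=1, H_over_a=h_a).H_grid == grid


def test_validator_flags_planted_violations():
    state = init_melt(RunConfig(N=40, M=4, H_over_a=2.12, seed=2))
    # three consecutive monomers on one site
    bad = state.copy()
    bad.pos[0, 2] = bad.pos[0, 0]
    bad.pos[0, 1] = bad.pos[0, 0]
    msgs = validate_state(bad)
    assert any("three consecutive" in m for m in msgs)
    # monomer beyond the wall
    bad2 = state.copy()
    bad2.pos[1, 5, 2] = bad2.box.H + 2
    msgs = validate_state(bad2)
    assert any("outside slit" in m for m in msgs)
    # two consecutive monomers on one site is legal
    ok = state.copy()   # staples double every site already
    assert validate_state(ok) == []


def test_wrap_roundtrip_xy_only():
    box = SlitBox(Lx=8, Ly=10, H=3)
    p = np.array([[9, -3, 2], [7, 11, 0]])
    w = box.wrap(p)
    assert np.all((w[:, 0] >= 0) & (w[:, 0] < 8))
    assert np.all((w[:, 1] >= 0) & (w[:, 1] < 10))
    assert np.all(w[:, 2] == p[:, 2])            # z never wrapped in a slit
    # wrapping preserves parity because box sides are even
    assert np.all(w.sum(axis=1) % 2 == p.sum(axis=1) % 2)


def test_infeasible_packing_raises():
    with pytest.raises(ValueError, match="infeasible"):
        init_melt(RunConfig(N=320, M=10, rho_site=1.9, H_over_a=2.12))
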