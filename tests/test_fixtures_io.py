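"""Fixture certificates, trajectory round-trips, config parsing."""

import json

import numpy as np
import pytest

from ringslit import RunConfig, init_melt, run_kmc
from ringslit.fixtures import FIXTURE_NAMES, FixtureSpec, make_fixture
from ringslit.io import (export_xyz, read_config, read_trajectory,
                         write_config, write_trajectory)
from ringslit.topology import (gauss_linking_number, knot_classify,
                               pair_link_classify, triplet_link_classify)


def test_every_fixture_certificate_verifies():
    """All named fixtures reproduce their certified invariants."""
    for name in ("unknot", "trefoil", "figure_eight", "hopf", "whitehead",
                 "borromean"):
        polys, cert = make_fixture(FixtureSpec(name=name))
        # GLN matrix
        n = len(polys)
        for i in range(n):
            for j in range(i + 1, n):
                g = gauss_linking_number(polys[i], polys[j])
                assert abs(g) == abs(cert["gln"][i][j]), name
        # knot determinants
        for poly, expect in zip(polys, cert["knots"]):
            rec = knot_classify(poly, rng=1)
            assert rec.det == expect["det"], name
            assert rec.label == expect["label"], name
        # pair/triplet classes
        if "pair" in cert:
            rec = pair_link_classify(polys[0], polys[1], rng=2)
            assert rec.C == cert["pair"]["C"], name
            assert rec.chi == cert["pair"]["chi"], name
        if cert.get("triplet"):
            precs = [pair_link_classify(polys[i], polys[j], rng=3,
                                        ids=(i, j))
                     for i, j in ((0, 1), (0, 2), (1, 2))]
            trec = triplet_link_classify(*[p for p in polys], precs, rng=4)
            assert trec.link_class == cert["triplet"], name


def test_unknown_fixture_name_rejected():
    with pytest.raises(ValueError, match="unknown fixture"):
        make_fixture(FixtureSpec(name="granny"))


def test_fixture_determinism():
    a, _ = make_fixture(FixtureSpec(name="random_ring", seed=9))
    b, _ = make_fixture(FixtureSpec(name="random_ring", seed=9))
    assert np.array_equal(a[0].vertices, b[0].vertices)


def test_trajectory_roundtrip(tmp_path, small_melt):
    state = small_melt.copy()
    traj = run_kmc(state, 120_000, snapshot_stride=40_000, rng=2)
    p = tmp_path / "t.h5"
    write_trajectory(traj, p)
    back = read_trajectory(p)
    assert np.array_equal(back.sites, traj.sites)
    assert np.array_equal(back.taus, traj.taus)
    assert back.config == traj.config
    assert back.box == traj.box
    assert back.counters == traj.counters


def test_truncated_trajectory_errors(tmp_path, small_melt):
    import h5py
    state = small_melt.copy()
    traj = run_kmc(state, 50_000, rng=3)
    p = tmp_path / "t.h5"
    write_trajectory(traj, p)
    with h5py.File(p, "a") as f:
        del f["taus"]
    with pytest.raises(ValueError, match="truncated"):
        read_trajectory(p)


def test_schema_mismatch_errors(tmp_path, small_melt):
    import h5py
    state = small_melt.copy()
    traj = run_kmc(state, 50_000, rng=3)
    p = tmp_path / "t.h5"
    write_trajectory(traj, p)
    with h5py.File(p, "a") as f:
        f.attrs["schema_version"] = 99
    with pytest.raises(ValueError, match="schema"):
        read_trajectory(p)


def test_xyz_export_line_counts(tmp_path, small_melt):
    state = small_melt.copy()
    traj = run_kmc(state, 80_000, snapshot_stride=40_000, rng=4)
    p = tmp_path / "t.xyz"
    export_xyz(traj, p)
    lines = p.read_text().splitlines()
    S = traj.n_snapshots
    M, N = state.M, state.N
    assert len(lines) == S * (M * N + 2)
    # atom lines carry ring id and monomer index
    first_atom = lines[2].split()
    assert len(first_atom) == 6


def test_config_roundtrip(tmp_path):
    cfg = RunConfig(N=64, M=5, H_over_a=3.53, steps=1000, seed=77)
    p = tmp_path / "c.json"
    write_config(cfg, p)
    assert read_config(p) == cfg


def test_config_toml(tmp_path):
    p = tmp_path / "c.toml"
    p.write_text('N = 32\nM = 4\nkappa_bend = 2.0\nsteps = 10\nseed = 5\n')
    cfg = read_config(p)
    assert cfg.N == 32 and cfg.M == 4 and cfg.H_over_a is None
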