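"""Conformational observables: identities, closed forms, estimators."""

import numpy as np
import pytest

from ringslit import RunConfig, init_melt, run_kmc
from ringslit.fixtures import gaussian_rings
from ringslit.lattice import GRID_PER_A
from ringslit.observables import (bond_vector_correlation, contact_probability,
                                  ensemble_gyration, gyration_metrics,
                                  knot_statistics, linking_degree_stats,
                                  local_exponent, msd_g2, neighbor_stats,
                                  shape_ratios_and_scaling, xi_effective)
from ringslit.topology import KnotRecord


def test_gyration_trace_identity(entangled_melt):
    for i in range(entangled_melt.M):
        g = gyration_metrics(entangled_melt.ring(i))
        assert g.rg2 == pytest.approx(g.eigenvalues.sum(), rel=1e-12)
        assert g.rg2 == pytest.approx(g.rg2_perp + g.rg2_par, rel=1e-12)
        assert np.all(g.eigenvalues >= -1e-12)
        assert np.all(np.diff(g.eigenvalues) <= 1e-12)   # descending


def test_planar_ring_has_zero_transverse_extent():
    # flat square in the z=0 plane
    sq = np.array([(0, 0, 0), (4, 0, 0), (4, 4, 0), (0, 4, 0)], np.int64)
    g = gyration_metrics(sq)
    assert g.rg2_perp == pytest.approx(0.0, abs=1e-12)
    assert g.eigenvalues[2] == pytest.approx(0.0, abs=1e-12)


def test_regular_polygon_closed_form():
    # regular N-gon of circumradius R: Rg^2 = R^2 exactly (all vertices
    # at distance R from the center), computed by direct vertex sum
    N, R = 360, 70.0
    t = np.linspace(0, 2 * np.pi, N + 1)[:-1]
    # work in float directly through the raw-array interface
    poly = np.stack([R * np.cos(t) * GRID_PER_A, R * np.sin(t) * GRID_PER_A,
                     np.zeros_like(t)], axis=1)
    g = gyration_metrics(poly)
    assert g.rg2 == pytest.approx(R * R, rel=1e-3)


def test_ensemble_gyration_matches_single_ring(entangled_melt):
    snaps = entangled_melt.pos[None]
    ens = ensemble_gyration(snaps)
    g0 = gyration_metrics(entangled_melt.ring(0))
    assert ens["rg2"][0] == pytest.approx(g0.rg2, rel=1e-12)
    assert np.allclose(ens["eig"][0], g0.eigenvalues)


def test_affine_flattening_monotonicity(rng):
    """Compressing an ideal-ring ensemble in z drives Rg2_perp down,
    Rg2_par (unchanged here) relatively up, and the lambda2/lambda3
    ratio up like 1/s^2: the confinement trend before any simulation."""
    base = gaussian_rings(200, 64, rng)
    perp = []
    ratio23 = []
    for s in (1.0, 0.5, 0.25):
        ens = base.copy()
        ens[..., 2] *= s
        d = ens - ens.mean(axis=1, keepdims=True)
        Q = np.einsum("rna,rnb->rab", d, d) / ens.shape[1]
        ev = np.linalg.eigvalsh(Q)[..., ::-1]
        perp.append(Q[:, 2, 2].mean())
        ratio23.append(ev[:, 1].mean() / ev[:, 2].mean())
    assert perp[0] > perp[1] > perp[2]
    assert ratio23[0] < ratio23[1] < ratio23[2]
    # ratio grows ~ s^-2 under strong compression
    assert ratio23[2] / ratio23[1] == pytest.approx(4.0, rel=0.35)


def test_shape_ratio_scaling_requires_window():
    out = shape_ratios_and_scaling({1.5: np.ones((10, 3))})
    assert out["alpha"] is None


def test_shape_ratio_alpha_on_synthetic_power_law():
    per_H = {}
    for h in (0.2, 0.35, 0.5, 0.7):
        lam3 = h ** 2
        per_H[h] = np.tile([4.0, 2.0, lam3], (50, 1))
    out = shape_ratios_and_scaling(per_H)
    assert out["alpha"] == pytest.approx(2.0, rel=1e-6)


def test_bond_correlation_normalized_at_zero(entangled_melt):
    c = bond_vector_correlation(entangled_melt.pos[None])
    assert c.y[0] == pytest.approx(1.0, rel=1e-9)


def test_bond_correlation_planar_ring_has_no_transverse_part():
    sq = np.array([[(0, 0, 0), (1, 1, 0), (2, 0, 0), (1, -1, 0)]], np.int64)
    c = bond_vector_correlation(sq[None], component="transverse")
    assert np.allclose(np.nan_to_num(c.y), 0.0)


def test_bond_correlation_rigid_polygon_cosine():
    # rigid planar hexagon: correlation at separation k is cos(2 pi k/6)
    t = np.linspace(0, 2 * np.pi, 7)[:-1]
    hexagon = np.stack([10 * np.cos(t), 10 * np.sin(t), np.zeros_like(t)], 1)
    c = bond_vector_correlation(hexagon[None, None])
    for k in range(len(c.x)):
        assert c.y[k] == pytest.approx(np.cos(2 * np.pi * k / 6), abs=1e-9)


def test_contact_probability_identities(entangled_melt):
    pc = contact_probability(entangled_melt.pos[None])
    # bonded neighbors are always within a
    assert pc.y[0] == pytest.approx(1.0)
    # ring symmetry p(l) = p(N - l): the curve only covers l <= N/2,
    # so check via the full distance matrix on one ring
    r = entangled_melt.pos[0].astype(float)
    N = len(r)
    for l in (3, 7, 11):
        d1 = ((np.roll(r, -l, axis=0) - r) ** 2).sum(1)
        d2 = ((np.roll(r, -(N - l), axis=0) - r) ** 2).sum(1)
        assert np.sort(d1).tolist() == pytest.approx(np.sort(d2).tolist())


def test_local_exponent_recovers_power_law():
    xi = np.geomspace(1.0, 1e3, 200)
    y = 7.3 * xi ** -1.5
    g = local_exponent(xi, y, n_bins=30)
    assert np.allclose(g.y, 1.5, atol=1e-3)


def test_xi_effective_symmetry():
    L = 100.0
    l = np.array([10.0, 90.0])
    xi = xi_effective(l, L)
    assert xi[0] == pytest.approx(xi[1])


def test_knot_statistics_arithmetic():
    recs = [KnotRecord(ring_id=i, K=3, det=3, label="3_1") for i in range(13)]
    recs += [KnotRecord(ring_id=i, K=0, det=1, label="unknot")
             for i in range(13, 100)]
    ks = knot_statistics(recs)
    assert ks["P_knot"] == pytest.approx(0.13)
    # spectrum normalization: P(K=0) + sum_{K>=3} P(K) = 1
    total = sum(p for p, _ in ks["spectrum"].values())
    assert total == pytest.approx(1.0)
    assert ks["spectrum"][0][0] == pytest.approx(1 - ks["P_knot"])
    # binomial error
    assert ks["P_knot_err"] == pytest.approx(np.sqrt(0.13 * 0.87 / 100))


def test_all_unknots_give_zero_knotting():
    recs = [KnotRecord(ring_id=i, K=0, det=1, label="unknot") for i in range(5)]
    assert knot_statistics(recs)["P_knot"] == 0.0


def test_neighbor_relation_symmetric_and_cutoff(entangled_melt):
    g = ensemble_gyration(entangled_melt.pos)
    ns = neighbor_stats(entangled_melt, g["rg2"].mean())
    assert ns.rho_ring.sum() % 2 == 0          # symmetric pair counting
    assert np.all(ns.d_cm_neighbors < ns.meta["cutoff_a"])


def test_single_ring_has_no_neighbors():
    state = init_melt(RunConfig(N=40, M=1, rho_site=0.1, seed=4))
    ns = neighbor_stats(state, 5.0)
    assert ns.rho_ring.tolist() == [0]


def test_g2_zero_lag_and_translation_invariance(small_melt):
    state = small_melt.copy()
    traj = run_kmc(state, 400_000, snapshot_stride=40_000, rng=6)
    out = msd_g2(traj)
    assert np.all(out["g2"] >= 0)
    # rigid translation of every ring leaves g2 unchanged (CM frame)
    shifted = traj.sites + np.array([10, 4, 0])
    class T:
        sites = shifted
        taus = traj.taus
    out2 = msd_g2(T)
    assert np.allclose(out["g2"], out2["g2"])


def test_g2_plateau_level_for_iid_snapshots(rng):
    """Independent equilibrium snapshots: the CM-frame displacement
    variance saturates at 2<Rg^2> (decorrelated-positions oracle)."""
    rings = gaussian_rings(400, 32, rng)      # (S*M) independent rings
    sites = rings.reshape(100, 4, 32, 3) * GRID_PER_A
    class T:
        taus = np.arange(100)
        sites_arr = sites
    T.sites = sites
    out = msd_g2(T)
    d = rings - rings.mean(axis=1, keepdims=True)
    rg2 = (d ** 2).sum(-1).mean(-1).mean()
    # compare over well-sampled mid-range lags (the largest lags are
    # estimated from a single snapshot pair)
    mid = (out["tau"] >= 5) & (out["tau"] <= 60)
    assert out["g2"][mid].mean() == pytest.approx(2 * rg2, rel=0.08)


def test_distributions_normalize():
    rng = np.random.default_rng(3)
    x = rng.normal(size=20_000)
    hist, edges = np.histogram(x, bins=60, density=True)
    centers = 0.5 * (edges[1:] + edges[:-1])
    assert np.trapezoid(hist, centers) == pytest.approx(1.0, abs=1e-2)
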