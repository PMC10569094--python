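"""Conformational and network observables for ring melts.

All lengths are reported in units of the fcc step ``a`` (grid
coordinates are divided by sqrt(2)).  The slit normal is z, so
"transverse" (perpendicular) components are z-projections and
"parallel" components live in the xy plane.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .lattice import GRID_PER_A, MeltState

__all__ = [
    "GyrationResult", "CorrelationCurve", "NetworkStats",
    "gyration_metrics", "ensemble_gyration", "shape_ratios_and_scaling",
    "bond_vector_correlation", "contact_probability", "local_exponent",
    "knot_statistics", "neighbor_stats", "linking_degree_stats", "msd_g2",
    "xi_effective",
]


@dataclass
class GyrationResult:
    """Gyration tensor summary of one ring (units of a^2)."""
    Q: np.ndarray               # 3x3 symmetric
    eigenvalues: np.ndarray     # descending lambda1^2 >= lambda2^2 >= lambda3^2
    rg2: float
    rg2_perp: float             # zz component
    rg2_par: float              # xx + yy


@dataclass
class CorrelationCurve:
    """A binned or per-separation curve with sample counts."""
    x: np.ndarray
    y: np.ndarray
    err: np.ndarray
    n: np.ndarray
    component: str = "full"
    meta: dict = field(default_factory=dict)


@dataclass
class NetworkStats:
    """Per-ring network quantities of one snapshot ensemble."""
    rho_ring: np.ndarray        # neighbors per ring
    d_cm_neighbors: np.ndarray  # CM distances of neighbor pairs (units a)
    mean_rho: float = 0.0
    meta: dict = field(default_factory=dict)


def _coords_a(x) -> np.ndarray:
    """Grid coordinates -> units of a."""
    return np.asarray(x, dtype=np.float64) / GRID_PER_A


# ----------------------------------------------------------------------
# gyration
# ----------------------------------------------------------------------

def gyration_metrics(ring) -> GyrationResult:
    """Gyration tensor Q, descending eigenvalues, and the
    transverse/parallel decomposition of Rg^2 for one ring.

    Accepts a RingConformation (uses unwrapped coordinates) or a raw
    (N, 3) coordinate array in grid units.
    """
    v = getattr(ring, "unwrapped", ring)
    r = _coords_a(v)
    c = r.mean(axis=0)
    d = r - c
    Q = d.T @ d / len(r)
    ev = np.linalg.eigvalsh(Q)[::-1]
    return GyrationResult(Q=Q, eigenvalues=ev, rg2=float(np.trace(Q)),
                          rg2_perp=float(Q[2, 2]),
                          rg2_par=float(Q[0, 0] + Q[1, 1]))


def ensemble_gyration(snapshots: np.ndarray) -> dict:
    """Vectorized gyration statistics over (S, M, N, 3) grid coords.

    Returns per-ring arrays (flattened over snapshots) of rg2,
    rg2_perp, rg2_par and the three descending eigenvalues.
    """
    r = _coords_a(snapshots)
    if r.ndim == 3:
        r = r[None]
    S, M, N, _ = r.shape
    d = r - r.mean(axis=2, keepdims=True)
    Q = np.einsum("smna,smnb->smab", d, d) / N
    ev = np.linalg.eigvalsh(Q)[..., ::-1]
    rg2 = np.trace(Q, axis1=-2, axis2=-1)
    return {
        "rg2": rg2.reshape(-1),
        "rg2_perp": Q[..., 2, 2].reshape(-1),
        "rg2_par": (Q[..., 0, 0] + Q[..., 1, 1]).reshape(-1),
        "eig": ev.reshape(-1, 3),
    }


def shape_ratios_and_scaling(per_H: dict) -> dict:
    """Eigenvalue-ratio curves vs confinement and the flattening
    exponent alpha.

    ``per_H`` maps H_hat (H over the bulk root-mean-square gyration
    radius; None or inf for bulk) to an (n, 3) array of descending
    eigenvalues.  alpha is fitted by log-log least squares of the two
    ratios against lambda3^2 over the strong-confinement window
    H_hat <= 0.7 and reported as their mean; with fewer than 2 points
    in the window alpha is None (curves only).
    """
    hs, r12, r13, r23 = [], [], [], []
    for h, eig in per_H.items():
        eig = np.asarray(eig)
        m = eig.mean(axis=0)
        if h is None or not np.isfinite(h):
            continue
        hs.append(h)
        r12.append(m[0] / m[1])
        r13.append(m[0] / m[2])
        r23.append(m[1] / m[2])
    hs = np.array(hs)
    out = {"H_hat": hs, "l1_over_l2": np.array(r12),
           "l1_over_l3": np.array(r13), "l2_over_l3": np.array(r23)}
    win = hs <= 0.7
    if win.sum() >= 2:
        alphas = []
        for curve in (out["l1_over_l3"], out["l2_over_l3"]):
            s, _ = np.polyfit(np.log(hs[win]), np.log(curve[win]), 1)
            alphas.append(-s)
        out["alpha"] = float(np.mean(alphas))
    else:
        out["alpha"] = None
    return out


# ----------------------------------------------------------------------
# bond correlations
# ----------------------------------------------------------------------

def bond_vector_correlation(snapshots: np.ndarray, component: str = "full",
                            H_grid: int | None = None) -> CorrelationCurve:
    """Normalized bond-vector correlation vs contour separation.

    ``<b_i . b_{i+l}> / <b^2>`` computed cyclically over all rings and
    snapshots; products involving zero-length (stored-length) bonds
    are skipped and the normalization uses only contributing pairs.
    ``component``: "full", "parallel" (xy) or "transverse" (z).  The
    abscissa is the separation in bonds; ``meta`` carries the mean
    bond length so callers can rescale to contour length, and l/H
    when the slit height is given.
    """
    r = np.asarray(snapshots, dtype=np.float64)
    if r.ndim == 3:
        r = r[None]
    b = (np.roll(r, -1, axis=2) - r) / GRID_PER_A
    nz = (b ** 2).sum(-1) > 1e-12
    if component == "parallel":
        bc = b[..., :2]
    elif component == "transverse":
        bc = b[..., 2:]
    elif component == "full":
        bc = b
    else:
        raise ValueError("component must be full, parallel or transverse")
    N = b.shape[2]
    ls = np.arange(N // 2 + 1)
    y = np.empty(len(ls))
    err = np.empty(len(ls))
    cnt = np.empty(len(ls), dtype=np.int64)
    norm = (bc[nz] ** 2).sum(-1).mean() if nz.any() else 1.0
    if norm == 0.0:
        norm = 1.0   # e.g. transverse component of a planar ring
    for k, l in enumerate(ls):
        b2 = np.roll(bc, -l, axis=2)
        m = nz & np.roll(nz, -l, axis=2)
        prods = (bc * b2).sum(-1)[m] / norm
        y[k] = prods.mean()
        err[k] = prods.std() / np.sqrt(max(len(prods), 1))
        cnt[k] = len(prods)
    meta = {"mean_bond_a": float(np.sqrt(norm)) if component == "full" else None,
            "component": component}
    if H_grid is not None:
        meta["l_over_H"] = ls / (H_grid / GRID_PER_A)
    return CorrelationCurve(x=ls.astype(float), y=y, err=err, n=cnt,
                            component=component, meta=meta)


# ----------------------------------------------------------------------
# contact probability
# ----------------------------------------------------------------------

def xi_effective(l: np.ndarray, L: float) -> np.ndarray:
    """Ring finite-size reduced contour variable xi = l (L - l) / L."""
    l = np.asarray(l, dtype=float)
    return l * (L - l) / L


def contact_probability(snapshots: np.ndarray, r_c_a: float = 1.0) -> CorrelationCurve:
    """Mean intra-ring contact probability vs contour separation.

    Two monomers are in contact when their Euclidean distance is at
    most ``r_c_a`` (units of a; the default a captures same-site and
    nearest-neighbor pairs on the lattice).  Cyclic in the separation:
    p(l) = p(N - l).
    """
    r = np.asarray(snapshots, dtype=np.float64)
    if r.ndim == 3:
        r = r[None]
    S, M, N, _ = r.shape
    cut2 = (r_c_a * GRID_PER_A) ** 2 + 1e-9   # compare in grid units
    ls = np.arange(1, N // 2 + 1)
    y = np.empty(len(ls))
    err = np.empty(len(ls))
    cnt = np.empty(len(ls), dtype=np.int64)
    for k, l in enumerate(ls):
        d = np.roll(r, -l, axis=2) - r
        hit = ((d ** 2).sum(-1) <= cut2)
        y[k] = hit.mean()
        n = hit.size
        err[k] = np.sqrt(max(y[k] * (1 - y[k]), 1e-300) / n)
        cnt[k] = n
    return CorrelationCurve(x=ls.astype(float), y=y, err=err, n=cnt,
                            component="contact", meta={"r_c_a": r_c_a})


def local_exponent(x: np.ndarray, y: np.ndarray, n_bins: int = 20) -> CorrelationCurve:
    """Local differential exponent gamma = -dlog y / dlog x by centered
    differences on log-binned data."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    good = (x > 0) & (y > 0)
    x, y = x[good], y[good]
    lo, hi = np.log(x.min()), np.log(x.max())
    edges = np.exp(np.linspace(lo, hi, n_bins + 1))
    xs, ys = [], []
    for k in range(n_bins):
        m = (x >= edges[k]) & (x < edges[k + 1] if k < n_bins - 1 else x <= edges[k + 1])
        if m.any():
            xs.append(np.exp(np.log(x[m]).mean()))
            ys.append(np.exp(np.log(y[m]).mean()))
    xs, ys = np.array(xs), np.array(ys)
    if len(xs) < 3:
        return CorrelationCurve(x=xs, y=np.full_like(xs, np.nan),
                                err=np.full_like(xs, np.nan),
                                n=np.zeros(len(xs), np.int64), component="gamma")
    lx, ly = np.log(xs), np.log(ys)
    g = np.empty(len(xs))
    g[1:-1] = -(ly[2:] - ly[:-2]) / (lx[2:] - lx[:-2])
    g[0] = -(ly[1] - ly[0]) / (lx[1] - lx[0])
    g[-1] = -(ly[-1] - ly[-2]) / (lx[-1] - lx[-2])
    return CorrelationCurve(x=xs, y=g, err=np.zeros_like(g),
                            n=np.ones(len(g), np.int64), component="gamma")


# ----------------------------------------------------------------------
# knot and network statistics
# ----------------------------------------------------------------------

def knot_statistics(knot_records) -> dict:
    """Cumulative knotting probability and the spectrum by crossing
    number K, with binomial error bars.

    ``P(K=0) = 1 - P_knot`` and the spectrum sums to one.
    """
    n = len(knot_records)
    if n == 0:
        raise ValueError("no knot records")
    ks = np.array([0 if r.label == "unknot" else max(r.K, 3)
                   for r in knot_records])
    n_knot = int((ks > 0).sum())
    p = n_knot / n
    spectrum = {}
    for k in sorted(set(ks)):
        cnt = int((ks == k).sum())
        pk = cnt / n
        spectrum[int(k)] = (pk, float(np.sqrt(pk * (1 - pk) / n)))
    return {
        "P_knot": p,
        "P_knot_err": float(np.sqrt(p * (1 - p) / n)),
        "n_rings": n,
        "spectrum": spectrum,
    }


def neighbor_stats(state: MeltState, rg2_mean_a2: float) -> NetworkStats:
    """Neighbor count per ring: rings whose center-of-mass distance
    (minimum image in the periodic directions) is below twice the
    root-mean-square gyration radius of the analyzed system."""
    box = state.box
    cms = state.pos.mean(axis=1) / GRID_PER_A
    L = np.array([box.Lx, box.Ly, 0 if box.is_slit else box.Lz],
                 dtype=float) / GRID_PER_A
    M = state.M
    cut = 2.0 * np.sqrt(rg2_mean_a2)
    rho = np.zeros(M, dtype=np.int64)
    dists = []
    for i in range(M):
        for j in range(i + 1, M):
            d = cms[i] - cms[j]
            for ax in range(3):
                if L[ax] > 0:
                    d[ax] -= L[ax] * round(d[ax] / L[ax])
            dist = float(np.linalg.norm(d))
            if dist < cut:
                rho[i] += 1
                rho[j] += 1
                dists.append(dist)
    return NetworkStats(rho_ring=rho, d_cm_neighbors=np.array(dists),
                        mean_rho=float(rho.mean()),
                        meta={"cutoff_a": cut, "rg2_mean_a2": rg2_mean_a2})


def linking_degree_stats(C: np.ndarray, chi: np.ndarray, N: int) -> dict:
    """Linking degree LD_i = sum_j chi_ij C_ij, its mean, the scaled
    distribution variable X = LD / <LD>, and the entanglement length
    N_e = N / <LD> (unbounded when the melt is unlinked)."""
    C = np.asarray(C)
    chi = np.asarray(chi)
    if not np.allclose(C, C.T) or not np.allclose(chi, chi.T):
        raise ValueError("C and chi must be symmetric")
    ld = (chi * C).sum(axis=1)
    mean = float(ld.mean())
    out = {"LD": ld, "mean_LD": mean}
    if mean > 0:
        out["N_e"] = N / mean
        out["X"] = ld / mean
    else:
        out["N_e"] = np.inf
        out["X"] = np.zeros_like(ld)
        out["flag"] = "unlinked melt: N_e unbounded"
    return out


# ----------------------------------------------------------------------
# dynamics: g2
# ----------------------------------------------------------------------

def msd_g2(traj, max_lags: int = 64, plateau_slope: float = 0.05) -> dict:
    """Monomer mean-square displacement in each ring's center-of-mass
    frame vs MC time lag, with a plateau detector.

    The plateau (log-slope of the last decade below
    ``plateau_slope``) certifies equilibration; the pre-plateau window
    is the recommended discard.  For i.i.d. equilibrium snapshots the
    plateau level is 2<Rg^2>.
    """
    sites = traj.sites if hasattr(traj, "sites") else np.asarray(traj)
    taus = traj.taus if hasattr(traj, "taus") else np.arange(len(sites))
    S = sites.shape[0]
    if S < 2:
        raise ValueError("need at least 2 snapshots")
    r = _coords_a(sites)
    cm = r.mean(axis=2, keepdims=True)
    rel = r - cm
    lags = np.unique(np.round(np.geomspace(1, S - 1, min(max_lags, S - 1))
                              ).astype(int))
    g2 = np.empty(len(lags))
    for k, lag in enumerate(lags):
        d = rel[lag:] - rel[:-lag]
        g2[k] = (d ** 2).sum(-1).mean()
    tau_lag = (np.asarray(taus)[lags] - taus[0]).astype(float)
    out = {"tau": tau_lag, "g2": g2}
    if len(lags) >= 4:
        tail = tau_lag >= tau_lag[-1] / 10.0
        if tail.sum() >= 2 and np.all(g2[tail] > 0):
            slope = np.polyfit(np.log(tau_lag[tail]), np.log(g2[tail]), 1)[0]
            out["plateau"] = bool(slope < plateau_slope)
            out["tail_log_slope"] = float(slope)
            if out["plateau"]:
                below = g2 < 0.75 * g2[tail].mean()
                out["discard_before_tau"] = float(tau_lag[below][-1]) if below.any() else 0.0
    return out
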