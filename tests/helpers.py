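"""Shared test utilities: independent oracles kept deliberately simple
and separate from the implementation paths they check."""

import numpy as np


def rotation_from_seed(rng: np.random.Generator) -> np.ndarray:
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])


def gln_projection_oracle(c1, c2, rng, n_dirs=20):
    """Brute-force Gauss linking number: half the signed sum of
    inter-curve crossings in a generic projection, repeated over many
    random directions; all directions must agree."""
    c1 = np.asarray(c1, dtype=float)
    c2 = np.asarray(c2, dtype=float)
    results = []
    tries = 0
    while len(results) < n_dirs and tries < 10 * n_dirs:
        tries += 1
        R = rotation_from_seed(rng)
        a = c1 @ R.T
        b = c2 @ R.T
        val = _signed_crossing_sum(a, b)
        if val is None:
            continue  # degenerate projection, retry
        results.append(val)
    assert results, "no generic projection found"
    assert len(set(results)) == 1, f"projection disagreement: {set(results)}"
    return results[0]


def _signed_crossing_sum(a, b, eps=1e-9):
    e1a, e1b = a, np.roll(a, -1, axis=0)
    e2a, e2b = b, np.roll(b, -1, axis=0)
    total = 0
    for i in range(len(a)):
        p0, p1 = e1a[i], e1b[i]
        d1 = p1 - p0
        for j in range(len(b)):
            q0, q1 = e2a[j], e2b[j]
            d2 = q1 - q0
            den = d1[0] * d2[1] - d1[1] * d2[0]
            if abs(den) < eps:
                continue
            rhs = q0 - p0
            t = (rhs[0] * d2[1] - rhs[1] * d2[0]) / den
            s = (rhs[0] * d1[1] - rhs[1] * d1[0]) / den
            if t < -eps or t > 1 + eps or s < -eps or s > 1 + eps:
                continue
            if min(t, s) < eps or max(t, s) > 1 - eps:
                return None
            z1 = p0[2] + t * d1[2]
            z2 = q0[2] + s * d2[2]
            if abs(z1 - z2) < eps:
                return None
            # crossing sign: orientation of (under-direction, over-direction)
            sign = -1 if den > 0 else 1
            if z1 < z2:
                sign = -sign
            total += sign
    if total % 2:
        return None
    return total // 2


def mean_bond_a(state) -> float:
    b = np.roll(state.pos, -1, axis=1) - state.pos
    return float(((b ** 2).sum(axis=2) > 0).mean())
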