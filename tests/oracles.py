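"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's own computation paths: the
Kirchhoff matrix is rebuilt from scratch at every step, the pseudoinverse
comes from numpy's SVD-based ``pinv``, and the deformation gradient from a
weighted least-squares fit.  They are slow and only used on tiny systems.
"""

from __future__ import annotations

import numpy as np

TIE_RTOL = 1e-9


def gamma_from_pairs(n, backbone, contacts, c):
    """Rebuild the Kirchhoff matrix from explicit pair lists (from scratch)."""
    g = np.zeros((n, n))
    for (i, j) in backbone:
        g[i - 1, j - 1] = g[j - 1, i - 1] = -c
    for (i, j) in contacts:
        g[i - 1, j - 1] = g[j - 1, i - 1] = -1.0
    for k in range(n):
        g[k, k] = -(g[k].sum() - g[k, k])
    return g


def pick_max_pair(values: dict) -> tuple:
    best = max(values.values())
    tol = TIE_RTOL * max(abs(best), 1e-300)
    return min(p for p, v in values.items() if v >= best - tol)


def thermal_sequence(n, backbone, contacts, c):
    """Full thermal bond-breaking order via per-step numpy pinv."""
    contacts = set(contacts)
    order = []
    while contacts:
        g = gamma_from_pairs(n, backbone, contacts, c)
        gp = np.linalg.pinv(g, rcond=1e-10, hermitian=True)
        d = np.diag(gp)
        crit = {
            (i, j): d[i - 1] + d[j - 1] - 2 * gp[i - 1, j - 1]
            for (i, j) in contacts
        }
        pair = pick_max_pair(crit)
        order.append(pair)
        contacts.discard(pair)
    return order


def force_sequence(n, backbone, contacts, c, kappa, forces):
    """Force-induced breaking order via per-step numpy pinv."""
    contacts = set(contacts)
    order = []
    while contacts:
        g = gamma_from_pairs(n, backbone, contacts, c)
        gp = np.linalg.pinv(g, rcond=1e-10, hermitian=True)
        u = gp @ forces / kappa
        crit = {
            (i, j): float(np.linalg.norm(u[i - 1] - u[j - 1]))
            for (i, j) in contacts
        }
        pair = pick_max_pair(crit)
        order.append(pair)
        contacts.discard(pair)
    return order


def lstsq_deformation_gradient(coords0, coords1, m, idx, w):
    """Weighted least-squares fit of F minimizing sum_n w |F dx - dx'|^2."""
    dx = coords0[idx] - coords0[m]
    dxp = coords1[idx] - coords1[m]
    sw = np.sqrt(w)[:, None]
    f_t, *_ = np.linalg.lstsq(dx * sw, dxp * sw, rcond=None)
    return f_t.T


def random_walk_coords(n, seed, step=3.8, min_sep=3.2):
    """Self-avoiding-ish 3-D random walk with fixed step length."""
    rng = np.random.default_rng(seed)
    coords = [np.zeros(3)]
    while len(coords) < n:
        for _ in range(200):
            v = rng.normal(size=3)
            cand = coords[-1] + step * v / np.linalg.norm(v)
            if all(np.linalg.norm(cand - p) >= min_sep for p in coords[:-1]):
                coords.append(cand)
                break
        else:  # pragma: no cover - restart on pathological walks
            coords = [np.zeros(3)]
    return np.array(coords)
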