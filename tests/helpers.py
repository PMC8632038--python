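"""Shared independent oracles for the test suite.

Everything here is deliberately naive (nested loops, exhaustive
enumeration) and stays independent of the library code paths it checks.
"""

from __future__ import annotations

from itertools import product

import numpy as np

from wjsdm import CovarianceSet, DEWeights, dtrace_loss, nearest_psd


def brute_tau(x, y) -> float:
    """Literal ordered-pair enumeration of the dropout-masked Kendall tau."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    dx = np.isfinite(x) & (x != 0)
    dy = np.isfinite(y) & (y != 0)
    n = len(x)
    n_ij = sum(1 for l in range(n) if dx[l] and dy[l])
    if n_ij <= 1:
        return 0.0
    total = 0.0
    for l in range(n):
        for m in range(n):
            if l == m:
                continue
            if dx[l] and dx[m] and dy[l] and dy[m]:
                total += np.sign((x[l] - x[m]) * (y[l] - y[m]))
    return total / (n_ij * (n_ij - 1))


def random_difference_instance(rng, p=12, K=2):
    """Covariances of two states sharing a backbone precision structure but
    differing on a few strong edges, plus random DE weights."""
    mats = np.zeros((K, 2, p, p))
    for k in range(K):
        base = np.zeros((p, p))
        for _ in range(p):
            i, j = rng.choice(p, 2, replace=False)
            base[i, j] = base[j, i] = rng.uniform(0.5, 1.0) * rng.choice([-1.0, 1.0])
        for c in range(2):
            theta = base.copy()
            for _ in range(3):
                i, j = rng.choice(p, 2, replace=False)
                theta[i, j] = theta[j, i] = rng.uniform(0.5, 1.0) * rng.choice([-1.0, 1.0])
            theta += np.diag(np.abs(theta).sum(axis=1) + 0.1)
            S = np.linalg.inv(theta)
            d = 1.0 / np.sqrt(np.diag(S))
            S = S * np.outer(d, d)
            mats[k, c] = nearest_psd(0.5 * (S + S.T))
    cov = CovarianceSet(mats, [f"g{i}" for i in range(p)])
    de = DEWeights(rng.uniform(0.0, 1.0, (K, p)))
    return cov, de


_POSITIONS_3 = [(0, 0), (1, 1), (2, 2), (0, 1), (0, 2), (1, 2)]


def _from_free(v):
    d = np.zeros((3, 3))
    for val, (i, j) in zip(v, _POSITIONS_3):
        d[i, j] = d[j, i] = val
    return d


def dtrace_lasso_oracle(S1, S2, thresholds, tol=1e-9):
    """Exhaustive minimizer of the weighted-lasso D-trace problem at p = 3.

    Enumerates all 3^6 sign patterns of the six free entries of a symmetric
    3x3 matrix, solves the stationarity system on each candidate support,
    and keeps sign-consistent solutions whose inactive entries satisfy the
    subgradient bound. Returns the feasible solution with the lowest
    objective (unique by convexity up to numerical ties).
    """
    S1 = np.asarray(S1, float)
    S2 = np.asarray(S2, float)
    T = np.asarray(thresholds, float)
    C = S1 - S2
    m = len(_POSITIONS_3)
    A = np.zeros((m, m))
    for col, (i, j) in enumerate(_POSITIONS_3):
        E = np.zeros((3, 3))
        E[i, j] = E[j, i] = 1.0
        G = 0.5 * (S1 @ E @ S2 + S2 @ E @ S1)
        A[:, col] = [G[a, b] for a, b in _POSITIONS_3]
    b = -np.array([C[a, b] for a, b in _POSITIONS_3])
    t = np.array([T[a, b] for a, b in _POSITIONS_3])

    best = None
    best_obj = np.inf
    for s in product((-1, 0, 1), repeat=m):
        s = np.array(s, float)
        supp = np.nonzero(s)[0]
        v = np.zeros(m)
        if supp.size:
            sub = A[np.ix_(supp, supp)]
            rhs = -b[supp] - t[supp] * s[supp]
            try:
                v[supp] = np.linalg.solve(sub, rhs)
            except np.linalg.LinAlgError:
                continue
            if np.any(np.sign(v[supp]) != s[supp]):
                continue
        g = A @ v + b
        inactive = np.setdiff1d(np.arange(m), supp)
        if np.any(np.abs(g[inactive]) > t[inactive] + tol):
            continue
        delta = _from_free(v)
        obj = dtrace_loss(delta, S1, S2) + float(np.sum(T * np.abs(delta)))
        if obj < best_obj - 1e-15:
            best_obj = obj
            best = delta
    if best is None:
        raise RuntimeError("no KKT-consistent candidate found")
    return best


def kkt_max_violation(delta, S1, S2, thresholds, active_tol=1e-8):
    """Largest violation of the entrywise subgradient conditions."""
    G = 0.5 * (S1 @ delta @ S2 + S2 @ delta @ S1) - (S1 - S2)
    T = np.asarray(thresholds, float)
    active = np.abs(delta) > active_tol
    viol_active = np.abs(G[active] + T[active] * np.sign(delta[active]))
    viol_inactive = np.abs(G[~active]) - T[~active]
    worst = 0.0
    if viol_active.size:
        worst = max(worst, float(viol_active.max()))
    if viol_inactive.size:
        worst = max(worst, float(np.maximum(viol_inactive, 0.0).max()))
    return worst
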