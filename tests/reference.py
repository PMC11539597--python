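"""Independent reference implementations used as test oracles.

Each function here is written as directly as possible from the defining
formula — loops instead of vectorization, no shared code with the
package — so agreement between package and oracle is evidence, not
tautology.
"""

from __future__ import annotations

import numpy as np


def opls_nipals(X: np.ndarray, y: np.ndarray, n_ortho: int) -> np.ndarray:
    """Direct NIPALS OPLS (Trygg & Wold orthogonal signal correction).

    Returns fitted values on the original y scale. Used as the oracle
    for the kernel-OPLS fit with a linear kernel K = X Xᵀ.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    Xc = X - X.mean(axis=0)
    ymean = y.mean()
    yc = y - ymean
    for _ in range(n_ortho):
        w = Xc.T @ yc
        w = w / np.linalg.norm(w)
        t = Xc @ w
        p = Xc.T @ t / (t @ t)
        w_o = p - (w @ p) * w
        n_wo = np.linalg.norm(w_o)
        if n_wo < 1e-12:
            break
        w_o = w_o / n_wo
        t_o = Xc @ w_o
        p_o = Xc.T @ t_o / (t_o @ t_o)
        Xc = Xc - np.outer(t_o, p_o)
    w = Xc.T @ yc
    w = w / np.linalg.norm(w)
    t = Xc @ w
    b = (t @ yc) / (t @ t)
    return b * t + ymean


def tom_brute_force(A: np.ndarray) -> np.ndarray:
    """Triple-loop topological overlap of a symmetric adjacency."""
    A = np.asarray(A, dtype=float)
    n = A.shape[0]
    k = np.array([sum(A[i, u] for u in range(n) if u != i) for i in range(n)])
    T = np.eye(n)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            shared = sum(A[i, u] * A[u, j] for u in range(n) if u != i and u != j)
            T[i, j] = (shared + A[i, j]) / (min(k[i], k[j]) + 1.0 - A[i, j])
    return T


def tmm_factor_pair(
    obs: np.ndarray, ref: np.ndarray, trim_M: float = 0.3, trim_A: float = 0.05
) -> float:
    """Weighted trimmed mean of M-values of one sample vs a reference.

    Re-derived from the published TMM definition: two-tailed trims of
    the M (log-ratio) and A (abundance) distributions, inverse
    asymptotic-variance weights, 2^(weighted mean of retained M).
    """
    obs = np.asarray(obs, dtype=float)
    ref = np.asarray(ref, dtype=float)
    n_o, n_r = obs.sum(), ref.sum()
    keep = (obs > 0) & (ref > 0)
    o, r = obs[keep], ref[keep]
    M = np.log2((o / n_o) / (r / n_r))
    A = 0.5 * (np.log2(o / n_o) + np.log2(r / n_r))
    w = 1.0 / ((n_o - o) / (n_o * o) + (n_r - r) / (n_r * r))
    if np.max(np.abs(M)) < 1e-6:
        return 1.0
    n = len(M)
    # two-tailed trim by rank (ranks averaged on ties)
    def ranks(v):
        order = np.argsort(v, kind="mergesort")
        rk = np.empty(n)
        i = 0
        sv = v[order]
        while i < n:
            j = i
            while j + 1 < n and sv[j + 1] == sv[i]:
                j += 1
            rk[order[i : j + 1]] = (i + j) / 2.0 + 1.0
            i = j + 1
        return rk

    rM, rA = ranks(M), ranks(A)
    loM = np.floor(n * trim_M) + 1
    hiM = n + 1 - loM
    loA = np.floor(n * trim_A) + 1
    hiA = n + 1 - loA
    sel = (rM >= loM) & (rM <= hiM) & (rA >= loA) & (rA <= hiA)
    f = np.sum(w[sel] * M[sel]) / np.sum(w[sel])
    return float(2.0**f)


def es_brute_force(z: np.ndarray, hit: np.ndarray, weight: float = 1.0) -> float:
    """Enumerated weighted-KS running sum; returns the extremum ES."""
    z = np.asarray(z, dtype=float)
    hit = np.asarray(hit, dtype=bool)
    n = len(z)
    n_hit = int(hit.sum())
    total = sum(abs(z[i]) ** weight for i in range(n) if hit[i])
    running = 0.0
    best = 0.0
    for i in range(n):
        if hit[i]:
            if total > 0:
                running += abs(z[i]) ** weight / total
            else:
                running += 1.0 / n_hit
        else:
            running -= 1.0 / (n - n_hit)
        if abs(running) > abs(best):
            best = running
    return best


def bh_brute_force(p: np.ndarray) -> np.ndarray:
    """Step-up Benjamini-Hochberg by the textbook definition."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    adj = np.empty(m)
    running_min = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        val = min(p[i] * m / rank_from_top, 1.0)
        running_min = min(running_min, val)
        adj[i] = running_min
    return adj
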