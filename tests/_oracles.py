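"""Independent brute-force oracles used by the test suite.

Everything here is written from the definitions with plain loops, kept
deliberately separate from the package implementation it checks.
"""

from __future__ import annotations

import numpy as np


def modularity_direct(A: np.ndarray, labels: np.ndarray, gamma: float, omega: float) -> float:
    """Multislice modularity by direct summation over all (i, j, l, r)."""
    N, _, L = A.shape
    k = A.sum(axis=1)  # (N, L)
    two_m = A.sum(axis=(0, 1))  # (L,)
    score = 0.0
    for l in range(L):
        for i in range(N):
            for j in range(N):
                if labels[i, l] != labels[j, l]:
                    continue
                null = gamma * k[i, l] * k[j, l] / two_m[l] if two_m[l] > 0 else 0.0
                score += A[i, j, l] - null
    for i in range(N):
        for l in range(L):
            for r in (l - 1, l + 1):
                if 0 <= r < L and labels[i, l] == labels[i, r]:
                    score += omega
    two_mu = two_m.sum() + 2.0 * omega * N * (L - 1)
    return score / two_mu if two_mu > 0 else 0.0


def _slot_matrix(A: np.ndarray, gamma: float, omega: float) -> np.ndarray:
    """Supra matrix over slots (layer-major) built with plain loops."""
    N, _, L = A.shape
    k = A.sum(axis=1)
    two_m = A.sum(axis=(0, 1))
    n = N * L
    B = np.zeros((n, n))
    for l in range(L):
        for i in range(N):
            for j in range(N):
                null = gamma * k[i, l] * k[j, l] / two_m[l] if two_m[l] > 0 else 0.0
                B[l * N + i, l * N + j] = A[i, j, l] - null
    for i in range(N):
        for l in range(L - 1):
            B[l * N + i, (l + 1) * N + i] = omega
            B[(l + 1) * N + i, l * N + i] = omega
    return B


def exhaustive_max_modularity(A: np.ndarray, gamma: float, omega: float) -> float:
    """Maximum multislice modularity over every set partition of the slots.

    Enumerates restricted-growth partitions recursively with incremental
    score updates; feasible for N * L <= ~10 slots.
    """
    N, _, L = A.shape
    B = _slot_matrix(A, gamma, omega)
    n = N * L
    two_mu = A.sum() + 2.0 * omega * N * (L - 1)
    best = -np.inf
    groups: list[list[int]] = []

    def rec(u: int, score: float) -> None:
        nonlocal best
        if u == n:
            best = max(best, score)
            return
        for g in groups:
            dq = B[u, u] + 2.0 * sum(B[u, v] for v in g)
            g.append(u)
            rec(u + 1, score + dq)
            g.pop()
        groups.append([u])
        rec(u + 1, score + B[u, u])
        groups.pop()

    rec(0, 0.0)
    return best / two_mu if two_mu > 0 else 0.0


def bh_reject(pvalues: np.ndarray, q: float) -> np.ndarray:
    """Benjamini-Hochberg step-up from the definition; returns a bool mask."""
    p = np.asarray(pvalues, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    k_star = 0
    for rank, idx in enumerate(order, start=1):
        if p[idx] <= q * rank / m:
            k_star = rank
    mask = np.zeros(m, dtype=bool)
    mask[order[:k_star]] = True
    return mask


def ranksum_exact_p(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided Wilcoxon rank-sum p-value by full enumeration (no ties)."""
    from itertools import combinations

    pooled = np.concatenate([x, y])
    assert len(np.unique(pooled)) == len(pooled), "oracle assumes no ties"
    ranks = pooled.argsort().argsort() + 1.0
    n_x = len(x)
    obs = ranks[:n_x].sum()
    all_sums = [sum(c) for c in combinations(ranks, n_x)]
    all_sums = np.array(all_sums)
    mean = all_sums.mean()
    extreme = np.abs(all_sums - mean) >= np.abs(obs - mean) - 1e-12
    return float(extreme.mean())


def spearman_direct(x: np.ndarray, y: np.ndarray) -> float:
    """Spearman rho: Pearson correlation of average ranks."""

    def avg_rank(v):
        order = np.argsort(v, kind="stable")
        ranks = np.empty(len(v))
        sv = v[order]
        i = 0
        while i < len(v):
            j = i
            while j + 1 < len(v) and sv[j + 1] == sv[i]:
                j += 1
            ranks[order[i : j + 1]] = 0.5 * (i + j) + 1.0
            i = j + 1
        return ranks

    rx, ry = avg_rank(np.asarray(x, float)), avg_rank(np.asarray(y, float))
    return float(np.corrcoef(rx, ry)[0, 1])
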