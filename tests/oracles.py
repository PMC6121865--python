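"""Independent brute-force oracles used to cross-check the implementation.

These deliberately use naive algorithms (double loops, exhaustive dynamic
programming, exact enumeration) and share no code with the package paths
they verify.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np

MISSING = -1


def brute_force_distances(calls: np.ndarray) -> list[tuple[int, int, int, int]]:
    """Naive double-loop pairwise (i, j, d, n_compared) over a dosage matrix."""
    n, L = calls.shape
    out = []
    for i, j in combinations(range(n), 2):
        d = 0
        nc = 0
        for s in range(L):
            a, b = calls[i, s], calls[j, s]
            if a == MISSING or b == MISSING:
                continue
            nc += 1
            if a != b:
                d += 1
        out.append((i, j, d, nc))
    return out


def dp_1d_kmeans_wss(values: np.ndarray, k: int) -> float:
    """Exact optimal within-cluster SS for 1-D k-means via dynamic programming.

    Optimal 1-D clusters are contiguous in sorted order, so an O(k n^2) DP
    over split points finds the global optimum.
    """
    x = np.sort(np.asarray(values, dtype=float))
    n = x.size
    pref = np.concatenate([[0.0], np.cumsum(x)])
    pref2 = np.concatenate([[0.0], np.cumsum(x * x)])

    def seg_cost(i: int, j: int) -> float:  # cost of x[i:j]
        m = j - i
        s = pref[j] - pref[i]
        s2 = pref2[j] - pref2[i]
        return s2 - s * s / m

    INF = float("inf")
    dp = [[INF] * (n + 1) for _ in range(k + 1)]
    dp[0][0] = 0.0
    for c in range(1, k + 1):
        for j in range(1, n + 1):
            for i in range(c - 1, j):
                cand = dp[c - 1][i] + seg_cost(i, j)
                if cand < dp[c][j]:
                    dp[c][j] = cand
    return dp[k][n]


def exact_mannwhitney_two_sided_p(a, b) -> float:
    """Exact two-sided Mann-Whitney p by enumerating all rank assignments."""
    from itertools import combinations as comb

    pooled = list(a) + list(b)
    n1 = len(a)
    idx = range(len(pooled))

    def u_stat(group1_idx):
        g1 = [pooled[i] for i in group1_idx]
        g2 = [pooled[i] for i in idx if i not in set(group1_idx)]
        u = sum(1 for x in g1 for y in g2 if x > y) + 0.5 * sum(
            1 for x in g1 for y in g2 if x == y
        )
        return u

    observed = u_stat(tuple(range(n1)))
    n2 = len(pooled) - n1
    mean_u = n1 * n2 / 2.0
    dev = abs(observed - mean_u)
    count = 0
    total = 0
    for g1 in comb(idx, n1):
        total += 1
        if abs(u_stat(g1) - mean_u) >= dev - 1e-12:
            count += 1
    return count / total


def wc_theta_single_site(n1, p1, h1, n2, p2, h2) -> tuple[float, float, float]:
    """Scalar transcription of the Weir & Cockerham (1984) a, b, c
    components for two populations at one site (independent of the
    vectorized package implementation)."""
    r = 2.0
    nbar = (n1 + n2) / r
    nc = (r * nbar - (n1 * n1 + n2 * n2) / (r * nbar)) / (r - 1.0)
    pbar = (n1 * p1 + n2 * p2) / (r * nbar)
    s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1.0) * nbar)
    hbar = (n1 * h1 + n2 * h2) / (r * nbar)
    a = (nbar / nc) * (
        s2 - (1.0 / (nbar - 1.0)) * (pbar * (1.0 - pbar) - s2 * (r - 1.0) / r - hbar / 4.0)
    )
    b = (nbar / (nbar - 1.0)) * (
        pbar * (1.0 - pbar) - s2 * (r - 1.0) / r - hbar * (2.0 * nbar - 1.0) / (4.0 * nbar)
    )
    c = hbar / 2.0
    return a, b, c


def mean_pairwise_allele_diff(calls: np.ndarray) -> float:
    """Mean per-site mismatch fraction over all pairs of allele copies,
    summed across sites (oracle for the unbiased per-site diversity).
    Unphased heterozygotes contribute one copy of each allele."""
    total = 0.0
    for s in range(calls.shape[1]):
        alleles: list[int] = []
        for g in calls[:, s]:
            if g == MISSING:
                continue
            alleles += {0: [0, 0], 1: [0, 1], 2: [1, 1]}[int(g)]
        n = len(alleles)
        if n < 2:
            continue
        mismatches = sum(
            1 for i, j in combinations(range(n), 2) if alleles[i] != alleles[j]
        )
        total += mismatches / (n * (n - 1) / 2)
    return total
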