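"""Independent brute-force oracles used to check the implementation.

Everything here is written from first principles (loops, enumeration, closed
forms) and deliberately avoids the code paths — and where possible the
libraries — used by the package itself.
"""

from __future__ import annotations

from math import comb, sqrt

import numpy as np


def pearson_by_hand(x, y) -> float:
    x = list(map(float, x))
    y = list(map(float, y))
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    cov = sum((a - mx) * (b - my) for a, b in zip(x, y))
    sx = sqrt(sum((a - mx) ** 2 for a in x))
    sy = sqrt(sum((b - my) ** 2 for b in y))
    return cov / (sx * sy)


def correlation_t_by_hand(r: float, k: int) -> float:
    return r * sqrt(k - 2) / sqrt(1 - r * r)


def fisher_two_sided_by_enumeration(table) -> float:
    """Sum hypergeometric probabilities <= that of the observed table over all
    tables with the same margins."""
    (a, b), (c, d) = table
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2

    def prob(aa: int) -> float:
        bb, cc = r1 - aa, c1 - aa
        dd = r2 - cc
        if min(bb, cc, dd) < 0:
            return 0.0
        return comb(r1, aa) * comb(r2, cc) / comb(n, c1)

    p_obs = prob(a)
    total = 0.0
    for aa in range(0, min(r1, c1) + 1):
        p = prob(aa)
        if p <= p_obs * (1 + 1e-12):
            total += p
    return min(1.0, total)


def bh_fdr_by_hand(pvals) -> np.ndarray:
    """Step-up recursion: q_(i) = min_{j >= i} m * p_(j) / j."""
    p = np.asarray(pvals, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    q_sorted = np.empty(m)
    running = np.inf
    for rank in range(m, 0, -1):
        running = min(running, m * p[order[rank - 1]] / rank)
        q_sorted[rank - 1] = min(1.0, running)
    q = np.empty(m)
    q[order] = q_sorted
    return q


def partial_corr_by_precision(x, y, covariates) -> float:
    """Partial correlation from the inverse correlation matrix of
    [x, y, covariates]: r = -P01 / sqrt(P00 * P11)."""
    M = np.column_stack([x, y, covariates])
    corr = np.corrcoef(M.T)
    P = np.linalg.inv(corr)
    return float(-P[0, 1] / np.sqrt(P[0, 0] * P[1, 1]))


def strength_by_hand(adjacency, R) -> float:
    n = adjacency.shape[0]
    vals = [abs(R[i][j]) for i in range(n) for j in range(i + 1, n) if adjacency[i][j]]
    return sum(vals) / len(vals) if vals else 0.0


def degree_by_hand(adjacency) -> float:
    n = adjacency.shape[0]
    return sum(adjacency[i][j] for i in range(n) for j in range(n) if i != j) / n


def path_length_by_hand(adjacency) -> float:
    """Floyd-Warshall average over connected unordered pairs; NaN if none."""
    n = adjacency.shape[0]
    INF = float("inf")
    d = [[0 if i == j else (1 if adjacency[i][j] else INF) for j in range(n)] for i in range(n)]
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if d[i][k] + d[k][j] < d[i][j]:
                    d[i][j] = d[i][k] + d[k][j]
    dists = [d[i][j] for i in range(n) for j in range(i + 1, n) if d[i][j] < INF]
    return sum(dists) / len(dists) if dists else float("nan")


def clustering_by_hand(adjacency) -> float:
    """Mean over nodes of 2*triangles/(k*(k-1)), 0 for degree < 2."""
    n = adjacency.shape[0]
    total = 0.0
    for i in range(n):
        nbrs = [j for j in range(n) if j != i and adjacency[i][j]]
        k = len(nbrs)
        if k < 2:
            continue
        tri = sum(
            1 for a in range(k) for b in range(a + 1, k) if adjacency[nbrs[a]][nbrs[b]]
        )
        total += 2.0 * tri / (k * (k - 1))
    return total / n


def paired_t_by_hand(a, b):
    d = np.asarray(a, dtype=float) - np.asarray(b, dtype=float)
    n = d.size
    t = d.mean() / (d.std(ddof=1) / sqrt(n))
    from scipy.stats import t as tdist  # distribution function only

    p = 2 * tdist.sf(abs(t), df=n - 1)
    return t, p
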