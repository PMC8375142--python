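"""Independent brute-force oracles used to verify the statistical core.

Everything here is deliberately naive — exact integer enumeration for
the tail/contingency tests, the direct step-up formula for BH,
rank-then-Pearson for Spearman, and a recompute-everything UPGMA — and
shares no code with the implementations it checks.
"""
from __future__ import annotations

import math

import numpy as np


def hypergeom_tail_oracle(k: int, K: int, n: int, N: int) -> float:
    """P(X >= k) by exact integer binomial-coefficient enumeration."""
    denom = math.comb(N, n)
    num = sum(math.comb(K, j) * math.comb(N - K, n - j)
              for j in range(k, min(K, n) + 1))
    return num / denom


def fisher_two_sided_oracle(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher p by enumeration of all tables with fixed margins.

    Includes every table whose (integer) probability numerator does not
    exceed the observed one — the classical definition, with exact ties.
    """
    r1, c1, N = a + b, a + c, a + b + c + d
    obs = math.comb(c1, a) * math.comb(N - c1, r1 - a)
    total = math.comb(N, r1)
    acc = 0
    for x in range(max(0, r1 - (N - c1)), min(r1, c1) + 1):
        w = math.comb(c1, x) * math.comb(N - c1, r1 - x)
        if w <= obs:
            acc += w
    return acc / total


def bh_oracle(p: list[float]) -> list[float]:
    """Direct step-up formula: q_(i) = min_{j>=i}(p_(j) * m / j), cap 1."""
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    q = [0.0] * m
    for rank_pos, i in enumerate(order):
        q[i] = min(min(p[order[j]] * m / (j + 1) for j in range(rank_pos, m)),
                   1.0)
    return q


def spearman_oracle(x, y) -> float:
    """Mid-rank then Pearson, written out longhand."""
    def midranks(v):
        order = sorted(range(len(v)), key=lambda i: v[i])
        ranks = [0.0] * len(v)
        i = 0
        while i < len(v):
            j = i
            while j + 1 < len(v) and v[order[j + 1]] == v[order[i]]:
                j += 1
            avg = (i + j) / 2 + 1
            for t in range(i, j + 1):
                ranks[order[t]] = avg
            i = j + 1
        return ranks

    rx, ry = midranks(list(x)), midranks(list(y))
    mx, my = sum(rx) / len(rx), sum(ry) / len(ry)
    num = sum((a - mx) * (b - my) for a, b in zip(rx, ry))
    den = math.sqrt(sum((a - mx) ** 2 for a in rx)
                    * sum((b - my) ** 2 for b in ry))
    return num / den if den else float("nan")


def upgma_oracle(dist: np.ndarray):
    """Brute-force average linkage: recompute every cluster-pair average
    distance from the original matrix at each step.

    Returns a list of (merged_leafset_a, merged_leafset_b, height).
    """
    n = dist.shape[0]
    clusters: list[frozenset[int]] = [frozenset([i]) for i in range(n)]
    merges = []
    while len(clusters) > 1:
        best = None
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                d = np.mean([dist[a, b] for a in clusters[i]
                             for b in clusters[j]])
                if best is None or d < best[0]:
                    best = (d, i, j)
        d, i, j = best
        merges.append((clusters[i], clusters[j], float(d)))
        merged = clusters[i] | clusters[j]
        clusters = [c for k, c in enumerate(clusters) if k not in (i, j)]
        clusters.append(merged)
    return merges


def median_oracle(rows: np.ndarray) -> np.ndarray:
    """Per-column median by sort-and-pick."""
    out = []
    for col in rows.T:
        s = sorted(col)
        m = len(s)
        out.append(s[m // 2] if m % 2 else (s[m // 2 - 1] + s[m // 2]) / 2)
    return np.array(out)
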