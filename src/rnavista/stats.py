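"""Shared numerical primitives: exact tests, BH correction, Spearman
correlation, UPGMA clustering with mean reordering, and PCA.

Every downstream analysis (over-representation, upstream-regulator,
spatial, overlap, signatures, heatmap ordering) calls into this module so
that statistical conventions are defined exactly once.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as _sps
from scipy.cluster.hierarchy import linkage as _linkage


@dataclass(frozen=True)
class HypergeomQuery:
    """Counts for a one-sided over-representation test.

    k: observed overlap; K: gene-set size in the universe; n: query size;
    N: universe size.
    """

    k: int
    K: int
    n: int
    N: int

    def __post_init__(self) -> None:
        if not (0 <= self.K <= self.N and 0 <= self.n <= self.N):
            raise ValueError(f"set/query sizes exceed universe: {self}")
        if not (0 <= self.k <= min(self.K, self.n)):
            raise ValueError(f"overlap k out of range: {self}")


def hypergeometric_tail(q: HypergeomQuery) -> float:
    """Upper-tail probability P(X >= k) for X ~ Hypergeom(N, K, n).

    Survival function evaluated at k-1; computed in log space by scipy for
    numerical stability. Returns 1.0 for k = 0 by construction.
    """
    if q.k == 0:
        return 1.0
    return float(_sps.hypergeom.sf(q.k - 1, q.N, q.K, q.n))


def fisher_exact_two_sided(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p for the 2x2 table [[a, b], [c, d]].

    Classical definition: sum of probabilities of all tables with the same
    margins whose probability does not exceed the observed table's.
    """
    if min(a, b, c, d) < 0:
        raise ValueError("counts must be non-negative")
    if a + b + c + d < 1:
        raise ValueError("table total must be >= 1")
    return float(_sps.fisher_exact([[a, b], [c, d]], alternative="two-sided")[1])


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    q_(i) = min_{j >= i}(p_(j) * m / j), capped at 1, returned in the input
    order. NaN entries are passed through unchanged and do not count
    towards m.
    """
    p = np.asarray(p_values, dtype=float)
    out = np.full(p.shape, np.nan)
    mask = ~np.isnan(p)
    pv = p[mask]
    if pv.size == 0:
        return out
    if pv.min() < 0 or pv.max() > 1:
        raise ValueError("p-values must lie in [0, 1]")
    m = pv.size
    order = np.argsort(pv, kind="stable")
    ranked = pv[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    q = np.empty(m)
    q[order] = adj
    out[mask] = q
    return out


def spearman(x, y) -> float:
    """Spearman rank correlation (mid-ranks for ties)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("need two equal-length vectors of length >= 3")
    rho = _sps.spearmanr(x, y).statistic
    return float(rho)


@dataclass
class Dendrogram:
    """UPGMA merge tree plus the mean-reordered leaf order.

    ``merges`` follows the scipy linkage convention: row i merges nodes
    ``(int(a), int(b))`` at height ``h`` into new node ``n_leaves + i``.
    """

    merges: list[tuple[int, int, float]]
    leaf_order: list[int]
    n_leaves: int

    @property
    def heights(self) -> list[float]:
        return [h for _, _, h in self.merges]


def spearman_distance_matrix(rows: np.ndarray) -> np.ndarray:
    """Pairwise 1 - SCC distances between matrix rows.

    Rows with zero variance have no defined rank correlation; their
    distance to every other row (and to each other) is fixed at 1.0 so the
    clustering stays total.
    """
    rows = np.asarray(rows, dtype=float)
    n = rows.shape[0]
    const = np.ptp(rows, axis=1) == 0
    ranks = np.apply_along_axis(_sps.rankdata, 1, rows)
    with np.errstate(invalid="ignore"):
        corr = np.corrcoef(ranks)
    dist = 1.0 - corr
    dist[const, :] = 1.0
    dist[:, const] = 1.0
    np.fill_diagonal(dist, 0.0)
    # guard tiny negative values from float round-off
    return np.clip(dist, 0.0, None)


def upgma_cluster(rows: np.ndarray, dist: np.ndarray | None = None) -> Dendrogram:
    """Average-linkage (UPGMA) clustering of matrix rows under 1 - SCC.

    Leaf order is produced by mean reordering: at every internal node the
    subtree whose leaves have the lower mean of row-means is placed first.
    """
    rows = np.asarray(rows, dtype=float)
    n = rows.shape[0]
    if n < 2:
        raise ValueError("need at least two rows to cluster")
    if dist is None:
        dist = spearman_distance_matrix(rows)
    condensed = dist[np.triu_indices(n, k=1)]
    Z = _linkage(condensed, method="average")
    merges = [(int(a), int(b), float(h)) for a, b, h, _ in Z]
    row_means = rows.mean(axis=1)

    # mean reordering: recursively place the lower-mean subtree first
    order: list[int] = []

    def _mean_and_leaves(node: int) -> tuple[float, list[int]]:
        if node < n:
            return row_means[node], [node]
        a, b, _ = merges[node - n]
        ma, la = _mean_and_leaves(a)
        mb, lb = _mean_and_leaves(b)
        total = (ma * len(la) + mb * len(lb)) / (len(la) + len(lb))
        if mb < ma:
            la, lb = lb, la
        return total, la + lb

    _, order = _mean_and_leaves(n + len(merges) - 1)
    return Dendrogram(merges=merges, leaf_order=order, n_leaves=n)


@dataclass
class PCAResult:
    """Sample scores and percent variance per principal component."""

    scores: np.ndarray          # samples x components
    percent_variance: np.ndarray

    @property
    def n_components(self) -> int:
        return self.scores.shape[1]


def pca(matrix: np.ndarray, log_transform: bool = True,
        pseudocount: float = 1.0) -> PCAResult:
    """PCA of samples from a genes x samples expression matrix.

    The matrix is log10(x + pseudocount) transformed and per-gene
    mean-centred (no unit scaling), then decomposed by SVD on the
    samples x genes matrix. Components 1..min(G, S-1) are returned; the
    percent-variance entries sum to 100.
    """
    X = np.asarray(matrix, dtype=float)
    if X.ndim != 2 or X.shape[1] < 2:
        raise ValueError("need a genes x samples matrix with >= 2 samples")
    if log_transform:
        X = np.log10(X + pseudocount)
    X = X - X.mean(axis=1, keepdims=True)   # centre each gene
    Y = X.T                                  # samples x genes
    U, s, _ = np.linalg.svd(Y, full_matrices=False)
    k = min(X.shape[0], X.shape[1] - 1)
    U, s = U[:, :k], s[:k]
    scores = U * s
    var = s ** 2
    total = var.sum()
    pct = var / total * 100.0 if total > 0 else np.zeros_like(var)
    return PCAResult(scores=scores, percent_variance=pct)
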