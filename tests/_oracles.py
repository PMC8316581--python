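"""Brute-force reference implementations used only for cross-checking.

Every function here is written independently of the package's code paths:
explicit sorts, explicit agglomeration, exact integer enumeration.  They
are deliberately slow and simple.
"""

from __future__ import annotations

from math import comb

import numpy as np


def midranks(values: np.ndarray) -> np.ndarray:
    """Mid-ranks by explicit sorting (average rank over tied values)."""
    values = np.asarray(values, dtype=float)
    order = np.argsort(values, kind="stable")
    ranks = np.empty(values.size)
    i = 0
    while i < values.size:
        j = i
        while j + 1 < values.size and values[order[j + 1]] == values[order[i]]:
            j += 1
        avg = (i + j) / 2.0 + 1.0
        for m in range(i, j + 1):
            ranks[order[m]] = avg
        i = j + 1
    return ranks


def kruskal_wallis_brute(groups) -> tuple[float, float]:
    """Tie-corrected Kruskal-Wallis H and chi-square p, from first principles."""
    from scipy.stats import chi2

    groups = [np.asarray(g, dtype=float) for g in groups]
    pooled = np.concatenate(groups)
    N = pooled.size
    ranks = midranks(pooled)
    start = 0
    H = 0.0
    for g in groups:
        r = ranks[start : start + g.size]
        H += g.size * (r.mean() - (N + 1) / 2.0) ** 2
        start += g.size
    H *= 12.0 / (N * (N + 1))
    _, counts = np.unique(pooled, return_counts=True)
    tie = 1.0 - float(np.sum(counts**3 - counts)) / (N**3 - N)
    H /= tie
    return H, float(chi2.sf(H, len(groups) - 1))


def dunn_brute(groups, i: int, j: int) -> tuple[float, float]:
    """Dunn post-hoc z and two-sided normal p from pooled mid-ranks."""
    from scipy.stats import norm

    groups = [np.asarray(g, dtype=float) for g in groups]
    pooled = np.concatenate(groups)
    N = pooled.size
    ranks = midranks(pooled)
    bounds = np.cumsum([0] + [g.size for g in groups])
    mean_ranks = [ranks[bounds[m] : bounds[m + 1]].mean() for m in range(len(groups))]
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(counts**3 - counts))
    var = N * (N + 1) / 12.0 - tie_term / (12.0 * (N - 1))
    se = np.sqrt(var * (1.0 / groups[i - 1].size + 1.0 / groups[j - 1].size))
    z = (mean_ranks[i - 1] - mean_ranks[j - 1]) / se
    return z, float(2.0 * norm.sf(abs(z)))


def hypergeom_tail_brute(overlap: int, query: int, set_size: int, universe: int) -> float:
    """Exact upper-tail probability by integer enumeration."""
    num = sum(
        comb(set_size, x) * comb(universe - set_size, query - x)
        for x in range(overlap, min(query, set_size) + 1)
    )
    return num / comb(universe, query)


def average_linkage_cophenetic(D: np.ndarray) -> np.ndarray:
    """Cophenetic distances from an explicit UPGMA agglomeration.

    Returns the condensed upper-triangle vector (same pair order as
    ``scipy.spatial.distance.squareform``).  Cluster-cluster distance is
    the unweighted mean of all between-point original distances; the
    cophenetic distance of two points is the merge height at which they
    first share a cluster.
    """
    D = np.asarray(D, dtype=float)
    n = D.shape[0]
    clusters: list[list[int]] = [[i] for i in range(n)]
    coph = np.zeros((n, n))
    active = list(range(n))

    def cluster_dist(a: list[int], b: list[int]) -> float:
        return float(np.mean([D[p, q] for p in a for q in b]))

    while len(active) > 1:
        best = None
        for ai in range(len(active)):
            for bi in range(ai + 1, len(active)):
                d = cluster_dist(clusters[active[ai]], clusters[active[bi]])
                if best is None or d < best[0]:
                    best = (d, ai, bi)
        d, ai, bi = best
        a, b = active[ai], active[bi]
        for p in clusters[a]:
            for q in clusters[b]:
                coph[p, q] = coph[q, p] = d
        clusters.append(clusters[a] + clusters[b])
        active = [x for m, x in enumerate(active) if m not in (ai, bi)] + [len(clusters) - 1]

    out = []
    for i in range(n):
        for j in range(i + 1, n):
            out.append(coph[i, j])
    return np.asarray(out)


def cophenetic_coefficient_brute(consensus: np.ndarray) -> float:
    """Pearson correlation of 1-C distances with UPGMA cophenetic distances."""
    C = np.asarray(consensus, dtype=float)
    D = 1.0 - C
    np.fill_diagonal(D, 0.0)
    n = D.shape[0]
    d = np.asarray([D[i, j] for i in range(n) for j in range(i + 1, n)])
    coph = average_linkage_cophenetic(D)
    dx = d - d.mean()
    cy = coph - coph.mean()
    return float(np.dot(dx, cy) / np.sqrt(np.dot(dx, dx) * np.dot(cy, cy)))


def auc_brute(scores, labels) -> float:
    """Mann-Whitney AUC by enumerating all positive-negative pairs."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                wins += 1.0
            elif p == q:
                wins += 0.5
    return wins / (pos.size * neg.size)


def welch_t_brute(x, y) -> tuple[float, float]:
    """Welch t with Welch-Satterthwaite df, from the textbook formulas."""
    from scipy.stats import t as tdist

    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    vx, vy = x.var(ddof=1) / x.size, y.var(ddof=1) / y.size
    t = (x.mean() - y.mean()) / np.sqrt(vx + vy)
    df = (vx + vy) ** 2 / (vx**2 / (x.size - 1) + vy**2 / (y.size - 1))
    return float(t), float(2.0 * tdist.sf(abs(t), df))


def random_consensus(rng: np.random.Generator, n: int, n_labelings: int = 40) -> np.ndarray:
    """A valid consensus matrix: averaged random co-clusterings plus a tiny
    symmetric jitter that makes all pairwise distances distinct (so the
    agglomeration order is unambiguous for oracle comparison)."""
    C = np.zeros((n, n))
    for _ in range(n_labelings):
        labels = rng.integers(0, 3, size=n)
        C += labels[:, None] == labels[None, :]
    C /= n_labelings
    jitter = rng.uniform(0, 1e-6, size=(n, n))
    jitter = (jitter + jitter.T) / 2.0
    C = np.clip(C - jitter, 0.0, 1.0)
    np.fill_diagonal(C, 1.0)
    return C
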