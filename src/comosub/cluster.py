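"""Sample/gene cluster assignment and rank-test gene filtering.

Samples take the cluster of their largest ``H`` coefficient.  Genes are
assigned twice: a "max" assignment (cluster of the largest ``W = A F``
coefficient; relatively upregulated there) and a "min" assignment
(smallest coefficient; relatively downregulated).  Plain argmax/argmin
assignment puts every gene somewhere, so assignments are then filtered:
a gene stays in cluster i only if its per-cluster fold-change
distributions differ overall (Kruskal-Wallis, Bonferroni over genes
tested) and every Dunn post-hoc pair involving cluster i is significant
(Bonferroni over the k(k-1)/2 pairs).  Surviving genes form the
relatively-up/-down sets ``G_i^+`` / ``G_i^-``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import FoldChangeMatrix
from .nmf import ConvexNMFFit

log = logging.getLogger(__name__)

#: per-gene rows with zero spread are excluded from assignment/filtering
_CONSTANT_FLAG = 0


@dataclass
class ClusterAssignment:
    """Sample clusters plus filtered up/down gene clusters.

    ``sample_cluster`` maps patient ID -> cluster in 1..k.  ``G_up[i]`` /
    ``G_down[i]`` are the filtered relatively-up/-down gene sets of cluster
    i.  ``per_gene_stats`` holds, per direction, the KW statistic/q-value
    and the per-pair Dunn q-values for every gene tested.
    """

    k: int
    sample_cluster: dict[str, int]
    up_assignment: dict[str, int]
    down_assignment: dict[str, int]
    G_up: dict[int, set[str]] = field(default_factory=dict)
    G_down: dict[int, set[str]] = field(default_factory=dict)
    per_gene_stats: dict[str, pd.DataFrame] = field(default_factory=dict)

    def all_filtered_genes(self) -> set[str]:
        out: set[str] = set()
        for s in self.G_up.values():
            out |= s
        for s in self.G_down.values():
            out |= s
        return out


def assign_samples(fit: ConvexNMFFit) -> np.ndarray:
    """Per-sample cluster labels: argmax of each sample's H coefficients.

    Labels are 1-based; ties resolve to the lowest cluster index.
    """
    return np.argmax(fit.H, axis=1) + 1


def assign_genes(fit: ConvexNMFFit, direction: str) -> tuple[np.ndarray, np.ndarray]:
    """Per-gene labels from W = A F rows.

    ``direction="max"`` takes the argmax (relatively upregulated cluster),
    ``"min"`` the argmin.  Returns ``(labels, valid)`` where constant rows
    are flagged invalid (label 0) and excluded from downstream filtering.
    """
    if direction not in ("max", "min"):
        raise ValueError("direction must be 'max' or 'min'")
    W = fit.W
    labels = (np.argmax(W, axis=1) if direction == "max" else np.argmin(W, axis=1)) + 1
    valid = np.ptp(W, axis=1) > 0
    labels = np.where(valid, labels, _CONSTANT_FLAG)
    return labels, valid


def kruskal_wallis_gene(values_by_cluster) -> tuple[float, float]:
    """Kruskal-Wallis H (tie-corrected mid-ranks) and its chi-square p-value.

    All-identical values leave the statistic undefined; that degenerate
    case returns ``(0.0, 1.0)``.
    """
    groups = [np.asarray(g, dtype=float) for g in values_by_cluster]
    if len(groups) < 3:
        raise ValueError("Kruskal-Wallis filtering needs >= 3 groups")
    if any(g.size == 0 for g in groups):
        raise ValueError("empty group in Kruskal-Wallis test")
    pooled = np.concatenate(groups)
    if np.ptp(pooled) == 0:
        return 0.0, 1.0
    stat, p = stats.kruskal(*groups)
    return float(stat), float(p)


def dunn_pairwise(values_by_cluster, pair: tuple[int, int]) -> tuple[float, float]:
    """Dunn's post-hoc z-test on mean ranks for one cluster pair.

    z = (R_i - R_j) / sqrt((N(N+1)/12 - sum(t^3 - t)/(12(N-1))) (1/n_i + 1/n_j))
    with ranks over the pooled values and the tie-group correction term.
    Two-sided normal p.  ``pair`` uses 1-based cluster indices; a fully
    tied pool (zero denominator) returns ``(0.0, 1.0)``.
    """
    groups = [np.asarray(g, dtype=float) for g in values_by_cluster]
    if len(groups) < 3:
        raise ValueError("Dunn post-hoc needs >= 3 groups")
    if any(g.size == 0 for g in groups):
        raise ValueError("empty group in Dunn test")
    i, j = pair
    if not (1 <= i <= len(groups) and 1 <= j <= len(groups)):
        raise ValueError(f"pair {pair} out of range for {len(groups)} groups")
    if i == j:
        return 0.0, 1.0
    pooled = np.concatenate(groups)
    N = pooled.size
    ranks = stats.rankdata(pooled)
    bounds = np.cumsum([0] + [g.size for g in groups])
    mean_rank = [ranks[bounds[m] : bounds[m + 1]].mean() for m in range(len(groups))]
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(counts**3 - counts))
    var = N * (N + 1) / 12.0 - tie_term / (12.0 * (N - 1))
    denom_sq = var * (1.0 / groups[i - 1].size + 1.0 / groups[j - 1].size)
    if denom_sq <= 0:
        return 0.0, 1.0
    z = (mean_rank[i - 1] - mean_rank[j - 1]) / np.sqrt(denom_sq)
    p = 2.0 * stats.norm.sf(abs(z))
    return float(z), float(p)


def _filter_direction(
    fc: FoldChangeMatrix,
    sample_labels: np.ndarray,
    gene_labels: np.ndarray,
    valid: np.ndarray,
    k: int,
    alpha: float,
) -> tuple[dict[int, set[str]], pd.DataFrame]:
    """KW + Dunn filtering for one direction's gene assignment."""
    cluster_cols = {c: np.flatnonzero(sample_labels == c) for c in range(1, k + 1)}
    empty = [c for c, cols in cluster_cols.items() if cols.size == 0]
    if empty:
        raise ValueError(f"sample clusters without members: {empty}")
    small = [c for c, cols in cluster_cols.items() if cols.size < 2]
    if small:
        log.warning("sample clusters with a single member: %s", small)

    tested = np.flatnonzero(valid)
    n_tested = tested.size
    pairs = list(combinations(range(1, k + 1), 2))
    n_pairs = len(pairs)

    rows = []
    selected: dict[int, set[str]] = {c: set() for c in range(1, k + 1)}
    for gi in tested:
        gene = fc.gene_ids[gi]
        cluster = int(gene_labels[gi])
        groups = [fc.values[gi, cluster_cols[c]] for c in range(1, k + 1)]
        H, p = kruskal_wallis_gene(groups)
        q_kw = min(1.0, p * n_tested)
        row: dict[str, object] = {
            "gene": gene,
            "cluster": cluster,
            "kw_stat": H,
            "kw_q": q_kw,
        }
        keep = q_kw < alpha
        if keep:
            own_ok = True
            for a, b in pairs:
                _, dp = dunn_pairwise(groups, (a, b))
                q_d = min(1.0, dp * n_pairs)
                row[f"dunn_q_{a}_{b}"] = q_d
                if (a == cluster or b == cluster) and not (q_d < alpha):
                    own_ok = False
            keep = own_ok
        row["selected"] = keep
        rows.append(row)
        if keep:
            selected[cluster].add(gene)
    stats_df = pd.DataFrame(rows)
    return selected, stats_df


def select_cluster_genes(
    fc: FoldChangeMatrix,
    fit: ConvexNMFFit,
    alpha: float = 0.05,
) -> ClusterAssignment:
    """Build the filtered bi-clustering from a factorization.

    Per direction (max/min): Kruskal-Wallis across the k sample-cluster
    fold-change distributions of each assigned gene, Bonferroni over the
    genes tested in that direction; KW survivors then need every Dunn pair
    involving their own cluster significant after a Bonferroni correction
    over the k(k-1)/2 pairs.  Needs k >= 3.
    """
    k = fit.k
    if k < 3:
        raise ValueError("gene filtering requires k >= 3 sample clusters")
    sample_labels = assign_samples(fit)
    up_labels, up_valid = assign_genes(fit, "max")
    down_labels, down_valid = assign_genes(fit, "min")

    G_up, stats_up = _filter_direction(fc, sample_labels, up_labels, up_valid, k, alpha)
    G_down, stats_down = _filter_direction(fc, sample_labels, down_labels, down_valid, k, alpha)
    for c in range(1, k + 1):
        log.info(
            "cluster %d: %d samples, |G+|=%d, |G-|=%d",
            c,
            int(np.sum(sample_labels == c)),
            len(G_up[c]),
            len(G_down[c]),
        )
    return ClusterAssignment(
        k=k,
        sample_cluster=dict(zip(fc.patient_ids, (int(c) for c in sample_labels))),
        up_assignment={
            g: int(c) for g, c, v in zip(fc.gene_ids, up_labels, up_valid) if v
        },
        down_assignment={
            g: int(c) for g, c, v in zip(fc.gene_ids, down_labels, down_valid) if v
        },
        G_up=G_up,
        G_down=G_down,
        per_gene_stats={"up": stats_up, "down": stats_down},
    )
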