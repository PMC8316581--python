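"""Per-cluster differential-expression modules versus controls.

The filtered gene clusters say a gene behaves differently *across patient
clusters*; they do not say it is differentially expressed versus healthy
controls.  This stage pools every filtered gene (union of the up/down
cluster sets), then for each sample cluster i tests each pooled gene
between that cluster's patients and all controls (Welch t, Bonferroni over
genes tested, per cluster).  Survivors split by the sign of the patient -
control mean difference into the DEG modules ``M_i^+`` / ``M_i^-``.

Tests run on the normalized expression dataset (the one still carrying
control columns), not on fold changes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .cluster import ClusterAssignment
from .datatypes import ExpressionDataset

log = logging.getLogger(__name__)


@dataclass
class DEGModules:
    """Per-cluster up/down DEG modules and the per-test statistics."""

    k: int
    M_up: dict[int, set[str]] = field(default_factory=dict)
    M_down: dict[int, set[str]] = field(default_factory=dict)
    per_gene_per_cluster: pd.DataFrame = field(default_factory=pd.DataFrame)

    def module(self, cluster: int, direction: str) -> set[str]:
        if direction == "up":
            return self.M_up.get(cluster, set())
        if direction == "down":
            return self.M_down.get(cluster, set())
        raise ValueError("direction must be 'up' or 'down'")


def welch_t_test(x, y) -> tuple[float, float]:
    """Welch's unequal-variance t-test, two-sided.

    Both samples need >= 2 values.  The fully degenerate case (both
    variances zero, equal means) returns ``(0.0, 1.0)``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("welch_t_test needs >= 2 values per sample")
    if x.var(ddof=1) == 0 and y.var(ddof=1) == 0:
        if x.mean() == y.mean():
            return 0.0, 1.0
        return float(np.inf) if x.mean() > y.mean() else float(-np.inf), 0.0
    t, p = stats.ttest_ind(x, y, equal_var=False)
    return float(t), float(p)


def build_deg_modules(
    ds: ExpressionDataset,
    assignment: ClusterAssignment,
    alpha: float = 0.05,
    pooled_variance: bool = False,
) -> DEGModules:
    """Per-cluster patient-vs-control t-tests over the pooled filtered genes.

    ``pooled_variance=True`` switches from Welch to the classic
    equal-variance t-test.
    """
    tested_genes = sorted(assignment.all_filtered_genes())
    if not tested_genes:
        raise ValueError("no genes survived cluster filtering; nothing to test")
    gene_index = {g: i for i, g in enumerate(ds.gene_ids)}
    missing = [g for g in tested_genes if g not in gene_index]
    if missing:
        raise ValueError(f"filtered genes absent from dataset: {missing[:5]}")

    cmask = ds.control_mask
    if not cmask.any():
        raise ValueError("DEG testing requires control samples")
    controls = ds.values[:, cmask]
    sample_pos = {s: i for i, s in enumerate(ds.sample_ids)}

    rows = [gene_index[g] for g in tested_genes]
    n_tested = len(tested_genes)
    records = []
    M_up: dict[int, set[str]] = {}
    M_down: dict[int, set[str]] = {}
    for c in range(1, assignment.k + 1):
        cluster_samples = [s for s, lab in assignment.sample_cluster.items() if lab == c]
        cols = [sample_pos[s] for s in cluster_samples]
        X = ds.values[np.ix_(rows, cols)]
        Y = controls[rows]
        t, p = stats.ttest_ind(X, Y, axis=1, equal_var=pooled_variance)
        diff = X.mean(axis=1) - Y.mean(axis=1)
        # zero-variance ties produce NaN; equal means -> p=1, else p=0
        nan = ~np.isfinite(p)
        if nan.any():
            p = np.where(nan & (diff == 0), 1.0, np.where(nan, 0.0, p))
            t = np.where(np.isfinite(t), t, np.sign(diff) * np.inf)
        q = np.minimum(1.0, p * n_tested)
        sig = q < alpha
        M_up[c] = {g for g, s, d in zip(tested_genes, sig, diff) if s and d > 0}
        M_down[c] = {g for g, s, d in zip(tested_genes, sig, diff) if s and d < 0}
        records.append(
            pd.DataFrame(
                {
                    "gene": tested_genes,
                    "cluster": c,
                    "t": t,
                    "q": q,
                    "mean_diff": diff,
                }
            )
        )
        log.info("cluster %d: |M+|=%d, |M-|=%d (of %d tested)", c, len(M_up[c]), len(M_down[c]), n_tested)
    return DEGModules(
        k=assignment.k,
        M_up=M_up,
        M_down=M_down,
        per_gene_per_cluster=pd.concat(records, ignore_index=True),
    )
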