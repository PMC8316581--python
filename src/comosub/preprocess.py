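"""Data preparation: duplicate-ID merging, gene filtering, batch-mean
adjustment and the log2 fold-change transform against control means.

The transform implemented here is literal: ``y_ij = log2(patient_ij) -
log2(mean_controls(gene_i))``, applied to the stored expression values.
Nonpositive values are a hard error rather than pseudo-counted, since the
intended inputs are positive microarray-style intensities.
"""

from __future__ import annotations

import logging
from dataclasses import replace

import numpy as np

from .datatypes import ExpressionDataset, FoldChangeMatrix

log = logging.getLogger(__name__)


def merge_duplicate_genes(ds: ExpressionDataset) -> ExpressionDataset:
    """Collapse rows sharing a gene ID into their per-sample mean.

    Gene order is the order of first occurrence.
    """
    order: dict[str, int] = {}
    groups: dict[str, list[int]] = {}
    for i, g in enumerate(ds.gene_ids):
        if g not in order:
            order[g] = len(order)
            groups[g] = []
        groups[g].append(i)
    if len(order) == len(ds.gene_ids):
        return ds.copy()
    gene_ids = list(order)
    values = np.empty((len(gene_ids), ds.n_samples))
    for g, rows in groups.items():
        values[order[g]] = ds.values[rows].mean(axis=0)
    n_merged = ds.n_genes - len(gene_ids)
    log.info("merged %d duplicate gene rows into means", n_merged)
    return replace(ds.copy(), gene_ids=gene_ids, values=values)


def filter_genes(ds: ExpressionDataset, keep) -> ExpressionDataset:
    """Retain only genes in ``keep`` (e.g. a protein-coding list), preserving order."""
    keep = set(keep)
    rows = np.asarray([i for i, g in enumerate(ds.gene_ids) if g in keep], dtype=int)
    if rows.size == 0:
        raise ValueError("no genes left after filtering: keep list disjoint from dataset")
    log.info("gene filter retained %d / %d genes", rows.size, ds.n_genes)
    return replace(ds.copy(), gene_ids=[ds.gene_ids[i] for i in rows], values=ds.values[rows])


def remove_batch_effect(ds: ExpressionDataset) -> ExpressionDataset:
    """Equalize per-gene batch means by subtracting (batch mean - grand mean).

    A no-covariate linear batch adjustment: after it, every gene's batch
    means coincide with its grand mean, and the grand mean is unchanged
    when batches are balanced.
    """
    if ds.batch is None:
        raise ValueError("remove_batch_effect requires batch labels")
    batches = sorted(set(ds.batch))
    if len(batches) < 2:
        raise ValueError(f"need >= 2 batches, found {len(batches)}")
    batch_arr = np.asarray(ds.batch)
    values = ds.values.copy()
    grand = values.mean(axis=1, keepdims=True)
    for b in batches:
        cols = batch_arr == b
        if cols.sum() < 2:
            raise ValueError(f"batch {b!r} has fewer than 2 samples")
        values[:, cols] -= values[:, cols].mean(axis=1, keepdims=True) - grand
    return replace(ds.copy(), values=values)


def log2_fold_change(ds: ExpressionDataset) -> FoldChangeMatrix:
    """Per-gene log2 ratio of each patient value to the control mean.

    ``y_ij = log2(patient_ij / normal_i)`` with ``normal_i`` the arithmetic
    mean of gene *i* over control samples.  Columns of the result are the
    patients only.
    """
    pmask = ds.patient_mask
    cmask = ds.control_mask
    if not cmask.any():
        raise ValueError("log2_fold_change requires at least one control sample")
    if not pmask.any():
        raise ValueError("log2_fold_change requires at least one patient sample")
    patients = ds.values[:, pmask]
    if np.any(patients <= 0):
        i, j = np.argwhere(patients <= 0)[0]
        raise ValueError(
            f"nonpositive patient value for gene {ds.gene_ids[i]!r}, "
            f"sample {ds.patient_ids()[j]!r}"
        )
    control_means = ds.values[:, cmask].mean(axis=1)
    if np.any(control_means <= 0):
        i = int(np.argmax(control_means <= 0))
        raise ValueError(f"nonpositive control mean for gene {ds.gene_ids[i]!r}")
    values = np.log2(patients) - np.log2(control_means)[:, None]
    return FoldChangeMatrix(
        gene_ids=list(ds.gene_ids),
        patient_ids=ds.patient_ids(),
        values=values,
        control_means=control_means,
    )
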