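"""Candidate-panel evaluation: logistic regression under cross-validation,
random-panel baselines, and covariate ANOVA across clusters.

The classifier is deliberately plain: full-batch gradient ascent on the
mean log-likelihood of a logistic model, weights (and intercept) starting
at exactly zero, a fixed learning rate and a fixed epoch count, no
regularization.  Features are z-scored per fold with training-fold
statistics.  Performance is the rank-based ROC AUC, averaged over
stratified folds.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold

from .datatypes import ExpressionDataset

log = logging.getLogger(__name__)


@dataclass
class CVResult:
    per_fold_auc: list[float]
    mean_auc: float
    n_folds: int
    learning_rate: float
    epochs: int
    seed: int
    gene_panel: list[str]


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def fit_logistic_gd(
    X: np.ndarray, y: np.ndarray, learning_rate: float = 0.05, epochs: int = 500
) -> np.ndarray:
    """Zero-initialized full-batch logistic regression by gradient ascent.

    Returns the weight vector ``[intercept, w_1 .. w_p]`` after exactly
    ``epochs`` updates with the mean log-likelihood gradient and a fixed
    learning rate.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.shape[0] != y.shape[0]:
        raise ValueError("X row count does not match label count")
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite feature values")
    classes = np.unique(y)
    if not np.array_equal(classes, [0.0, 1.0]):
        raise ValueError("labels must contain both classes 0 and 1")
    Xb = np.hstack([np.ones((X.shape[0], 1)), X])
    w = np.zeros(Xb.shape[1])
    for _ in range(epochs):
        p = _sigmoid(Xb @ w)
        w += learning_rate * (Xb.T @ (y - p)) / Xb.shape[0]
    return w


def predict_proba(X: np.ndarray, w: np.ndarray) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    Xb = np.hstack([np.ones((X.shape[0], 1)), X])
    return _sigmoid(Xb @ w)


def roc_auc(scores, labels) -> float:
    """Rank-based ROC AUC (Mann-Whitney, half credit for tied scores)."""
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("AUC requires both classes")
    return float(roc_auc_score(labels, np.asarray(scores, dtype=float)))


def cross_validated_auc(
    ds: ExpressionDataset,
    panel,
    n_folds: int = 10,
    learning_rate: float = 0.05,
    epochs: int = 500,
    seed: int = 0,
) -> CVResult:
    """Stratified k-fold CV AUC of a gene panel classifying patient vs control.

    Panel genes missing from the dataset are dropped (their count is
    logged); features are the expression rows of the remaining panel,
    z-scored with training-fold statistics inside each fold.
    """
    panel = list(dict.fromkeys(panel))
    gene_index = {g: i for i, g in enumerate(ds.gene_ids)}
    present = [g for g in panel if g in gene_index]
    n_missing = len(panel) - len(present)
    if n_missing:
        log.info("%d of %d panel genes missing from dataset; %d used", n_missing, len(panel), len(present))
    if not present:
        raise ValueError("no panel gene is measured in the dataset")

    X = ds.values[[gene_index[g] for g in present]].T  # samples x genes
    y = ds.patient_mask.astype(float)
    counts = np.bincount(y.astype(int))
    if counts.min() < n_folds:
        raise ValueError(
            f"each class needs >= n_folds={n_folds} samples, got {counts.tolist()}"
        )
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    aucs = []
    for train, test in skf.split(X, y):
        assert len(np.unique(y[test])) == 2  # stratification guarantees both classes
        mu = X[train].mean(axis=0)
        sd = X[train].std(axis=0)
        sd[sd < 1e-8] = 1.0
        w = fit_logistic_gd((X[train] - mu) / sd, y[train], learning_rate, epochs)
        scores = predict_proba((X[test] - mu) / sd, w)
        aucs.append(roc_auc(scores, y[test]))
    return CVResult(
        per_fold_auc=aucs,
        mean_auc=float(np.mean(aucs)),
        n_folds=n_folds,
        learning_rate=learning_rate,
        epochs=epochs,
        seed=seed,
        gene_panel=present,
    )


def random_gene_baseline(
    ds: ExpressionDataset,
    panel_size: int,
    reps: int,
    candidate_mean_auc: float,
    n_folds: int = 10,
    learning_rate: float = 0.05,
    epochs: int = 500,
    seed: int = 0,
) -> tuple[np.ndarray, float]:
    """Mean CV-AUCs of ``reps`` random same-size gene panels, plus a
    one-sample two-sided t-test p comparing them to the candidate mean AUC."""
    if panel_size > ds.n_genes:
        raise ValueError("panel_size exceeds the number of measured genes")
    if reps < 2:
        raise ValueError("need reps >= 2 for the baseline comparison")
    rng = np.random.default_rng(seed)
    means = []
    for r in range(reps):
        panel = rng.choice(ds.gene_ids, size=panel_size, replace=False)
        cv = cross_validated_auc(
            ds, panel, n_folds=n_folds, learning_rate=learning_rate,
            epochs=epochs, seed=seed + r + 1,
        )
        means.append(cv.mean_auc)
    means_arr = np.asarray(means)
    if np.ptp(means_arr) == 0:
        p = 1.0 if means_arr[0] == candidate_mean_auc else 0.0
    else:
        p = float(stats.ttest_1samp(means_arr, candidate_mean_auc).pvalue)
    return means_arr, p


def covariate_anova(covariate, clusters) -> tuple[float, float]:
    """One-way ANOVA of a numeric covariate (e.g. age) across sample clusters."""
    covariate = np.asarray(covariate, dtype=float)
    clusters = np.asarray(clusters)
    groups = [covariate[clusters == c] for c in np.unique(clusters)]
    if len(groups) < 2 or any(g.size < 2 for g in groups):
        raise ValueError("ANOVA needs >= 2 clusters with >= 2 samples each")
    if all(np.ptp(g) == 0 for g in groups) and np.ptp(covariate) == 0:
        return 0.0, 1.0
    F, p = stats.f_oneway(*groups)
    return float(F), float(p)
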