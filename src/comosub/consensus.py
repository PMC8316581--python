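"""Consensus matrices, cophenetic correlation, and rank selection.

Cluster-count selection follows the consensus-clustering recipe: repeat the
factorization under random restarts, summarize how consistently sample
pairs co-cluster in a consensus matrix ``C`` (entries in [0, 1]), and score
each rank k by the cophenetic correlation between the consensus distance
``1 - C`` and the dendrogram distances of its average-linkage hierarchical
clustering.  A rank whose clustering is stable yields a near-ultrametric
consensus distance and a cophenetic coefficient near 1.

Three consensus protocols are available:

``pooled`` (default)
    one consensus per rank, averaging the connectivity matrices of every
    recorded iteration of every restart; one cophenetic value per rank.
    This reads "average of all connectivity matrices" across the whole
    restart protocol and is the most stable discriminator of the three.
``iterations``
    one consensus per run, averaging the connectivity matrices of every
    recorded iteration of that run; one cophenetic value per restart,
    averaged over restarts.
``restarts``
    one consensus per rank, averaging only the final-assignment
    connectivity matrices across restarts (the Brunet-style protocol);
    one cophenetic value per rank.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import cophenet, linkage
from scipy.spatial.distance import squareform

from .nmf import ConvexNMFFit, convex_nmf_fit

log = logging.getLogger(__name__)

#: returned by :func:`cophenetic_coefficient` when either distance vector is
#: constant (zero variance), e.g. a consensus with one cluster at all times.
COPHENETIC_UNDEFINED = float("nan")


@dataclass
class ConsensusResult:
    """A consensus matrix with its cophenetic correlation coefficient."""

    consensus: np.ndarray
    cophenetic: float
    k: int
    n_runs_averaged: int

    def __post_init__(self) -> None:
        C = np.asarray(self.consensus, dtype=float)
        if C.ndim != 2 or C.shape[0] != C.shape[1]:
            raise ValueError("consensus must be square")
        if not np.allclose(C, C.T):
            raise ValueError("consensus must be symmetric")
        if C.min() < -1e-12 or C.max() > 1 + 1e-12:
            raise ValueError("consensus entries must lie in [0, 1]")
        if not np.allclose(np.diag(C), 1.0):
            raise ValueError("consensus diagonal must be 1")
        self.consensus = C


@dataclass
class RankSelection:
    """Outcome of scanning ranks k_min..k_max."""

    per_k_mean_cophenetic: dict[int, float]
    chosen_k: int
    best_fit: ConvexNMFFit
    per_k_restart_cophenetic: dict[int, list[float]] = field(default_factory=dict)


def connectivity_matrix(assignment) -> np.ndarray:
    """Binary sample x sample matrix: 1 where two samples share a cluster."""
    labels = np.asarray(assignment)
    if labels.size == 0:
        raise ValueError("empty assignment")
    return (labels[:, None] == labels[None, :]).astype(float)


def consensus_from_trace(fit: ConvexNMFFit, burn_in: int = 0) -> ConsensusResult:
    """Average the per-iteration connectivity matrices of one run.

    ``burn_in`` drops that many leading iterations before averaging.
    """
    trace = fit.assignment_trace[burn_in:]
    if trace.shape[0] == 0:
        raise ValueError("assignment trace is empty (burn_in too large?)")
    n = trace.shape[1]
    consensus = np.zeros((n, n))
    for labels in trace:
        consensus += labels[:, None] == labels[None, :]
    consensus /= trace.shape[0]
    return ConsensusResult(
        consensus=consensus,
        cophenetic=cophenetic_coefficient(consensus),
        k=fit.k,
        n_runs_averaged=1,
    )


def consensus_across_fits(
    fits: list[ConvexNMFFit], pool_iterations: bool = False, burn_in: int = 0
) -> ConsensusResult:
    """Average connectivity matrices across several restarts.

    With ``pool_iterations=False`` only each restart's final assignment
    contributes; with ``True`` every recorded iteration of every restart
    (after ``burn_in``) enters the average.
    """
    if not fits:
        raise ValueError("no fits supplied")
    n = fits[0].n_samples
    consensus = np.zeros((n, n))
    count = 0
    for fit in fits:
        if pool_iterations:
            trace = fit.assignment_trace[burn_in:]
            if trace.shape[0] == 0:
                raise ValueError("assignment trace is empty (burn_in too large?)")
            for labels in trace:
                consensus += labels[:, None] == labels[None, :]
                count += 1
        else:
            consensus += connectivity_matrix(fit.sample_labels())
            count += 1
    consensus /= count
    return ConsensusResult(
        consensus=consensus,
        cophenetic=cophenetic_coefficient(consensus),
        k=fits[0].k,
        n_runs_averaged=len(fits),
    )


def cophenetic_coefficient(consensus: np.ndarray) -> float:
    """Pearson correlation between consensus distances and dendrogram distances.

    The consensus distance is ``1 - C`` element-wise (same-cluster pairs at
    distance 0); its average-linkage dendrogram supplies the cophenetic
    distances.  Returns :data:`COPHENETIC_UNDEFINED` (NaN) when either
    distance vector has zero variance.
    """
    C = np.asarray(consensus, dtype=float)
    if C.ndim != 2 or C.shape[0] != C.shape[1] or not np.allclose(C, C.T):
        raise ValueError("consensus must be a symmetric square matrix")
    if C.min() < -1e-12 or C.max() > 1 + 1e-12:
        raise ValueError("consensus entries must lie in [0, 1]")
    D = 1.0 - C
    np.fill_diagonal(D, 0.0)
    d = squareform(D, checks=False)
    Z = linkage(d, method="average")
    coph = cophenet(Z)
    if np.ptp(d) == 0 or np.ptp(coph) == 0:
        return COPHENETIC_UNDEFINED
    dc = d - d.mean()
    cc = coph - coph.mean()
    r = float(np.dot(dc, cc) / np.sqrt(np.dot(dc, dc) * np.dot(cc, cc)))
    return max(-1.0, min(1.0, r))


def select_rank(
    A: np.ndarray,
    k_min: int,
    k_max: int,
    n_restarts: int = 10,
    max_iter: int = 200,
    tol: float = 1e-6,
    seed: int = 0,
    consensus_mode: str = "pooled",
    burn_in: int = 0,
) -> RankSelection:
    """Scan ranks, score each by the cophenetic coefficient, keep the argmax.

    For every rank, ``n_restarts`` seeded fits are run and summarized into
    cophenetic values according to ``consensus_mode`` (see the module
    docstring for the three protocols); the rank score is the mean of the
    finite values.  Ties go to the smallest rank.  ``best_fit`` is the
    restart with the highest cophenetic value at the chosen rank, scored
    by its own trajectory consensus.
    """
    if k_min < 2:
        raise ValueError("k_min must be >= 2")
    if k_max < k_min:
        raise ValueError("k_max must be >= k_min")
    if consensus_mode not in ("pooled", "iterations", "restarts"):
        raise ValueError("consensus_mode must be 'pooled', 'iterations' or 'restarts'")

    ss = np.random.SeedSequence(seed)
    per_k_mean: dict[int, float] = {}
    per_k_values: dict[int, list[float]] = {}
    fits_by_k: dict[int, list[ConvexNMFFit]] = {}
    for k in range(k_min, k_max + 1):
        child_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n_restarts)]
        fits = [convex_nmf_fit(A, k, max_iter=max_iter, tol=tol, seed=s) for s in child_seeds]
        fits_by_k[k] = fits
        if consensus_mode == "iterations":
            values = [consensus_from_trace(f, burn_in=burn_in).cophenetic for f in fits]
        elif consensus_mode == "pooled":
            values = [consensus_across_fits(fits, pool_iterations=True, burn_in=burn_in).cophenetic]
        else:
            values = [consensus_across_fits(fits).cophenetic]
        per_k_values[k] = values
        finite = [v for v in values if np.isfinite(v)]
        per_k_mean[k] = float(np.mean(finite)) if finite else COPHENETIC_UNDEFINED

    if all(not np.isfinite(v) for v in per_k_mean.values()):
        raise ValueError("cophenetic coefficient undefined at every rank")

    # argmax of the mean cophenetic; ties and NaNs resolve toward smaller k
    chosen_k = max(
        sorted(per_k_mean),
        key=lambda k: (per_k_mean[k] if np.isfinite(per_k_mean[k]) else -np.inf),
    )
    if chosen_k < 3:
        warnings.warn(
            f"chosen rank k={chosen_k} < 3: downstream Kruskal-Wallis/Dunn gene "
            "filtering requires at least 3 sample clusters",
            stacklevel=2,
        )

    fits = fits_by_k[chosen_k]
    per_fit = [consensus_from_trace(f, burn_in=burn_in).cophenetic for f in fits]
    scores = [v if np.isfinite(v) else -np.inf for v in per_fit]
    best_fit = fits[int(np.argmax(scores))]
    log.info("selected rank k=%d (mean cophenetic %.4f)", chosen_k, per_k_mean[chosen_k])
    return RankSelection(
        per_k_mean_cophenetic=per_k_mean,
        chosen_k=chosen_k,
        best_fit=best_fit,
        per_k_restart_cophenetic=per_k_values,
    )
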