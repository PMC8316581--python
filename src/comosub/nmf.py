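"""Convex non-negative matrix factorization with multiplicative updates.

The input matrix ``A`` (genes x samples) may be mixed-sign (log2
fold-changes).  Convex NMF factorizes ``A ~ A F H^T`` where the basis
``W = A F`` is constrained to convex combinations of the data columns and
both ``F`` (samples x k) and ``H`` (samples x k) stay element-wise
nonnegative.  The alternating updates touch ``A`` only through the Gram
matrix ``K = A^T A``, split into positive and negative parts ``K = K+ - K-``:

    H_ik <- H_ik * sqrt( [K+ F + H F^T K- F]_ik / [K- F + H F^T K+ F]_ik )
    F_ik <- F_ik * sqrt( [K+ H + K- F H^T H]_ik / [K- H + K+ F H^T H]_ik )

These updates monotonically decrease ||A - A F H^T||_F^2.  Per-iteration
sample assignments (argmax of each H row) are recorded so consensus
matrices can be built from a run's trajectory.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

_DENOM_FLOOR = 1e-12
_INIT_FLOOR = 1e-4


@dataclass
class ConvexNMFFit:
    """Result of one convex-NMF run.

    ``assignment_trace`` holds the argmax-cluster label (1-based) of every
    sample at every recorded iteration, shape (n_iterations, n_samples).
    """

    F: np.ndarray
    H: np.ndarray
    W: np.ndarray
    objective_trace: np.ndarray
    assignment_trace: np.ndarray
    k: int
    seed: int

    @property
    def n_samples(self) -> int:
        return self.H.shape[0]

    @property
    def n_iterations(self) -> int:
        return self.assignment_trace.shape[0]

    def sample_labels(self) -> np.ndarray:
        """Final per-sample cluster labels in 1..k (ties -> lowest index)."""
        return self.assignment_trace[-1]


def positive_negative_parts(B: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Split ``B`` into nonnegative parts with ``B = B_plus - B_minus``."""
    B = np.asarray(B, dtype=float)
    absB = np.abs(B)
    return (absB + B) / 2.0, (absB - B) / 2.0


def _assignments(H: np.ndarray) -> np.ndarray:
    # np.argmax takes the first maximum, which is the lowest-index tie rule
    return np.argmax(H, axis=1) + 1


def _objective(sqnorm_A: float, K: np.ndarray, F: np.ndarray, H: np.ndarray) -> float:
    # ||A - A F H^T||^2 = ||A||^2 - 2 tr(H^T K F) + tr(F^T K F H^T H)
    KF = K @ F
    return float(sqnorm_A - 2.0 * np.sum(H * KF) + np.sum((F.T @ KF) * (H.T @ H)))


def convex_nmf_fit(
    A: np.ndarray,
    k: int,
    max_iter: int = 200,
    tol: float = 1e-6,
    seed: int = 0,
) -> ConvexNMFFit:
    """Run convex NMF on ``A`` (genes x samples) at rank ``k``.

    ``F`` and ``H`` are initialized from seeded uniform(0, 1) draws with a
    small positive floor; updates alternate until the relative objective
    change drops below ``tol`` or ``max_iter`` is reached.  The objective
    and the per-sample argmax assignments are recorded at every iteration.
    """
    A = np.asarray(A, dtype=float)
    if not np.all(np.isfinite(A)):
        raise ValueError("input matrix contains non-finite values")
    n_samples = A.shape[1]
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > n_samples:
        raise ValueError(f"k={k} exceeds the sample count {n_samples}")
    if max_iter < 1:
        raise ValueError("max_iter must be >= 1")

    rng = np.random.default_rng(seed)
    F = rng.uniform(size=(n_samples, k)) + _INIT_FLOOR
    H = rng.uniform(size=(n_samples, k)) + _INIT_FLOOR

    K = A.T @ A  # the updates only see A through its Gram matrix
    Kp, Km = positive_negative_parts(K)
    sqnorm_A = float(np.sum(A * A))

    objective = [_objective(sqnorm_A, K, F, H)]
    assignments = [_assignments(H)]
    prev = objective[0]
    for _ in range(max_iter):
        KpF = Kp @ F
        KmF = Km @ F
        FtKpF = F.T @ KpF
        FtKmF = F.T @ KmF
        H *= np.sqrt((KpF + H @ FtKmF) / (KmF + H @ FtKpF + _DENOM_FLOOR))

        HtH = H.T @ H
        FHtH = F @ HtH
        F *= np.sqrt((Kp @ H + Km @ FHtH) / (Km @ H + Kp @ FHtH + _DENOM_FLOOR))

        obj = _objective(sqnorm_A, K, F, H)
        objective.append(obj)
        assignments.append(_assignments(H))
        if prev > 0 and abs(prev - obj) / max(abs(prev), _DENOM_FLOOR) < tol:
            break
        prev = obj

    return ConvexNMFFit(
        F=F,
        H=H,
        W=A @ F,
        objective_trace=np.asarray(objective),
        assignment_trace=np.asarray(assignments),
        k=k,
        seed=seed,
    )
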