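"""Core containers shared across the pipeline.

An :class:`ExpressionDataset` holds a gene-by-sample log-scale expression
matrix together with per-sample annotation (patient/control group, optional
batch, optional numeric covariates).  A :class:`FoldChangeMatrix` is the
patient-only log2 fold-change matrix fed to convex NMF.  A
:class:`GeneSetCollection` carries named gene sets (pathways) plus the
background universe used for hypergeometric enrichment.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

PATIENT = "patient"
CONTROL = "control"


@dataclass
class ExpressionDataset:
    """Gene x sample expression matrix with sample annotation.

    Parameters
    ----------
    gene_ids : list of str
        Row identifiers; unique after preprocessing (raw input may repeat).
    sample_ids : list of str
        Column identifiers; always unique.
    values : ndarray, shape (n_genes, n_samples)
        Log-scale expression intensities.
    group : list of str
        Per-sample label, each ``"patient"`` or ``"control"``.
    batch : list of str, optional
        Per-sample categorical batch label.
    covariates : DataFrame, optional
        Per-sample numeric covariates (rows indexed by ``sample_ids``).
    """

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    group: list[str]
    batch: list[str] | None = None
    covariates: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if len(self.group) != len(self.sample_ids):
            raise ValueError("group length does not match sample count")
        bad = sorted({g for g in self.group} - {PATIENT, CONTROL})
        if bad:
            raise ValueError(f"unknown group labels: {bad}")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample IDs")
        if self.batch is not None and len(self.batch) != len(self.sample_ids):
            raise ValueError("batch length does not match sample count")

    # -- convenience views ------------------------------------------------
    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def patient_mask(self) -> np.ndarray:
        return np.asarray([g == PATIENT for g in self.group], dtype=bool)

    @property
    def control_mask(self) -> np.ndarray:
        return ~self.patient_mask

    def patient_ids(self) -> list[str]:
        return [s for s, g in zip(self.sample_ids, self.group) if g == PATIENT]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)

    def subset_genes(self, rows: np.ndarray, gene_ids: list[str]) -> "ExpressionDataset":
        return replace(self, gene_ids=list(gene_ids), values=self.values[rows])

    def copy(self) -> "ExpressionDataset":
        return ExpressionDataset(
            gene_ids=list(self.gene_ids),
            sample_ids=list(self.sample_ids),
            values=self.values.copy(),
            group=list(self.group),
            batch=None if self.batch is None else list(self.batch),
            covariates=None if self.covariates is None else self.covariates.copy(),
        )

    def equals(self, other: "ExpressionDataset") -> bool:
        same = (
            self.gene_ids == other.gene_ids
            and self.sample_ids == other.sample_ids
            and self.group == other.group
            and self.batch == other.batch
            and np.array_equal(self.values, other.values)
        )
        if not same:
            return False
        if (self.covariates is None) != (other.covariates is None):
            return False
        if self.covariates is not None:
            return self.covariates.equals(other.covariates)
        return True


@dataclass
class FoldChangeMatrix:
    """Patient-only log2 fold-change matrix.

    ``values[i, j] = log2(patient_ij / normal_i)`` where ``normal_i`` is the
    mean expression of gene *i* over the control samples (``control_means``).
    """

    gene_ids: list[str]
    patient_ids: list[str]
    values: np.ndarray
    control_means: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.control_means = np.asarray(self.control_means, dtype=float)
        if self.values.shape != (len(self.gene_ids), len(self.patient_ids)):
            raise ValueError("fold-change matrix shape mismatch")
        if self.control_means.shape != (len(self.gene_ids),):
            raise ValueError("control_means length mismatch")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("fold-change values must be finite")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_patients(self) -> int:
        return len(self.patient_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.patient_ids)


@dataclass
class GeneSetCollection:
    """Named gene sets plus the enrichment background universe."""

    sets: dict[str, set[str]]
    universe: set[str] = field(default_factory=set)
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if not members:
                raise ValueError(f"gene set {name!r} is empty")
        if not self.universe:
            self.universe = set().union(*self.sets.values()) if self.sets else set()

    def __len__(self) -> int:
        return len(self.sets)

    def names(self) -> list[str]:
        return list(self.sets)


@dataclass
class RunConfig:
    """Run parameters for the full pipeline.

    Defaults follow the published protocol: ranks 2-10 with 10 random
    restarts each, Bonferroni level 0.05 throughout, logistic-regression
    learning rate 0.05 under tenfold cross-validation, and 100 random-panel
    baseline repetitions.
    """

    k_min: int = 2
    k_max: int = 10
    n_restarts: int = 10
    max_iter: int = 200
    tol: float = 1e-6
    alpha: float = 0.05
    seed: int = 0
    learning_rate: float = 0.05
    n_folds: int = 10
    epochs: int = 500
    baseline_reps: int = 100
    consensus_mode: str = "pooled"  # or "iterations" / "restarts"

    def __post_init__(self) -> None:
        if not (2 <= self.k_min <= self.k_max):
            raise ValueError(f"need 2 <= k_min <= k_max, got {self.k_min}..{self.k_max}")
        if self.n_restarts < 1:
            raise ValueError("n_restarts must be >= 1")
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must lie in (0, 1)")
        if self.consensus_mode not in ("pooled", "iterations", "restarts"):
            raise ValueError("consensus_mode must be 'pooled', 'iterations' or 'restarts'")
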