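"""Synthetic paired two-disease expression studies with planted structure.

The generator emulates the statistical shape the analysis assumes: each
disease cohort is partitioned into ``k_true`` latent patient clusters;
every cluster carries an up- and a down-regulated gene module (additive
``+/- effect_size`` on a log2 expression scale); i.i.d. Gaussian noise is
added everywhere; controls carry baseline plus noise only.  A designated
cluster pair shares a set of candidate genes planted with the same
direction in both diseases.  Pathway sets are built around the planted
modules (plus decoys) and reference gene lists around the shared
candidates (plus decoys), so that the planted pair is the unique maximizer
of reference-pathway overlap and every downstream stage has ground truth.

Baselines are drawn uniformly on [6, 10] log2 units and noise is truncated
at four standard deviations, keeping all expression values strictly
positive so log2 ratios are always defined.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import ceil

import numpy as np
import pandas as pd

from .datatypes import ExpressionDataset, GeneSetCollection

_BASELINE_LOW = 6.0
_BASELINE_HIGH = 10.0
_NOISE_TRUNC_SD = 4.0
#: fraction of shared candidates planted in the up modules (rest go down)
_SHARED_UP_FRACTION = 0.7


@dataclass
class SimulationDesign:
    """Parameters of one simulated disease cohort.

    All effects are additive on the log2 scale.  ``shared_pair`` names the
    (cluster in disease A, cluster in disease B) pair that carries the
    planted cross-disease candidates; ``module_size`` is per cluster per
    direction.
    """

    n_genes: int = 1000
    k_true: int = 3
    patients_per_cluster: list[int] = field(default_factory=lambda: [30, 30, 30])
    n_controls: int = 30
    effect_size: float = 2.0
    noise_sd: float = 0.5
    module_size: int = 40
    shared_candidate_size: int = 20
    shared_pair: tuple[int, int] = (3, 3)
    batch_offset: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k_true < 2:
            raise ValueError("k_true must be >= 2")
        if len(self.patients_per_cluster) != self.k_true:
            raise ValueError("patients_per_cluster length must equal k_true")
        if 2 * self.module_size * self.k_true > self.n_genes:
            raise ValueError("module sizes x clusters exceed n_genes")
        if self.shared_candidate_size > self.module_size:
            raise ValueError("shared_candidate_size must be <= module_size")
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        if self.n_controls < 2:
            raise ValueError("need at least 2 controls")

    @property
    def n_patients(self) -> int:
        return int(sum(self.patients_per_cluster))


@dataclass
class GroundTruth:
    """Planted structure of one simulated cohort."""

    sample_cluster: dict[str, int]
    up_modules: dict[int, set[str]]
    down_modules: dict[int, set[str]]
    shared_candidates: dict[str, str] = field(default_factory=dict)  # gene -> direction
    enriched_sets: set[str] = field(default_factory=set)

    def module_genes(self) -> set[str]:
        out: set[str] = set()
        for s in self.up_modules.values():
            out |= s
        for s in self.down_modules.values():
            out |= s
        return out


@dataclass
class PairedStudy:
    """A two-disease synthetic study plus everything the pipeline consumes."""

    dataset_a: ExpressionDataset
    dataset_b: ExpressionDataset
    gene_sets: GeneSetCollection
    reference_genes_a: list[str]
    reference_genes_b: list[str]
    truth_a: GroundTruth
    truth_b: GroundTruth

    @property
    def shared_candidates(self) -> dict[str, str]:
        return self.truth_a.shared_candidates


def _gene_ids(n: int) -> list[str]:
    return [f"G{i:05d}" for i in range(1, n + 1)]


def _truncated_noise(rng: np.random.Generator, sd: float, shape) -> np.ndarray:
    noise = rng.normal(0.0, sd, size=shape)
    return np.clip(noise, -_NOISE_TRUNC_SD * sd, _NOISE_TRUNC_SD * sd)


def _draw_modules(
    design: SimulationDesign,
    rng: np.random.Generator,
    gene_ids: list[str],
    forced: dict[tuple[int, str], list[str]] | None = None,
    exclude: set[str] | None = None,
) -> tuple[dict[int, set[str]], dict[int, set[str]]]:
    """Draw disjoint up/down modules per cluster, honoring forced members."""
    forced = forced or {}
    taken: set[str] = set(exclude or set())
    for genes in forced.values():
        taken |= set(genes)
    free = [g for g in gene_ids if g not in taken]
    rng.shuffle(free)
    it = iter(free)
    up: dict[int, set[str]] = {}
    down: dict[int, set[str]] = {}
    for c in range(1, design.k_true + 1):
        for direction, store in (("up", up), ("down", down)):
            members = list(forced.get((c, direction), []))
            while len(members) < design.module_size:
                members.append(next(it))
            store[c] = set(members)
    return up, down


def generate_disease_dataset(
    design: SimulationDesign,
    disease_tag: str,
    forced_modules: dict[tuple[int, str], list[str]] | None = None,
    exclude_genes: set[str] | None = None,
) -> tuple[ExpressionDataset, GroundTruth]:
    """Simulate one disease cohort (patients plus controls).

    ``forced_modules`` maps ``(cluster, direction)`` to gene IDs that must
    be members of that planted module (used to plant shared candidates);
    ``exclude_genes`` are kept out of all randomly drawn module slots.
    """
    rng = np.random.default_rng(design.seed)
    gene_ids = _gene_ids(design.n_genes)
    up, down = _draw_modules(design, rng, gene_ids, forced_modules, exclude_genes)
    gene_pos = {g: i for i, g in enumerate(gene_ids)}

    n_pat = design.n_patients
    n = n_pat + design.n_controls
    baseline = rng.uniform(_BASELINE_LOW, _BASELINE_HIGH, size=design.n_genes)
    values = baseline[:, None] + _truncated_noise(rng, design.noise_sd, (design.n_genes, n))

    patient_ids = [f"{disease_tag}_P{i:03d}" for i in range(1, n_pat + 1)]
    control_ids = [f"{disease_tag}_C{i:03d}" for i in range(1, design.n_controls + 1)]
    sample_cluster: dict[str, int] = {}
    col = 0
    for c, size in enumerate(design.patients_per_cluster, start=1):
        up_rows = [gene_pos[g] for g in up[c]]
        down_rows = [gene_pos[g] for g in down[c]]
        values[np.ix_(up_rows, range(col, col + size))] += design.effect_size
        values[np.ix_(down_rows, range(col, col + size))] -= design.effect_size
        for pid in patient_ids[col : col + size]:
            sample_cluster[pid] = c
        col += size

    batch = None
    if design.batch_offset is not None:
        half = rng.permutation(n)[: n // 2]
        values[:, half] += design.batch_offset
        batch = ["b2" if i in set(half) else "b1" for i in range(n)]

    assert values.min() > 0, "baseline floor violated"
    ds = ExpressionDataset(
        gene_ids=gene_ids,
        sample_ids=patient_ids + control_ids,
        values=values,
        group=["patient"] * n_pat + ["control"] * design.n_controls,
        batch=batch,
    )
    truth = GroundTruth(sample_cluster=sample_cluster, up_modules=up, down_modules=down)
    return ds, truth


def generate_gene_sets(
    truths,
    n_decoys: int = 20,
    set_size_range: tuple[int, int] = (20, 60),
    seed: int = 0,
    tags: tuple[str, ...] = ("A", "B"),
    filler_fraction: float = 0.2,
    n_genes: int | None = None,
) -> GeneSetCollection:
    """Pathway collection: one set per planted module plus random decoys.

    Each module set takes all module members plus a few random fillers
    (at most ``filler_fraction`` of the set), so >= 80 percent of members
    come from the module by default.  Decoy sets are uniform random draws
    from the universe with sizes in ``set_size_range``.
    """
    if isinstance(truths, GroundTruth):
        truths = [truths]
    truths = list(truths)
    rng = np.random.default_rng(seed)
    # the universe is every simulated gene; fall back to the largest ID seen
    if n_genes is None:
        n_genes = max(int(g[1:]) for t in truths for g in t.module_genes())
    universe = set(_gene_ids(n_genes))
    all_genes = sorted(universe)

    sets: dict[str, set[str]] = {}
    for tag, truth in zip(tags, truths):
        for direction, modules in (("up", truth.up_modules), ("down", truth.down_modules)):
            for c, members in modules.items():
                n_fill = int(len(members) * filler_fraction / (1 - filler_fraction))
                pool = [g for g in all_genes if g not in members]
                fillers = rng.choice(pool, size=n_fill, replace=False) if n_fill else []
                name = f"SET_{tag}_c{c}_{direction}"
                if len(members) + n_fill > len(universe):
                    raise ValueError("gene-set size exceeds the simulated gene count")
                sets[name] = set(members) | set(map(str, fillers))
                truth.enriched_sets.add(name)
    lo, hi = set_size_range
    for d in range(1, n_decoys + 1):
        size = int(rng.integers(lo, hi + 1))
        if size > len(universe):
            raise ValueError("decoy set size exceeds the simulated gene count")
        sets[f"DECOY_{d:03d}"] = set(map(str, rng.choice(all_genes, size=size, replace=False)))
    return GeneSetCollection(sets=sets, universe=universe)


def generate_paired_study(
    design_a: SimulationDesign,
    design_b: SimulationDesign,
    n_ref_decoys: int = 30,
    n_decoy_sets: int = 20,
) -> PairedStudy:
    """Simulate two disease cohorts sharing a planted candidate gene set.

    The shared candidates are planted with identical direction in the
    ``shared_pair`` clusters of both diseases; all other module slots are
    drawn disjointly across the two diseases so the planted candidates are
    exactly the same-direction intersection of the paired modules.
    Reference gene lists are the shared candidates plus per-disease decoy
    genes drawn outside every module.
    """
    if design_a.shared_pair != design_b.shared_pair:
        raise ValueError("designs disagree on shared_pair")
    if design_a.shared_candidate_size != design_b.shared_candidate_size:
        raise ValueError("designs disagree on shared_candidate_size")
    ca, cb = design_a.shared_pair
    if not (1 <= ca <= design_a.k_true and 1 <= cb <= design_b.k_true):
        raise ValueError(f"shared_pair {design_a.shared_pair} out of cluster range")
    need = (
        2 * design_a.module_size * design_a.k_true
        + 2 * design_b.module_size * design_b.k_true
        - design_a.shared_candidate_size
    )
    n_common = min(design_a.n_genes, design_b.n_genes)
    if need > n_common:
        raise ValueError(
            f"disjoint modules of both diseases need {need} genes but only "
            f"{n_common} are shared; increase n_genes or shrink module_size"
        )

    master = np.random.default_rng(np.random.SeedSequence([design_a.seed, design_b.seed, 7]))
    n_common = min(design_a.n_genes, design_b.n_genes)
    common_genes = _gene_ids(n_common)

    s = design_a.shared_candidate_size
    n_up = ceil(s * _SHARED_UP_FRACTION)
    shared = list(map(str, master.choice(common_genes, size=s, replace=False)))
    shared_dir = {g: ("up" if i < n_up else "down") for i, g in enumerate(shared)}
    shared_up = [g for g in shared if shared_dir[g] == "up"]
    shared_down = [g for g in shared if shared_dir[g] == "down"]

    ds_a, truth_a = generate_disease_dataset(
        design_a, "A", forced_modules={(ca, "up"): shared_up, (ca, "down"): shared_down}
    )
    # keep disease-B random module slots away from every disease-A module gene
    ds_b, truth_b = generate_disease_dataset(
        design_b,
        "B",
        forced_modules={(cb, "up"): shared_up, (cb, "down"): shared_down},
        exclude_genes=truth_a.module_genes() - set(shared),
    )
    truth_a.shared_candidates = dict(shared_dir)
    truth_b.shared_candidates = dict(shared_dir)

    collection = generate_gene_sets(
        [truth_a, truth_b],
        n_decoys=n_decoy_sets,
        seed=int(master.integers(2**31)),
        n_genes=max(design_a.n_genes, design_b.n_genes),
    )

    non_module = sorted(
        set(common_genes) - truth_a.module_genes() - truth_b.module_genes()
    )
    ref_a = shared + list(map(str, master.choice(non_module, size=n_ref_decoys, replace=False)))
    ref_b = shared + list(map(str, master.choice(non_module, size=n_ref_decoys, replace=False)))
    return PairedStudy(
        dataset_a=ds_a,
        dataset_b=ds_b,
        gene_sets=collection,
        reference_genes_a=ref_a,
        reference_genes_b=ref_b,
        truth_a=truth_a,
        truth_b=truth_b,
    )


def write_ground_truth(truth: GroundTruth, path) -> None:
    """Ground truth as a tidy TSV for test harnesses."""
    rows = []
    for sample, c in truth.sample_cluster.items():
        rows.append({"kind": "sample_cluster", "id": sample, "value": c})
    for c, genes in truth.up_modules.items():
        for g in sorted(genes):
            rows.append({"kind": "up_module", "id": g, "value": c})
    for c, genes in truth.down_modules.items():
        for g in sorted(genes):
            rows.append({"kind": "down_module", "id": g, "value": c})
    for g, d in truth.shared_candidates.items():
        rows.append({"kind": "shared_candidate", "id": g, "value": d})
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
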