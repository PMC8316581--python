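"""End-to-end orchestration of the cross-disease subgroup analysis.

Per disease: preprocessing (duplicate merging, optional protein-coding
filter, optional batch adjustment), log2 fold change versus control means,
rank selection by consensus stability, convex-NMF bi-clustering with
Kruskal-Wallis/Dunn gene filtering, and DEG modules versus controls.
Across diseases: enrichment-based cluster-pair selection, candidate-gene
extraction, the candidate/reference overlap test, and cross-validated
logistic-regression evaluation of the candidate panel.

Every stage draws its seed deterministically from the run seed, and a
report directory (when requested) receives per-stage tables plus a JSON
log of chosen ranks, table counts, multiple-testing denominators and
seeds, so a run is auditable end to end.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as cio
from .cluster import ClusterAssignment, select_cluster_genes
from .consensus import RankSelection, select_rank
from .datatypes import ExpressionDataset, FoldChangeMatrix, GeneSetCollection, RunConfig
from .degs import DEGModules, build_deg_modules
from .enrichment import PairSelection, candidate_overlap_test, select_related_pair
from .preprocess import (
    filter_genes,
    log2_fold_change,
    merge_duplicate_genes,
    remove_batch_effect,
)
from .validate import CVResult, cross_validated_auc, random_gene_baseline

log = logging.getLogger(__name__)


@dataclass
class DiseaseResult:
    """Single-disease outputs of the pipeline."""

    tag: str
    dataset: ExpressionDataset
    fold_change: FoldChangeMatrix
    rank_selection: RankSelection
    assignment: ClusterAssignment
    modules: DEGModules


@dataclass
class PipelineReport:
    """Everything the two-disease run produced."""

    disease_a: DiseaseResult
    disease_b: DiseaseResult
    pair: PairSelection
    overlap_p: float | None
    cv_a: CVResult | None
    cv_b: CVResult | None
    baseline_means: np.ndarray | None
    baseline_p: float | None
    config: RunConfig


def _analyze_disease(
    tag: str,
    ds: ExpressionDataset,
    config: RunConfig,
    seed: int,
    coding_genes=None,
) -> DiseaseResult:
    ds = merge_duplicate_genes(ds)
    if coding_genes is not None:
        ds = filter_genes(ds, coding_genes)
    if ds.batch is not None and len(set(ds.batch)) >= 2:
        ds = remove_batch_effect(ds)
    fc = log2_fold_change(ds)
    rank = select_rank(
        fc.values,
        k_min=config.k_min,
        k_max=config.k_max,
        n_restarts=config.n_restarts,
        max_iter=config.max_iter,
        tol=config.tol,
        seed=seed,
        consensus_mode=config.consensus_mode,
    )
    log.info("[%s] chosen rank k=%d", tag, rank.chosen_k)
    assignment = select_cluster_genes(fc, rank.best_fit, alpha=config.alpha)
    modules = build_deg_modules(ds, assignment, alpha=config.alpha)
    return DiseaseResult(
        tag=tag,
        dataset=ds,
        fold_change=fc,
        rank_selection=rank,
        assignment=assignment,
        modules=modules,
    )


def run_pipeline(
    config: RunConfig,
    dataset_a: ExpressionDataset,
    dataset_b: ExpressionDataset,
    gene_sets: GeneSetCollection,
    ref_genes_a,
    ref_genes_b,
    coding_genes=None,
    out_dir: str | Path | None = None,
) -> PipelineReport:
    """Run the full two-disease analysis; optionally write a report directory."""
    ss = np.random.SeedSequence(config.seed)
    seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(5)]

    try:
        res_a = _analyze_disease("A", dataset_a, config, seeds[0], coding_genes)
    except Exception as exc:
        raise RuntimeError(f"[disease A analysis] {exc}") from exc
    try:
        res_b = _analyze_disease("B", dataset_b, config, seeds[1], coding_genes)
    except Exception as exc:
        raise RuntimeError(f"[disease B analysis] {exc}") from exc

    # restrict the enrichment universe to genes measured in both cohorts
    measured = set(res_a.dataset.gene_ids) & set(res_b.dataset.gene_ids)
    universe = gene_sets.universe & measured if gene_sets.universe & measured else gene_sets.universe
    collection = GeneSetCollection(
        sets=dict(gene_sets.sets), universe=universe, descriptions=dict(gene_sets.descriptions)
    )

    try:
        pair = select_related_pair(
            res_a.modules, res_b.modules, collection, ref_genes_a, ref_genes_b, alpha=config.alpha
        )
    except Exception as exc:
        raise RuntimeError(f"[pair selection] {exc}") from exc

    overlap_p = None
    cv_a = cv_b = None
    baseline_means = baseline_p = None
    if pair.found and pair.candidate_genes:
        candidates = sorted(pair.candidate_genes)
        ref_common = set(ref_genes_a) & set(ref_genes_b)
        background = len(measured)
        if ref_common:
            overlap_p = candidate_overlap_test(candidates, ref_common, background)
        try:
            cv_a = cross_validated_auc(
                res_a.dataset, candidates, n_folds=config.n_folds,
                learning_rate=config.learning_rate, epochs=config.epochs, seed=seeds[2],
            )
            cv_b = cross_validated_auc(
                res_b.dataset, candidates, n_folds=config.n_folds,
                learning_rate=config.learning_rate, epochs=config.epochs, seed=seeds[3],
            )
        except Exception as exc:
            raise RuntimeError(f"[cross-validation] {exc}") from exc
        if config.baseline_reps >= 2 and cv_a is not None:
            baseline_means, baseline_p = random_gene_baseline(
                res_a.dataset, panel_size=len(cv_a.gene_panel), reps=config.baseline_reps,
                candidate_mean_auc=cv_a.mean_auc, n_folds=config.n_folds,
                learning_rate=config.learning_rate, epochs=config.epochs, seed=seeds[4],
            )

    report = PipelineReport(
        disease_a=res_a,
        disease_b=res_b,
        pair=pair,
        overlap_p=overlap_p,
        cv_a=cv_a,
        cv_b=cv_b,
        baseline_means=baseline_means,
        baseline_p=baseline_p,
        config=config,
    )
    if out_dir is not None:
        write_report(report, out_dir, seeds)
    return report


def _cluster_table(res: DiseaseResult) -> pd.DataFrame:
    rows = []
    for c in range(1, res.assignment.k + 1):
        rows.append(
            {
                "cluster": c,
                "n_samples": sum(1 for v in res.assignment.sample_cluster.values() if v == c),
                "n_G_up": len(res.assignment.G_up.get(c, set())),
                "n_G_down": len(res.assignment.G_down.get(c, set())),
                "n_M_up": len(res.modules.M_up.get(c, set())),
                "n_M_down": len(res.modules.M_down.get(c, set())),
            }
        )
    return pd.DataFrame(rows)


def _gene_membership_table(res: DiseaseResult) -> pd.DataFrame:
    rows = []
    for kind, store in (
        ("G_up", res.assignment.G_up),
        ("G_down", res.assignment.G_down),
        ("M_up", res.modules.M_up),
        ("M_down", res.modules.M_down),
    ):
        for c, genes in store.items():
            for g in sorted(genes):
                rows.append({"kind": kind, "cluster": c, "gene": g})
    return pd.DataFrame(rows, columns=["kind", "cluster", "gene"])


def write_report(report: PipelineReport, out_dir: str | Path, seeds=None) -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {"config": report.config.__dict__, "stage_seeds": seeds}
    for res in (report.disease_a, report.disease_b):
        tag = res.tag.lower()
        cio.write_fold_change(
            res.fold_change, out / f"fold_change_{tag}.tsv", out / f"control_means_{tag}.tsv"
        )
        _cluster_table(res).to_csv(out / f"cluster_summary_{tag}.tsv", sep="\t", index=False)
        _gene_membership_table(res).to_csv(out / f"gene_clusters_{tag}.tsv", sep="\t", index=False)
        pd.DataFrame(
            {"sample": list(res.assignment.sample_cluster),
             "cluster": list(res.assignment.sample_cluster.values())}
        ).to_csv(out / f"sample_clusters_{tag}.tsv", sep="\t", index=False)
        summary[f"disease_{tag}"] = {
            "chosen_k": res.rank_selection.chosen_k,
            "mean_cophenetic_per_k": {
                str(k): v for k, v in res.rank_selection.per_k_mean_cophenetic.items()
            },
            "n_genes": res.dataset.n_genes,
            "n_patients": int(res.dataset.patient_mask.sum()),
            "n_controls": int(res.dataset.control_mask.sum()),
            "kw_bonferroni_denominator": {
                d: int(len(df)) for d, df in res.assignment.per_gene_stats.items()
            },
            "cluster_counts": _cluster_table(res).to_dict(orient="records"),
        }
    report.pair.stageA_counts.to_csv(out / "pair_stage_a.tsv", sep="\t", index=False)
    report.pair.stageB_counts.to_csv(out / "pair_stage_b.tsv", sep="\t", index=False)
    if report.pair.found:
        pd.DataFrame(
            sorted(report.pair.candidate_genes.items()), columns=["gene", "direction"]
        ).to_csv(out / "candidate_genes.tsv", sep="\t", index=False)
    summary["pair"] = {
        "chosen_pair": list(report.pair.chosen_pair) if report.pair.found else None,
        "n_candidates": len(report.pair.candidate_genes),
        "overlap_p": report.overlap_p,
    }
    for tag, cv in (("a", report.cv_a), ("b", report.cv_b)):
        if cv is not None:
            summary[f"cv_{tag}"] = {
                "mean_auc": cv.mean_auc,
                "per_fold_auc": cv.per_fold_auc,
                "n_folds": cv.n_folds,
                "panel_size": len(cv.gene_panel),
            }
    if report.baseline_means is not None:
        summary["baseline"] = {
            "mean_auc": float(np.mean(report.baseline_means)),
            "reps": len(report.baseline_means),
            "p_vs_candidates": report.baseline_p,
        }
    with open(out / "report.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    return out


def run_pipeline_from_files(
    config: RunConfig,
    expr_a: str | Path,
    annot_a: str | Path,
    expr_b: str | Path,
    annot_b: str | Path,
    gmt: str | Path,
    ref_genes_a: str | Path,
    ref_genes_b: str | Path,
    coding_genes: str | Path | None = None,
    out_dir: str | Path | None = None,
) -> PipelineReport:
    """File-based front end of :func:`run_pipeline` (what the CLI calls)."""
    return run_pipeline(
        config,
        cio.read_expression_matrix(expr_a, annot_a),
        cio.read_expression_matrix(expr_b, annot_b),
        cio.read_gene_sets_gmt(gmt),
        cio.read_gene_list(ref_genes_a),
        cio.read_gene_list(ref_genes_b),
        coding_genes=None if coding_genes is None else cio.read_gene_list(coding_genes),
        out_dir=out_dir,
    )
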