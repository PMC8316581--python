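"""Readers and writers for the plain-text formats the pipeline touches.

Expression matrices travel as TSV (first column = gene ID, header row =
sample IDs) with a sidecar annotation TSV mapping sample IDs to group /
batch / numeric covariates.  Gene-set collections use the standard GMT
format; reference and protein-coding gene lists are one ID per line.
All writers round-trip losslessly through the matching reader.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import ExpressionDataset, FoldChangeMatrix, GeneSetCollection

_ANNOT_GROUP = "group"
_ANNOT_BATCH = "batch"
_RESERVED = {"sample_id", _ANNOT_GROUP, _ANNOT_BATCH}


def read_expression_matrix(path: str | Path, annotation_path: str | Path) -> ExpressionDataset:
    """Read an expression TSV plus its sample-annotation sidecar.

    Sample order follows the matrix header.  Every matrix sample must be
    present in the annotation; annotation-only samples are ignored.
    """
    mat = pd.read_csv(path, sep="\t", index_col=0, dtype={0: str}, float_precision="round_trip")
    if mat.columns.duplicated().any():
        dup = mat.columns[mat.columns.duplicated()].tolist()
        raise ValueError(f"duplicate sample IDs in {path}: {dup}")
    try:
        values = mat.to_numpy(dtype=float)
    except ValueError as exc:
        raise ValueError(f"non-numeric cell in {path}: {exc}") from exc

    annot = pd.read_csv(annotation_path, sep="\t", dtype=str)
    if "sample_id" not in annot.columns or _ANNOT_GROUP not in annot.columns:
        raise ValueError(f"annotation {annotation_path} needs 'sample_id' and 'group' columns")
    annot = annot.set_index("sample_id")
    missing = [s for s in mat.columns if s not in annot.index]
    if missing:
        raise ValueError(f"samples missing from annotation: {missing}")
    annot = annot.loc[list(mat.columns)]

    batch = None
    if _ANNOT_BATCH in annot.columns and annot[_ANNOT_BATCH].notna().all():
        batch = annot[_ANNOT_BATCH].tolist()
    cov_cols = [c for c in annot.columns if c not in _RESERVED]
    covariates = None
    if cov_cols:
        covariates = annot[cov_cols].astype(float)

    return ExpressionDataset(
        gene_ids=[str(g) for g in mat.index],
        sample_ids=[str(s) for s in mat.columns],
        values=values,
        group=annot[_ANNOT_GROUP].tolist(),
        batch=batch,
        covariates=covariates,
    )


def write_expression_matrix(ds: ExpressionDataset, path: str | Path, annotation_path: str | Path) -> None:
    ds.to_frame().to_csv(path, sep="\t", index_label="gene_id")
    annot = pd.DataFrame({"sample_id": ds.sample_ids, _ANNOT_GROUP: ds.group})
    if ds.batch is not None:
        annot[_ANNOT_BATCH] = ds.batch
    if ds.covariates is not None:
        for col in ds.covariates.columns:
            annot[col] = ds.covariates[col].to_numpy()
    annot.to_csv(annotation_path, sep="\t", index=False)


def read_gene_sets_gmt(path: str | Path) -> GeneSetCollection:
    """Read a GMT file: ``name TAB description TAB member1 TAB member2 ...``"""
    sets: dict[str, set[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: GMT line has fewer than 3 fields")
            name, desc, *members = fields
            if name in sets:
                raise ValueError(f"{path}:{lineno}: duplicate gene-set name {name!r}")
            sets[name] = {m for m in members if m}
            descriptions[name] = desc
    return GeneSetCollection(sets=sets, descriptions=descriptions)


def write_gene_sets_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, members in collection.sets.items():
            desc = collection.descriptions.get(name, "na")
            fh.write("\t".join([name, desc, *sorted(members)]) + "\n")


def read_gene_list(path: str | Path) -> list[str]:
    """Read a one-ID-per-line gene list; ordered, de-duplicated."""
    seen: dict[str, None] = {}
    with open(path) as fh:
        for line in fh:
            gid = line.strip()
            if gid:
                seen.setdefault(gid, None)
    if not seen:
        raise ValueError(f"gene list {path} is empty")
    return list(seen)


def write_gene_list(genes, path: str | Path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            fh.write(f"{g}\n")


def write_fold_change(fc: FoldChangeMatrix, path: str | Path, means_path: str | Path) -> None:
    fc.to_frame().to_csv(path, sep="\t", index_label="gene_id")
    pd.DataFrame({"gene_id": fc.gene_ids, "control_mean": fc.control_means}).to_csv(
        means_path, sep="\t", index=False
    )


def read_fold_change(path: str | Path, means_path: str | Path) -> FoldChangeMatrix:
    mat = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    means = pd.read_csv(means_path, sep="\t", float_precision="round_trip").set_index("gene_id")["control_mean"]
    return FoldChangeMatrix(
        gene_ids=[str(g) for g in mat.index],
        patient_ids=[str(s) for s in mat.columns],
        values=mat.to_numpy(dtype=float),
        control_means=means.loc[mat.index].to_numpy(dtype=float),
    )
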