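"""Hypergeometric enrichment and cross-disease cluster-pair selection.

A query gene set is tested against every pathway in a collection with the
upper-tail hypergeometric probability of its overlap, Bonferroni-adjusted
over the pathways tested.  Reference pathway lists are derived by
enriching disease gene lists the same way.  Cluster pairing between two
diseases proceeds in two stages:

stage A
    for every DEG module of disease A, count its enriched pathways that
    are also reference pathways of disease B (and symmetrically) — which
    clusters of one disease look like the other disease at all;
stage B
    for every cluster pair (i, j) and direction, enrich the same-direction
    common genes of the two modules and count overlap with the pathways of
    the joint (intersection) reference gene list — which pair shares
    biology attributable to both diseases.

The chosen pair maximizes the stage-B up+down count, with ties broken by
stage-A counts and then by lowest indices; its same-direction module
intersections are the candidate genes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import product

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import GeneSetCollection
from .degs import DEGModules

log = logging.getLogger(__name__)


@dataclass
class EnrichmentResult:
    """Per-pathway overlap counts and raw/adjusted hypergeometric p-values."""

    table: pd.DataFrame
    alpha: float
    universe_size: int
    query_size: int

    def enriched_names(self) -> set[str]:
        return set(self.table.loc[self.table["enriched"], "set"])


@dataclass
class PairSelection:
    """Bookkeeping of the two-stage pair search."""

    stageA_counts: pd.DataFrame
    stageB_counts: pd.DataFrame
    chosen_pair: tuple[int, int] | None
    candidate_genes: dict[str, str] = field(default_factory=dict)  # gene -> "up"/"down"

    @property
    def found(self) -> bool:
        return self.chosen_pair is not None

    def candidates_by_direction(self, direction: str) -> set[str]:
        return {g for g, d in self.candidate_genes.items() if d == direction}


def hypergeom_upper_tail(overlap: int, query_size: int, set_size: int, universe_size: int) -> float:
    """P(X >= overlap) for X ~ Hypergeometric(universe, set, query)."""
    if not (0 <= overlap <= min(query_size, set_size) <= universe_size):
        raise ValueError(
            f"inconsistent counts: overlap={overlap}, query={query_size}, "
            f"set={set_size}, universe={universe_size}"
        )
    if overlap == 0:
        return 1.0
    # survival function of the hypergeometric; computed stably by scipy
    return float(stats.hypergeom.sf(overlap - 1, universe_size, set_size, query_size))


def enrich_collection(
    query, collection: GeneSetCollection, alpha: float = 0.05
) -> EnrichmentResult:
    """Hypergeometric enrichment of a query against every set in a collection.

    Sets and query are first intersected with the universe; Bonferroni
    adjustment is over the number of sets tested.
    """
    universe = collection.universe
    query = set(query) & universe
    if not query:
        raise ValueError("query has no genes in the enrichment universe")
    n_sets = len(collection.sets)
    rows = []
    for name, members in collection.sets.items():
        members = members & universe
        overlap = len(query & members)
        p = hypergeom_upper_tail(overlap, len(query), len(members), len(universe))
        rows.append((name, overlap, len(members), p))
    table = pd.DataFrame(rows, columns=["set", "overlap", "set_size", "p"])
    table["adj_p"] = np.minimum(1.0, table["p"] * n_sets)
    table["enriched"] = table["adj_p"] < alpha
    return EnrichmentResult(
        table=table, alpha=alpha, universe_size=len(universe), query_size=len(query)
    )


def derive_reference_pathways(
    ref_genes, collection: GeneSetCollection, alpha: float = 0.05
) -> set[str]:
    """Names of pathways enriched for a disease reference gene list."""
    if not ref_genes:
        raise ValueError("reference gene list is empty")
    return enrich_collection(ref_genes, collection, alpha=alpha).enriched_names()


def _enriched_or_empty(query, collection, alpha) -> set[str]:
    query = set(query) & collection.universe
    if not query:
        return set()
    return enrich_collection(query, collection, alpha=alpha).enriched_names()


def select_related_pair(
    modsA: DEGModules,
    modsB: DEGModules,
    collection: GeneSetCollection,
    refA,
    refB,
    alpha: float = 0.05,
) -> PairSelection:
    """Two-stage enrichment-based selection of the related cluster pair.

    Returns a :class:`PairSelection`; when neither stage produces any
    reference-pathway overlap the result carries ``chosen_pair=None``
    ("no related pair") and no candidate genes.
    """
    pathsA = derive_reference_pathways(refA, collection, alpha=alpha)
    pathsB = derive_reference_pathways(refB, collection, alpha=alpha)
    ref_joint = set(refA) & set(refB)
    paths_joint = _enriched_or_empty(ref_joint, collection, alpha)
    log.info(
        "reference pathways: |A|=%d, |B|=%d, joint genes=%d -> joint pathways=%d",
        len(pathsA), len(pathsB), len(ref_joint), len(paths_joint),
    )

    # stage A: each disease's modules against the OTHER disease's reference pathways
    rowsA = []
    for disease, mods, other_paths in (("A", modsA, pathsB), ("B", modsB, pathsA)):
        for c in range(1, mods.k + 1):
            for direction in ("up", "down"):
                enriched = _enriched_or_empty(mods.module(c, direction), collection, alpha)
                rowsA.append(
                    {
                        "disease": disease,
                        "cluster": c,
                        "direction": direction,
                        "n_enriched": len(enriched),
                        "n_shared_with_other_ref": len(enriched & other_paths),
                    }
                )
    stageA = pd.DataFrame(rowsA)

    # stage B: same-direction common genes of every (i, j) pair against the
    # joint reference pathways
    rowsB = []
    for i, j in product(range(1, modsA.k + 1), range(1, modsB.k + 1)):
        for direction in ("up", "down"):
            common = modsA.module(i, direction) & modsB.module(j, direction)
            enriched = _enriched_or_empty(common, collection, alpha) if common else set()
            rowsB.append(
                {
                    "cluster_a": i,
                    "cluster_b": j,
                    "direction": direction,
                    "n_common_genes": len(common),
                    "n_enriched": len(enriched),
                    "n_shared_with_joint_ref": len(enriched & paths_joint),
                }
            )
    stageB = pd.DataFrame(rowsB)

    def stageA_score(i: int, j: int) -> int:
        a = stageA[(stageA.disease == "A") & (stageA.cluster == i)]["n_shared_with_other_ref"].sum()
        b = stageA[(stageA.disease == "B") & (stageA.cluster == j)]["n_shared_with_other_ref"].sum()
        return int(a + b)

    pair_scores = {}
    for i, j in product(range(1, modsA.k + 1), range(1, modsB.k + 1)):
        sub = stageB[(stageB.cluster_a == i) & (stageB.cluster_b == j)]
        pair_scores[(i, j)] = int(sub["n_shared_with_joint_ref"].sum())

    if all(v == 0 for v in pair_scores.values()) and stageA["n_shared_with_other_ref"].sum() == 0:
        log.info("no related pair: every reference-overlap count is zero")
        return PairSelection(stageA_counts=stageA, stageB_counts=stageB, chosen_pair=None)

    chosen = min(
        pair_scores,
        key=lambda ij: (-pair_scores[ij], -stageA_score(*ij), ij),
    )
    i, j = chosen
    candidates: dict[str, str] = {}
    for direction in ("up", "down"):
        for g in modsA.module(i, direction) & modsB.module(j, direction):
            candidates[g] = direction
    log.info("chosen pair %s with %d candidate genes", chosen, len(candidates))
    return PairSelection(
        stageA_counts=stageA,
        stageB_counts=stageB,
        chosen_pair=chosen,
        candidate_genes=candidates,
    )


def candidate_overlap_test(candidates, ref_common, background_size: int) -> float:
    """Hypergeometric significance of candidate overlap with a joint reference set."""
    candidates = set(candidates)
    ref_common = set(ref_common)
    if background_size < len(candidates | ref_common):
        raise ValueError("background smaller than the union of the two gene sets")
    return hypergeom_upper_tail(
        len(candidates & ref_common), len(candidates), len(ref_common), background_size
    )
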