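"""End-to-end convenience wrapper: matrix -> relation sets -> TO-GCN.

Mirrors the three-step workflow (Cutoff, GCN, TO-GCN): average replicates,
average each condition's varieties into one time series, compute the
target x TF PCC table, estimate (or accept) cutoffs, classify pairs into
the joint relation sets, and optionally walk the positive network with BFS
from the first-expressed acid gene.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

from .correlation import CutoffSet, PCCRecord, pcc_table
from .expression import (
    ConditionSeries,
    ExpressionMatrix,
    GeneSets,
    average_replicates,
    build_condition_series,
)
from .ordering import TimeOrderedNetwork, bfs_levels, select_seed
from .relations import RelationSets, build_relation_sets, condition_positive_graph


@dataclass
class PipelineResult:
    series_c1: ConditionSeries
    series_c2: ConditionSeries
    records: list[PCCRecord]
    cutoffs: CutoffSet
    relations: RelationSets


def run_pipeline(
    matrix: ExpressionMatrix,
    gene_sets: GeneSets,
    condition_map: Mapping[str, str],
    cutoffs: CutoffSet | str = "estimate",
    alpha: float = 0.05,
    bin_width: float = 0.01,
) -> PipelineResult:
    """Run averaging, correlation, cutoff estimation and classification.

    ``cutoffs`` may be a :class:`CutoffSet`, ``"estimate"`` (empirical CDF
    tails at ``alpha``) or ``"paper"`` (the published +0.75/-0.60 pair).
    """
    averaged = average_replicates(matrix)
    c1, c2 = build_condition_series(averaged, condition_map)
    gene_sets = gene_sets.restricted_to(matrix)
    records = pcc_table(c1, c2, gene_sets)
    if isinstance(cutoffs, str):
        if cutoffs == "estimate":
            cutoffs = CutoffSet.from_records(records, alpha=alpha, bin_width=bin_width)
        elif cutoffs == "paper":
            cutoffs = CutoffSet.paper_defaults()
        else:
            raise ValueError(f"unknown cutoff mode {cutoffs!r}")
    relations = build_relation_sets(records, cutoffs)
    return PipelineResult(
        series_c1=c1, series_c2=c2, records=records, cutoffs=cutoffs, relations=relations
    )


def time_order_positive_network(
    result: PipelineResult,
    candidates: set[str] | None = None,
    condition: str = "C1",
    seed_gene: str | None = None,
) -> TimeOrderedNetwork:
    """BFS time levels on a condition's positive co-expression network.

    The seed defaults to the first-expressed gene among ``candidates``
    (restricted to genes present in the network).
    """
    graph = condition_positive_graph(result.records, result.cutoffs, condition)
    series = result.series_c1 if condition == "C1" else result.series_c2
    if seed_gene is None:
        if candidates is None:
            raise ValueError("provide candidates for seed selection or a seed_gene")
        in_graph = {g for g in candidates if g in graph}
        if not in_graph:
            raise ValueError("no candidate gene appears in the positive network")
        seed_gene = select_seed(series, in_graph)
    return bfs_levels(graph, {seed_gene})
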