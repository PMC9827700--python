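"""Chronological (time-level) ordering of co-expression networks.

Levels are assigned by breadth-first search from seed genes: seeds sit at
level 1, and every other reachable node at 1 + its unweighted shortest-path
distance to the seed set. The seed is the first-expressed gene among the
pathway candidates — formalized as the candidate whose condition profile
peaks at the earliest stage (ties broken by higher first-stage expression,
then lexicographic ID, so the choice is reproducible).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import networkx as nx
import numpy as np
import pandas as pd

from .expression import ConditionSeries


def select_seed(series: ConditionSeries, candidates: Iterable[str]) -> str:
    """The first-expressed candidate: earliest expression peak wins."""
    cand = sorted(set(candidates))
    if not cand:
        raise ValueError("empty candidate set")
    best: tuple[int, float, str] | None = None
    for gene in cand:
        prof = series.profile(gene)  # KeyError if absent
        key = (int(np.argmax(prof)), -float(prof[0]), gene)
        if best is None or key < best:
            best = key
    return best[2]


@dataclass
class TimeOrderedNetwork:
    """A co-expression graph with BFS level labels (1 = seed level)."""

    graph: nx.Graph
    seeds: frozenset[str]
    levels: dict[str, int]
    unreached: frozenset[str]

    @property
    def n_levels(self) -> int:
        return len(set(self.levels.values()))

    def levels_of(self, genes: Iterable[str]) -> dict[str, int]:
        return {g: self.levels[g] for g in genes if g in self.levels}


def bfs_levels(graph: nx.Graph, seeds: Iterable[str]) -> TimeOrderedNetwork:
    """Multi-source BFS levels: level = 1 + distance to the nearest seed."""
    seed_set = frozenset(seeds)
    if not seed_set:
        raise ValueError("seed set is empty")
    missing = seed_set - set(graph.nodes)
    if missing:
        raise ValueError(f"seed(s) not in graph: {sorted(missing)}")
    dist = nx.multi_source_dijkstra_path_length(graph, seed_set, weight=None)
    levels = {node: int(d) + 1 for node, d in dist.items()}
    unreached = frozenset(set(graph.nodes) - set(levels))
    return TimeOrderedNetwork(
        graph=graph, seeds=seed_set, levels=levels, unreached=unreached
    )


def order_report(
    ton: TimeOrderedNetwork, annotations: Mapping[str, str] | None = None
) -> pd.DataFrame:
    """Table (gene, level, degree, annotation) sorted by level, then degree
    descending, then gene ID."""
    annotations = annotations or {}
    rows = [
        {
            "gene": g,
            "level": lvl,
            "degree": ton.graph.degree(g),
            "annotation": annotations.get(g, ""),
        }
        for g, lvl in ton.levels.items()
    ]
    df = pd.DataFrame(rows, columns=["gene", "level", "degree", "annotation"])
    if not df.empty:
        df = df.sort_values(
            ["level", "degree", "gene"], ascending=[True, False, True]
        ).reset_index(drop=True)
    return df
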