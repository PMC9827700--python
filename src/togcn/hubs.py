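"""Hub-gene candidates: degree ranking within a relation network.

The "Count" reported per candidate is the gene's degree in the selected
joint co-expression network (by default the high-acid-specific C1+C20
set); genes with the most partners are proposed as candidate regulators.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import networkx as nx
import pandas as pd

logger = logging.getLogger(__name__)


@dataclass
class HubRanking:
    """Rank/Name/Count/Annotation rows, ordered by degree."""

    table: pd.DataFrame  # columns: Rank, Name, Count, Annotation
    network_type: str = ""

    def __len__(self) -> int:
        return len(self.table)

    def to_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def degree_ranking(
    graph: nx.Graph,
    annotations: Mapping[str, str] | None = None,
    network_type: str = "",
) -> HubRanking:
    """Rank every node by degree (descending; ties by gene ID)."""
    if graph.number_of_nodes() == 0:
        raise ValueError("empty graph")
    annotations = annotations or {}
    degrees = dict(graph.degree())
    # handshake lemma: the degree sum must be twice the edge count
    assert sum(degrees.values()) == 2 * graph.number_of_edges()
    order = sorted(degrees.items(), key=lambda kv: (-kv[1], kv[0]))
    table = pd.DataFrame(
        {
            "Rank": range(1, len(order) + 1),
            "Name": [g for g, _ in order],
            "Count": [d for _, d in order],
            "Annotation": [annotations.get(g, "") for g, _ in order],
        }
    )
    return HubRanking(table=table, network_type=network_type)


def top_candidates(ranking: HubRanking, k: int = 20) -> HubRanking:
    """First ``k`` rows of the ranking (all rows, warned, if fewer exist)."""
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > len(ranking):
        logger.warning(
            "requested %d candidates but the network has only %d genes", k, len(ranking)
        )
    return HubRanking(
        table=ranking.table.head(k).reset_index(drop=True),
        network_type=ranking.network_type,
    )
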