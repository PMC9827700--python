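"""Joint co-expression classification across two conditions.

Each target-TF pair receives a label per condition — positive (+) above the
positive cutoff, negative (-) below the negative cutoff, zero (0) inside
the not-co-expressed band — and the two labels combine into a joint type
such as ``C1+C20`` (positively co-expressed only under the high-acid
condition). Eight joint types are exported; the double-null ``C10C20`` set
is kept separately and not exported as a network. PCCs falling in the gap
between the band and a cutoff are unclassified and dropped with a count,
since the published bands do not tile [-1, 1].
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import networkx as nx

from .correlation import CutoffSet, PCCRecord

logger = logging.getLogger(__name__)

#: The eight exported joint types, in the order the method lists them.
EXPORTED_TYPES: tuple[str, ...] = (
    "C1+C2+",
    "C1+C20",
    "C1+C2-",
    "C10C2+",
    "C1-C2+",
    "C1-C2-",
    "C1-C20",
    "C10C2-",
)

#: Numeric presets used by the time-ordering step (0/1/2).
TYPE_PRESETS: dict[int, str] = {0: "C1+C2+", 1: "C1+C20", 2: "C10C2+"}


def _condition_label(pcc: float, pos: float, neg: float, z_lo: float, z_hi: float) -> str | None:
    if pcc > pos:
        return "+"
    if pcc < neg:
        return "-"
    if z_lo <= pcc < z_hi:
        return "0"
    return None


def classify_pair(
    pcc_c1: float, pcc_c2: float, cutoffs: CutoffSet
) -> str | None:
    """Joint type of a pair, or ``None`` when either PCC is unclassifiable.

    Both PCCs must be defined; undefined values are refused so callers
    filter (and count) them explicitly.
    """
    if pcc_c1 is None or pcc_c2 is None:
        raise ValueError("undefined PCC cannot be classified; filter the record")
    l1 = _condition_label(pcc_c1, cutoffs.pos_c1, cutoffs.neg_c1, cutoffs.z_lo, cutoffs.z_hi)
    l2 = _condition_label(pcc_c2, cutoffs.pos_c2, cutoffs.neg_c2, cutoffs.z_lo, cutoffs.z_hi)
    if l1 is None or l2 is None:
        return None
    return f"C1{l1}C2{l2}"


@dataclass(frozen=True)
class ClassifiedPair:
    """A PCC record together with its joint co-expression type."""

    target: str
    tf: str
    pcc_c1: float
    pcc_c2: float
    joint_type: str

    @property
    def pair(self) -> tuple[str, str]:
        return (self.target, self.tf)


@dataclass
class RelationSets:
    """The partition of classified pairs into joint co-expression sets."""

    exported: dict[str, list[ClassifiedPair]]
    c10c20: list[ClassifiedPair]
    unclassified: list[PCCRecord]
    undefined: list[PCCRecord]
    cutoffs: CutoffSet

    def pairs(self, joint_type: str) -> set[tuple[str, str]]:
        if joint_type == "C10C20":
            return {p.pair for p in self.c10c20}
        return {p.pair for p in self.exported[joint_type]}

    def counts(self) -> dict[str, int]:
        out = {t: len(v) for t, v in self.exported.items()}
        out["C10C20"] = len(self.c10c20)
        out["unclassified"] = len(self.unclassified)
        out["undefined"] = len(self.undefined)
        return out


def build_relation_sets(
    records: Sequence[PCCRecord], cutoffs: CutoffSet
) -> RelationSets:
    """Partition a PCC table into the eight exported sets (+ held-back ones)."""
    if not records:
        raise ValueError("empty PCC table")
    exported: dict[str, list[ClassifiedPair]] = {t: [] for t in EXPORTED_TYPES}
    c10c20: list[ClassifiedPair] = []
    unclassified: list[PCCRecord] = []
    undefined: list[PCCRecord] = []
    for rec in records:
        if not rec.defined:
            undefined.append(rec)
            continue
        joint = classify_pair(rec.pcc_c1, rec.pcc_c2, cutoffs)
        if joint is None:
            unclassified.append(rec)
            continue
        pair = ClassifiedPair(rec.target, rec.tf, rec.pcc_c1, rec.pcc_c2, joint)
        if joint == "C10C20":
            c10c20.append(pair)
        else:
            exported[joint].append(pair)
    sets = RelationSets(exported, c10c20, unclassified, undefined, cutoffs)
    logger.info("relation-set counts: %s", sets.counts())
    return sets


def build_graph(
    relations: RelationSets, types: Iterable[str] = ("C1+C20",)
) -> nx.Graph:
    """Undirected graph over the pairs of the selected joint types.

    Nodes are genes, edges are classified pairs (duplicates collapsed);
    edge attributes keep both PCCs and the joint type.
    """
    types = list(types)
    unknown = [t for t in types if t not in EXPORTED_TYPES]
    if unknown:
        raise KeyError(f"unknown joint type(s): {unknown}")
    g = nx.Graph()
    n_pairs = 0
    for t in types:
        for p in relations.exported[t]:
            g.add_edge(
                p.target, p.tf, pcc_c1=p.pcc_c1, pcc_c2=p.pcc_c2, joint_type=p.joint_type
            )
            n_pairs += 1
    if n_pairs == 0:
        logger.warning("selected joint types %s contain no pairs; graph is empty", types)
    return g


def condition_positive_graph(
    records: Sequence[PCCRecord], cutoffs: CutoffSet, condition: str = "C1"
) -> nx.Graph:
    """The single-condition positive co-expression network.

    Edges join pairs whose PCC under ``condition`` exceeds that condition's
    positive cutoff, regardless of the other condition — the graph the
    time-ordering step walks.
    """
    pos, _ = cutoffs.for_condition(condition)
    g = nx.Graph()
    for rec in records:
        pcc = rec.pcc_c1 if condition == "C1" else rec.pcc_c2
        if pcc is not None and pcc > pos:
            g.add_edge(rec.target, rec.tf, pcc=pcc, condition=condition)
    return g


def write_relation_graph(graph: nx.Graph, path: str, fmt: str = "edgelist") -> None:
    """Export a relation network as edge-list TSV or GraphML."""
    if fmt == "edgelist":
        with open(path, "w") as fh:
            fh.write("gene_a\tgene_b\tpcc_c1\tpcc_c2\tjoint_type\n")
            for u, v, d in graph.edges(data=True):
                fh.write(
                    f"{u}\t{v}\t{d.get('pcc_c1', '')}\t{d.get('pcc_c2', '')}"
                    f"\t{d.get('joint_type', '')}\n"
                )
    elif fmt == "graphml":
        nx.write_graphml(graph, path)
    else:
        raise ValueError(f"unknown graph format {fmt!r}")
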