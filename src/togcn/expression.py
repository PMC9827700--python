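"""Expression-matrix containers and I/O.

The pipeline consumes a replicate-level FPKM matrix (genes x samples) whose
sample names follow the ``VARIETY_STAGE_REPn`` grammar, e.g. ``LG_T1_REP2``.
Replicates are arithmetically averaged into per-(variety, stage) profiles,
and variety profiles are averaged again into one time series per condition
(high-acid C1 vs low-acid C2); those condition series are what all pairwise
Pearson correlations are computed on.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

_SAMPLE_RE = re.compile(r"^(?P<variety>.+)_(?P<stage>[^_]+)_REP(?P<rep>\d+)$")
_AVERAGED_RE = re.compile(r"^(?P<variety>.+)_(?P<stage>[^_]+)$")


class FormatError(ValueError):
    """Raised when an input file violates the expected dialect."""


def parse_sample_name(name: str) -> tuple[str, str, int | None]:
    """Split ``VARIETY_STAGE_REPn`` (or averaged ``VARIETY_STAGE``) names."""
    m = _SAMPLE_RE.match(name)
    if m:
        return m.group("variety"), m.group("stage"), int(m.group("rep"))
    m = _AVERAGED_RE.match(name)
    if m:
        return m.group("variety"), m.group("stage"), None
    raise FormatError(f"sample column {name!r} does not parse as VARIETY_STAGE_REPn")


@dataclass
class ExpressionMatrix:
    """FPKM values (genes x samples) plus parsed sample metadata.

    ``data`` is indexed by gene ID; ``samples`` is indexed by the sample
    column names and carries ``variety``, ``stage`` and ``replicate``
    (nullable after replicate averaging).
    """

    data: pd.DataFrame
    samples: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        dup = self.data.index[self.data.index.duplicated()]
        if len(dup):
            raise FormatError(f"duplicate gene ID(s): {', '.join(map(str, dup.unique()))}")
        vals = self.data.to_numpy()
        if vals.size and (not np.isfinite(vals).all() or (vals < 0).any()):
            raise FormatError("expression values must be finite and non-negative")
        key = list(zip(self.samples["variety"], self.samples["stage"], self.samples["replicate"]))
        if len(key) != len(set(key)):
            raise FormatError("duplicate (variety, stage, replicate) sample")
        if list(self.samples.index) != list(self.data.columns):
            raise ValueError("sample metadata does not match matrix columns")

    @classmethod
    def from_dataframe(cls, data: pd.DataFrame) -> "ExpressionMatrix":
        data = data.rename_axis("gene_id")
        meta = pd.DataFrame(
            [parse_sample_name(c) for c in data.columns],
            index=data.columns,
            columns=["variety", "stage", "replicate"],
        )
        return cls(data=data, samples=meta)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def n_genes(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def stage_order(self) -> list[str]:
        """Stage labels in first-appearance (column) order."""
        seen: dict[str, None] = {}
        for s in self.samples["stage"]:
            seen.setdefault(s, None)
        return list(seen)

    def to_tsv(self, path: str | Path) -> None:
        out = self.data.copy()
        out.index.name = "gene_id"
        out.to_csv(path, sep="\t")


@dataclass(frozen=True)
class GeneSets:
    """The two gene populations correlated against each other: pathway
    target genes ("acid genes") and transcription factors."""

    tf_genes: frozenset[str]
    acid_genes: frozenset[str]

    def restricted_to(self, matrix: ExpressionMatrix) -> "GeneSets":
        """Drop list entries absent from the matrix (warned, not an error)."""
        present = set(matrix.gene_ids)
        missing = (self.tf_genes | self.acid_genes) - present
        if missing:
            logger.warning(
                "%d gene-list entries absent from the matrix were ignored", len(missing)
            )
        return GeneSets(
            tf_genes=frozenset(self.tf_genes & present),
            acid_genes=frozenset(self.acid_genes & present),
        )


@dataclass
class ConditionSeries:
    """Per-condition averaged time series: one length-T profile per gene."""

    condition: str
    varieties: tuple[str, ...]
    stages: tuple[str, ...]
    data: pd.DataFrame  # genes x stages

    def __post_init__(self) -> None:
        if len(self.stages) < 3:
            raise ValueError("condition series needs >= 3 stages for PCC")
        if (self.data.to_numpy() < 0).any():
            raise ValueError("condition series values must be non-negative")

    def profile(self, gene: str) -> np.ndarray:
        if gene not in self.data.index:
            raise KeyError(f"gene {gene!r} missing from {self.condition} series")
        return self.data.loc[gene].to_numpy(dtype=float)


def read_fpkm(path: str | Path) -> ExpressionMatrix:
    """Read a TSV expression matrix (header ``gene_id`` then sample columns)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    try:
        df = df.astype(float)
    except ValueError as exc:
        raise FormatError(f"non-numeric expression value: {exc}") from exc
    return ExpressionMatrix.from_dataframe(df)


def read_gene_list(path: str | Path) -> frozenset[str]:
    lines = Path(path).read_text().splitlines()
    return frozenset(s.strip() for s in lines if s.strip())


def write_gene_list(genes: Iterable[str], path: str | Path) -> None:
    Path(path).write_text("\n".join(sorted(genes)) + "\n")


def average_replicates(m: ExpressionMatrix) -> ExpressionMatrix:
    """Arithmetic mean over replicates of each (variety, stage) group.

    Idempotent: an already averaged matrix (one column per group) is
    returned value-identical.
    """
    groups: dict[tuple[str, str], list[str]] = {}
    for name, row in m.samples.iterrows():
        groups.setdefault((row["variety"], row["stage"]), []).append(name)
    cols = {}
    for (variety, stage), names in groups.items():
        cols[f"{variety}_{stage}"] = m.data[names].mean(axis=1)
    out = pd.DataFrame(cols, index=m.data.index)
    return ExpressionMatrix.from_dataframe(out)


def expressed_fraction(m: ExpressionMatrix, threshold: float = 0.0) -> float:
    """Fraction of genes exceeding ``threshold`` in at least one sample."""
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    if m.n_genes == 0:
        raise ValueError("empty expression matrix")
    expressed = (m.data.to_numpy() > threshold).any(axis=1)
    return float(expressed.sum()) / m.n_genes


def build_condition_series(
    m: ExpressionMatrix,
    condition_map: Mapping[str, str],
) -> tuple[ConditionSeries, ConditionSeries]:
    """Average a replicate-averaged matrix over each condition's varieties.

    ``condition_map`` sends variety -> ``"C1"`` / ``"C2"`` / ``"excluded"``.
    """
    if m.samples["replicate"].notna().any():
        raise ValueError("matrix must be replicate-averaged first (average_replicates)")
    stages = m.stage_order()
    out: dict[str, ConditionSeries] = {}
    for cond in ("C1", "C2"):
        members = sorted(v for v, c in condition_map.items() if c == cond)
        if not members:
            raise ValueError(f"condition {cond} has no varieties")
        series = pd.DataFrame(index=m.data.index, columns=stages, dtype=float)
        for stage in stages:
            cols = [
                name
                for name, row in m.samples.iterrows()
                if row["stage"] == stage and row["variety"] in members
            ]
            if not cols:
                raise ValueError(f"no samples for condition {cond} at stage {stage}")
            series[stage] = m.data[cols].mean(axis=1)
        out[cond] = ConditionSeries(
            condition=cond, varieties=tuple(members), stages=tuple(stages), data=series
        )
    return out["C1"], out["C2"]


def write_relation_csv(records: Sequence, path: str | Path) -> None:
    """Write pairs in the five-column relation dialect.

    Columns, in order: acidity gene ID, co-expression type, gene ID, PCC
    under condition 1, PCC under condition 2. PCCs carry 4 decimals.
    """
    with open(path, "w") as fh:
        fh.write("acid_gene,type,tf_gene,pcc_c1,pcc_c2\n")
        for rec in records:
            fh.write(
                f"{rec.target},{rec.joint_type},{rec.tf},"
                f"{rec.pcc_c1:.4f},{rec.pcc_c2:.4f}\n"
            )


def read_relation_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    expected = ["acid_gene", "type", "tf_gene", "pcc_c1", "pcc_c2"]
    if list(df.columns) != expected:
        raise FormatError(f"relation CSV must have columns {expected}")
    return df
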