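"""Organic-acid phenotypes and the high/low-acid condition split.

The comparative network contrasts two variety groups: C1 (high total acid)
and C2 (low total acid). When the user does not fix the split explicitly,
it is inferred from total acid (malate + citrate + quinate) at a reference
developmental stage — by default the maturity stage, where the high/low
contrast is largest.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

ACIDS = ("malate", "citrate", "quinate")


@dataclass
class AcidProfile:
    """Acid concentrations per (variety, stage); units are an opaque label."""

    data: pd.DataFrame  # columns: variety, stage, malate, citrate, quinate
    stage_order: tuple[str, ...]
    units: str = "ug/g"

    def __post_init__(self) -> None:
        missing = [c for c in ("variety", "stage", *ACIDS) if c not in self.data.columns]
        if missing:
            raise ValueError(f"acid table missing columns: {missing}")
        if (self.data[list(ACIDS)].to_numpy() < 0).any():
            raise ValueError("acid concentrations must be non-negative")
        by_var = self.data.groupby("variety")["stage"].apply(tuple)
        if len(set(by_var)) > 1:
            raise ValueError("every variety must cover the same ordered stage set")

    @property
    def varieties(self) -> list[str]:
        seen: dict[str, None] = {}
        for v in self.data["variety"]:
            seen.setdefault(v, None)
        return list(seen)

    def cell(self, variety: str, stage: str) -> pd.Series:
        rows = self.data[(self.data["variety"] == variety) & (self.data["stage"] == stage)]
        if rows.empty:
            raise KeyError(f"no acid measurement for ({variety}, {stage})")
        return rows.iloc[0]

    def to_csv(self, path: str | Path) -> None:
        self.data[["variety", "stage", *ACIDS]].to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "AcidProfile":
        df = pd.read_csv(path)
        stages: dict[str, None] = {}
        for s in df["stage"]:
            stages.setdefault(s, None)
        return cls(data=df, stage_order=tuple(stages))


def total_acid(profile: AcidProfile, variety: str, stage: str) -> float:
    row = profile.cell(variety, stage)
    return float(sum(row[a] for a in ACIDS))


def assign_conditions(
    profile: AcidProfile,
    varieties: Iterable[str] | None = None,
    reference_stage: str | None = None,
    exclude: Iterable[str] = ("ST",),
    explicit: Mapping[str, str] | None = None,
) -> dict[str, str]:
    """Split varieties into C1 (high acid) / C2 (low acid).

    Varieties whose total acid at ``reference_stage`` exceeds the median of
    the non-excluded varieties go to C1. An ``explicit`` map short-circuits
    inference and is returned unchanged (after light validation).
    """
    if explicit is not None:
        bad = set(explicit.values()) - {"C1", "C2", "excluded"}
        if bad:
            raise ValueError(f"explicit condition labels must be C1/C2/excluded, got {bad}")
        return dict(explicit)

    pool = [v for v in (varieties or profile.varieties) if v not in set(exclude)]
    if len(pool) < 2:
        raise ValueError("need >= 2 non-excluded varieties to infer a split")
    stage = reference_stage or profile.stage_order[-1]
    totals = {v: total_acid(profile, v, stage) for v in pool}
    vals = sorted(totals.values())
    median = (vals[len(vals) // 2] + vals[(len(vals) - 1) // 2]) / 2.0
    split = {v: ("C1" if t > median else "C2") for v, t in totals.items()}
    groups = set(split.values())
    if groups != {"C1", "C2"}:
        raise ValueError(
            "total acid does not resolve a high/low split at stage "
            f"{stage}; supply an explicit condition map"
        )
    return split
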