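"""Pearson correlation tables and empirical-distribution cutoffs.

For every (target gene, TF) pair the PCC of their condition time series is
computed under each condition. The pooled PCC values form an empirical
distribution (binned PDF/CDF on [-1, 1]); the significance cutoffs are read
off its tails: the positive cutoff is the largest bin edge that still has
at least ``alpha`` probability mass at or beyond it, so that exceeding the
cutoff is rarer than ``alpha`` under the empirical distribution. The
published reference cutoffs (+0.75 / -0.60, not-co-expressed band
[-0.5, 0.5)) are available as :meth:`CutoffSet.paper_defaults`.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .expression import ConditionSeries, GeneSets

logger = logging.getLogger(__name__)


def pearson(x: Sequence[float], y: Sequence[float]) -> float | None:
    """Product-moment correlation; ``None`` when a series has no variance.

    A zero-variance series makes the coefficient undefined; it is flagged
    as ``None`` rather than coerced to 0, so downstream classification can
    exclude (and count) such pairs explicitly.
    """
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.shape != ya.shape:
        raise ValueError("series length mismatch")
    if xa.size < 3:
        raise ValueError("PCC needs series of length >= 3")
    dx = xa - xa.mean()
    dy = ya - ya.mean()
    sx = float(dx @ dx)
    sy = float(dy @ dy)
    if sx == 0.0 or sy == 0.0:
        return None
    r = float(dx @ dy) / math.sqrt(sx * sy)
    return max(-1.0, min(1.0, r))


@dataclass(frozen=True)
class PCCRecord:
    """One target-TF pair with its per-condition PCCs (None = undefined)."""

    target: str
    tf: str
    pcc_c1: float | None
    pcc_c2: float | None

    @property
    def defined(self) -> bool:
        return self.pcc_c1 is not None and self.pcc_c2 is not None


def pcc_table(
    c1: ConditionSeries,
    c2: ConditionSeries,
    genes: GeneSets,
) -> list[PCCRecord]:
    """One record per (acid gene, TF) pair, per-condition PCCs attached.

    The table is targets x TFs (not all-vs-all); a gene acting as both
    target and TF is never paired with itself.
    """
    if tuple(c1.stages) != tuple(c2.stages):
        raise ValueError("condition series are on different stage grids")
    targets = sorted(genes.acid_genes)
    tfs = sorted(genes.tf_genes)

    def standardized(series: ConditionSeries, ids: list[str]) -> tuple[np.ndarray, np.ndarray]:
        for g in ids:
            if g not in series.data.index:
                raise KeyError(f"gene {g!r} missing from {series.condition} series")
        mat = series.data.loc[ids].to_numpy(dtype=float)
        centered = mat - mat.mean(axis=1, keepdims=True)
        norms = np.linalg.norm(centered, axis=1)
        flat = norms == 0.0
        safe = np.where(flat, 1.0, norms)
        return centered / safe[:, None], flat

    out: list[PCCRecord] = []
    corr = {}
    flat_t = {}
    flat_f = {}
    for cond, series in (("C1", c1), ("C2", c2)):
        zt, ft = standardized(series, targets)
        zf, ff = standardized(series, tfs)
        corr[cond] = np.clip(zt @ zf.T, -1.0, 1.0)
        flat_t[cond], flat_f[cond] = ft, ff
    n_undef = 0
    for i, tg in enumerate(targets):
        for j, tf in enumerate(tfs):
            if tg == tf:
                continue
            vals = {}
            for cond in ("C1", "C2"):
                if flat_t[cond][i] or flat_f[cond][j]:
                    vals[cond] = None
                else:
                    vals[cond] = float(corr[cond][i, j])
            if vals["C1"] is None or vals["C2"] is None:
                n_undef += 1
            out.append(PCCRecord(target=tg, tf=tf, pcc_c1=vals["C1"], pcc_c2=vals["C2"]))
    if n_undef:
        logger.info("%d pairs have an undefined PCC (zero-variance series)", n_undef)
    return out


@dataclass(frozen=True)
class PccDistribution:
    """Histogram of PCC values on [-1, 1]: bin probabilities and CDF."""

    bin_edges: np.ndarray
    pdf: np.ndarray
    cdf: np.ndarray

    @property
    def bin_width(self) -> float:
        return float(self.bin_edges[1] - self.bin_edges[0])


def empirical_pdf_cdf(pccs: Sequence[float], bin_width: float = 0.01) -> PccDistribution:
    values = np.asarray([p for p in pccs if p is not None], dtype=float)
    if values.size == 0:
        raise ValueError("no defined PCC values")
    n_bins = int(round(2.0 / bin_width))
    edges = np.linspace(-1.0, 1.0, n_bins + 1)
    # epsilon-robust bin assignment so values on a nominal edge (e.g. 0.9)
    # land in the bin whose left edge they name; 1.0 goes to the last bin
    idx = np.floor((values + 1.0) / bin_width + 1e-9).astype(int)
    idx = np.clip(idx, 0, n_bins - 1)
    counts = np.bincount(idx, minlength=n_bins)
    pdf = counts / counts.sum()
    return PccDistribution(bin_edges=edges, pdf=pdf, cdf=np.cumsum(pdf))


class CutoffEstimationError(ValueError):
    """Tail rule unattainable; caller should supply explicit cutoffs."""


def estimate_cutoffs(dist: PccDistribution, alpha: float = 0.05) -> tuple[float, float]:
    """Positive/negative cutoffs from the empirical CDF tails.

    Positive cutoff: the largest positive bin edge c with upper-tail mass
    P(PCC >= c) >= alpha, i.e. the last point where the tail is still
    non-negligible; beyond it, mass is rarer than alpha. When even the
    smallest positive edge has tail mass < alpha, that smallest edge is
    returned (the whole positive side is already significant). The negative
    cutoff mirrors this on the lower tail.
    """
    if not 0.0 < alpha < 0.5:
        raise ValueError("alpha must be in (0, 0.5)")
    edges = dist.bin_edges
    pdf = dist.pdf
    # upper tail at a left edge i: mass of bins i..end
    upper = np.concatenate([np.cumsum(pdf[::-1])[::-1], [0.0]])
    pos_candidates = [
        i for i in range(len(edges) - 1) if edges[i] > 0 and upper[i] >= alpha
    ]
    if pos_candidates:
        pos = round(float(edges[max(pos_candidates)]), 10)
    else:
        first_pos = next(i for i in range(len(edges)) if edges[i] > 0)
        pos = round(float(edges[first_pos]), 10)
    # lower tail at a right edge i: mass of bins 0..i-1
    lower = np.concatenate([[0.0], np.cumsum(pdf)])
    neg_candidates = [
        i for i in range(1, len(edges)) if edges[i] < 0 and lower[i] >= alpha
    ]
    if neg_candidates:
        neg = round(float(edges[min(neg_candidates)]), 10)
    else:
        last_neg = max(i for i in range(len(edges)) if edges[i] < 0)
        neg = round(float(edges[last_neg]), 10)
    if not (pos > 0.0 > neg):
        raise CutoffEstimationError(
            f"estimated cutoffs ({pos}, {neg}) do not bracket zero; "
            "supply explicit cutoffs"
        )
    return pos, neg


@dataclass(frozen=True)
class CutoffSet:
    """Per-condition significance cutoffs plus the not-co-expressed band."""

    pos_c1: float
    neg_c1: float
    pos_c2: float
    neg_c2: float
    z_lo: float = -0.5
    z_hi: float = 0.5
    alpha: float = 0.05
    bin_width: float = 0.01

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 0.5:
            raise ValueError("alpha must be in (0, 0.5)")
        for pos, neg in ((self.pos_c1, self.neg_c1), (self.pos_c2, self.neg_c2)):
            if not 0.0 < pos <= 1.0:
                raise ValueError(f"positive cutoff {pos} outside (0, 1]")
            if not -1.0 <= neg < 0.0:
                raise ValueError(f"negative cutoff {neg} outside [-1, 0)")
            if not (neg <= self.z_lo <= 0.0 <= self.z_hi <= pos):
                raise CutoffEstimationError(
                    f"cutoffs ({pos}, {neg}) overlap the zero band "
                    f"[{self.z_lo}, {self.z_hi}); supply explicit cutoffs"
                )

    def for_condition(self, condition: str) -> tuple[float, float]:
        if condition == "C1":
            return self.pos_c1, self.neg_c1
        if condition == "C2":
            return self.pos_c2, self.neg_c2
        raise KeyError(condition)

    @classmethod
    def paper_defaults(cls) -> "CutoffSet":
        """The published reference cutoffs: +0.75 / -0.60, band [-0.5, 0.5)."""
        return cls(pos_c1=0.75, neg_c1=-0.60, pos_c2=0.75, neg_c2=-0.60)

    @classmethod
    def from_records(
        cls,
        records: Sequence[PCCRecord],
        alpha: float = 0.05,
        bin_width: float = 0.01,
        shared: bool = False,
    ) -> "CutoffSet":
        """Estimate per-condition cutoffs from a PCC table.

        With ``shared=True`` both conditions' PCCs are pooled into one
        distribution and a single cutoff pair is used for both.
        """
        c1_vals = [r.pcc_c1 for r in records if r.pcc_c1 is not None]
        c2_vals = [r.pcc_c2 for r in records if r.pcc_c2 is not None]
        if shared:
            pos, neg = estimate_cutoffs(
                empirical_pdf_cdf(c1_vals + c2_vals, bin_width), alpha
            )
            return cls(pos, neg, pos, neg, alpha=alpha, bin_width=bin_width)
        pos1, neg1 = estimate_cutoffs(empirical_pdf_cdf(c1_vals, bin_width), alpha)
        pos2, neg2 = estimate_cutoffs(empirical_pdf_cdf(c2_vals, bin_width), alpha)
        return cls(pos1, neg1, pos2, neg2, alpha=alpha, bin_width=bin_width)
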