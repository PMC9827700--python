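"""Synthetic 3D transcriptome (time x phenotype x expression) generator.

Emulates the study design the pipeline targets: 5 varieties (two high-acid,
two low-acid, one wild) x 5 developmental stages x 3 replicates = 75 RNA-seq
samples, with planted co-expression structure and matching acid phenotypes,
so every downstream stage is testable without any external data.

Wave model
----------
Each developmental stage carries a latent phase ``psi`` on a developmental
circle, and a planted "wave" k is the cosine profile ``1 + cos(psi -
phi_k)`` sampled at the stage phases — a travelling expression wave whose
peak advances with the wave's phase. Stages sit at equally spaced phases
around the full circle, which makes the centered cosine/sine stage vectors
exactly isotropic, so the PCC between two waves equals the cosine of their
phase difference exactly. Waves advance in 18-degree steps: adjacent waves
correlate at cos 18 = 0.951 while every other target-TF wave offset stays
clear of the classification boundaries (+-0.5, +0.75, -0.60).
Wave-adjacent genes are therefore strongly co-expressed, giving a
breadth-first search from the first wave a well-posed chain of time levels.

Backbone (condition-shared) acid genes occupy odd waves and backbone TFs
even waves, so consecutive waves alternate between the two populations the
pair table correlates. Condition-specific genes follow a wave only in their
active condition; in the other condition they are expressed with one of the
two null-space patterns of span{1, cos psi, sin psi}, which have exactly
zero correlation with every wave and with each other — a planted
high-acid-specific pair is thus perfectly co-expressed under C1 and exactly
uncorrelated under C2 before noise; the groups' active profiles mix their
wave with orthogonal-plane content so they stay detached from the backbone
network. Anti-correlated pairs ride a backbone wave (acid member) and its
inverted shape (TF member), giving PCC exactly -1 under both conditions.
Background genes carry a weak gene-specific pattern, mostly in the
orthogonal plane with a bounded wave-plane share, shared by both
conditions. Noise is multiplicative log-normal per sample.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .correlation import CutoffSet, pearson
from .expression import ExpressionMatrix, GeneSets
from .phenotype import ACIDS, AcidProfile
from .relations import EXPORTED_TYPES, RelationSets, classify_pair

#: The developmental cycle: stages sit at equally spaced phases around the
#: full circle, so the centered cosine and sine stage vectors are exactly
#: orthogonal with equal norms and the PCC between any two waves equals
#: cos(phase difference) exactly.
#: Wave phase step (degrees): adjacent waves correlate at cos 18 = 0.951;
#: waves three apart at cos 54 = 0.588 (inside the unclassified gap), five
#: apart at 0, seven apart at -0.588.
WAVE_STEP_DEG = 18.0
#: Phase of the condition-specific groups' wave component (anywhere works:
#: the orthogonal-plane mixing below caps their backbone correlation).
GROUP_PHASE_DEG = 243.0
#: Wave-vs-pattern mixing weight of group profiles: a group profile is
#: wave + KAPPA * pattern, so its PCC with any pure wave is at most
#: 1/sqrt(1+KAPPA^2) = 0.447 -- inside the not-co-expressed band.
GROUP_KAPPA = 2.0
#: Anti-correlated pairs ride this backbone wave (acid member) and its
#: inversion (TF member).
ANTI_WAVE = 3
#: Background directions: mostly orthogonal-plane, with a wave-plane
#: component bounded by this value so background genes never reach the
#: positive cutoff against any wave.
BG_WAVE_SHARE_MAX = 0.35

DEFAULT_VARIETIES: tuple[tuple[str, str], ...] = (
    ("LG", "high"),
    ("MY", "high"),
    ("XC", "low"),
    ("XH", "low"),
    ("ST", "wild"),
)
DEFAULT_STAGES: tuple[tuple[str, int], ...] = (
    ("T1", 34),
    ("T2", 50),
    ("T3", 75),
    ("T4", 97),
    ("T5", 117),
)


@dataclass(frozen=True)
class SimConfig:
    """Study-design and generator parameters (defaults = the emulated study)."""

    n_genes: int = 2000
    n_tf: int = 200
    n_acid_genes: int = 182
    varieties: tuple[tuple[str, str], ...] = DEFAULT_VARIETIES
    stages: tuple[tuple[str, int], ...] = DEFAULT_STAGES
    n_replicates: int = 3
    n_waves: int = 8
    noise_sigma: float = 0.2
    frac_shared: float = 0.15
    frac_c1_specific: float = 0.07
    frac_c2_specific: float = 0.07
    frac_anticorrelated: float = 0.04
    amplitude: float = 4.0
    seed_boost: float = 1.5
    pattern_amplitude: float = 0.5
    background_amplitude: float = 0.03
    baseline_range: tuple[float, float] = (2.0, 20.0)
    seed_baseline: float = 30.0
    acid_amplitude_scale: float = 1.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1 or self.n_tf < 1 or self.n_acid_genes < 1:
            raise ValueError("gene counts must be positive")
        if self.n_tf + self.n_acid_genes > self.n_genes:
            raise ValueError("TF and acid gene sets exceed n_genes (sets are disjoint)")
        if self.n_waves < 1:
            raise ValueError("n_waves must be >= 1")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        fracs = (
            self.frac_shared,
            self.frac_c1_specific,
            self.frac_c2_specific,
            self.frac_anticorrelated,
        )
        if any(f < 0 for f in fracs):
            raise ValueError("fractions must be non-negative")
        if sum(fracs) > 1.0 + 1e-12:
            raise ValueError("specificity fractions sum above 1")
        if len(self.stages) < 5 and (
            self.frac_c1_specific or self.frac_c2_specific or self.frac_anticorrelated
        ):
            raise ValueError(
                "condition-specific and anti-correlated genes need >= 5 stages "
                "(they use the two wave-orthogonal patterns)"
            )
        tags = {tag for _, tag in self.varieties}
        if not {"high", "low"} <= tags:
            raise ValueError("varieties must include at least one high and one low tag")

    @property
    def n_samples(self) -> int:
        return len(self.varieties) * len(self.stages) * self.n_replicates

    @property
    def stage_labels(self) -> tuple[str, ...]:
        return tuple(label for label, _ in self.stages)


@dataclass
class SyntheticTruth:
    """Planted ground truth accompanying a simulated dataset.

    ``genes`` carries each structured gene's wave index and specificity
    label; ``pair_types`` maps every target-TF pair whose noiseless
    condition profiles classify into one of the eight exported joint types
    (under the reference cutoffs) to that type; ``designated_pairs`` is the
    explicitly planted one-to-one subset.
    """

    genes: pd.DataFrame  # index gene_id; columns: wave (nullable Int64), label
    pair_types: dict[tuple[str, str], str]
    designated_pairs: dict[tuple[str, str], str]
    seed_gene: str
    rng_seed: int
    reference_cutoffs: CutoffSet

    def pairs_of_type(self, joint_type: str) -> set[tuple[str, str]]:
        return {p for p, t in self.pair_types.items() if t == joint_type}

    def genes_with_label(self, label: str) -> list[str]:
        return list(self.genes.index[self.genes["label"] == label])


def make_wave_profile(
    peak_index: int, width: float, amplitude: float, n_points: int
) -> np.ndarray:
    """Gaussian expression bump on a 1..n integer grid, peaking at
    ``peak_index`` with maximum exactly ``amplitude``."""
    if not 1 <= peak_index <= n_points:
        raise ValueError(f"peak_index {peak_index} outside [1, {n_points}]")
    if width <= 0 or amplitude < 0:
        raise ValueError("width must be positive and amplitude non-negative")
    grid = np.arange(1, n_points + 1, dtype=float)
    return amplitude * np.exp(-0.5 * ((grid - peak_index) / width) ** 2)


# ---------------------------------------------------------------------------
# internal geometry helpers


def _stage_phases(n_stages: int) -> np.ndarray:
    """Stage phases: equally spaced around the full circle, so the centered
    cosine/sine stage vectors are orthogonal with equal norms and wave-wave
    PCC equals the cosine of the phase difference exactly."""
    return np.linspace(0.0, 2.0 * np.pi, n_stages, endpoint=False)


def _wave_phases(n_waves: int) -> np.ndarray:
    return np.radians(WAVE_STEP_DEG) * np.arange(n_waves)


def _minmax_shape(v: np.ndarray) -> np.ndarray:
    """Affine-map a profile vector onto [0, 1] (correlations unchanged)."""
    span = v.max() - v.min()
    if span < 1e-12:
        return np.full_like(v, 0.5)
    return (v - v.min()) / span


def _wave_shape(psi: np.ndarray, phi: float) -> np.ndarray:
    return _minmax_shape(np.cos(psi - phi))


def _null_patterns(psi: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Two orthonormal patterns with exactly zero PCC against every wave
    (they span the orthogonal complement of {1, cos psi, sin psi})."""
    basis = np.stack([np.ones_like(psi), np.cos(psi), np.sin(psi)])
    _, _, vt = np.linalg.svd(basis, full_matrices=True)
    out = []
    for row in vt[3:5]:
        lead = row[np.argmax(np.abs(row) > 1e-12)]
        out.append(row * np.sign(lead))
    return out[0], out[1]


def _group_shape(psi: np.ndarray, u_mix: np.ndarray) -> np.ndarray:
    """Active-condition profile of a condition-specific group.

    A unit wave at GROUP_PHASE_DEG mixed with GROUP_KAPPA parts of an
    orthogonal-plane direction: within-group pairs still correlate at
    exactly 1, but the profile's PCC with any pure wave is capped at
    cos(delta) / sqrt(1 + KAPPA^2) <= 0.45, keeping the group detached
    from the backbone network.
    """
    c = np.cos(psi - math.radians(GROUP_PHASE_DEG))
    v = c / np.linalg.norm(c) + GROUP_KAPPA * u_mix
    return _minmax_shape(v)


def _allocate(ids: Sequence[str], config: SimConfig) -> dict[str, tuple[str, int | None]]:
    """Assign (label, wave) per gene: shared genes round-robin over this
    population's waves, then c1/c2/anti groups, remainder background."""
    n = len(ids)
    n_shared = int(round(config.frac_shared * n))
    n_c1 = int(round(config.frac_c1_specific * n))
    n_c2 = int(round(config.frac_c2_specific * n))
    n_anti = int(round(config.frac_anticorrelated * n))
    while n_shared + n_c1 + n_c2 + n_anti > n:  # rounding overflow guard
        n_anti = max(0, n_anti - 1)
    out: dict[str, tuple[str, int | None]] = {}
    i = 0
    for j in range(n_shared):
        out[ids[i]] = ("shared", j)  # wave filled in by caller (parity-aware)
        i += 1
    for _ in range(n_c1):
        out[ids[i]] = ("c1_only", None)
        i += 1
    for _ in range(n_c2):
        out[ids[i]] = ("c2_only", None)
        i += 1
    for _ in range(n_anti):
        out[ids[i]] = ("anti", None)
        i += 1
    while i < n:
        out[ids[i]] = ("background", None)
        i += 1
    return out


# ---------------------------------------------------------------------------
# main entry points


def simulate_dataset(
    config: SimConfig = SimConfig(),
) -> tuple[ExpressionMatrix, AcidProfile, GeneSets, SyntheticTruth]:
    """Generate (expression matrix, acid profiles, gene sets, ground truth).

    Deterministic for a fixed ``config.rng_seed``.
    """
    rng = np.random.default_rng(config.rng_seed)
    n_stages = len(config.stages)
    psi = _stage_phases(n_stages)
    phi = _wave_phases(config.n_waves)
    ua, ut = (None, None)
    if n_stages >= 5:
        ua, ut = _null_patterns(psi)

    acid_ids = [f"ACID{i:04d}" for i in range(1, config.n_acid_genes + 1)]
    tf_ids = [f"TF{i:04d}" for i in range(1, config.n_tf + 1)]
    n_bg = config.n_genes - config.n_acid_genes - config.n_tf
    filler_ids = [f"BG{i:04d}" for i in range(1, n_bg + 1)]

    odd_waves = list(range(1, config.n_waves + 1, 2)) or [1]
    even_waves = list(range(2, config.n_waves + 1, 2)) or [1]

    alloc = _allocate(acid_ids, config)
    # acid genes must include the seed: force the first one onto wave 1
    if not any(lbl == "shared" for lbl, _ in alloc.values()):
        alloc[acid_ids[0]] = ("shared", 0)
    alloc_tf = _allocate(tf_ids, config)

    labels: dict[str, str] = {}
    waves: dict[str, int | None] = {}
    phases: dict[str, float | None] = {}  # active-condition wave phase

    anti_wave = min(ANTI_WAVE, config.n_waves)

    def finish(alloc_map, wave_cycle, role):
        group_wave = {"c1_only": config.n_waves, "c2_only": 1, "anti": anti_wave}
        for gene, (label, slot) in alloc_map.items():
            labels[gene] = label
            if label == "shared":
                w = wave_cycle[slot % len(wave_cycle)]
                waves[gene] = w
                phases[gene] = float(phi[w - 1])
            elif label in group_wave:
                waves[gene] = group_wave[label]
                phases[gene] = None
            else:
                waves[gene] = None
                phases[gene] = None

    finish(alloc, odd_waves, "acid")
    finish(alloc_tf, even_waves, "tf")
    for gene in filler_ids:
        labels[gene] = "background"
        waves[gene] = None
        phases[gene] = None

    seed_gene = next(
        g for g in acid_ids if labels[g] == "shared" and waves[g] == odd_waves[0]
    )

    gene_ids = acid_ids + tf_ids + filler_ids
    lo, hi = config.baseline_range
    baselines = np.exp(rng.uniform(np.log(lo), np.log(hi), size=len(gene_ids)))
    baseline = dict(zip(gene_ids, baselines))
    baseline[seed_gene] = config.seed_baseline

    def role_of(gene: str) -> str:
        return "acid" if gene.startswith("ACID") else "tf" if gene.startswith("TF") else "bg"

    # pattern profiles scaled to max |value| 1 so the swing is bounded
    ua_hat = ua / np.abs(ua).max() if ua is not None else None
    ut_hat = ut / np.abs(ut).max() if ut is not None else None
    group_mix = {
        "c1_only": None if ua is None else (ua + ut) / math.sqrt(2.0),
        "c2_only": None if ua is None else (ua - ut) / math.sqrt(2.0),
    }

    # noiseless per-condition mean profiles (varieties within a condition share them)
    means: dict[str, dict[str, np.ndarray]] = {"C1": {}, "C2": {}}
    for gene in gene_ids:
        label = labels[gene]
        b = baseline[gene]
        amp = config.amplitude * (config.seed_boost if gene == seed_gene else 1.0)
        if label == "background":
            # A strong smooth temporal program, mostly in the wave-orthogonal
            # plane with a bounded wave-plane share: background genes vary
            # like real transcripts but can never reach the positive cutoff
            # against a planted wave, so the empirical PCC tail is governed
            # by planted structure plus the attenuated sampling null.
            if ua is not None:
                share = rng.uniform(0.0, BG_WAVE_SHARE_MAX)
                theta, beta = rng.uniform(0.0, 2.0 * np.pi, size=2)
                w = np.cos(psi - theta)
                w /= np.linalg.norm(w)
                u = math.cos(beta) * ua + math.sin(beta) * ut
                z = share * w + math.sqrt(1.0 - share**2) * u
            else:
                z = rng.standard_normal(n_stages)
            z = z / max(z.std(), 1e-12)
            prof = np.maximum(b * (1.0 + config.background_amplitude * z), 0.0)
            means["C1"][gene] = prof
            means["C2"][gene] = prof
        elif label == "shared":
            prof = b * (1.0 + amp * _wave_shape(psi, phases[gene]))
            means["C1"][gene] = prof
            means["C2"][gene] = prof
        elif label == "anti":
            # acid member rides the anti wave; its TF partner the inverted
            # wave -> PCC exactly -1 under both conditions
            wave_phi = float(phi[anti_wave - 1])
            raw = np.cos(psi - wave_phi)
            if role_of(gene) == "tf":
                raw = -raw
            prof = b * (1.0 + amp * _minmax_shape(raw))
            means["C1"][gene] = prof
            means["C2"][gene] = prof
        else:  # c1_only / c2_only
            active = b * (1.0 + amp * _group_shape(psi, group_mix[label]))
            pattern = ua_hat if role_of(gene) == "acid" else ut_hat
            inactive = b * (1.0 + config.pattern_amplitude * pattern)
            if label == "c1_only":
                means["C1"][gene], means["C2"][gene] = active, inactive
            else:
                means["C1"][gene], means["C2"][gene] = inactive, active

    condition_of = {name: tag for name, tag in config.varieties}
    sample_names: list[str] = []
    sample_means = []
    for vname, tag in config.varieties:
        if tag == "high":
            vmean = means["C1"]
        elif tag == "low":
            vmean = means["C2"]
        else:  # wild: intermediate between the two condition programs
            vmean = {
                g: (means["C1"][g] + means["C2"][g]) / 2.0 for g in gene_ids
            }
        stage_mat = np.stack([vmean[g] for g in gene_ids])  # genes x stages
        for s_idx, (s_label, _) in enumerate(config.stages):
            for rep in range(1, config.n_replicates + 1):
                sample_names.append(f"{vname}_{s_label}_REP{rep}")
                sample_means.append(stage_mat[:, s_idx])
    mean_mat = np.stack(sample_means, axis=1)  # genes x samples
    sigma = config.noise_sigma
    if sigma > 0:
        eps = rng.standard_normal(mean_mat.shape)
        values = mean_mat * np.exp(sigma * eps - sigma**2 / 2.0)
    else:
        values = mean_mat
    matrix = ExpressionMatrix.from_dataframe(
        pd.DataFrame(values, index=gene_ids, columns=sample_names)
    )

    acids = simulate_acid_profiles(config, rng=rng)
    gene_sets = GeneSets(tf_genes=frozenset(tf_ids), acid_genes=frozenset(acid_ids))
    truth = _build_truth(
        config, acid_ids, tf_ids, means, labels, waves, seed_gene
    )
    return matrix, acids, gene_sets, truth


def _build_truth(
    config: SimConfig,
    acid_ids: list[str],
    tf_ids: list[str],
    means: dict[str, dict[str, np.ndarray]],
    labels: dict[str, str],
    waves: dict[str, int | None],
    seed_gene: str,
) -> SyntheticTruth:
    reference = CutoffSet.paper_defaults()
    # Truth covers pairs of planted genes only: a background gene's 5-point
    # correlation with anything is incidental, not planted structure.
    planted_acid = [g for g in acid_ids if labels[g] != "background"]
    planted_tf = [g for g in tf_ids if labels[g] != "background"]
    pair_types: dict[tuple[str, str], str] = {}
    for tg in planted_acid:
        for tf in planted_tf:
            r1 = pearson(means["C1"][tg], means["C1"][tf])
            r2 = pearson(means["C2"][tg], means["C2"][tf])
            if r1 is None or r2 is None:
                continue
            joint = classify_pair(r1, r2, reference)
            if joint is not None and joint != "C10C20":
                pair_types[(tg, tf)] = joint

    by_label: dict[str, tuple[list[str], list[str]]] = {}
    for lbl in ("shared", "c1_only", "c2_only", "anti"):
        by_label[lbl] = (
            [g for g in acid_ids if labels[g] == lbl],
            [g for g in tf_ids if labels[g] == lbl],
        )
    designated: dict[tuple[str, str], str] = {}
    expected = {"c1_only": "C1+C20", "c2_only": "C10C2+", "anti": "C1-C2-"}
    for lbl, joint in expected.items():
        a_list, t_list = by_label[lbl]
        for a, t in zip(a_list, t_list):
            designated[(a, t)] = joint
    # shared designated pairs: each backbone acid gene with a wave-adjacent TF
    shared_acid, shared_tf = by_label["shared"]
    tf_by_wave: dict[int, list[str]] = {}
    for t in shared_tf:
        tf_by_wave.setdefault(waves[t], []).append(t)
    for a in shared_acid:
        partners = tf_by_wave.get(waves[a] + 1) or tf_by_wave.get(waves[a] - 1)
        if partners:
            designated[(a, partners[0])] = "C1+C2+"

    gene_table = pd.DataFrame(
        {
            "wave": pd.array(
                [waves[g] for g in labels], dtype="Int64"
            ),
            "label": list(labels.values()),
        },
        index=list(labels.keys()),
    )
    truth = SyntheticTruth(
        genes=gene_table,
        pair_types=pair_types,
        designated_pairs=designated,
        seed_gene=seed_gene,
        rng_seed=config.rng_seed,
        reference_cutoffs=reference,
    )
    assert gene_table.loc[seed_gene, "wave"] == 1
    return truth


#: five-point acid trajectory templates (interpolated for other stage counts)
_ACID_TEMPLATES = {
    "high": {
        "malate": [6.0, 8.0, 9.0, 7.0, 5.0],
        "citrate": [1.2, 1.3, 1.5, 4.0, 8.0],
        "quinate": [2.0, 3.5, 5.0, 3.0, 1.5],
    },
    "low": {
        "malate": [5.0, 7.0, 8.0, 6.0, 4.0],
        "citrate": [1.0, 1.1, 1.2, 1.0, 0.8],
        "quinate": [1.8, 3.2, 4.5, 2.7, 1.3],
    },
    "wild": {
        "malate": [5.5, 7.5, 8.5, 6.5, 4.5],
        "citrate": [1.1, 1.2, 1.4, 2.0, 3.0],
        "quinate": [1.9, 3.3, 4.8, 2.8, 1.4],
    },
}
_ACID_NOISE_SIGMA = 0.03


def simulate_acid_profiles(
    config: SimConfig = SimConfig(), rng: np.random.Generator | None = None
) -> AcidProfile:
    """Acid trajectories with the study's qualitative patterns planted:
    citrate surges after the hard-core stage in high-acid varieties,
    quinate declines late everywhere, and total acid at maturity separates
    high from low varieties by a wide margin."""
    if rng is None:
        rng = np.random.default_rng(config.rng_seed + 1)
    n_stages = len(config.stages)
    x = np.linspace(0.0, 1.0, n_stages)
    x5 = np.linspace(0.0, 1.0, 5)
    rows = []
    for vname, tag in config.varieties:
        tmpl = _ACID_TEMPLATES[tag]
        noise = np.exp(
            _ACID_NOISE_SIGMA * rng.standard_normal((3, n_stages))
        )
        for s_idx, (s_label, _) in enumerate(config.stages):
            row = {"variety": vname, "stage": s_label}
            for a_idx, acid in enumerate(ACIDS):
                base = np.interp(x[s_idx], x5, tmpl[acid])
                row[acid] = config.acid_amplitude_scale * base * noise[a_idx, s_idx]
            rows.append(row)
    return AcidProfile(
        data=pd.DataFrame(rows), stage_order=config.stage_labels
    )


@dataclass(frozen=True)
class RecoveryScore:
    """Precision/recall/F1 of one joint type against planted truth."""

    precision: float | None
    recall: float | None
    f1: float | None
    n_true: int
    n_predicted: int


def evaluate_recovery(
    truth: SyntheticTruth, relations: RelationSets
) -> dict[str, RecoveryScore]:
    """Per-joint-type recovery of the planted pairs.

    Scoring is restricted to pairs of planted (non-background) genes, the
    universe the truth describes; within it, pairs absent from truth count
    as negatives. Precision is unavailable on an empty prediction; recall
    is unavailable on an empty planted set.
    """
    planted = set(truth.genes.index[truth.genes["label"] != "background"])
    out: dict[str, RecoveryScore] = {}
    for joint in EXPORTED_TYPES:
        true = truth.pairs_of_type(joint)
        pred = {
            (a, b) for a, b in relations.pairs(joint) if a in planted and b in planted
        }
        tp = len(true & pred)
        precision = tp / len(pred) if pred else None
        recall = tp / len(true) if true else None
        if precision is None or recall is None:
            f1 = None
        elif precision + recall == 0:
            f1 = 0.0
        else:
            f1 = 2 * precision * recall / (precision + recall)
        out[joint] = RecoveryScore(precision, recall, f1, len(true), len(pred))
    return out


def write_dataset(
    outdir: str | Path,
    matrix: ExpressionMatrix,
    acids: AcidProfile,
    gene_sets: GeneSets,
    truth: SyntheticTruth,
) -> None:
    """Write the simulated dataset as plain-text files."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    matrix.to_tsv(outdir / "expression_fpkm.tsv")
    acids.to_csv(outdir / "acids.csv")
    from .expression import write_gene_list

    write_gene_list(gene_sets.tf_genes, outdir / "tf_genes.txt")
    write_gene_list(gene_sets.acid_genes, outdir / "acid_genes.txt")
    labels = truth.genes.copy()
    labels.index.name = "gene_id"
    labels.to_csv(outdir / "truth_genes.csv")
    with open(outdir / "truth_pairs.csv", "w") as fh:
        fh.write("acid_gene,tf_gene,joint_type,designated\n")
        for (a, t), joint in sorted(truth.pair_types.items()):
            des = int((a, t) in truth.designated_pairs)
            fh.write(f"{a},{t},{joint},{des}\n")
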