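"""Pearson correlation, its empirical distribution and cutoff estimation."""

import numpy as np
import pandas as pd
import pytest
import scipy.stats
from hypothesis import given
from hypothesis import strategies as st

from togcn import (
    CutoffSet,
    GeneSets,
    empirical_pdf_cdf,
    estimate_cutoffs,
    pcc_table,
    pearson,
)
from togcn.correlation import CutoffEstimationError
from togcn.expression import ConditionSeries


def series(values_by_gene, condition="C1", stages=("T1", "T2", "T3", "T4", "T5")):
    df = pd.DataFrame(values_by_gene, index=list(stages)).T
    df.columns = list(stages)
    return ConditionSeries(
        condition=condition, varieties=("LG",), stages=tuple(stages), data=df
    )


class TestPearson:
    @pytest.mark.parametrize(
        "x,y,expected",
        [
            ((1, 2, 3, 4, 5), (2, 4, 6, 8, 10), 1.0),
            ((1, 2, 3, 4, 5), (5, 4, 3, 2, 1), -1.0),
            # hand-derived: sum dx*dy = 8, sum dx^2 = sum dy^2 = 10
            ((2, 1, 3, 5, 4), (1, 2, 3, 4, 5), 0.8),
        ],
    )
    def test_known_values(self, x, y, expected):
        assert pearson(x, y) == pytest.approx(expected, abs=1e-12)

    def test_zero_variance_flagged_not_zero(self):
        assert pearson((1, 1, 1), (1, 2, 3)) is None

    @pytest.mark.parametrize("x,y", [((1, 2), (1, 2)), ((1, 2, 3), (1, 2))])
    def test_short_or_mismatched_rejected(self, x, y):
        with pytest.raises(ValueError):
            pearson(x, y)

    def test_matches_definitional_oracle_on_1000_series(self):
        rng = np.random.default_rng(42)
        for _ in range(1000):
            x = rng.normal(size=5)
            y = rng.normal(size=5)
            expected = scipy.stats.pearsonr(x, y).statistic
            assert pearson(x, y) == pytest.approx(expected, abs=1e-12)

    @given(
        a=st.floats(min_value=0.01, max_value=100),
        b=st.floats(min_value=-50, max_value=50),
    )
    def test_affine_invariance_positive_slope(self, a, b):
        x = np.array([2.0, 1.0, 3.0, 5.0, 4.0])
        y = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        assert pearson(a * x + b, y) == pytest.approx(pearson(x, y), abs=1e-9)
        assert pearson(-a * x + b, y) == pytest.approx(-pearson(x, y), abs=1e-9)


class TestPccTable:
    def gene_sets(self):
        return GeneSets(
            tf_genes=frozenset({"TF1", "TF2", "TF3"}),
            acid_genes=frozenset({"A1", "A2"}),
        )

    def test_cardinality_targets_times_tfs(self):
        prof = {g: np.arange(5) + i for i, g in enumerate(["A1", "A2", "TF1", "TF2", "TF3"])}
        recs = pcc_table(series(prof), series(prof, "C2"), self.gene_sets())
        assert len(recs) == 6

    def test_constant_tf_flagged_undefined(self):
        prof = {
            "A1": [1, 2, 3, 4, 5],
            "A2": [5, 4, 3, 2, 1],
            "TF1": [7, 7, 7, 7, 7],
            "TF2": [1, 3, 2, 5, 4],
            "TF3": [2, 2, 3, 4, 4],
        }
        recs = pcc_table(series(prof), series(prof, "C2"), self.gene_sets())
        flagged = [r for r in recs if r.tf == "TF1"]
        assert flagged and all(r.pcc_c1 is None and r.pcc_c2 is None for r in flagged)

    def test_missing_gene_named(self):
        prof = {"A1": [1, 2, 3, 4, 5]}
        gs = GeneSets(tf_genes=frozenset({"TFX"}), acid_genes=frozenset({"A1"}))
        with pytest.raises(KeyError, match="TFX"):
            pcc_table(series(prof), series(prof, "C2"), gs)

    def test_planted_identical_profiles_give_unit_pcc(self, noiseless_dataset, condition_map):
        from togcn import average_replicates, build_condition_series

        matrix, _, gene_sets, truth = noiseless_dataset
        c1, c2 = build_condition_series(average_replicates(matrix), condition_map)
        (acid, tf), _ = next(
            (p, t) for p, t in truth.designated_pairs.items() if t == "C1+C20"
        )
        small = GeneSets(tf_genes=frozenset({tf}), acid_genes=frozenset({acid}))
        rec = pcc_table(c1, c2, small)[0]
        assert rec.pcc_c1 == pytest.approx(1.0, abs=1e-9)
        assert abs(rec.pcc_c2) < 1e-9


class TestDistribution:
    def test_single_value_mass_in_one_bin(self):
        dist = empirical_pdf_cdf([0.0])
        assert dist.pdf.sum() == pytest.approx(1.0)
        assert dist.pdf.max() == 1.0

    def test_uniform_grid_cdf_half_at_zero(self):
        values = np.linspace(-1, 1, 201)
        dist = empirical_pdf_cdf(values)
        mid = np.searchsorted(dist.bin_edges, 0.0)
        assert dist.cdf[mid - 1] == pytest.approx(0.5, abs=0.01)

    @given(st.lists(st.floats(min_value=-1, max_value=1), min_size=1, max_size=50))
    def test_pdf_normalized_cdf_monotone(self, values):
        dist = empirical_pdf_cdf(values)
        assert dist.pdf.sum() == pytest.approx(1.0, abs=1e-9)
        assert np.all(np.diff(dist.cdf) >= -1e-12)
        assert dist.cdf[-1] == pytest.approx(1.0, abs=1e-9)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            empirical_pdf_cdf([])


class TestEstimateCutoffs:
    def test_tail_count_example(self):
        # 19 zeros and one 0.9: P(PCC >= 0.9) = 1/20 = alpha
        values = [0.0] * 19 + [0.9]
        pos, neg = estimate_cutoffs(empirical_pdf_cdf(values), alpha=0.05)
        assert pos == pytest.approx(0.9, abs=1e-9)

    def test_all_zeros_fall_back_to_smallest_positive_edge(self):
        pos, neg = estimate_cutoffs(empirical_pdf_cdf([0.0] * 10), alpha=0.05)
        assert pos == pytest.approx(0.01, abs=1e-9)
        assert neg == pytest.approx(-0.01, abs=1e-9)

    def test_paper_defaults(self):
        cs = CutoffSet.paper_defaults()
        assert (cs.pos_c1, cs.neg_c1) == (0.75, -0.60)
        assert (cs.pos_c2, cs.neg_c2) == (0.75, -0.60)
        assert (cs.z_lo, cs.z_hi) == (-0.5, 0.5)

    def test_monotone_in_alpha(self):
        rng = np.random.default_rng(7)
        dist = empirical_pdf_cdf(np.clip(rng.normal(0, 0.4, 500), -1, 1))
        cuts = [estimate_cutoffs(dist, a) for a in (0.01, 0.05, 0.1, 0.2)]
        pos = [c[0] for c in cuts]
        neg = [c[1] for c in cuts]
        assert all(pos[i] >= pos[i + 1] for i in range(len(pos) - 1))
        assert all(neg[i] <= neg[i + 1] for i in range(len(neg) - 1))

    def test_permutation_invariance(self):
        rng = np.random.default_rng(3)
        values = np.clip(rng.normal(0, 0.5, 200), -1, 1)
        a = estimate_cutoffs(empirical_pdf_cdf(values))
        b = estimate_cutoffs(empirical_pdf_cdf(values[::-1]))
        assert a == b

    def test_overlapping_band_rejected(self):
        with pytest.raises(CutoffEstimationError):
            CutoffSet(pos_c1=0.3, neg_c1=-0.6, pos_c2=0.75, neg_c2=-0.6)
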