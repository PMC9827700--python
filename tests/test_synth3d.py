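"""The synthetic 3D-transcriptome generator and its ground truth."""

import numpy as np
import pandas as pd
import pytest

from togcn import (
    CutoffSet,
    PCCRecord,
    SimConfig,
    build_relation_sets,
    evaluate_recovery,
    make_wave_profile,
    simulate_acid_profiles,
    simulate_dataset,
    total_acid,
)
from togcn.synth3d import SyntheticTruth


class TestSimConfig:
    def test_default_sample_count_is_75(self):
        assert SimConfig().n_samples == 75

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"frac_shared": 0.6, "frac_c1_specific": 0.3, "frac_c2_specific": 0.3},
            {"n_waves": 0},
            {"n_replicates": 0},
            {"noise_sigma": -0.1},
            {"n_tf": 1900, "n_acid_genes": 200},
        ],
    )
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SimConfig(**kwargs)


class TestSimulateDataset:
    def test_default_design_emits_75_samples(self, noisy_dataset):
        matrix, _, _, _ = noisy_dataset
        assert matrix.n_samples == 75
        assert matrix.n_genes == 2000

    def test_deterministic_for_fixed_seed(self):
        cfg = SimConfig(n_genes=60, n_tf=12, n_acid_genes=12, rng_seed=9)
        m1, a1, g1, t1 = simulate_dataset(cfg)
        m2, a2, g2, t2 = simulate_dataset(cfg)
        assert m1.data.to_csv() == m2.data.to_csv()
        assert a1.data.to_csv() == a2.data.to_csv()
        assert t1.pair_types == t2.pair_types
        assert t1.seed_gene == t2.seed_gene

    def test_different_seeds_differ(self):
        cfg1 = SimConfig(n_genes=60, n_tf=12, n_acid_genes=12, rng_seed=1)
        cfg2 = SimConfig(n_genes=60, n_tf=12, n_acid_genes=12, rng_seed=2)
        m1 = simulate_dataset(cfg1)[0]
        m2 = simulate_dataset(cfg2)[0]
        assert m1.data.to_csv() != m2.data.to_csv()

    def test_truth_has_one_seed_gene_at_wave_one(self, noisy_dataset):
        _, _, gene_sets, truth = noisy_dataset
        assert truth.seed_gene in gene_sets.acid_genes
        assert int(truth.genes.loc[truth.seed_gene, "wave"]) == 1
        assert truth.genes.loc[truth.seed_gene, "label"] == "shared"

    def test_planted_wave_indices_in_range(self, noisy_dataset):
        _, _, _, truth = noisy_dataset
        waves = truth.genes["wave"].dropna()
        assert waves.between(1, 8).all()

    def test_designated_pairs_carry_consistent_labels(self, noiseless_dataset):
        _, _, _, truth = noiseless_dataset
        expected_label = {
            "C1+C20": ("c1_only", "c1_only"),
            "C10C2+": ("c2_only", "c2_only"),
            "C1-C2-": ("anti", "anti"),
            "C1+C2+": ("shared", "shared"),
        }
        assert truth.designated_pairs
        for (acid, tf), joint in truth.designated_pairs.items():
            la = truth.genes.loc[acid, "label"]
            lt = truth.genes.loc[tf, "label"]
            assert (la, lt) == expected_label[joint]
            assert truth.pair_types[(acid, tf)] == joint

    def test_noiseless_planted_pair_pccs(self, noiseless_dataset, condition_map):
        """Planted high-acid-specific pairs: PCC 1 under C1, 0 under C2."""
        from togcn import average_replicates, build_condition_series, pearson

        matrix, _, _, truth = noiseless_dataset
        c1, c2 = build_condition_series(average_replicates(matrix), condition_map)
        for (acid, tf), joint in truth.designated_pairs.items():
            if joint != "C1+C20":
                continue
            assert pearson(c1.profile(acid), c1.profile(tf)) == pytest.approx(1.0, abs=1e-9)
            assert pearson(c2.profile(acid), c2.profile(tf)) == pytest.approx(0.0, abs=1e-9)


class TestMakeWaveProfile:
    def test_peak_placement(self):
        prof = make_wave_profile(1, 1.0, 10.0, 5)
        assert prof.argmax() == 0
        assert prof.max() == pytest.approx(10.0)

    def test_symmetry_around_peak(self):
        prof = make_wave_profile(3, 1.0, 10.0, 5)
        assert prof[1] == pytest.approx(prof[3])
        assert prof[0] == pytest.approx(prof[4])

    def test_zero_amplitude(self):
        assert not make_wave_profile(2, 1.0, 0.0, 5).any()

    def test_peak_outside_grid_rejected(self):
        with pytest.raises(ValueError):
            make_wave_profile(6, 1.0, 1.0, 5)


class TestAcidProfiles:
    def test_qualitative_patterns(self):
        cfg = SimConfig(rng_seed=3)
        acids = simulate_acid_profiles(cfg)
        high = [v for v, tag in cfg.varieties if tag == "high"]
        low = [v for v, tag in cfg.varieties if tag == "low"]
        for v in high:  # citrate rises through the late stages
            c = {s: acids.cell(v, s)["citrate"] for s in ("T3", "T4", "T5")}
            assert c["T3"] < c["T4"] < c["T5"]
        for v in acids.varieties:  # quinate declines after the hard-core stage
            q = {s: acids.cell(v, s)["quinate"] for s in ("T3", "T5")}
            assert q["T5"] < q["T3"]
        for hv in high:  # maturity total acid separates the conditions
            for lv in low:
                assert total_acid(acids, hv, "T5") > total_acid(acids, lv, "T5")
        assert (acids.data[["malate", "citrate", "quinate"]] >= 0).all().all()

    def test_zero_amplitude_scaling_gives_all_zero(self):
        acids = simulate_acid_profiles(SimConfig(acid_amplitude_scale=0.0))
        assert not acids.data[["malate", "citrate", "quinate"]].to_numpy().any()


class TestEvaluateRecovery:
    def tiny_truth(self, pairs):
        genes = {}
        for a, t in pairs:
            genes[a] = ("c1_only", 8)
            genes[t] = ("c1_only", 8)
        table = pd.DataFrame(
            {
                "wave": pd.array([w for _, w in genes.values()], dtype="Int64"),
                "label": [l for l, _ in genes.values()],
            },
            index=list(genes),
        )
        return SyntheticTruth(
            genes=table,
            pair_types={p: "C1+C20" for p in pairs},
            designated_pairs={p: "C1+C20" for p in pairs},
            seed_gene=pairs[0][0],
            rng_seed=0,
            reference_cutoffs=CutoffSet.paper_defaults(),
        )

    def relations_with(self, pairs):
        records = [PCCRecord(a, t, 0.9, 0.1) for a, t in pairs]
        return build_relation_sets(records, CutoffSet.paper_defaults())

    def test_exact_recovery_scores_one(self):
        pairs = [(f"A{i}", f"T{i}") for i in range(10)]
        scores = evaluate_recovery(self.tiny_truth(pairs), self.relations_with(pairs))
        assert scores["C1+C20"].precision == 1.0
        assert scores["C1+C20"].recall == 1.0
        assert scores["C1+C20"].f1 == 1.0

    def test_empty_prediction_gives_na_precision_zero_recall(self):
        pairs = [(f"A{i}", f"T{i}") for i in range(10)]
        empty = build_relation_sets(
            [PCCRecord("A0", "T0", 0.1, 0.1)], CutoffSet.paper_defaults()
        )
        scores = evaluate_recovery(self.tiny_truth(pairs), empty)
        assert scores["C1+C20"].precision is None
        assert scores["C1+C20"].recall == 0.0
        assert scores["C1+C20"].f1 is None

    def test_half_recovered_no_false_positives(self):
        pairs = [(f"A{i}", f"T{i}") for i in range(10)]
        scores = evaluate_recovery(self.tiny_truth(pairs), self.relations_with(pairs[:5]))
        s = scores["C1+C20"]
        assert s.precision == 1.0
        assert s.recall == pytest.approx(0.5)
        assert s.f1 == pytest.approx(2 / 3)

    def test_empty_planted_type_reports_na_recall(self):
        pairs = [("A0", "T0")]
        scores = evaluate_recovery(self.tiny_truth(pairs), self.relations_with(pairs))
        assert scores["C1-C2+"].recall is None
        assert scores["C1-C2+"].f1 is None
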