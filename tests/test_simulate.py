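"""Generator contracts: determinism, planted structure, config validation."""

import numpy as np
import pandas as pd
import pytest

from gliomir import (
    InvalidConfigError,
    SimulationConfig,
    combine_grades,
    differential_expression,
    intersect_targets,
    simulate_cohorts,
    simulate_control_contrasts,
    simulate_mrna_cohorts,
    simulate_stage_profiles,
    simulate_target_databases,
    simulate_tumor_profiles,
)


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"nb_dispersion": 0.0},
            {"nb_dispersion": -1.0},
            {"intensity_sd": -0.1},
            {"n_stage_reps": 1},
            {"n_mirna": 100, "n_shared_platform": 150},
            {"n_mirna": 100, "n_prognostic": 200},
            {"censor_rate": 1.0},
            {"target_overlap": 1.5},
            {"group_sizes": (6, 10, 13)},
            {"group_sizes": (1, 10, 13, 14)},
        ],
    )
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(InvalidConfigError):
            SimulationConfig(**kwargs)

    def test_cohorts_require_positive_intensity_sd(self):
        cfg = SimulationConfig(intensity_sd=0.0)
        with pytest.raises(InvalidConfigError):
            simulate_cohorts(cfg)

    def test_yaml_roundtrip(self, tmp_path):
        cfg = SimulationConfig(seed=3, n_mirna=99, n_shared_platform=80, markers_per_block=10)
        cfg.write(tmp_path / "cfg.yaml")
        assert SimulationConfig.from_file(tmp_path / "cfg.yaml") == cfg


class TestDeterminism:
    def test_cohorts_bit_identical_under_fixed_seed(self, small_config):
        a = simulate_cohorts(small_config)
        b = simulate_cohorts(small_config)
        pd.testing.assert_frame_equal(a[0].values, b[0].values)
        pd.testing.assert_frame_equal(a[1].values, b[1].values)
        pd.testing.assert_frame_equal(a[2], b[2])

    def test_tumors_bit_identical_under_fixed_seed(self, small_config):
        stages = simulate_stage_profiles(small_config)
        a = simulate_tumor_profiles(small_config, stages)
        b = simulate_tumor_profiles(small_config, stages)
        pd.testing.assert_frame_equal(a[0].values, b[0].values)
        pd.testing.assert_frame_equal(a[1], b[1])

    def test_streams_are_independent(self, small_config):
        # generating tumors must not perturb a later cohort draw
        first = simulate_cohorts(small_config)[0].values
        stages = simulate_stage_profiles(small_config)
        simulate_tumor_profiles(small_config, stages)
        second = simulate_cohorts(small_config)[0].values
        pd.testing.assert_frame_equal(first, second)


class TestCohorts:
    def test_annotation_layout(self, small_config):
        _, _, ann, _ = simulate_cohorts(small_config)
        n3g, n3p, n4g, n4p = small_config.group_sizes
        assert (ann["grade"] == "GIIIA").sum() == n3g + n3p
        assert (ann["grade"] == "GBM").sum() == n4g + n4p
        poor = ann[ann["group"] == "poor"]
        assert poor["event"].all()
        assert (poor.loc[poor["grade"] == "GIIIA", "survival_months"] < 10).all()
        assert (poor.loc[poor["grade"] == "GBM", "survival_months"] < 4).all()
        good = ann[ann["group"] == "good"]
        assert (good["survival_months"] > 48).all()

    def test_library_sizes_span_twofold(self, small_config):
        seq, _, _, _ = simulate_cohorts(small_config)
        libs = seq.values.sum(axis=0)
        assert libs.max() / libs.min() >= 2.0

    def test_counts_are_integers_and_platforms_tagged(self, small_config):
        seq, arr, _, _ = simulate_cohorts(small_config)
        assert seq.platform_kind == "counts"
        assert arr.platform_kind == "intensity"
        vals = seq.values.to_numpy()
        assert np.all(vals >= 0) and np.all(vals == np.floor(vals))

    def test_planted_effects_concordant_across_grades(self, small_config):
        _, _, _, truth = simulate_cohorts(small_config)
        lfc = truth.true_logfc_per_grade
        assert len(truth.prognostic_mirna_ids) == small_config.n_prognostic
        np.testing.assert_allclose(lfc["logfc_III"], lfc["logfc_IV"])
        np.testing.assert_allclose(np.abs(lfc["logfc_III"]), small_config.effect_logfc)

    def test_null_configuration_detects_at_nominal_rate(self):
        cfg = SimulationConfig(seed=21, n_mirna=500, n_prognostic=0, effect_logfc=0.0)
        seq, arr, ann, _ = simulate_cohorts(cfg)
        for matrix in (seq, arr):
            rate = (differential_expression(matrix, ann)["p"] < 0.05).mean()
            assert 0.02 <= rate <= 0.08


class TestStageAndTumor:
    def test_stage_replicate_geometry(self, small_config):
        stages = simulate_stage_profiles(small_config)
        assert stages.n_replicates == small_config.n_stage_reps
        assert len(stages.feature_ids) == small_config.n_mirna

    def test_zero_noise_replicates_identical(self):
        cfg = SimulationConfig(seed=1, stage_rep_sd=0.0)
        stages = simulate_stage_profiles(cfg)
        for stage, df in stages.replicates.items():
            assert (df.nunique(axis=1) == 1).all()

    def test_mixture_weights_are_convex(self, small_config):
        stages = simulate_stage_profiles(small_config)
        _, _, truth = simulate_tumor_profiles(small_config, stages)
        w = truth.stage_mixture_weights.to_numpy()
        assert np.all(w >= 0)
        np.testing.assert_allclose(w.sum(axis=1), 1.0, atol=1e-9)

    def test_pure_op1_tumor_without_noise_has_unit_similarity(self):
        cfg = SimulationConfig(seed=2, intensity_sd=0.0, tumor_distortion_max=0.0)
        stages = simulate_stage_profiles(cfg)
        weights = pd.DataFrame(
            [[0, 0, 0, 0, 1.0, 0, 0, 0]], index=["T1"],
            columns=list(stages.stage_order),
        )
        _, _, truth = simulate_tumor_profiles(cfg, stages, weights=weights)
        assert truth.op1_similarity["T1"] == pytest.approx(1.0)

    def test_censoring_fraction_near_config(self):
        cfg = SimulationConfig(seed=13, n_tumors=1000)
        stages = simulate_stage_profiles(cfg)
        _, surv, _ = simulate_tumor_profiles(cfg, stages)
        frac = (~surv["event"]).mean()
        assert abs(frac - cfg.censor_rate) < 0.1
        assert (surv["time"] > 0).all()


class TestTargetsAndControls:
    def test_zero_overlap_yields_empty_target_set(self, small_config):
        cfg = SimulationConfig(**{**small_config.to_dict(), "target_overlap": 0.0})
        genes = [f"G{i}" for i in range(50)]
        tabs = simulate_target_databases(cfg, genes)
        mirnas = sorted({m for t in tabs for m, _ in t.pairs})
        assert intersect_targets(mirnas, genes, tabs).empty

    def test_full_overlap_keeps_every_pair(self, small_config):
        cfg = SimulationConfig(**{**small_config.to_dict(), "target_overlap": 1.0})
        genes = [f"G{i}" for i in range(50)]
        tabs = simulate_target_databases(cfg, genes)
        universe = set().union(*(t.pairs for t in tabs))
        mirnas = sorted({m for m, _ in universe})
        res = intersect_targets(mirnas, genes, tabs)
        assert len(res) == len(universe)

    def test_control_contrasts_have_labelled_feature_subsets(self, small_config):
        controls = simulate_control_contrasts(small_config)
        assert set(controls) == {"ESC_to_HP", "NSC_to_NP"}
        for fc in controls.values():
            assert len(fc) == min(small_config.n_control_features, small_config.n_mirna)
            assert fc.index.is_unique


class TestMrnaCohorts:
    def test_planted_gene_pool_is_recoverable(self, small_config):
        seq, arr, ann, truth = simulate_mrna_cohorts(small_config)
        comb = combine_grades(
            differential_expression(seq, ann), differential_expression(arr, ann)
        )
        from gliomir import select_de_mrnas

        pool = set(select_de_mrnas(comb))
        planted = set(truth.de_gene_ids)
        recall = len(pool & planted) / len(planted)
        assert recall >= 0.7
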