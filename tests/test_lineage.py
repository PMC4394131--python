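"""Stage-transition fold changes, Spearman scoring, tumor-stage similarity."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from gliomir import (
    ExpressionMatrix,
    STAGE_ORDER,
    SimulationConfig,
    StageProfileSet,
    ValidationError,
    control_lineage_correlation,
    correlate_transition_with_contrast,
    simulate_stage_profiles,
    simulate_tumor_profiles,
    spearman,
    transition_foldchanges,
    tumor_stage_correlations,
)


def _stage_set(means: pd.DataFrame, noise_sd=0.0, n_reps=3, seed=0):
    """StageProfileSet from a features x stages mean table."""
    rng = np.random.default_rng(seed)
    reps = {}
    for stage in STAGE_ORDER:
        noise = (
            rng.normal(0, noise_sd, (len(means), n_reps))
            if noise_sd
            else np.zeros((len(means), n_reps))
        )
        reps[stage] = pd.DataFrame(
            means[stage].to_numpy()[:, None] + noise,
            index=means.index,
            columns=[f"{stage}.{k}" for k in range(n_reps)],
        )
    return StageProfileSet(replicates=reps)


class TestSpearman:
    def test_identity_is_one(self):
        rho, _ = spearman([1.0, 4.0, 2.0, 8.0], [1.0, 4.0, 2.0, 8.0])
        assert rho == pytest.approx(1.0)

    def test_hand_rank_example(self):
        # ranks differ by d = (2, -1, -1), sum d^2 = 6 -> rho = -0.5
        rho, p = spearman([1, 2, 3], [3, 1, 2])
        assert rho == pytest.approx(-0.5)
        # exact enumeration of 3! permutations: every |rho| >= 0.5
        assert p == pytest.approx(1.0)

    def test_exact_p_matches_enumeration_probability(self):
        # perfectly concordant n=4: only 1 of 24 permutations reaches rho=1,
        # one more reaches -1, so two-sided exact p = 2/24
        rho, p = spearman([1, 2, 3, 4], [10, 20, 30, 40])
        assert rho == pytest.approx(1.0)
        assert p == pytest.approx(2 / 24)

    def test_large_n_uses_t_approximation(self):
        rng = np.random.default_rng(0)
        x, y = rng.normal(size=40), rng.normal(size=40)
        rho, p = spearman(x, y)
        ref = stats.spearmanr(x, y)
        assert rho == pytest.approx(ref.statistic)
        assert p == pytest.approx(ref.pvalue)

    def test_constant_vector_is_undefined(self):
        rho, p = spearman([1, 1, 1, 1], [1, 2, 3, 4])
        assert math.isnan(rho) and math.isnan(p)

    def test_too_short_errors(self):
        with pytest.raises(ValidationError):
            spearman([1, 2], [3, 4])

    @given(st.lists(st.integers(-1000, 1000), min_size=5, max_size=20, unique=True))
    def test_monotone_transform_invariance(self, x):
        rng = np.random.default_rng(7)
        y = rng.normal(size=len(x))
        x = np.asarray(x, dtype=float)
        rho1, _ = spearman(x, y)
        rho2, _ = spearman(x**3 + 5.0, y)  # strictly monotone transform
        assert rho1 == pytest.approx(rho2, abs=1e-12)


class TestTransitionFoldChanges:
    def _means(self, n=30):
        idx = pd.Index([f"f{i}" for i in range(n)], name="feature_id")
        return pd.DataFrame(7.0, index=idx, columns=list(STAGE_ORDER))

    def test_fold_and_significance_filter(self):
        means = self._means()
        means.loc["f0", "EB"] += 1.32  # 2.5-fold, should pass
        means.loc["f1", "EB"] += 0.58  # 1.5-fold, significant but below fold cut
        stages = _stage_set(means, noise_sd=0.05, seed=1)
        tfc = {t.label: t for t in transition_foldchanges(stages, min_passing=1)}["ESC->EB"]
        assert tfc.table.loc["f0", "passing"]
        assert tfc.table.loc["f0", "p"] < 0.05
        assert not tfc.table.loc["f1", "passing"]

    def test_omission_of_sparse_transitions(self):
        means = self._means()
        means.loc[["f0", "f1"], "EB"] += 2.0  # only 2 passing features
        stages = _stage_set(means, noise_sd=0.05, seed=2)
        tfc = {t.label: t for t in transition_foldchanges(stages, min_passing=5)}["ESC->EB"]
        assert int(tfc.table["passing"].sum()) == 2
        assert tfc.omitted

    def test_zero_replicate_noise_degenerates(self):
        stages = _stage_set(self._means(), noise_sd=0.0)
        for tfc in transition_foldchanges(stages):
            assert tfc.table["degenerate"].all()
            assert not tfc.table["passing"].any()

    def test_replicate_requirement(self):
        with pytest.raises(ValidationError):
            _stage_set(self._means(), n_reps=1)

    def test_zero_amplitude_passes_only_false_positives(self):
        cfg = SimulationConfig(seed=3, trajectory_amplitude=0.0)
        stages = simulate_stage_profiles(cfg)
        total = sum(int(t.table["passing"].sum()) for t in transition_foldchanges(stages))
        assert total <= 0.01 * cfg.n_mirna * 7

    def test_generated_markers_pass_their_transitions(self):
        # ~100 trajectory features at amplitude 2: at least half pass somewhere
        cfg = SimulationConfig(seed=4, markers_per_block=14, trajectory_amplitude=2.0)
        stages = simulate_stage_profiles(cfg)
        passing_any = set()
        for t in transition_foldchanges(stages):
            passing_any |= set(t.passing_features)
        assert len(passing_any) >= 50

    def test_deterministic_under_fixed_seed(self):
        cfg = SimulationConfig(seed=5)
        a = transition_foldchanges(simulate_stage_profiles(cfg))
        b = transition_foldchanges(simulate_stage_profiles(cfg))
        for ta, tb in zip(a, b):
            pd.testing.assert_frame_equal(ta.table, tb.table)


class TestTransitionCorrelation:
    def _tfc(self, n=20, seed=0):
        means = pd.DataFrame(
            7.0,
            index=pd.Index([f"f{i}" for i in range(n)], name="feature_id"),
            columns=list(STAGE_ORDER),
        )
        rng = np.random.default_rng(seed)
        means["EB"] += rng.choice([-2.0, 2.0], n) + rng.normal(0, 0.3, n)
        stages = _stage_set(means, noise_sd=0.05, seed=seed)
        return {t.label: t for t in transition_foldchanges(stages, min_passing=1)}["ESC->EB"]

    def test_identical_contrast_gives_unity(self):
        tfc = self._tfc()
        fc = tfc.table["logfc"]
        c = correlate_transition_with_contrast(tfc, fc, "self")
        assert c.rho == pytest.approx(1.0)
        c = correlate_transition_with_contrast(tfc, -fc, "anti")
        assert c.rho == pytest.approx(-1.0)

    def test_too_few_shared_features_errors(self):
        tfc = self._tfc()
        fc = tfc.table["logfc"].iloc[:2]
        with pytest.raises(ValidationError):
            correlate_transition_with_contrast(tfc, fc, "tiny")

    def test_control_consistency_with_transition(self):
        tfc = self._tfc()
        fc = tfc.table["logfc"]
        contrast = fc * 0.5 + 0.1
        via_transition = correlate_transition_with_contrast(tfc, contrast, "c")
        via_control = control_lineage_correlation(
            fc.loc[tfc.passing_features], contrast, "ctrl"
        )
        assert via_control.rho == pytest.approx(via_transition.rho)

    def test_control_precondition(self):
        fc = pd.Series([1.0, 2.0], index=["a", "b"])
        with pytest.raises(ValidationError):
            control_lineage_correlation(fc, fc, "ctrl")


class TestTumorStageCorrelations:
    def _stages(self, seed=0):
        rng = np.random.default_rng(seed)
        idx = pd.Index([f"f{i}" for i in range(40)], name="feature_id")
        means = pd.DataFrame(
            rng.normal(7, 1, (40, 8)), index=idx, columns=list(STAGE_ORDER)
        )
        return _stage_set(means, noise_sd=0.0)

    def test_pure_stage_profile_recovers_itself(self):
        stages = self._stages()
        op1 = stages.mean_profile["OP1"]
        tumors = ExpressionMatrix(op1.to_frame("T1"), "intensity")
        m = tumor_stage_correlations(tumors, stages, stages.feature_ids)
        assert m.rho.loc["T1", "OP1"] == pytest.approx(1.0)
        assert m.argmax_stage["T1"] == "OP1"

    def test_rank_reversal_gives_minus_one(self):
        stages = self._stages()
        ol = stages.mean_profile["OL"]
        reversed_profile = pd.Series(
            ol.sort_values().to_numpy()[::-1], index=ol.sort_values().index
        ).reindex(ol.index)
        tumors = ExpressionMatrix(reversed_profile.to_frame("T1"), "intensity")
        m = tumor_stage_correlations(tumors, stages, stages.feature_ids)
        assert m.rho.loc["T1", "OL"] == pytest.approx(-1.0)

    def test_feature_order_invariance(self):
        stages = self._stages()
        op1 = stages.mean_profile["OP1"]
        tumors = ExpressionMatrix(op1.to_frame("T1") + 0.3, "intensity")
        shared = list(stages.feature_ids)
        a = tumor_stage_correlations(tumors, stages, shared).rho
        b = tumor_stage_correlations(tumors, stages, shared[::-1]).rho
        np.testing.assert_allclose(a.to_numpy(), b.to_numpy())

    def test_missing_shared_feature_errors(self):
        stages = self._stages()
        tumors = ExpressionMatrix(
            stages.mean_profile["OP1"].iloc[:-2].to_frame("T1"), "intensity"
        )
        with pytest.raises(ValidationError):
            tumor_stage_correlations(tumors, stages, stages.feature_ids)

    def test_similarity_monotone_in_op1_weight(self):
        cfg = SimulationConfig(
            seed=6, intensity_sd=0.0, tumor_distortion_max=0.0, censor_rate=0.0
        )
        stages = simulate_stage_profiles(cfg)
        ws = np.linspace(0.05, 0.95, 10)
        weights = pd.DataFrame(
            [[(1 - w) / 7.0] * 8 for w in ws],
            index=[f"T{i}" for i in range(10)],
            columns=list(STAGE_ORDER),
        )
        weights["OP1"] = ws
        tumors, _, _ = simulate_tumor_profiles(cfg, stages, weights=weights)
        m = tumor_stage_correlations(tumors, stages, tumors.feature_ids)
        assert (np.diff(m.rho["OP1"].to_numpy()) > 0).all()

    def test_half_feature_stability(self, default_bundle):
        tumors, stages = default_bundle["tumors"], default_bundle["stages"]
        shared = tumors.feature_ids
        full = tumor_stage_correlations(tumors, stages, shared).rho
        rng = np.random.default_rng(8)
        half = shared[np.sort(rng.choice(len(shared), len(shared) // 2, replace=False))]
        sub = tumor_stage_correlations(tumors, stages, half).rho
        r = np.corrcoef(full.to_numpy().ravel(), sub.to_numpy().ravel())[0, 1]
        assert r > 0.9
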