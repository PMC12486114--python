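"""Outcome labelling: t-test rule, LMFP curves/AUCs, windows, RQS."""

import numpy as np
import pytest

from neuromodml import outcomes as oc
from neuromodml import synthetic as syn
from neuromodml.errors import DataError
from neuromodml.synthetic import MEPBlock, TEPBlock


def _tep(trials, time_ms=None, labels=None, block_id="pre"):
    trials = np.asarray(trials, dtype=float)
    if time_ms is None:
        time_ms = np.linspace(0.0, 400.0, trials.shape[2])
    if labels is None:
        labels = tuple(syn.LM_CHANNELS[:trials.shape[1]])
    return TEPBlock(block_id, trials, time_ms, labels)


class TestMEPLabel:
    def test_identical_blocks_are_non_responders(self):
        amps = np.linspace(0.5, 1.5, 20)
        lab = oc.mep_ttest_label(MEPBlock("pre", amps), MEPBlock("T5", amps))
        assert lab.label == 0
        assert lab.statistic == pytest.approx(1.0)

    def test_extreme_shift_is_responder(self, rng):
        pre = MEPBlock("pre", 1.0 + 0.1 * rng.random(120))
        post = MEPBlock("T5", 2.0 + 0.1 * rng.random(120))
        lab = oc.mep_ttest_label(pre, post)
        assert lab.label == 1 and lab.statistic < 1e-10

    def test_zero_variance_equal_blocks_give_p_one(self):
        pre = MEPBlock("pre", np.full(5, 2.0))
        post = MEPBlock("T5", np.full(5, 2.0))
        assert oc.mep_ttest_label(pre, post).label == 0

    def test_welch_option(self, rng):
        pre = MEPBlock("pre", 1.0 + 0.01 * rng.random(30))
        post = MEPBlock("T5", 1.0 + 2.0 * rng.random(30))
        p_pooled = oc.mep_ttest_label(pre, post).statistic
        p_welch = oc.mep_ttest_label(pre, post, equal_var=False).statistic
        assert p_pooled != p_welch


class TestLMFPCurve:
    def test_single_channel_constant_gives_absolute_value(self):
        trial = np.full((1, 50), -3.0)
        curve = oc.lmfp_curve(trial, ("C3",), roi_channels=("C3",))
        assert np.allclose(curve, 3.0)

    def test_homogeneous_scaling(self, rng):
        trial = rng.standard_normal((6, 80))
        c1 = oc.lmfp_curve(trial, syn.LM_CHANNELS)
        c2 = oc.lmfp_curve(2.5 * trial, syn.LM_CHANNELS)
        assert np.allclose(c2, 2.5 * c1)

    def test_antiphase_channels_rms(self):
        trial = np.vstack([np.full(10, 4.0), np.full(10, -4.0)])
        curve = oc.lmfp_curve(trial, ("C1", "C3"), roi_channels=("C1", "C3"))
        assert np.allclose(curve, 4.0)

    def test_missing_roi_channel_named(self):
        with pytest.raises(DataError, match="FC5"):
            oc.lmfp_curve(np.zeros((2, 10)), ("C1", "C3"),
                          roi_channels=("C1", "FC5"))


class TestSimpsonAUC:
    def test_exact_on_cubic_with_odd_samples(self):
        x = np.linspace(0.0, 10.0, 11)
        y = x ** 3 - 2 * x ** 2 + 5
        exact = 10 ** 4 / 4 - 2 * 10 ** 3 / 3 + 5 * 10
        assert oc.simpson_auc(y, x) == pytest.approx(exact, rel=1e-12)

    def test_unit_curve_over_30ms_window(self):
        t = np.linspace(0.0, 400.0, 401)
        auc = oc.lmfp_window_auc(np.ones_like(t), t, (100.0, 130.0))
        assert auc == pytest.approx(30.0)

    def test_convergence_under_grid_refinement(self):
        f = lambda x: np.exp(-x / 50.0) * np.sin(x / 10.0) + 2
        x1 = np.linspace(0.0, 100.0, 201)
        x2 = np.linspace(0.0, 100.0, 401)
        a1 = oc.simpson_auc(f(x1), x1)
        a2 = oc.simpson_auc(f(x2), x2)
        assert abs(a1 - a2) < 1e-6

    def test_two_samples_fall_back_to_trapezoid(self):
        with pytest.warns(UserWarning):
            auc = oc.simpson_auc(np.array([1.0, 3.0]), np.array([0.0, 2.0]))
        assert auc == pytest.approx(4.0)

    def test_even_sample_count_near_odd_result(self):
        x = np.linspace(0.0, 10.0, 100)
        y = np.sin(x)
        assert oc.simpson_auc(y, x) == pytest.approx(1 - np.cos(10.0), abs=1e-4)


class TestLMFPRatioLabel:
    def test_identical_blocks_ratio_one_is_facilitation(self, rng):
        trials = rng.standard_normal((3, 6, 120)) + 5.0
        pre = _tep(trials)
        post = _tep(trials.copy(), block_id="T5")
        lab = oc.lmfp_ratio_label(pre, post, (25.0, 55.0))
        assert lab.statistic == pytest.approx(1.0)
        assert lab.label == 1  # boundary is inclusive

    def test_half_gain_is_suppression(self, rng):
        trials = rng.standard_normal((3, 6, 120)) + 5.0
        lab = oc.lmfp_ratio_label(_tep(trials), _tep(0.5 * trials, block_id="T5"),
                                  (25.0, 55.0))
        assert lab.statistic == pytest.approx(0.5)
        assert lab.label == 0

    def test_degenerate_pre_block_rejected(self):
        zeros = np.zeros((2, 6, 120))
        with pytest.raises(DataError):
            oc.lmfp_ratio_label(_tep(zeros), _tep(zeros, block_id="T5"),
                                (25.0, 55.0))


class TestWindowSet:
    def test_default_list_has_43_windows(self):
        windows = oc.default_window_set()
        assert len(windows) == 43
        sweep = windows[4:]
        assert all(hi - lo == pytest.approx(30.0, abs=0.11) for lo, hi in sweep)
        assert all(lo >= 25.0 and hi <= 345.0 for lo, hi in sweep)

    def test_a_priori_only(self):
        assert len(oc.default_window_set(n_sweep=0)) == 4

    def test_duplicates_dropped_with_warning(self):
        with pytest.warns(UserWarning):
            windows = oc.default_window_set(
                a_priori=((15.0, 45.0), (15.0, 45.0)), n_sweep=0)
        assert windows == [(15.0, 45.0)]

    def test_method_counts(self):
        assert len(oc.make_methods("MEP")) == 2
        assert len(oc.make_methods("LMFP")) == 43


class TestBaselineFeatures:
    @pytest.fixture()
    def session(self):
        spec = syn.small_spec(cohort1_counts=(1, 0, 0), cohort2_counts=(0, 0, 0),
                              seed=4)
        return syn.generate_cohorts(spec)[0]

    def test_mep_experiment_has_four_features(self, session):
        feats = oc.baseline_tms_features(session, "MEP")
        assert set(feats) == {"pre_mep_mean", "pre_mep_sd",
                              "pre_lmfp_auc_15_80", "pre_rqs"}

    def test_lmfp_experiment_has_two_features(self, session):
        feats = oc.baseline_tms_features(session, "LMFP")
        assert set(feats) == {"pre_lmfp_auc_15_80", "pre_rqs"}

    def test_constant_mep_block_statistics(self, session):
        session.mep_blocks["pre"] = MEPBlock("pre", np.full(10, 1.5))
        feats = oc.baseline_tms_features(session, "MEP")
        assert feats["pre_mep_mean"] == pytest.approx(1.5)
        assert feats["pre_mep_sd"] == pytest.approx(0.0)

    def test_noise_free_auc_matches_direct_integration(self):
        spec = syn.small_spec(seed=4)
        blk = syn.generate_tep_block(spec, "pre", 1.0, 0, n_trials=3, noise=0.0)
        _, template = syn.tep_template(spec)
        curve = oc.lmfp_curve(template, spec.channels)
        want = oc.lmfp_window_auc(curve, blk.time_ms, (15.0, 80.0))
        got = oc.block_mean_window_auc(blk, (15.0, 80.0))
        assert got == pytest.approx(want, rel=1e-12)


class TestRQS:
    def test_identical_trials_score_one(self, rng):
        wave = rng.standard_normal(120)
        trials = np.tile(wave, (5, 6, 1))
        blk = _tep(trials)
        assert oc.tep_rqs(blk) == pytest.approx(1.0)

    def test_pure_noise_scores_near_zero(self, rng):
        scores = []
        for _ in range(20):
            trials = rng.standard_normal((100, 6, 120))
            scores.append(oc.tep_rqs(_tep(trials)))
        assert np.mean(scores) < 0.1

    def test_invariant_to_trial_order(self, rng):
        trials = rng.standard_normal((10, 6, 120)) + np.sin(
            np.linspace(0, 6, 120))
        blk = _tep(trials)
        perm = _tep(trials[::-1])
        assert oc.tep_rqs(blk) == pytest.approx(oc.tep_rqs(perm))


class TestGroundTruthRecovery:
    def test_labels_recover_injected_gains_at_low_noise(self):
        spec = syn.small_spec(cohort1_counts=(4, 0, 0), cohort2_counts=(0, 0, 0),
                              seed=11, tep_noise=0.05)
        sessions = syn.generate_cohorts(spec)
        methods = oc.make_methods("LMFP", windows=[(15.0, 80.0), (100.0, 131.0)])
        for s in sessions:
            truth = s.ground_truth["LMFP_T5"]
            for lab in oc.derive_labels(s, methods):
                assert lab.label == truth
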