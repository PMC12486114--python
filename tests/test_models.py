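"""Model search: transforms, registry, metrics, CV, selection, validation."""

import numpy as np
import pandas as pd
import pytest

from neuromodml import models as md
from neuromodml.complexity import default_battery
from neuromodml.errors import ConfigurationError, DataError


@pytest.fixture()
def toy_features(rng):
    n = 100
    y = np.repeat([0, 1], n // 2)
    x = pd.DataFrame({
        "f_signal": y * 2.0 + 0.3 * rng.standard_normal(n) + 1.0,
        "f_noise": rng.standard_normal(n) + 5.0,
    })
    return x, y


class TestTransforms:
    def test_zscore_training_set_standardized(self, rng):
        train = pd.DataFrame(rng.standard_normal((50, 3)) * 4 + 2,
                             columns=list("abc"))
        tr, _ = md.transform_zscore(train, train)
        assert np.allclose(tr.mean(), 0, atol=1e-12)
        assert np.allclose(tr.std(ddof=0), 1, atol=1e-12)

    def test_zscore_heldout_uses_training_stats(self, rng):
        train = pd.DataFrame({"a": rng.standard_normal(40) + 3})
        apply = pd.DataFrame({"a": [train["a"].mean()]})
        _, ap = md.transform_zscore(train, apply)
        assert ap.iloc[0, 0] == pytest.approx(0.0)

    def test_zscore_drops_constant_feature(self, rng):
        train = pd.DataFrame({"a": np.ones(10), "b": rng.standard_normal(10)})
        with pytest.warns(UserWarning):
            tr, ap = md.transform_zscore(train, train)
        assert list(tr.columns) == ["b"]

    def test_log_distance_formula(self):
        train = pd.DataFrame({"a": [1.0, 10.0, 100.0]})
        tr, ap = md.transform_log_distance(train, pd.DataFrame({"a": [100.0]}))
        assert tr["a"].iloc[1] == pytest.approx(0.0)   # the median itself
        assert ap["a"].iloc[0] == pytest.approx(1.0)   # 10 x median
        assert tr["a"].is_monotonic_increasing

    def test_log_distance_rejects_nonpositive_naming_feature(self):
        train = pd.DataFrame({"bad_feature": [1.0, -1.0]})
        with pytest.raises(DataError, match="bad_feature"):
            md.transform_log_distance(train, train)


class TestEnumeration:
    def test_universe_size_is_94(self):
        bands = ["delta", "theta", "alpha", "beta"]
        measures = [m.name for m in default_battery()]
        assert len(md.feature_set_universe(bands, measures)) == 4 + 18 + 72

    def test_single_registry_gives_universe_count(self):
        fs = md.feature_set_universe(list("abcd"), [f"m{i}" for i in range(18)])
        specs = md.enumerate_models(["dt"], ["LM"], ["zscore"], ["M1"], fs)
        assert len(specs) == 94

    def test_empty_registry_rejected(self):
        with pytest.raises(ConfigurationError):
            md.enumerate_models([], ["LM"], ["zscore"], ["M1"], [("band", "a")])

    def test_roi_filters_channels(self):
        cols = [f"pow_alpha_{ch}" for ch in ("C1", "C3", "Cz", "Pz")]
        group = md.FeatureGroup("LM", "zscore", ("band", "alpha"))
        assert set(group.columns(cols)) == {"pow_alpha_C1", "pow_alpha_C3"}
        whole = md.FeatureGroup("whole_scalp", "zscore", ("band", "alpha"))
        assert set(whole.columns(cols)) == set(cols)


class TestRegistry:
    def test_exactly_nine_classifiers(self):
        reg = md.classifier_registry()
        assert len(reg) == 9

    def test_fixed_priors_dominate_uninformative_features(self, rng):
        reg = md.classifier_registry()
        # label-independent noise: the likelihood carries ~no information
        x = 1e-3 * rng.standard_normal((400, 2))
        y = np.tile([0, 1], 200)
        clf = reg["gnb_prior8020"](0)
        clf.fit(x, y)
        pred = clf.predict(1e-3 * rng.standard_normal((50, 2)))
        assert (pred == 1).mean() > 0.9

    def test_decision_tree_separates_toy_data(self, rng):
        reg = md.classifier_registry()
        x = np.vstack([rng.normal(-2, 0.1, (20, 2)), rng.normal(2, 0.1, (20, 2))])
        y = np.repeat([0, 1], 20)
        clf = reg["dt"](0)
        clf.fit(x, y)
        assert (clf.predict(x) == y).all()

    def test_all_classifiers_fit_and_score(self, toy_features):
        x, y = toy_features
        reg = md.classifier_registry()
        for cid, factory in reg.items():
            clf = factory(0)
            clf.fit(x.to_numpy(), y)
            scores = md.decision_scores(clf, x.to_numpy())
            assert scores.shape == (len(y),)
            assert (clf.predict(x.to_numpy()) == y).mean() > 0.8, cid


class TestMetrics:
    def test_perfect_confusion(self):
        y = np.array([1] * 5 + [0] * 5)
        m = md.metric_set(y, y, y.astype(float))
        assert m["accuracy"] == 1 and m["f1"] == 1 and m["precision"] == 1
        assert m["roc_auc"] == 1.0

    def test_printed_formula_example(self):
        # TP=3, FP=1, FN=1, TN=5
        y_true = np.array([1, 1, 1, 1, 0, 0, 0, 0, 0, 0])
        y_pred = np.array([1, 1, 1, 0, 1, 0, 0, 0, 0, 0])
        m = md.metric_set(y_true, y_pred)
        assert m["precision"] == pytest.approx(0.75)
        assert m["sensitivity"] == pytest.approx(0.75)
        assert m["f1"] == pytest.approx(0.75)
        assert m["specificity"] == pytest.approx(5 / 6)
        assert m["accuracy"] == pytest.approx(0.8)

    def test_no_positive_predictions_flagged_missing(self):
        y_true = np.array([1, 0, 1, 0])
        y_pred = np.zeros(4, dtype=int)
        m = md.metric_set(y_true, y_pred)
        assert np.isnan(m["precision"])
        assert m["sensitivity"] == 0.0


class TestCVEvaluate:
    def test_fifty_folds_and_ceiling_case(self, toy_features):
        x, y = toy_features
        reg = md.classifier_registry()
        x2 = x.copy()
        x2["f_signal"] = y * 10.0 + 0.01 * np.arange(len(y))
        res = md.cv_evaluate(reg["lda_lw"], x2, y, "zscore", seed=0)
        assert len(res.folds) == 50
        assert res.mean["accuracy"] == pytest.approx(1.0)
        assert res.ci_halfwidth["accuracy"] == pytest.approx(0.0)

    def test_permuted_labels_give_chance_auc(self, toy_features):
        x, y = toy_features
        reg = md.classifier_registry()
        aucs = []
        for s in range(10):
            yp = np.random.default_rng(s).permutation(y)
            res = md.cv_evaluate(reg["lda_lw"], x, yp, "zscore", seed=s,
                                 n_repeats=1)
            aucs.append(res.mean["roc_auc"])
        assert 0.4 <= np.mean(aucs) <= 0.6

    def test_tiny_class_is_skipped(self, rng):
        x = pd.DataFrame({"a": rng.standard_normal(12)})
        y = np.array([1] * 3 + [0] * 9)
        reg = md.classifier_registry()
        with pytest.raises(md.ModelSkipped):
            md.cv_evaluate(reg["dt"], x, y, "zscore", seed=0)


def _fake_result(sens, spec_, auc):
    folds = pd.DataFrame([{**{m: 0.5 for m in md.METRIC_NAMES},
                           "sensitivity": sens, "specificity": spec_,
                           "roc_auc": auc}] * 3)
    return md.CVResult(folds[list(md.METRIC_NAMES)])


def _spec(cid="dt", method="M1"):
    return md.ModelSpec(cid, md.FeatureGroup("LM", "zscore", ("band", "alpha")),
                        method)


class TestSelection:
    def test_admissibility_beats_raw_auc(self):
        a = (_spec("a"), _fake_result(0.9, 0.5, 0.95))
        b = (_spec("b"), _fake_result(0.7, 0.7, 0.80))
        spec, res = md.select_model([a, b])
        assert spec.classifier_id == "b"

    def test_single_admissible_model_wins(self):
        a = (_spec("a"), _fake_result(0.8, 0.8, 0.7))
        assert md.select_model([a])[0].classifier_id == "a"

    def test_tie_broken_lexicographically(self):
        a = (_spec("zzz"), _fake_result(0.8, 0.8, 0.7))
        b = (_spec("aaa"), _fake_result(0.8, 0.8, 0.7))
        assert md.select_model([a, b])[0].classifier_id == "aaa"

    def test_no_admissible_model_returns_none(self):
        a = (_spec("a"), _fake_result(0.5, 0.5, 0.99))
        assert md.select_model([a]) is None


class TestExternalValidation:
    def test_bootstrap_preserves_class_counts_exactly(self, rng):
        y = np.array([1] * 7 + [0] * 13)
        for _ in range(20):
            idx = md.stratified_bootstrap_indices(y, rng)
            assert (y[idx] == 1).sum() == 7
            assert (y[idx] == 0).sum() == 13

    def test_memorizing_classifier_on_identical_sets(self, toy_features):
        x, y = toy_features
        reg = md.classifier_registry()
        res = md.external_validate(reg["dt"], "zscore", x, y, x, y, seed=0,
                                   n_boot=100)
        assert res.point["accuracy"] == 1.0

    def test_percentile_ci_contains_point(self, toy_features, rng):
        x, y = toy_features
        x_noisy = x.copy()
        x_noisy["f_signal"] += 2.0 * rng.standard_normal(len(y))
        reg = md.classifier_registry()
        res = md.external_validate(reg["gnb_empirical"], "zscore",
                                   x, y, x_noisy, y, seed=0, n_boot=500)
        for m in md.METRIC_NAMES:
            assert res.ci_low[m] - 1e-9 <= res.point[m] <= res.ci_high[m] + 1e-9

    def test_validation_shift_does_not_leak_into_training_transform(
            self, toy_features):
        x, y = toy_features
        shifted = x + 1000.0
        tr1, _ = md.transform_zscore(x, x)
        tr2, _ = md.transform_zscore(x, shifted)
        assert tr1.equals(tr2)


class TestGiniImportance:
    def test_single_split_tree(self, rng):
        from sklearn.tree import DecisionTreeClassifier
        x = np.column_stack([np.repeat([0.0, 1.0], 20),
                             rng.standard_normal(40)])
        y = np.repeat([0, 1], 20)
        tree = DecisionTreeClassifier(random_state=0).fit(x, y)
        imp = md.gini_importance(tree)
        assert imp[0] == pytest.approx(1.0)
        assert imp[1] == 0.0

    def test_importances_normalized_and_label_feature_dominates(self, rng):
        from sklearn.tree import DecisionTreeClassifier
        top = 0
        for s in range(20):
            r = np.random.default_rng(s)
            y = r.integers(0, 2, 80)
            x = np.column_stack([y + 0.1 * r.standard_normal(80),
                                 r.standard_normal((80, 3))])
            tree = DecisionTreeClassifier(random_state=0).fit(x, y)
            imp = md.gini_importance(tree)
            assert imp.sum() == pytest.approx(1.0)
            if imp.argmax() == 0:
                top += 1
        assert top >= 18

    def test_non_tree_rejected(self, toy_features):
        x, y = toy_features
        reg = md.classifier_registry()
        clf = reg["gnb_empirical"](0)
        clf.fit(x.to_numpy(), y)
        with pytest.raises(TypeError):
            md.gini_importance(clf)


class TestRunExperiment:
    def _table(self, rng, n_participants=24):
        rows = []
        for pid in range(n_participants):
            trait = pid % 2
            for visit in ("initial", "retest"):
                rows.append({
                    "session_id": f"c1_p{pid:02d}_{visit}",
                    "participant": f"p{pid:02d}",
                    "cohort": 1 if pid < n_participants // 2 else 2,
                    "visit": visit,
                    "pow_alpha_C3": trait * 3.0 + rng.standard_normal() + 10.0,
                    "pow_alpha_C1": trait * 3.0 + rng.standard_normal() + 10.0,
                    "pre_rqs": 0.5 + 0.1 * rng.random(),
                    "label": trait,
                })
        df = pd.DataFrame(rows).set_index("session_id")
        labels = df[["label"]].rename(columns={"label": "M1"})
        return df.drop(columns="label"), labels

    def test_cross_session_recovers_stable_signal(self, rng):
        features, labels = self._table(rng)
        cfg = {"classifiers": ["lda_lw"], "rois": ["LM"],
               "transforms": ["zscore"], "methods": ["M1"],
               "feature_sets": [("band", "alpha")], "n_repeats": 2,
               "n_boot": 100}
        rep = md.run_experiment("cross_session", features, labels, cfg, seed=0)
        assert rep.selected is not None
        assert rep.validation.point["accuracy"] > 0.9
        assert rep.n_train == rep.n_val == 24

    def test_cross_cohort_appends_visit_type(self, rng):
        features, labels = self._table(rng)
        cfg = {"classifiers": ["dt"], "rois": ["LM"], "transforms": ["zscore"],
               "methods": ["M1"], "feature_sets": [("band", "alpha")],
               "n_repeats": 1, "n_boot": 50}
        rep = md.run_experiment("cross_cohort", features, labels, cfg, seed=0)
        assert rep.selected is not None
        assert rep.n_train == 24 and rep.n_val == 24

    def test_deterministic_given_seed(self, rng):
        features, labels = self._table(rng)
        cfg = {"classifiers": ["gnb_empirical"], "rois": ["LM"],
               "transforms": ["log_distance"], "methods": ["M1"],
               "feature_sets": [("band", "alpha")], "n_repeats": 2,
               "n_boot": 100}
        r1 = md.run_experiment("cross_session", features, labels, cfg, seed=3)
        r2 = md.run_experiment("cross_session", features, labels, cfg, seed=3)
        assert r1.leaderboard.equals(r2.leaderboard)
        assert r1.validation.point.equals(r2.validation.point)

    def test_unknown_classifier_rejected(self, rng):
        features, labels = self._table(rng)
        cfg = {"classifiers": ["svm"], "methods": ["M1"],
               "feature_sets": [("band", "alpha")]}
        with pytest.raises(ConfigurationError):
            md.run_experiment("cross_session", features, labels, cfg, seed=0)
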