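"""Exhaustive model search: feature groups x classifiers x categorization
methods, evaluated by repeated stratified cross-validation and validated
externally with stratified bootstrap confidence intervals.

Feature groups combine a region of interest (left motor, central, whole
scalp), a normalization (z-score or log-distance-to-median, both fit on
training data only) and a feature set drawn from a universe of 4 band
powers + 18 complexity measures + 4x18 (band, complexity) pairs = 94 sets;
the pre-stimulation TMS features are appended to every group, and the
cross-cohort design additionally appends a visit-type indicator.

Nine classifier types are enumerated; models with cross-validated mean
sensitivity or specificity below 0.60 are excluded, and among the rest the
highest mean ROC-AUC wins (lexicographic model-id tie-break).  The winner
is refit on the full training set and measured on the external set with
percentile 95% confidence intervals from 2000 class-stratified bootstrap
resamples.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.covariance import OAS
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import average_precision_score, pairwise_distances, roc_auc_score
from sklearn.model_selection import GridSearchCV, StratifiedKFold
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import NearestCentroid
from sklearn.tree import DecisionTreeClassifier

from neuromodml.errors import ConfigurationError, DataError, NeuromodError
from neuromodml.synthetic import CENTRAL_CHANNELS, LM_CHANNELS

METRIC_NAMES = ("accuracy", "sensitivity", "specificity", "f1",
                "roc_auc", "pr_auc", "precision")

ROIS = {
    "LM": tuple(LM_CHANNELS),
    "central": tuple(CENTRAL_CHANNELS),
    "whole_scalp": None,  # all channels present in the feature table
}

TRANSFORMS = ("zscore", "log_distance")


class ModelSkipped(NeuromodError):
    """Raised when a model cannot be evaluated (class too small, no features)."""


# ---------------------------------------------------------------------------
# Normalization (always fit on training data only)
# ---------------------------------------------------------------------------

def transform_zscore(train: pd.DataFrame, apply: pd.DataFrame) -> tuple:
    """(x - mean_train) / sd_train; zero-variance features are dropped."""
    mu = train.mean(axis=0)
    sd = train.std(axis=0, ddof=0)
    keep = sd > 0
    if not keep.all():
        warnings.warn(f"dropping constant features: {list(sd.index[~keep])}",
                      stacklevel=2)
    cols = sd.index[keep]
    return ((train[cols] - mu[cols]) / sd[cols],
            (apply[cols] - mu[cols]) / sd[cols])


def transform_log_distance(train: pd.DataFrame, apply: pd.DataFrame) -> tuple:
    """log10(x) - log10(median_train); requires strictly positive values."""
    for df, which in ((train, "training"), (apply, "apply")):
        bad = df.columns[(df <= 0).any(axis=0)]
        if len(bad):
            raise DataError(
                f"log-distance transform needs positive values; offending "
                f"{which} features: {list(bad)}")
    med = train.median(axis=0)
    return np.log10(train) - np.log10(med), np.log10(apply) - np.log10(med)


def apply_transform(name: str, train: pd.DataFrame, apply: pd.DataFrame) -> tuple:
    if name == "zscore":
        return transform_zscore(train, apply)
    if name == "log_distance":
        return transform_log_distance(train, apply)
    raise ConfigurationError(f"unknown transform {name!r}")


#: Binary indicator columns are appended to feature groups untransformed.
PASSTHROUGH_COLUMNS = ("visit_type",)


def transform_features(name: str, train: pd.DataFrame, apply: pd.DataFrame) -> tuple:
    """Apply a normalization, passing indicator columns through unchanged."""
    pt = [c for c in train.columns if c in PASSTHROUGH_COLUMNS]
    tr, ap = apply_transform(name, train.drop(columns=pt), apply.drop(columns=pt))
    if pt:
        tr = pd.concat([tr, train[pt]], axis=1)
        ap = pd.concat([ap, apply[pt]], axis=1)
    return tr, ap


# ---------------------------------------------------------------------------
# Feature groups
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FeatureGroup:
    """ROI x transform x feature-set selection over a feature table."""

    roi: str
    transform: str
    feature_set: tuple  # ('band', name) | ('complexity', name) | ('pair', b, c)

    @property
    def group_id(self) -> str:
        return f"{self.roi}|{self.transform}|{'+'.join(self.feature_set)}"

    def _prefixes(self) -> list:
        kind = self.feature_set[0]
        if kind == "band":
            return [f"pow_{self.feature_set[1]}_"]
        if kind == "complexity":
            return [f"cx_{self.feature_set[1]}_"]
        if kind == "pair":
            return [f"pow_{self.feature_set[1]}_", f"cx_{self.feature_set[2]}_"]
        raise ConfigurationError(f"unknown feature-set kind {kind!r}")

    def columns(self, all_columns) -> list:
        roi_channels = ROIS[self.roi]
        cols = []
        for prefix in self._prefixes():
            for c in all_columns:
                if not c.startswith(prefix):
                    continue
                ch = c.rsplit("_", 1)[1]
                if roi_channels is None or ch in roi_channels:
                    cols.append(c)
        if not cols:
            raise ModelSkipped(f"no feature columns for group {self.group_id}")
        return cols


def feature_set_universe(bands, measures) -> list:
    """4 + 18 + 4x18 feature sets with the default registries."""
    sets = [("band", b) for b in bands]
    sets += [("complexity", m) for m in measures]
    sets += [("pair", b, m) for b in bands for m in measures]
    return sets


@dataclass(frozen=True)
class ModelSpec:
    classifier_id: str
    group: FeatureGroup
    method_id: str

    @property
    def model_id(self) -> str:
        return f"{self.classifier_id}|{self.group.group_id}|{self.method_id}"


def enumerate_models(classifiers, rois, transforms, methods, feature_sets) -> list:
    """Full Cartesian product of the registries."""
    if not (classifiers and rois and transforms and methods and feature_sets):
        raise ConfigurationError("empty registry in model enumeration")
    return [
        ModelSpec(c, FeatureGroup(r, t, tuple(fs)), m)
        for c, r, t, m, fs in itertools.product(
            classifiers, rois, transforms, methods, feature_sets)
    ]


# ---------------------------------------------------------------------------
# Classifier registry
# ---------------------------------------------------------------------------

class _InnerCVClassifier(BaseEstimator, ClassifierMixin):
    """Grid search over one hyperparameter with inner stratified CV.

    The number of inner folds adapts down to the smallest class count so
    small outer training folds remain fittable.
    """

    def __init__(self, base, grid, inner_cv=5, seed=0, scoring="roc_auc"):
        self.base = base
        self.grid = grid
        self.inner_cv = inner_cv
        self.seed = seed
        self.scoring = scoring

    def fit(self, X, y):
        y = np.asarray(y)
        k = min(self.inner_cv, int(np.bincount(y.astype(int)).min()))
        if k >= 2:
            gs = GridSearchCV(
                clone(self.base), self.grid,
                cv=StratifiedKFold(k, shuffle=True, random_state=self.seed),
                scoring=self.scoring, n_jobs=1)
            gs.fit(X, y)
            self.est_ = gs.best_estimator_
        else:
            self.est_ = clone(self.base).fit(X, y)
        self.classes_ = self.est_.classes_
        return self

    def predict(self, X):
        return self.est_.predict(X)

    def predict_proba(self, X):
        return self.est_.predict_proba(X)

    def decision_function(self, X):
        return self.est_.decision_function(X)


class _ScoredNearestCentroid(NearestCentroid):
    """Nearest (shrunken) centroid with a continuous decision score:
    distance to the negative centroid minus distance to the positive one."""

    def decision_function(self, X):
        d = pairwise_distances(np.asarray(X), self.centroids_, metric=self.metric)
        neg = list(self.classes_).index(self.classes_.min())
        pos = list(self.classes_).index(self.classes_.max())
        return d[:, neg] - d[:, pos]


def classifier_registry(inner_cv: int = 5, logreg_penalty: str = "l2",
                        nsc_shrink_threshold=None,
                        gnb_positive_prior: float = 0.8) -> dict:
    """The nine classifier contracts: id -> factory(seed) -> estimator.

    Ids sort lexicographically; that order is the selection tie-break.
    """
    c_grid = {"C": np.logspace(-3, 3, 7)}
    shrink_grid = {"shrinkage": np.linspace(0.0, 1.0, 11)}
    solver = "liblinear" if logreg_penalty == "l1" else "lbfgs"

    return {
        "dt": lambda seed: DecisionTreeClassifier(
            criterion="gini", random_state=seed),
        "gnb_empirical": lambda seed: GaussianNB(),
        "gnb_prior8020": lambda seed: GaussianNB(
            priors=[1.0 - gnb_positive_prior, gnb_positive_prior]),
        "lda_cv": lambda seed: _InnerCVClassifier(
            LinearDiscriminantAnalysis(solver="lsqr"), shrink_grid,
            inner_cv, seed),
        "lda_lw": lambda seed: LinearDiscriminantAnalysis(
            solver="lsqr", shrinkage="auto"),
        "lda_oas": lambda seed: LinearDiscriminantAnalysis(
            solver="lsqr", covariance_estimator=OAS()),
        "logreg_cv": lambda seed: _InnerCVClassifier(
            LogisticRegression(penalty=logreg_penalty, solver=solver,
                               max_iter=2000), c_grid, inner_cv, seed),
        "nsc_euclidean": lambda seed: _ScoredNearestCentroid(
            metric="euclidean", shrink_threshold=nsc_shrink_threshold),
        "nsc_manhattan": lambda seed: _ScoredNearestCentroid(
            metric="manhattan", shrink_threshold=nsc_shrink_threshold),
    }


def decision_scores(est, X) -> np.ndarray:
    """Continuous score for the positive class."""
    if hasattr(est, "predict_proba"):
        try:
            proba = est.predict_proba(X)
            pos = list(est.classes_).index(1)
            return proba[:, pos]
        except AttributeError:
            pass
    return np.asarray(est.decision_function(X), dtype=float)


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------

def metric_set(y_true, y_pred, scores=None) -> dict:
    """The seven evaluation metrics; undefined entries are NaN."""
    y_true = np.asarray(y_true).astype(int)
    y_pred = np.asarray(y_pred).astype(int)
    tp = int(np.sum((y_true == 1) & (y_pred == 1)))
    tn = int(np.sum((y_true == 0) & (y_pred == 0)))
    fp = int(np.sum((y_true == 0) & (y_pred == 1)))
    fn = int(np.sum((y_true == 1) & (y_pred == 0)))
    nan = float("nan")
    out = {
        "accuracy": (tp + tn) / len(y_true) if len(y_true) else nan,
        "sensitivity": tp / (tp + fn) if tp + fn else nan,
        "specificity": tn / (fp + tn) if fp + tn else nan,
        "f1": 2 * tp / (2 * tp + fp + fn) if 2 * tp + fp + fn else nan,
        "precision": tp / (tp + fp) if tp + fp else nan,
        "roc_auc": nan,
        "pr_auc": nan,
    }
    if scores is not None and len(np.unique(y_true)) == 2:
        scores = np.asarray(scores, dtype=float)
        out["roc_auc"] = float(roc_auc_score(y_true, scores))
        out["pr_auc"] = float(average_precision_score(y_true, scores))
    return out


@dataclass
class CVResult:
    """Per-fold metrics with Student-t 95% confidence intervals."""

    folds: pd.DataFrame   # n_folds x 7
    mean: pd.Series = field(init=False)
    ci_halfwidth: pd.Series = field(init=False)

    def __post_init__(self):
        self.mean = self.folds.mean(skipna=True)
        k = self.folds.notna().sum()
        sd = self.folds.std(ddof=1, skipna=True)
        hw = {}
        for m in self.folds.columns:
            if k[m] >= 2:
                hw[m] = float(stats.t.ppf(0.975, k[m] - 1) * sd[m] / np.sqrt(k[m]))
            else:
                hw[m] = float("nan")
        self.ci_halfwidth = pd.Series(hw)


@dataclass
class ValidationResult:
    """External-set point metrics with percentile bootstrap 95% CIs."""

    point: pd.Series
    ci_low: pd.Series
    ci_high: pd.Series
    n_boot: int


def cv_evaluate(clf_factory, X: pd.DataFrame, y, transform: str, seed: int,
                n_splits: int = 5, n_repeats: int = 10) -> CVResult:
    """Repeated stratified cross-validation (default 10 x 5 = 50 folds).

    Normalization and inner hyperparameter search are fit inside each
    training fold only.  Repetition r is seeded with seed + r.
    """
    y = np.asarray(y).astype(int)
    counts = np.bincount(y, minlength=2)
    if counts.min() < n_splits:
        raise ModelSkipped(
            f"class counts {counts.tolist()} too small for {n_splits}-fold CV")
    rows = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for r in range(n_repeats):
            skf = StratifiedKFold(n_splits, shuffle=True, random_state=seed + r)
            for tr_idx, te_idx in skf.split(X, y):
                xtr, xte = transform_features(
                    transform, X.iloc[tr_idx], X.iloc[te_idx])
                clf = clf_factory(seed + r)
                clf.fit(xtr.to_numpy(), y[tr_idx])
                pred = clf.predict(xte.to_numpy())
                scores = decision_scores(clf, xte.to_numpy())
                rows.append(metric_set(y[te_idx], pred, scores))
    return CVResult(pd.DataFrame(rows, columns=METRIC_NAMES))


def select_model(results, min_sens: float = 0.60, min_spec: float = 0.60):
    """Pick the admissible model with the highest mean ROC-AUC.

    ``results`` is a list of (ModelSpec, CVResult).  Models whose mean
    sensitivity or specificity falls below the floor are excluded; ties on
    ROC-AUC break lexicographically on the model id.  Returns None when no
    model is admissible.
    """
    if not results:
        raise ValueError("no results to select from")
    admissible = [
        (spec, res) for spec, res in results
        if res.mean["sensitivity"] >= min_sens and res.mean["specificity"] >= min_spec
    ]
    if not admissible:
        return None
    return min(admissible,
               key=lambda sr: (-sr[1].mean["roc_auc"], sr[0].model_id))


def stratified_bootstrap_indices(y, rng) -> np.ndarray:
    """Resample indices with replacement within each class, preserving the
    original class counts exactly."""
    y = np.asarray(y)
    idx = []
    for c in np.unique(y):
        members = np.flatnonzero(y == c)
        idx.append(rng.choice(members, size=len(members), replace=True))
    return np.concatenate(idx)


def external_validate(clf_factory, transform: str, x_train: pd.DataFrame, y_train,
                      x_val: pd.DataFrame, y_val, seed: int,
                      n_boot: int = 2000) -> ValidationResult:
    """Refit on the full training set, score the external set, and compute
    percentile 95% CIs from class-stratified bootstrap resamples."""
    y_train = np.asarray(y_train).astype(int)
    y_val = np.asarray(y_val).astype(int)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        xtr, xv = transform_features(transform, x_train, x_val)
        clf = clf_factory(seed)
        clf.fit(xtr.to_numpy(), y_train)
        pred = clf.predict(xv.to_numpy())
        scores = decision_scores(clf, xv.to_numpy())
        point = pd.Series(metric_set(y_val, pred, scores))[list(METRIC_NAMES)]
        rng = np.random.default_rng(seed)
        boot = []
        for _ in range(n_boot):
            idx = stratified_bootstrap_indices(y_val, rng)
            boot.append(metric_set(y_val[idx], pred[idx], scores[idx]))
    boot_df = pd.DataFrame(boot, columns=METRIC_NAMES)
    lo = boot_df.quantile(0.025)
    hi = boot_df.quantile(0.975)
    return ValidationResult(point, lo, hi, n_boot)


def gini_importance(clf) -> np.ndarray:
    """Normalized total Gini-impurity reduction per feature (trees only)."""
    if not isinstance(clf, DecisionTreeClassifier):
        raise TypeError("Gini importance is only defined for decision trees")
    return clf.feature_importances_


# ---------------------------------------------------------------------------
# Experiment driver
# ---------------------------------------------------------------------------

METADATA_COLUMNS = ("participant", "cohort", "visit")


def split_design(feature_table: pd.DataFrame, design: str) -> tuple:
    """Train/validation session masks for a design.

    cross_session: train on initial visits, validate on retests.
    cross_cohort: train on cohort 1, validate on cohort 2 (both visits); a
    visit-type indicator is appended to the features.
    """
    df = feature_table
    if design == "cross_session":
        train = df["visit"] == "initial"
        val = df["visit"] == "retest"
        extra = []
    elif design == "cross_cohort":
        train = df["cohort"] == 1
        val = df["cohort"] == 2
        extra = ["visit_type"]
    else:
        raise ConfigurationError(f"unknown design {design!r}")
    if not train.any() or not val.any():
        raise ConfigurationError(f"empty split for design {design!r}")
    return train, val, extra


@dataclass
class ExperimentReport:
    design: str
    leaderboard: pd.DataFrame
    selected: ModelSpec | None
    selected_cv: CVResult | None
    validation: ValidationResult | None
    n_train: int
    n_val: int
    config: dict


def run_experiment(design: str, feature_table: pd.DataFrame,
                   labels: pd.DataFrame, config: dict, seed: int
                   ) -> ExperimentReport:
    """Enumerate, cross-validate, select and externally validate.

    ``feature_table``: sessions x (metadata + features), indexed by session
    id.  ``labels``: sessions x method ids (binary).  ``config`` supplies
    the registries to enumerate (classifier ids, ROIs, transforms, feature
    sets, method ids) plus CV/bootstrap sizes.
    """
    registry = classifier_registry(
        inner_cv=config.get("inner_cv", 5),
        logreg_penalty=config.get("logreg_penalty", "l2"),
    )
    classifiers = config.get("classifiers") or sorted(registry)
    unknown = set(classifiers) - set(registry)
    if unknown:
        raise ConfigurationError(f"unknown classifier ids: {sorted(unknown)}")
    rois = config.get("rois") or list(ROIS)
    transforms = config.get("transforms") or list(TRANSFORMS)
    methods = config.get("methods") or [c for c in labels.columns]
    feature_sets = config["feature_sets"]
    n_splits = config.get("n_splits", 5)
    n_repeats = config.get("n_repeats", 10)
    n_boot = config.get("n_boot", 2000)

    table = feature_table.copy()
    if "visit_type" not in table.columns:
        table["visit_type"] = (table["visit"] == "retest").astype(float)
    train_mask, val_mask, extra_cols = split_design(table, design)
    pre_cols = [c for c in table.columns if c.startswith("pre_")]
    specs = enumerate_models(classifiers, rois, transforms, methods, feature_sets)

    rows, results = [], {}
    for spec in specs:
        try:
            cols = spec.group.columns(table.columns)
        except ModelSkipped:
            continue
        use_cols = cols + pre_cols + extra_cols
        sub = table.loc[train_mask, use_cols]
        ok = np.isfinite(sub.to_numpy()).all(axis=1)
        y = labels.loc[sub.index[ok], spec.method_id].to_numpy()
        try:
            res = cv_evaluate(registry_factory(registry, spec.classifier_id),
                              sub[ok], y, spec.group.transform, seed,
                              n_splits, n_repeats)
        except ModelSkipped:
            continue
        results[spec.model_id] = (spec, res)
        rows.append({"model_id": spec.model_id,
                     "classifier": spec.classifier_id,
                     "roi": spec.group.roi,
                     "transform": spec.group.transform,
                     "feature_set": "+".join(spec.group.feature_set),
                     "method": spec.method_id,
                     **{f"mean_{m}": res.mean[m] for m in METRIC_NAMES},
                     **{f"ci_{m}": res.ci_halfwidth[m] for m in METRIC_NAMES}})
    leaderboard = pd.DataFrame(rows).sort_values(
        "mean_roc_auc", ascending=False).reset_index(drop=True) if rows \
        else pd.DataFrame()

    picked = select_model(list(results.values())) if results else None
    validation = None
    sel_spec = sel_cv = None
    n_train = int(train_mask.sum())
    n_val = int(val_mask.sum())
    if picked is not None:
        sel_spec, sel_cv = picked
        cols = sel_spec.group.columns(table.columns) + pre_cols + extra_cols
        tr = table.loc[train_mask, cols]
        va = table.loc[val_mask, cols]
        tr_ok = np.isfinite(tr.to_numpy()).all(axis=1)
        va_ok = np.isfinite(va.to_numpy()).all(axis=1)
        y_tr = labels.loc[tr.index[tr_ok], sel_spec.method_id].to_numpy()
        y_va = labels.loc[va.index[va_ok], sel_spec.method_id].to_numpy()
        validation = external_validate(
            registry_factory(registry, sel_spec.classifier_id),
            sel_spec.group.transform, tr[tr_ok], y_tr, va[va_ok], y_va,
            seed, n_boot)
    return ExperimentReport(design, leaderboard, sel_spec, sel_cv, validation,
                            n_train, n_val, dict(config))


def registry_factory(registry: dict, classifier_id: str):
    try:
        return registry[classifier_id]
    except KeyError:
        raise ConfigurationError(f"unknown classifier id {classifier_id!r}") from None
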