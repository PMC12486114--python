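"""Covariate-shift, label-shift and test-retest reliability diagnostics.

Covariate shift is probed per feature with two-sample Kolmogorov-Smirnov
tests between initial and retest sessions; label shift per categorization
method with two-tailed Fisher exact tests on the class-by-visit table.
Reliability of continuous measures uses ICC(1,1) from a one-way
random-effects ANOVA (p from the F-test) and of binary outcomes uses
Cohen's kappa (p from the large-sample z-test) plus the percentage of
participants with the same outcome on both visits.

Concept drift has no direct test; it is inferred when feature and label
distributions are stable across visits while the outcomes themselves are
unreliable.  The "widespread" thresholds for that verdict are package
policy: shift is flagged when the rejection fraction exceeds 2*alpha, low
reliability when the mean outcome ICC falls below 0.2.  No multiple-testing
correction is applied; rejection fractions are reported instead.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from neuromodml.errors import DataError


def ks_two_sample(a, b) -> tuple:
    """Two-sample KS statistic and asymptotic two-sided p-value."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise DataError("KS test needs at least 2 observations per sample")
    res = stats.ks_2samp(a, b, method="asymp")
    return float(res.statistic), float(res.pvalue)


def fisher_exact_2x2(table) -> float:
    """Two-tailed Fisher exact p-value for a 2x2 count table."""
    t = np.asarray(table)
    if t.shape != (2, 2) or np.any(t < 0):
        raise ValueError("table must be 2x2 with non-negative counts")
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        warnings.warn("zero margin in 2x2 table: p set to 1", stacklevel=2)
        return 1.0
    return float(stats.fisher_exact(t, alternative="two-sided").pvalue)


def icc_1_1(paired) -> tuple:
    """ICC(1,1) for n subjects x 2 sessions, with the one-way ANOVA F-test p.

    ICC = (MSB - MSW) / (MSB + MSW) for k = 2 raters.  Returns (nan, nan)
    when the total variance is zero.
    """
    x = np.asarray(paired, dtype=float)
    x = x[~np.isnan(x).any(axis=1)]
    n, k = x.shape
    if k != 2:
        raise ValueError("expected an n x 2 array")
    if n < 3:
        raise DataError("ICC needs at least 3 complete pairs")
    subj_means = x.mean(axis=1)
    grand = x.mean()
    ssb = k * np.sum((subj_means - grand) ** 2)
    ssw = np.sum((x - subj_means[:, None]) ** 2)
    msb = ssb / (n - 1)
    msw = ssw / (n * (k - 1))
    if msb + msw == 0:
        warnings.warn("zero total variance: ICC undefined", stacklevel=2)
        return float("nan"), float("nan")
    icc = (msb - msw) / (msb + (k - 1) * msw)
    if msw == 0:
        return float(icc), 0.0
    f = msb / msw
    p = float(stats.f.sf(f, n - 1, n * (k - 1)))
    return float(icc), p


def cohens_kappa(paired_labels) -> tuple:
    """Cohen's kappa between two binary ratings with the z-test p-value.

    Returns (nan, nan) when chance agreement is 1 (both ratings constant).
    """
    x = np.asarray(paired_labels)
    if x.ndim != 2 or x.shape[1] != 2:
        raise ValueError("expected an n x 2 array of labels")
    n = x.shape[0]
    if n < 2:
        raise DataError("kappa needs at least 2 pairs")
    cats = np.unique(x)
    p_o = float(np.mean(x[:, 0] == x[:, 1]))
    pa = np.array([np.mean(x[:, 0] == c) for c in cats])
    pb = np.array([np.mean(x[:, 1] == c) for c in cats])
    p_e = float(np.sum(pa * pb))
    if p_e == 1.0:
        warnings.warn("both ratings constant: kappa undefined", stacklevel=2)
        return float("nan"), float("nan")
    kappa = (p_o - p_e) / (1.0 - p_e)
    # Fleiss large-sample variance under H0: kappa = 0
    var0 = (p_e + p_e ** 2 - float(np.sum(pa * pb * (pa + pb)))) / (
        n * (1.0 - p_e) ** 2)
    if var0 <= 0:
        return float(kappa), float("nan")
    z = kappa / np.sqrt(var0)
    p = float(2.0 * stats.norm.sf(abs(z)))
    return float(kappa), p


def percent_consistent(paired_labels) -> float:
    """Percentage of participants with the same outcome on both visits."""
    x = np.asarray(paired_labels)
    if x.shape[0] < 1:
        raise DataError("need at least one complete pair")
    return float(100.0 * np.mean(x[:, 0] == x[:, 1]))


@dataclass
class PairedVisitTable:
    """Per-participant values for both visits of one feature or method.

    ``initial``/``retest`` are participant-indexed Series; participants
    missing a visit carry NaN there.  Paired statistics (ICC, kappa,
    percent-consistent) use only complete pairs; the two-sample shift tests
    use all available sessions of each visit.
    """

    name: str
    initial: pd.Series
    retest: pd.Series

    def paired(self) -> np.ndarray:
        df = pd.concat({"initial": self.initial, "retest": self.retest}, axis=1)
        return df.dropna().to_numpy()

    def visit_samples(self) -> tuple:
        return (self.initial.dropna().to_numpy(),
                self.retest.dropna().to_numpy())


@dataclass
class DriftReport:
    """Joint shift/reliability diagnostics and the concept-drift verdict."""

    alpha: float
    ks: pd.DataFrame                  # per feature: D, p
    fisher: pd.Series                 # per method: p
    icc: pd.DataFrame                 # per measure: icc, p
    kappa: pd.DataFrame               # per method: kappa, p
    consistency: pd.Series            # per method: percent consistent
    ks_rejection_fraction: float
    fisher_rejection_fraction: float
    mean_outcome_icc: float
    flags: dict = field(default_factory=dict)

    def summary(self) -> str:
        lines = [
            f"alpha = {self.alpha}",
            f"covariate shift: {self.ks_rejection_fraction:.1%} of "
            f"{len(self.ks)} features reject KS "
            f"-> widespread: {self.flags['covariate_shift']}",
            f"label shift: {self.fisher_rejection_fraction:.1%} of "
            f"{len(self.fisher)} methods reject Fisher "
            f"-> widespread: {self.flags['label_shift']}",
            f"mean outcome ICC = {self.mean_outcome_icc:.3f} "
            f"-> low reliability: {self.flags['low_reliability']}",
            f"concept drift suspected: {self.flags['concept_drift_suspected']}",
        ]
        return "\n".join(lines)

    def to_json(self) -> str:
        return json.dumps({
            "alpha": self.alpha,
            "ks": self.ks.to_dict(orient="index"),
            "fisher": self.fisher.to_dict(),
            "icc": self.icc.to_dict(orient="index"),
            "kappa": self.kappa.to_dict(orient="index"),
            "percent_consistent": self.consistency.to_dict(),
            "ks_rejection_fraction": self.ks_rejection_fraction,
            "fisher_rejection_fraction": self.fisher_rejection_fraction,
            "mean_outcome_icc": self.mean_outcome_icc,
            "flags": self.flags,
        }, indent=2, default=float)


def drift_report(features, outcome_labels, outcome_stats=None,
                 alpha: float = 0.05, widespread_factor: float = 2.0,
                 icc_low: float = 0.2) -> DriftReport:
    """Run every diagnostic and combine them into the drift verdict.

    ``features``: PairedVisitTables of continuous baseline features (KS and
    ICC).  ``outcome_labels``: PairedVisitTables of binary outcome labels
    (Fisher, kappa, percent-consistent).  ``outcome_stats``: optional
    continuous outcome statistics (ratios / p-values) for outcome ICC; when
    absent, the reliability verdict falls back to the mean kappa.
    """
    if not features or not outcome_labels:
        raise ValueError("need at least one feature and one outcome table")

    ks_rows = {}
    for t in features:
        a, b = t.visit_samples()
        d, p = ks_two_sample(a, b)
        ks_rows[t.name] = {"D": d, "p": p}
    ks_df = pd.DataFrame.from_dict(ks_rows, orient="index")

    fisher_rows, kappa_rows, cons_rows = {}, {}, {}
    for t in outcome_labels:
        a, b = t.visit_samples()
        table = [[int((a == 1).sum()), int((a == 0).sum())],
                 [int((b == 1).sum()), int((b == 0).sum())]]
        fisher_rows[t.name] = fisher_exact_2x2(table)
        pairs = t.paired().astype(int)
        if len(pairs) >= 2:
            k, kp = cohens_kappa(pairs)
            kappa_rows[t.name] = {"kappa": k, "p": kp}
            cons_rows[t.name] = percent_consistent(pairs)
    fisher_s = pd.Series(fisher_rows)
    kappa_df = pd.DataFrame.from_dict(kappa_rows, orient="index")
    cons_s = pd.Series(cons_rows)

    icc_rows = {}
    for t in (outcome_stats or []):
        pairs = t.paired()
        if len(pairs) >= 3:
            icc, p = icc_1_1(pairs)
            icc_rows[t.name] = {"icc": icc, "p": p}
    icc_df = pd.DataFrame.from_dict(icc_rows, orient="index") if icc_rows \
        else pd.DataFrame(columns=["icc", "p"])

    ks_frac = float((ks_df["p"] <= alpha).mean())
    fisher_frac = float((fisher_s <= alpha).mean())
    if len(icc_df):
        mean_outcome_icc = float(np.nanmean(icc_df["icc"]))
    else:
        mean_outcome_icc = float(np.nanmean(kappa_df["kappa"])) if len(kappa_df) \
            else float("nan")

    cov_shift = ks_frac > widespread_factor * alpha
    lab_shift = fisher_frac > widespread_factor * alpha
    low_rel = bool(mean_outcome_icc < icc_low)
    flags = {
        "covariate_shift": bool(cov_shift),
        "label_shift": bool(lab_shift),
        "low_reliability": low_rel,
        "concept_drift_suspected": bool(not cov_shift and not lab_shift and low_rel),
    }
    return DriftReport(alpha, ks_df, fisher_s, icc_df, kappa_df, cons_s,
                       ks_frac, fisher_frac, mean_outcome_icc, flags)
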