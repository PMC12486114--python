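"""Outcome labelling and baseline TMS features.

Corticospinal modulation: a two-tailed two-sample t-test between pre- and
post-stimulation MEP peak-to-peak amplitudes; a session is a responder when
p <= 0.05 (direction-agnostic).

Cortical modulation: the local mean field power (LMFP) over the left-motor
ROI, integrated with the composite Simpson rule over a time window per
trial, averaged within block; the post/pre ratio labels the session as
facilitation when >= 1 and suppression otherwise.  43 windows (4 a priori
plus a swept family of 30-ms windows over 25-345 ms) each define one
categorization method.

Baseline (pre-stimulation) TMS features: mean and SD of MEP amplitudes,
LMFP AUC over 15-80 ms, and a TEP regression quality score (RQS) — here a
trial-consistency score defined as the mean R² of regressing each trial's
ROI-averaged waveform onto the block-mean waveform.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.integrate import simpson

from neuromodml.errors import DataError
from neuromodml.synthetic import LM_CHANNELS, MEPBlock, SessionRecord, TEPBlock

ALPHA = 0.05

#: Windows named in prior literature, used alongside the swept family.
A_PRIORI_WINDOWS = ((15.0, 45.0), (15.0, 80.0), (100.0, 131.0), (105.0, 135.0))


@dataclass(frozen=True)
class CategorizationMethod:
    """One way of labelling a session (MEP t-test or LMFP window ratio)."""

    kind: str                 # 'MEP' or 'LMFP'
    post_block: str           # 'T5' or 'T25'
    window: tuple | None = None  # (start_ms, end_ms) for LMFP

    def __post_init__(self):
        if self.kind not in ("MEP", "LMFP"):
            raise ValueError(f"unknown categorization kind {self.kind!r}")
        if self.kind == "LMFP" and self.window is None:
            raise ValueError("LMFP method requires a window")

    @property
    def method_id(self) -> str:
        if self.kind == "MEP":
            return f"MEP_{self.post_block}"
        lo, hi = self.window
        return f"LMFP_{self.post_block}_{lo:g}-{hi:g}"

    @property
    def truth_key(self) -> str:
        """Key into the generator's ground-truth map."""
        return f"{self.kind}_{self.post_block}"


@dataclass
class OutcomeLabel:
    session_id: str
    method_id: str
    label: int          # 1 = responder / facilitation
    statistic: float    # p-value (MEP) or post/pre ratio (LMFP)


def mep_ttest_label(pre: MEPBlock, post: MEPBlock, session_id: str = "",
                    method_id: str = "", equal_var: bool = True) -> OutcomeLabel:
    """Two-tailed two-sample t-test label: responder iff p <= 0.05."""
    res = stats.ttest_ind(post.amplitudes, pre.amplitudes, equal_var=equal_var)
    p = float(res.pvalue)
    if not np.isfinite(p):
        # zero variance in both blocks: identical means give no evidence
        p = 1.0 if np.isclose(pre.amplitudes.mean(), post.amplitudes.mean()) else 0.0
    return OutcomeLabel(session_id, method_id, int(p <= ALPHA), p)


def lmfp_curve(trial: np.ndarray, channel_labels, roi_channels=LM_CHANNELS
               ) -> np.ndarray:
    """Root-mean-square voltage across the ROI channels, per time point."""
    labels = list(channel_labels)
    idx = []
    for ch in roi_channels:
        if ch not in labels:
            raise DataError(f"ROI channel {ch!r} missing from TEP data")
        idx.append(labels.index(ch))
    return np.sqrt(np.mean(np.asarray(trial, dtype=float)[idx, :] ** 2, axis=0))


def simpson_auc(y: np.ndarray, x: np.ndarray) -> float:
    """Composite Simpson integral; even sample counts use Simpson on the
    largest odd prefix plus a trapezoid on the final interval."""
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    if y.size < 3:
        warnings.warn("fewer than 3 samples: falling back to trapezoid",
                      stacklevel=2)
        return float(np.trapezoid(y, x))
    if y.size % 2 == 1:
        return float(simpson(y, x=x))
    body = float(simpson(y[:-1], x=x[:-1]))
    tail = 0.5 * (y[-2] + y[-1]) * (x[-1] - x[-2])
    return body + tail


def lmfp_window_auc(curve: np.ndarray, time_ms: np.ndarray, window) -> float:
    """AUC of an LMFP curve over a time window (µV·ms)."""
    lo, hi = window
    time_ms = np.asarray(time_ms, dtype=float)
    if lo < time_ms[0] or hi > time_ms[-1]:
        raise ValueError(f"window {window} outside the time axis")
    mask = (time_ms >= lo) & (time_ms <= hi)
    return simpson_auc(np.asarray(curve)[mask], time_ms[mask])


def block_mean_window_auc(block: TEPBlock, window, roi=LM_CHANNELS) -> float:
    """Per-trial LMFP window AUCs averaged across trials of a block."""
    aucs = [lmfp_window_auc(lmfp_curve(tr, block.channel_labels, roi),
                            block.time_ms, window)
            for tr in block.trials]
    return float(np.mean(aucs))


def lmfp_ratio_label(pre: TEPBlock, post: TEPBlock, window, roi=LM_CHANNELS,
                     session_id: str = "", method_id: str = "") -> OutcomeLabel:
    """Facilitation iff mean post-block AUC / mean pre-block AUC >= 1."""
    mean_pre = block_mean_window_auc(pre, window, roi)
    mean_post = block_mean_window_auc(post, window, roi)
    if mean_pre == 0:
        raise DataError("degenerate pre block: zero mean LMFP AUC")
    ratio = mean_post / mean_pre
    return OutcomeLabel(session_id, method_id, int(ratio >= 1.0), float(ratio))


def default_window_set(a_priori=A_PRIORI_WINDOWS, n_sweep: int = 39,
                       sweep_len: float = 30.0,
                       sweep_range=(25.0, 345.0)) -> list:
    """The default categorization-window list: a priori + swept windows.

    The sweep places ``n_sweep`` windows of length ``sweep_len`` with starts
    evenly spaced over the allowed range; with the defaults the list has
    4 + 39 = 43 windows.  Exact duplicates are dropped with a warning.
    """
    lo, hi = sweep_range
    windows = [tuple(map(float, w)) for w in a_priori]
    if n_sweep > 0:
        starts = np.linspace(lo, hi - sweep_len, n_sweep)
        windows += [(round(float(s), 1), round(float(s + sweep_len), 1))
                    for s in starts]
    seen, out = set(), []
    for w in windows:
        if w in seen:
            warnings.warn(f"duplicate window {w} dropped", stacklevel=2)
            continue
        seen.add(w)
        out.append(w)
    return out


def make_methods(experiment: str, windows=None, post_blocks=("T5", "T25"),
                 lmfp_post_block: str = "T5") -> list:
    """Categorization methods for one experiment.

    MEP: one method per post block.  LMFP: one method per window, with the
    ratio taken against a single configured post block.
    """
    if experiment == "MEP":
        return [CategorizationMethod("MEP", blk) for blk in post_blocks]
    if experiment == "LMFP":
        if windows is None:
            windows = default_window_set()
        return [CategorizationMethod("LMFP", lmfp_post_block, tuple(w))
                for w in windows]
    raise ValueError(f"unknown experiment {experiment!r}")


def tep_rqs(block: TEPBlock, roi=LM_CHANNELS) -> float:
    """Trial-consistency score: mean R² of each trial's ROI-averaged
    waveform regressed on the block-mean waveform, clipped to [0, 1]."""
    if block.trials.shape[0] < 2:
        raise DataError("RQS needs at least 2 trials")
    labels = list(block.channel_labels)
    idx = []
    for ch in roi:
        if ch not in labels:
            raise DataError(f"ROI channel {ch!r} missing from TEP data")
        idx.append(labels.index(ch))
    waves = block.trials[:, idx, :].mean(axis=1)   # trials x time
    mean_wave = waves.mean(axis=0)
    if mean_wave.std() == 0:
        raise DataError("zero-variance block-mean waveform")
    scores = []
    for w in waves:
        sd = w.std()
        if sd == 0:
            scores.append(0.0)
            continue
        r = np.corrcoef(w, mean_wave)[0, 1]
        scores.append(r * r)
    return float(np.clip(np.mean(scores), 0.0, 1.0))


def baseline_tms_features(session: SessionRecord, experiment: str = "MEP",
                          roi=LM_CHANNELS) -> dict:
    """Pre-stimulation feature set appended to every feature group.

    MEP experiment: mean and SD of baseline MEP amplitudes, LMFP AUC over
    15-80 ms and the TEP RQS.  LMFP experiment: only the latter two (the
    locally-focused subset).
    """
    if "pre" not in session.tep_blocks:
        raise DataError("missing pre TEP block")
    pre_tep = session.tep_blocks["pre"]
    feats = {
        "pre_lmfp_auc_15_80": block_mean_window_auc(pre_tep, (15.0, 80.0), roi),
        "pre_rqs": tep_rqs(pre_tep, roi),
    }
    if experiment == "MEP":
        if "pre" not in session.mep_blocks:
            raise DataError("missing pre MEP block")
        amps = session.mep_blocks["pre"].amplitudes
        feats["pre_mep_mean"] = float(amps.mean())
        feats["pre_mep_sd"] = float(amps.std(ddof=1))
    elif experiment != "LMFP":
        raise ValueError(f"unknown experiment {experiment!r}")
    return feats


def derive_labels(session: SessionRecord, methods) -> list:
    """Apply every categorization method to one session.

    LMFP trial curves are computed once per block and reused across windows.
    """
    curves = {}

    def block_curves(block_id):
        if block_id not in curves:
            blk = session.tep_blocks[block_id]
            curves[block_id] = (np.stack([
                lmfp_curve(tr, blk.channel_labels, LM_CHANNELS)
                for tr in blk.trials]), blk.time_ms)
        return curves[block_id]

    out = []
    for m in methods:
        if m.kind == "MEP":
            lab = mep_ttest_label(session.mep_blocks["pre"],
                                  session.mep_blocks[m.post_block],
                                  session.session_id, m.method_id)
        else:
            pre_c, t = block_curves("pre")
            post_c, _ = block_curves(m.post_block)
            mean_pre = float(np.mean([lmfp_window_auc(c, t, m.window)
                                      for c in pre_c]))
            mean_post = float(np.mean([lmfp_window_auc(c, t, m.window)
                                       for c in post_c]))
            if mean_pre == 0:
                raise DataError("degenerate pre block: zero mean LMFP AUC")
            ratio = mean_post / mean_pre
            lab = OutcomeLabel(session.session_id, m.method_id,
                               int(ratio >= 1.0), ratio)
        out.append(lab)
    return out
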