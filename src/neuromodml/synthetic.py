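"""Synthetic two-cohort test-retest TMS-EEG generator.

Produces session bundles (resting-state EEG, TMS-evoked potential blocks,
motor-evoked potential blocks) with known ground truth so that every
downstream stage — feature extraction, outcome labelling, drift diagnostics
and model selection — can be exercised and validated without real data.

The generative model:

* resting EEG: 1/f^beta background noise plus four band-limited oscillators
  (delta/theta/alpha/beta) and white sensor noise.  A latent binary
  participant trait scales the oscillator amplitudes, which induces a
  recoverable class signal in both band powers and complexity measures.
* TEPs: a shared template of damped (Gaussian-windowed) sinusoids with
  component peaks near 15, 30, 45, 60, 100 and 180 ms; post-stimulation
  blocks are the template scaled by a modulation gain, plus trial noise.
* MEPs: log-normal peak-to-peak amplitudes; responders receive a
  standardized location shift on the log scale in post-stimulation blocks.

Outcome ground truth is injected at the block level (gains and effect
sizes), never copied into labels: the outcomes module re-derives labels, so
label derivation is itself under test.  The trait drives baseline features
on *both* visits, while the per-visit responder state drives the outcome
blocks; the probability that the retest state equals the initial state is
the label-consistency parameter.  Setting it to 0.5 reproduces the
concept-drift regime (stable features, unreliable outcomes).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from neuromodml.errors import ConfigurationError, DataError
from neuromodml.rng import child_seed

# 32-channel 10-10 subset; covers the left-motor ROI and a central ROI.
MONTAGE_32 = (
    "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8",
    "FC5", "FC3", "FC1", "FCz", "FC2", "FC4", "FC6",
    "C5", "C3", "C1", "Cz", "C2", "C4", "C6",
    "CP5", "CP3", "CP1", "CPz", "CP2", "CP4", "CP6",
    "P3", "Pz", "P4", "Oz",
)

#: Left-motor ROI: the six channels over the stimulated left M1 region.
LM_CHANNELS = ("C1", "C3", "C5", "FC1", "FC3", "FC5")

#: Central ROI (midline-adjacent sensorimotor strip).
CENTRAL_CHANNELS = ("FC1", "FC2", "C1", "Cz", "C2", "CP1", "CP2")

BLOCK_IDS = ("pre", "T5", "T25")

# Band-limited oscillator pass-bands (Hz), matching the analysis bands.
OSC_BANDS = {
    "delta": (1.0, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 12.0),
    "beta": (12.0, 20.0),
}

# TEP template components: (latency ms, amplitude µV, width ms, frequency Hz).
TEP_COMPONENTS = (
    (15.0, 6.0, 4.0, 40.0),
    (30.0, -5.0, 6.0, 30.0),
    (45.0, 4.0, 8.0, 25.0),
    (60.0, -3.0, 10.0, 18.0),
    (100.0, 5.0, 18.0, 9.0),
    (180.0, -2.5, 30.0, 5.0),
)


@dataclass
class EEGRecording:
    """Multichannel resting EEG: ``data`` is channels x samples in µV."""

    channel_labels: tuple
    fs: float
    data: np.ndarray
    epoch_len_s: float = 10.0

    def __post_init__(self):
        self.channel_labels = tuple(self.channel_labels)
        if len(set(self.channel_labels)) != len(self.channel_labels):
            raise ConfigurationError("channel labels must be unique")
        if self.fs <= 0:
            raise ConfigurationError("sampling rate must be positive")
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2 or self.data.shape[0] != len(self.channel_labels):
            raise DataError("data must be channels x samples")
        if self.duration_s < 60.0:
            raise DataError("recording must be at least 60 s long")

    @property
    def duration_s(self) -> float:
        return self.data.shape[1] / self.fs

    def channel_index(self, label: str) -> int:
        try:
            return self.channel_labels.index(label)
        except ValueError:
            raise DataError(f"channel {label!r} not in recording") from None


@dataclass
class TEPBlock:
    """One block of TMS-evoked potential trials (trials x channels x time, µV)."""

    block_id: str
    trials: np.ndarray
    time_ms: np.ndarray
    channel_labels: tuple

    def __post_init__(self):
        self.trials = np.asarray(self.trials, dtype=float)
        self.time_ms = np.asarray(self.time_ms, dtype=float)
        self.channel_labels = tuple(self.channel_labels)
        if self.block_id not in BLOCK_IDS:
            raise ConfigurationError(f"unknown block id {self.block_id!r}")
        if self.trials.ndim != 3:
            raise DataError("trials must be trials x channels x time")
        if self.trials.shape[0] < 2:
            raise DataError("a TEP block needs at least 2 trials")
        if np.any(np.diff(self.time_ms) <= 0):
            raise DataError("time axis must be strictly increasing")
        if self.time_ms[0] > 0 or self.time_ms[-1] < 345.0:
            raise DataError("time axis must span at least [0, 345] ms")

    def channel_index(self, label: str) -> int:
        try:
            return self.channel_labels.index(label)
        except ValueError:
            raise DataError(f"channel {label!r} not in TEP block") from None


@dataclass
class MEPBlock:
    """One block of MEP peak-to-peak amplitudes in mV."""

    block_id: str
    amplitudes: np.ndarray

    def __post_init__(self):
        self.amplitudes = np.asarray(self.amplitudes, dtype=float)
        if self.block_id not in BLOCK_IDS:
            raise ConfigurationError(f"unknown block id {self.block_id!r}")
        if self.amplitudes.size < 2:
            raise DataError("an MEP block needs at least 2 trials")
        if np.any(self.amplitudes <= 0):
            raise DataError("MEP amplitudes must be positive")


@dataclass
class SessionRecord:
    """One participant-visit bundle."""

    participant_id: str
    cohort_id: int
    visit: str  # 'initial' or 'retest'
    rseeg: EEGRecording
    tep_blocks: dict
    mep_blocks: dict
    ground_truth: dict | None = None

    def __post_init__(self):
        if self.visit not in ("initial", "retest"):
            raise ConfigurationError(f"unknown visit type {self.visit!r}")
        if self.cohort_id not in (1, 2):
            raise ConfigurationError("cohort_id must be 1 or 2")
        post = set(self.tep_blocks) - {"pre"}
        if post and "pre" not in self.tep_blocks:
            raise DataError("pre TEP block required when a post block is present")
        post_mep = set(self.mep_blocks) - {"pre"}
        if post_mep and "pre" not in self.mep_blocks:
            raise DataError("pre MEP block required when a post block is present")

    @property
    def session_id(self) -> str:
        return f"c{self.cohort_id}_{self.participant_id}_{self.visit}"


@dataclass
class CohortSpec:
    """Parameters of the two-cohort test-retest simulation.

    Availability patterns default to the reference analysis sample: cohort 1
    has 15 participants with both visits, 2 initial-only and 4 retest-only
    (36 sessions); cohort 2 has 18 with both visits and 1 retest-only
    (37 sessions) — 73 sessions in total, 35 initial and 38 retest.
    """

    # (both visits, initial only, retest only) per cohort
    cohort1_counts: tuple = (15, 2, 4)
    cohort2_counts: tuple = (18, 0, 1)

    # resting EEG
    channels: tuple = MONTAGE_32
    fs: float = 1000.0
    duration_s: float = 180.0
    psd_exponent: float = 1.0       # 1/f^beta background
    background_rms: float = 10.0    # µV
    band_amps: dict = field(default_factory=lambda: {
        "delta": 4.0, "theta": 3.0, "alpha": 6.0, "beta": 2.0})  # µV RMS
    channel_noise: float = 2.0      # µV white sensor noise

    # latent class structure
    responder_fraction: float = 0.5
    responder_osc_scale: float = 1.5   # oscillator amplitude scale for trait=1
    label_consistency: float = 0.5     # P(retest state == initial state)

    # MEPs (log-normal; location/scale on the log scale, amplitudes in mV)
    mep_mu: float = 0.0
    mep_sigma: float = 0.5
    mep_effect_size: float = 1.5       # standardized log-scale shift for responders

    # TEPs
    tep_fs: float = 1000.0
    tep_tmin_ms: float = 0.0
    tep_tmax_ms: float = 400.0
    tep_noise: float = 0.5             # µV per-sample trial noise
    tep_gain_responder: float = 1.3    # post/pre LMFP multiplier, state=1
    tep_gain_nonresponder: float = 0.8

    # trial counts per cohort (single-pulse TMS protocol differs by cohort)
    trial_counts: dict = field(default_factory=lambda: {
        1: {"pre": 150, "T5": 150, "T25": 60},
        2: {"pre": 120, "T5": 120, "T25": 60},
    })

    seed: int = 0

    def __post_init__(self):
        self.validate()

    def validate(self):
        for counts in (self.cohort1_counts, self.cohort2_counts):
            if len(counts) != 3 or any(c < 0 for c in counts):
                raise ConfigurationError("availability counts must be 3 non-negative ints")
        if not 0.0 <= self.responder_fraction <= 1.0:
            raise ConfigurationError("responder fraction must be in [0, 1]")
        if not 0.0 <= self.label_consistency <= 1.0:
            raise ConfigurationError("label consistency must be in [0, 1]")
        if self.tep_gain_responder <= 0 or self.tep_gain_nonresponder <= 0:
            raise ConfigurationError("TEP gains must be positive")
        missing = [ch for ch in LM_CHANNELS if ch not in self.channels]
        if missing:
            raise ConfigurationError(f"montage is missing LM channels: {missing}")

    def counts(self, cohort_id: int) -> tuple:
        return self.cohort1_counts if cohort_id == 1 else self.cohort2_counts


def _powerlaw_noise(rng, n, exponent, fs):
    """Unit-SD noise with a 1/f^exponent power spectrum."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, d=1.0 / fs)
    scale = np.ones_like(f)
    scale[1:] = f[1:] ** (-exponent / 2.0)
    scale[0] = 0.0
    x = np.fft.irfft(spec * scale, n=n)
    sd = x.std()
    return x / sd if sd > 0 else x


def _bandlimited_noise(rng, n, lo, hi, fs):
    """Unit-SD noise confined to [lo, hi] Hz (brick-wall in frequency)."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, d=1.0 / fs)
    mask = (f >= lo) & (f <= hi)
    spec[~mask] = 0.0
    x = np.fft.irfft(spec, n=n)
    sd = x.std()
    return x / sd if sd > 0 else x


def generate_rseeg(spec: CohortSpec, seed: int, osc_scale: float = 1.0) -> EEGRecording:
    """Generate one resting-state EEG recording.

    ``osc_scale`` multiplies every oscillator amplitude; it is how the
    latent participant trait expresses itself in baseline EEG.  The output
    is a pure function of ``(spec, seed, osc_scale)``.
    """
    spec.validate()
    amps = {b: spec.band_amps.get(b, 0.0) * osc_scale for b in OSC_BANDS}
    if spec.background_rms == 0 and spec.channel_noise == 0 and all(
            a == 0 for a in amps.values()):
        raise DataError("degenerate spec: zero background, oscillators and noise")
    rng = np.random.default_rng(int(seed))
    n = int(round(spec.duration_s * spec.fs))
    data = np.empty((len(spec.channels), n))
    for ci in range(len(spec.channels)):
        x = spec.background_rms * _powerlaw_noise(rng, n, spec.psd_exponent, spec.fs)
        for band, (lo, hi) in OSC_BANDS.items():
            a = amps[band]
            if a > 0:
                x = x + a * _bandlimited_noise(rng, n, lo, hi, spec.fs)
        if spec.channel_noise > 0:
            x = x + spec.channel_noise * rng.standard_normal(n)
        data[ci] = x
    return EEGRecording(spec.channels, spec.fs, data)


def tep_template(spec: CohortSpec) -> tuple:
    """Shared TEP component template: (time_ms, channels x time array, µV).

    Sum of Gaussian-windowed (damped) sinusoids at canonical TEP component
    latencies, scaled per channel by a fixed topography (left-motor channels
    strongest, since the simulated pulse targets left M1).
    """
    dt = 1000.0 / spec.tep_fs
    time_ms = np.arange(spec.tep_tmin_ms, spec.tep_tmax_ms + dt / 2, dt)
    wave = np.zeros_like(time_ms)
    for lat, amp, width, freq in TEP_COMPONENTS:
        env = np.exp(-0.5 * ((time_ms - lat) / width) ** 2)
        wave += amp * env * np.sin(2 * np.pi * freq * (time_ms - lat) / 1000.0 + np.pi / 2)
    weights = np.array([1.0 if ch in LM_CHANNELS else 0.4 for ch in spec.channels])
    return time_ms, weights[:, None] * wave[None, :]


def generate_tep_block(spec: CohortSpec, block_id: str, modulation_gain: float,
                       seed: int, n_trials: int | None = None,
                       noise: float | None = None,
                       cohort_id: int = 1) -> TEPBlock:
    """Generate one TEP block: gain-scaled shared template plus trial noise."""
    if modulation_gain <= 0:
        raise ValueError("modulation gain must be positive")
    spec.validate()
    if n_trials is None:
        n_trials = spec.trial_counts[cohort_id][block_id]
    if noise is None:
        noise = spec.tep_noise
    time_ms, template = tep_template(spec)
    rng = np.random.default_rng(int(seed))
    trials = modulation_gain * template[None, :, :] + noise * rng.standard_normal(
        (n_trials, template.shape[0], template.shape[1]))
    return TEPBlock(block_id, trials, time_ms, spec.channels)


def generate_mep_block(spec: CohortSpec, block_id: str, responder: bool,
                       seed: int, n_trials: int | None = None,
                       cohort_id: int = 1) -> MEPBlock:
    """Generate one MEP block of log-normal peak-to-peak amplitudes (mV).

    Responders receive a shift of ``mep_effect_size`` standard deviations on
    the log scale in post-stimulation blocks; the pre block is never shifted.
    """
    spec.validate()
    if n_trials is None:
        n_trials = spec.trial_counts[cohort_id][block_id]
    rng = np.random.default_rng(int(seed))
    shift = 0.0
    if responder and block_id != "pre":
        shift = spec.mep_effect_size * spec.mep_sigma
    z = rng.standard_normal(n_trials)
    return MEPBlock(block_id, np.exp(spec.mep_mu + shift + spec.mep_sigma * z))


def cohort_structure(spec: CohortSpec) -> list:
    """Participant/visit skeleton implied by the availability pattern.

    Returns dicts with participant_id, cohort_id and the list of visits,
    without generating any signals.
    """
    out = []
    for cohort_id in (1, 2):
        both, init_only, retest_only = spec.counts(cohort_id)
        idx = 0
        for _ in range(both):
            out.append({"participant_id": f"p{idx:02d}", "cohort_id": cohort_id,
                        "visits": ["initial", "retest"]})
            idx += 1
        for _ in range(init_only):
            out.append({"participant_id": f"p{idx:02d}", "cohort_id": cohort_id,
                        "visits": ["initial"]})
            idx += 1
        for _ in range(retest_only):
            out.append({"participant_id": f"p{idx:02d}", "cohort_id": cohort_id,
                        "visits": ["retest"]})
            idx += 1
    return out


def _visit_states(spec: CohortSpec, rng) -> tuple:
    """(trait, initial_state, retest_state) for one participant.

    The retest state equals the initial state with probability
    ``label_consistency`` and is flipped otherwise, so consistency 1.0 gives
    perfectly reproducible outcomes and 0.5 gives chance-level agreement.
    """
    trait = int(rng.random() < spec.responder_fraction)
    s_init = trait
    s_retest = s_init if rng.random() < spec.label_consistency else 1 - s_init
    return trait, s_init, s_retest


def participant_states(spec: CohortSpec) -> list:
    """Latent trait and per-visit responder states for every participant."""
    out = []
    for entry in cohort_structure(spec):
        pid, cohort_id = entry["participant_id"], entry["cohort_id"]
        prng = np.random.default_rng(child_seed(spec.seed, "state", cohort_id, pid))
        trait, s_init, s_retest = _visit_states(spec, prng)
        out.append({**entry, "trait": trait,
                    "state": {"initial": s_init, "retest": s_retest}})
    return out


def generate_cohorts(spec: CohortSpec) -> list:
    """Generate all sessions of the two-cohort test-retest dataset.

    Baseline EEG is driven by the stable participant trait on both visits;
    outcome blocks are driven by the per-visit responder state.
    """
    sessions = []
    for entry in participant_states(spec):
        pid, cohort_id = entry["participant_id"], entry["cohort_id"]
        trait = entry["trait"]
        s_init, s_retest = entry["state"]["initial"], entry["state"]["retest"]
        for visit in entry["visits"]:
            state = s_init if visit == "initial" else s_retest
            key = (cohort_id, pid, visit)
            osc = spec.responder_osc_scale if trait else 1.0
            rseeg = generate_rseeg(
                spec, child_seed(spec.seed, "rseeg", *key), osc_scale=osc)
            gain = {"pre": 1.0}
            for blk in ("T5", "T25"):
                gain[blk] = (spec.tep_gain_responder if state
                             else spec.tep_gain_nonresponder)
            tep_blocks = {
                blk: generate_tep_block(
                    spec, blk, gain[blk], child_seed(spec.seed, "tep", blk, *key),
                    cohort_id=cohort_id)
                for blk in BLOCK_IDS}
            mep_blocks = {
                blk: generate_mep_block(
                    spec, blk, bool(state), child_seed(spec.seed, "mep", blk, *key),
                    cohort_id=cohort_id)
                for blk in BLOCK_IDS}
            truth = {
                "MEP_T5": state, "MEP_T25": state,
                "LMFP_T5": int(gain["T5"] >= 1.0),
                "LMFP_T25": int(gain["T25"] >= 1.0),
            }
            sessions.append(SessionRecord(pid, cohort_id, visit, rseeg,
                                          tep_blocks, mep_blocks, truth))
    return sessions


def small_spec(**overrides) -> CohortSpec:
    """A desk-scale spec: same cohort structure, reduced signal sizes.

    Used by examples and the demo pipeline; the cohort availability pattern
    is unchanged, only sampling rates, durations, channel and trial counts
    are reduced.
    """
    defaults = dict(
        channels=("FC5", "FC3", "FC1", "C5", "C3", "C1", "Cz", "Pz"),
        fs=64.0, duration_s=60.0,
        tep_fs=250.0,
        trial_counts={1: {"pre": 30, "T5": 30, "T25": 20},
                      2: {"pre": 30, "T5": 30, "T25": 20}},
    )
    defaults.update(overrides)
    return CohortSpec(**defaults)


# ---------------------------------------------------------------------------
# On-disk layout: one directory per session.
#   rseeg.npy + rseeg.json   channels x samples array + sidecar (labels, fs)
#   tep_<blk>.npy + .json    trials x channels x time + sidecar (time axis)
#   mep_<blk>.csv            one amplitude per line (mV)
#   session.json             metadata and ground truth
# ---------------------------------------------------------------------------

def save_session(session: SessionRecord, root) -> Path:
    d = Path(root) / session.session_id
    d.mkdir(parents=True, exist_ok=True)
    np.save(d / "rseeg.npy", session.rseeg.data)
    (d / "rseeg.json").write_text(json.dumps({
        "channel_labels": list(session.rseeg.channel_labels),
        "fs": session.rseeg.fs, "epoch_len_s": session.rseeg.epoch_len_s}))
    for blk, tep in session.tep_blocks.items():
        np.save(d / f"tep_{blk}.npy", tep.trials)
        (d / f"tep_{blk}.json").write_text(json.dumps({
            "time_ms": tep.time_ms.tolist(),
            "channel_labels": list(tep.channel_labels)}))
    for blk, mep in session.mep_blocks.items():
        np.savetxt(d / f"mep_{blk}.csv", mep.amplitudes, fmt="%.8g")
    (d / "session.json").write_text(json.dumps({
        "participant_id": session.participant_id,
        "cohort_id": session.cohort_id,
        "visit": session.visit,
        "ground_truth": session.ground_truth}))
    return d


def load_session(path) -> SessionRecord:
    d = Path(path)
    meta = json.loads((d / "session.json").read_text())
    rmeta = json.loads((d / "rseeg.json").read_text())
    rseeg = EEGRecording(tuple(rmeta["channel_labels"]), rmeta["fs"],
                         np.load(d / "rseeg.npy"), rmeta["epoch_len_s"])
    tep_blocks, mep_blocks = {}, {}
    for blk in BLOCK_IDS:
        tf = d / f"tep_{blk}.npy"
        if tf.exists():
            tmeta = json.loads((d / f"tep_{blk}.json").read_text())
            tep_blocks[blk] = TEPBlock(blk, np.load(tf),
                                       np.asarray(tmeta["time_ms"]),
                                       tuple(tmeta["channel_labels"]))
        mf = d / f"mep_{blk}.csv"
        if mf.exists():
            mep_blocks[blk] = MEPBlock(blk, np.loadtxt(mf))
    return SessionRecord(meta["participant_id"], meta["cohort_id"], meta["visit"],
                         rseeg, tep_blocks, mep_blocks, meta.get("ground_truth"))


def save_cohort(sessions, root) -> Path:
    root = Path(root)
    for s in sessions:
        save_session(s, root)
    return root


def load_cohort(root) -> list:
    root = Path(root)
    dirs = sorted(p for p in root.iterdir() if (p / "session.json").exists())
    return [load_session(p) for p in dirs]
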