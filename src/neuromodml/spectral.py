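"""Multitaper band-power features from baseline resting-state EEG.

Power spectral densities are estimated per channel on consecutive 10-s
epochs with DPSS (Slepian) tapers, band powers are integrated under the PSD
for the four analysis bands (delta 1-4, theta 4-8, alpha 8-12, beta
12-20 Hz) and averaged across epochs.

Defaults: time-bandwidth NW = 4 with 2*NW - 1 = 7 tapers and uniform
(non-adaptive) taper weighting.  The estimate is a one-sided density in
µV²/Hz, Parseval-consistent with the epoch variance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import windows

from neuromodml.errors import DataError
from neuromodml.synthetic import EEGRecording


@dataclass(frozen=True)
class BandDefinition:
    name: str
    lo_hz: float
    hi_hz: float

    def __post_init__(self):
        if not 0 < self.lo_hz < self.hi_hz:
            raise ValueError("band edges must satisfy 0 < lo < hi")


#: The four analysis bands.  Shared edges (4, 8, 12 Hz) belong to both
#: adjacent bands: integration is over closed intervals as printed.
DEFAULT_BANDS = (
    BandDefinition("delta", 1.0, 4.0),
    BandDefinition("theta", 4.0, 8.0),
    BandDefinition("alpha", 8.0, 12.0),
    BandDefinition("beta", 12.0, 20.0),
)


@dataclass
class PSDEstimate:
    freqs: np.ndarray
    power: np.ndarray  # channels x freqs, µV²/Hz
    epoch_id: int

    def __post_init__(self):
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.power = np.asarray(self.power, dtype=float)
        if np.any(np.diff(self.freqs) <= 0):
            raise DataError("frequency grid must be increasing")
        if np.any(self.power < 0):
            raise DataError("PSD must be non-negative")


def multitaper_psd(recording: EEGRecording, epoch_index: int,
                   nw: float = 4.0, n_tapers: int | None = None) -> PSDEstimate:
    """DPSS-taper averaged periodogram of one 10-s epoch, per channel.

    The epoch is demeaned per channel before tapering; the returned
    one-sided density integrates to the demeaned epoch variance.
    """
    if nw <= 0:
        raise ValueError("time-bandwidth product nw must be positive")
    if n_tapers is None:
        n_tapers = int(2 * nw - 1)
    if n_tapers < 1:
        raise ValueError("need at least one taper")
    n = int(round(recording.epoch_len_s * recording.fs))
    n_epochs = recording.data.shape[1] // n
    if not 0 <= epoch_index < n_epochs:
        raise IndexError(f"epoch {epoch_index} out of range (0..{n_epochs - 1})")
    seg = recording.data[:, epoch_index * n:(epoch_index + 1) * n]
    seg = seg - seg.mean(axis=1, keepdims=True)

    tapers = windows.dpss(n, nw, Kmax=n_tapers)  # each taper has unit energy
    # channels x tapers x freqs
    spec = np.fft.rfft(seg[:, None, :] * tapers[None, :, :], axis=-1)
    psd = (np.abs(spec) ** 2).mean(axis=1)
    freqs = np.fft.rfftfreq(n, d=1.0 / recording.fs)
    # one-sided density scaling
    psd /= recording.fs
    scale = np.full(freqs.shape, 2.0)
    scale[0] = 1.0
    if n % 2 == 0:
        scale[-1] = 1.0
    psd *= scale
    return PSDEstimate(freqs, psd, epoch_index)


def band_power(psd: PSDEstimate, band: BandDefinition) -> np.ndarray:
    """Area under the PSD between the band edges (inclusive), per channel."""
    if band.lo_hz < psd.freqs[0] or band.hi_hz > psd.freqs[-1]:
        raise ValueError(f"band {band.name} outside the PSD frequency grid")
    mask = (psd.freqs >= band.lo_hz) & (psd.freqs <= band.hi_hz)
    if mask.sum() < 2:
        raise ValueError(f"band {band.name} covers fewer than 2 grid points")
    return np.trapezoid(psd.power[:, mask], psd.freqs[mask], axis=1)


def band_power_table(recording: EEGRecording, bands=DEFAULT_BANDS,
                     nw: float = 4.0, n_tapers: int | None = None) -> pd.Series:
    """Epoch-averaged band powers: one feature per (band, channel).

    Epochs are consecutive non-overlapping 10-s windows from t = 0; features
    are named ``pow_<band>_<channel>``.
    """
    n = int(round(recording.epoch_len_s * recording.fs))
    n_epochs = recording.data.shape[1] // n
    if n_epochs < 1:
        raise DataError("recording shorter than one epoch")
    acc = None
    for e in range(n_epochs):
        psd = multitaper_psd(recording, e, nw=nw, n_tapers=n_tapers)
        vals = np.stack([band_power(psd, b) for b in bands])  # bands x channels
        acc = vals if acc is None else acc + vals
    acc /= n_epochs
    index, values = [], []
    for bi, b in enumerate(bands):
        for ci, ch in enumerate(recording.channel_labels):
            index.append(f"pow_{b.name}_{ch}")
            values.append(acc[bi, ci])
    return pd.Series(values, index=index, name="band_power")
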