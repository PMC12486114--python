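"""Temporal-complexity battery for resting-state EEG.

Eighteen measures per channel: six single-scale measures (approximate
entropy, sample entropy, permutation entropy with embedding dimension 3,
distribution entropy, increment entropy and Lempel-Ziv complexity) and
twelve multiscale complexity indices (permutation entropy with embedding
dimensions 2 and 3, sample entropy and distribution entropy, each under
coarse-graining, time-shifted and composite multiscale procedures).  A
multiscale complexity index is the area under the entropy-versus-scale
curve over temporal scales 1..20.

Parameter defaults (all configurable): ApEn/SampEn m = 2, r = 0.2 x SD;
DistEn m = 2, 512 histogram bins; IncrEn m = 2, resolution R = 4;
permutation-entropy ties broken by order of occurrence (stable ranking).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from scipy.spatial.distance import cdist, pdist

from neuromodml.errors import DataError
from neuromodml.synthetic import EEGRecording

DEFAULT_SCALES = tuple(range(1, 21))

# Above this length, Chebyshev neighbour counting switches from a dense
# distance matrix to a KD-tree.
_KDTREE_THRESHOLD = 1200


def _embed(x: np.ndarray, m: int) -> np.ndarray:
    """All length-m delay vectors of x (delay 1), shape (n - m + 1, m)."""
    x = np.asarray(x, dtype=float)
    n = x.size
    if n < m:
        raise DataError(f"series of length {n} too short for embedding m={m}")
    return np.lib.stride_tricks.sliding_window_view(x, m)


def _chebyshev_counts(emb: np.ndarray, r: float) -> np.ndarray:
    """Per-template count of templates within Chebyshev distance r (self included)."""
    n = emb.shape[0]
    if n <= _KDTREE_THRESHOLD:
        d = np.max(np.abs(emb[:, None, :] - emb[None, :, :]), axis=-1)
        return (d <= r).sum(axis=1)
    tree = cKDTree(emb)
    return np.asarray(tree.query_ball_point(emb, r, p=np.inf, return_length=True))


def approximate_entropy(x, m: int = 2, r_frac: float = 0.2) -> float:
    """Pincus approximate entropy Phi(m) - Phi(m+1), self-matches included."""
    x = np.asarray(x, dtype=float)
    if x.size < m + 2:
        raise DataError("series too short for ApEn")
    r = r_frac * x.std()
    if r == 0:
        warnings.warn("constant series: ApEn degenerates to 0", stacklevel=2)
        return 0.0

    def phi(mm):
        emb = _embed(x, mm)
        c = _chebyshev_counts(emb, r) / emb.shape[0]
        return np.mean(np.log(c))

    return float(phi(m) - phi(m + 1))


def sample_entropy(x, m: int = 2, r_frac: float = 0.2,
                   r: float | None = None) -> float:
    """Sample entropy -ln(A/B), self-matches excluded.

    A and B are the numbers of (m+1)- and m-template pairs within r; both
    are counted over the first n - m templates.  The tolerance defaults to
    ``r_frac`` times the SD of ``x``; an absolute ``r`` overrides it (used
    by the multiscale procedures, which keep r fixed at the scale-1 value).
    Returns +inf when A = 0.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    if n < m + 2:
        raise DataError("series too short for SampEn")
    if r is None:
        r = r_frac * x.std()
    emb_m = _embed(x, m)[:n - m]        # n - m templates of length m
    emb_m1 = _embed(x, m + 1)           # n - m templates of length m + 1

    def pair_count(emb):
        # number of template pairs i < j within r (Chebyshev)
        if emb.shape[0] <= _KDTREE_THRESHOLD:
            c = _chebyshev_counts(emb, r)
            return (c.sum() - len(c)) / 2.0
        tree = cKDTree(np.ascontiguousarray(emb))
        total = tree.count_neighbors(tree, r, p=np.inf)  # ordered pairs + self
        return (total - emb.shape[0]) / 2.0

    b = pair_count(emb_m)
    a = pair_count(emb_m1)
    if b == 0:
        warnings.warn("no m-template matches: SampEn undefined", stacklevel=2)
        return float("inf")
    if a == 0:
        warnings.warn("no (m+1)-template matches: SampEn infinite", stacklevel=2)
        return float("inf")
    return float(-np.log(a / b))


def permutation_entropy(x, m: int = 3) -> float:
    """Normalized permutation entropy in [0, 1].

    Shannon entropy of ordinal-pattern frequencies divided by ln(m!); ties
    are broken by order of occurrence (stable sort).
    """
    x = np.asarray(x, dtype=float)
    if x.size < m:
        raise DataError("series too short for PermEn")
    emb = _embed(x, m)
    patterns = np.argsort(emb, axis=1, kind="stable")
    codes = patterns @ (m ** np.arange(m))
    _, counts = np.unique(codes, return_counts=True)
    p = counts / counts.sum()
    h = -np.sum(p * np.log(p))
    return float(h / math.log(math.factorial(m)))


def distribution_entropy(x, m: int = 2, n_bins: int = 512) -> float:
    """Distribution entropy in [0, 1].

    Base-2 Shannon entropy, normalized by log2(n_bins), of the histogram of
    all pairwise Chebyshev distances between length-m embedding vectors.
    """
    x = np.asarray(x, dtype=float)
    emb = np.ascontiguousarray(_embed(x, m))
    n = emb.shape[0]
    if n < 2:
        raise DataError("need at least 2 embedding vectors for DistEn")
    if n <= 6000:
        d = pdist(emb, metric="chebyshev")
        dmax = float(d.max())
        if dmax == 0.0:
            return 0.0
        hist = np.histogram(d, bins=n_bins, range=(0.0, dmax))[0].astype(float)
    else:
        # two-pass chunked upper-triangle accumulation to bound memory
        chunk = 2000
        dmax = 0.0
        for i0 in range(0, n - 1, chunk):
            blk = cdist(emb[i0:i0 + chunk], emb[i0 + 1:], metric="chebyshev")
            for ii in range(blk.shape[0]):
                row = blk[ii, i0 + ii + 1 - (i0 + 1):]
                if row.size:
                    dmax = max(dmax, float(row.max()))
        if dmax == 0.0:
            return 0.0
        hist = np.zeros(n_bins)
        edges = np.linspace(0.0, dmax, n_bins + 1)
        for i0 in range(0, n - 1, chunk):
            blk = cdist(emb[i0:i0 + chunk], emb[i0 + 1:], metric="chebyshev")
            for ii in range(blk.shape[0]):
                row = blk[ii, i0 + ii + 1 - (i0 + 1):]
                if row.size:
                    hist += np.histogram(row, bins=edges)[0]
    p = hist / hist.sum()
    p = p[p > 0]
    return float(-np.sum(p * np.log2(p)) / np.log2(n_bins))


def increment_entropy(x, m: int = 2, resolution: int = 4) -> float:
    """Increment entropy: entropy of sign-and-magnitude quantized increments.

    Each consecutive increment is mapped to a (sign, magnitude) symbol with
    the magnitude quantized against the SD of the increment series and
    bounded by the resolution R; words are m consecutive symbols.  The
    base-2 word entropy is normalized by m*log2(2(R+1)).
    """
    if resolution < 1:
        raise ValueError("resolution R must be >= 1")
    x = np.asarray(x, dtype=float)
    if x.size < m + 1:
        raise DataError("series too short for IncrEn")
    v = np.diff(x)
    sd = v.std()
    s = np.sign(v).astype(int)
    if sd == 0:
        q = np.zeros_like(s)
    else:
        q = np.minimum(np.floor(resolution * np.abs(v) / sd), resolution).astype(int)
    symbols = (s + 1) * (resolution + 1) + q
    if symbols.size < m:
        raise DataError("not enough increments to form a word")
    words = np.lib.stride_tricks.sliding_window_view(symbols, m)
    base = 3 * (resolution + 1)
    codes = words @ (base ** np.arange(m))
    _, counts = np.unique(codes, return_counts=True)
    p = counts / counts.sum()
    h = -np.sum(p * np.log2(p))
    return float(h / (m * np.log2(2.0 * (resolution + 1))))


def _lz76_phrases(bits: np.ndarray) -> int:
    """Number of phrases in the Lempel-Ziv (1976) exhaustive parsing."""
    s = bits.tolist()
    n = len(s)
    i, k, l = 0, 1, 1
    k_max = 1
    c = 1
    while True:
        if s[i + k - 1] == s[l + k - 1]:
            k += 1
            if l + k > n:
                c += 1
                break
        else:
            k_max = max(k, k_max)
            i += 1
            if i == l:
                c += 1
                l += k_max
                if l + 1 > n:
                    break
                i = 0
                k = 1
                k_max = 1
            else:
                k = 1
    return c


def lempel_ziv(x, binarize: str = "median") -> float:
    """Normalized Lempel-Ziv (LZ76) complexity of the binarized series.

    The series is binarized about its median (values strictly above map to
    1); the phrase count is normalized by n / log2(n), so i.i.d. binary
    noise is close to 1.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    if n < 2:
        raise DataError("series too short for LZC")
    if binarize != "median":
        raise ValueError(f"unknown binarize rule {binarize!r}")
    bits = (x > np.median(x)).astype(np.int8)
    c = _lz76_phrases(bits)
    return float(c / (n / np.log2(n)))


def coarse_grain(x, scale: int, offset: int = 0) -> np.ndarray:
    """Non-overlapping window means at the given scale, starting at offset."""
    if scale < 1:
        raise ValueError("scale must be >= 1")
    x = np.asarray(x, dtype=float)
    if scale > x.size:
        raise DataError("scale exceeds series length")
    if not 0 <= offset < scale:
        raise ValueError("offset must be in [0, scale)")
    y = x[offset:]
    k = y.size // scale
    if k == 0:
        raise DataError("no complete window at this scale/offset")
    return y[:k * scale].reshape(k, scale).mean(axis=1)


def multiscale_entropy_curve(x, entropy_fn, procedure: str = "coarse",
                             scales=DEFAULT_SCALES) -> np.ndarray:
    """Entropy as a function of temporal scale under one of three procedures.

    coarse     entropy of the offset-0 coarse-grained series
    composite  mean entropy over all tau coarse-graining offsets
    shifted    mean entropy over the tau lag-subsampled subsequences
    """
    if procedure not in ("coarse", "shifted", "composite"):
        raise ValueError(f"unknown multiscale procedure {procedure!r}")
    x = np.asarray(x, dtype=float)
    values = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for tau in scales:
            if procedure == "coarse":
                v = entropy_fn(coarse_grain(x, tau, 0))
            elif procedure == "composite":
                v = float(np.mean([entropy_fn(coarse_grain(x, tau, o))
                                   for o in range(tau)]))
            else:
                v = float(np.mean([entropy_fn(x[o::tau]) for o in range(tau)]))
            values.append(v)
    return np.asarray(values, dtype=float)


def complexity_index(curve, scales=None) -> float:
    """Area under the entropy-versus-scale curve (trapezoidal).

    Non-finite curve values propagate to a non-finite index.
    """
    curve = np.asarray(curve, dtype=float)
    if scales is None:
        scales = np.arange(1, curve.size + 1)
    scales = np.asarray(scales, dtype=float)
    if not np.all(np.isfinite(curve)):
        return float("nan")
    return float(np.trapezoid(curve, scales))


# ---------------------------------------------------------------------------
# Battery definition
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ComplexityMeasureSpec:
    """One entry of the complexity battery."""

    name: str
    family: str          # ApEn | SampEn | PermEn | DistEn | IncrEn | LZC
    m: int | None
    multiscale: str      # none | coarse | shifted | composite

    def entropy_fn(self, r_abs: float | None = None):
        fam = self.family
        if fam == "ApEn":
            return lambda s: approximate_entropy(s, m=self.m)
        if fam == "SampEn":
            if r_abs is not None:
                return lambda s: sample_entropy(s, m=self.m, r=r_abs)
            return lambda s: sample_entropy(s, m=self.m)
        if fam == "PermEn":
            return lambda s: permutation_entropy(s, m=self.m)
        if fam == "DistEn":
            return lambda s: distribution_entropy(s, m=self.m)
        if fam == "IncrEn":
            return lambda s: increment_entropy(s, m=self.m)
        if fam == "LZC":
            return lambda s: lempel_ziv(s)
        raise ValueError(f"unknown family {fam!r}")

    def compute(self, x, scales=DEFAULT_SCALES) -> float:
        x = np.asarray(x, dtype=float)
        if self.multiscale == "none":
            return float(self.entropy_fn()(x))
        # multiscale SampEn keeps the tolerance fixed at 0.2 x SD of the
        # scale-1 series, so coarse-graining genuinely reduces entropy for
        # uncorrelated noise
        r_abs = 0.2 * x.std() if self.family == "SampEn" else None
        fn = self.entropy_fn(r_abs)
        curve = multiscale_entropy_curve(x, fn, self.multiscale, scales)
        return complexity_index(curve, np.asarray(scales, dtype=float))


def default_battery() -> tuple:
    """The 18-measure battery: 6 single-scale + 12 multiscale indices."""
    single = (
        ComplexityMeasureSpec("apen_m2", "ApEn", 2, "none"),
        ComplexityMeasureSpec("sampen_m2", "SampEn", 2, "none"),
        ComplexityMeasureSpec("permen_m3", "PermEn", 3, "none"),
        ComplexityMeasureSpec("disten_m2", "DistEn", 2, "none"),
        ComplexityMeasureSpec("incren_m2", "IncrEn", 2, "none"),
        ComplexityMeasureSpec("lzc", "LZC", None, "none"),
    )
    multi = tuple(
        ComplexityMeasureSpec(f"{fam.lower()}_m{m}_{proc}", fam, m, proc)
        for fam, m in (("PermEn", 2), ("PermEn", 3), ("SampEn", 2), ("DistEn", 2))
        for proc in ("coarse", "shifted", "composite")
    )
    return single + multi


def battery_manifest(measures=None) -> list:
    """JSON-serializable description of the battery."""
    measures = default_battery() if measures is None else measures
    return [{"name": s.name, "family": s.family, "m": s.m,
             "multiscale": s.multiscale} for s in measures]


def complexity_battery(recording: EEGRecording, measures=None,
                       channels=None, scales=DEFAULT_SCALES,
                       segment_s: float = 60.0) -> pd.Series:
    """All complexity measures per channel from the first minute of EEG.

    The first six 10-s epochs are concatenated and each measure is computed
    once on the 60-s series.  Features are named ``cx_<measure>_<channel>``.
    """
    if recording.duration_s < segment_s:
        raise DataError(f"recording shorter than {segment_s} s")
    measures = default_battery() if measures is None else tuple(measures)
    if channels is None:
        channels = recording.channel_labels
    n = int(round(segment_s * recording.fs))
    index, values = [], []
    for ch in channels:
        x = recording.data[recording.channel_index(ch), :n]
        for spec in measures:
            index.append(f"cx_{spec.name}_{ch}")
            values.append(spec.compute(x, scales))
    return pd.Series(values, index=index, name="complexity")
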