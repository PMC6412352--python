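"""Per-window feature extraction: 18 descriptors per channel, 36 in all.

Each detrended window of steering angle and steering velocity yields
12 time-domain features (range, sample SD, energy, zero-crossing rate,
quartiles, Katz fractal dimension, skewness, kurtosis, sample entropy,
Shannon entropy) and 6 frequency-domain features from a Hann-tapered
one-sided periodogram (spectral variance, spectral entropy, spectral
flux, spectral centroid, dominant frequency, mean PSD).

Feature names follow the ``I01a``..``I18a`` / ``I01v``..``I18v`` scheme,
where the trailing letter marks the source channel (angle / velocity).
Features are min-max normalized to [0, 1] with bounds learned on the
training windows only.

Conventions fixed here (the one-line textbook definitions admit several):
sample entropy uses m=2, tolerance r = 0.2 x window SD, Chebyshev distance,
self-matches excluded; Shannon entropy uses a 16-bin equal-width histogram
of the window; kurtosis is the non-excess m4/m2^2; spectral flux is the
squared L1-normalized magnitude-spectrum difference between a window and
its predecessor in the same recording (zero for a recording's first
window); the dominant frequency excludes the DC bin (windows are
mean-removed, so DC is numerically ~0 but not exactly).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import signal as sps

from .preprocess import DROPPED, WindowSegment

__all__ = [
    "FEATURE_NAMES",
    "N_FEATURES",
    "FeatureMatrix",
    "MinMaxNormalizer",
    "extract_window_features",
    "extract_features",
    "fit_normalizer",
    "apply_normalizer",
    "sample_entropy",
    "katz_fractal_dimension",
    "shannon_entropy",
    "zero_crossing_rate",
]

#: Base descriptor order within one channel (I1..I18).
_BASE = [
    "range", "std", "energy", "zcr", "q1", "q2", "q3", "katz_fd",
    "skewness", "kurtosis", "sampen", "shannon_entropy",
    "spec_var", "spec_entropy", "spec_flux", "cgf", "dom_freq", "mean_psd",
]

FEATURE_NAMES: tuple[str, ...] = tuple(
    f"I{i:02d}{ch}" for ch in ("a", "v") for i in range(1, 19)
)
N_FEATURES = len(FEATURE_NAMES)  # 36

_SHEN_BINS = 16


def zero_crossing_rate(x: np.ndarray, fs: float) -> float:
    """Strict sign changes per second of window duration."""
    x = np.asarray(x, float)
    crossings = int(np.count_nonzero(x[:-1] * x[1:] < 0))
    return crossings / (len(x) / fs)


def katz_fractal_dimension(x: np.ndarray) -> float:
    """Katz's waveform complexity index over the unit-index abscissa.

    FD = log10(n-1) / (log10(n-1) + log10(d/L)) with L the total path
    length sum(sqrt(1 + dx^2)) and d the maximal Euclidean excursion from
    the first sample.  A straight line gives exactly 1.
    """
    x = np.asarray(x, float)
    n = len(x)
    if n < 3:
        raise ValueError("Katz FD needs at least 3 samples")
    dx = np.diff(x)
    L = float(np.sum(np.sqrt(1.0 + dx * dx)))
    k = np.arange(1, n, dtype=float)
    d = float(np.sqrt(k * k + (x[1:] - x[0]) ** 2).max())
    log_n = math.log10(n - 1)
    return log_n / (log_n + math.log10(d / L))


def sample_entropy(x: np.ndarray, m: int = 2, r_frac: float = 0.2) -> float:
    """SampEn(m, r = r_frac*SD): -ln(A/B), Chebyshev distance, no self-matches.

    When no template pair matches at either length (A=0 or B=0), or the
    window has zero variance (r=0), the maximum resolvable value
    -ln(2 / ((n-m-1)(n-m))) is returned so the statistic stays finite while
    preserving the regularity ordering.
    """
    x = np.asarray(x, float)
    n = len(x)
    if n < m + 2:
        raise ValueError(f"sample entropy needs at least {m + 2} samples")
    cap = -math.log(2.0 / ((n - m - 1) * (n - m)))
    r = r_frac * float(np.std(x, ddof=1))
    if r <= 0.0:
        return cap
    D = np.abs(x[:, None] - x[None, :])
    nt = n - m  # templates whose (m+1)-extension exists
    dist_m = D[:nt, :nt].copy()
    for offset in range(1, m):
        np.maximum(dist_m, D[offset : offset + nt, offset : offset + nt], out=dist_m)
    dist_m1 = np.maximum(dist_m, D[m : m + nt, m : m + nt])
    iu = np.triu_indices(nt, k=1)
    B = int(np.count_nonzero(dist_m[iu] <= r))
    A = int(np.count_nonzero(dist_m1[iu] <= r))
    if A == 0 or B == 0:
        return cap
    return -math.log(A / B)


def shannon_entropy(x: np.ndarray, n_bins: int = _SHEN_BINS) -> float:
    """Histogram entropy in bits over an equal-width binning of the window."""
    x = np.asarray(x, float)
    if float(x.max()) == float(x.min()):
        return 0.0
    counts, _ = np.histogram(x, bins=n_bins)
    p = counts[counts > 0] / len(x)
    return float(-(p * np.log2(p)).sum())


def _moment_shape(x: np.ndarray) -> tuple[float, float]:
    """(skewness m3/m2^1.5, non-excess kurtosis m4/m2^2); 0 for flat windows."""
    d = x - x.mean()
    m2 = float(np.mean(d**2))
    if m2 == 0.0:
        return 0.0, 0.0
    m3 = float(np.mean(d**3))
    m4 = float(np.mean(d**4))
    return m3 / m2**1.5, m4 / m2**2


def _time_features(x: np.ndarray, fs: float) -> list[float]:
    q1, q2, q3 = np.percentile(x, [25.0, 50.0, 75.0])
    skew, kurt = _moment_shape(x)
    return [
        float(x.max() - x.min()),
        float(np.std(x, ddof=1)),
        float(np.sum(x * x)),
        zero_crossing_rate(x, fs),
        float(q1),
        float(q2),
        float(q3),
        katz_fractal_dimension(x),
        skew,
        kurt,
        sample_entropy(x),
        shannon_entropy(x),
    ]


def _magnitude_spectrum(x: np.ndarray) -> np.ndarray:
    """L1-normalized one-sided Hann-tapered magnitude spectrum."""
    w = sps.get_window("hann", len(x))
    mag = np.abs(np.fft.rfft(x * w))
    s = mag.sum()
    return mag / s if s > 0.0 else mag


def _freq_features(
    x: np.ndarray, fs: float, prev_mag: np.ndarray | None
) -> tuple[list[float], np.ndarray]:
    f, P = sps.periodogram(x, fs=fs, window="hann", detrend=False)
    mag = _magnitude_spectrum(x)
    flux = 0.0 if prev_mag is None else float(np.sum((mag - prev_mag) ** 2))
    total = float(P.sum())
    if total > 0.0:
        p = P / total
        cgf = float((f * p).sum())
        spec_var = float((p * (f - cgf) ** 2).sum())
        nz = p[p > 0]
        spec_ent = float(-(nz * np.log2(nz)).sum())
    else:
        cgf = spec_var = spec_ent = 0.0
    dom_freq = float(f[1:][int(np.argmax(P[1:]))])
    mean_psd = float(P.mean())
    return [spec_var, spec_ent, flux, cgf, dom_freq, mean_psd], mag


def extract_window_features(
    seg: WindowSegment,
    fs: float,
    prev_spectra: tuple[np.ndarray, np.ndarray] | None = None,
    return_spectra: bool = False,
):
    """Feature vector of one window, ordered I01a..I18a, I01v..I18v.

    ``prev_spectra`` carries the previous window's (angle, velocity)
    normalized magnitude spectra for the spectral-flux computation; when
    absent the window is treated as the first of its recording (flux 0).
    With ``return_spectra`` the current spectra are returned as well, to be
    threaded into the next call.
    """
    out: list[float] = []
    spectra: list[np.ndarray] = []
    for ch, x in enumerate((seg.angle_detrended, seg.velocity_detrended)):
        x = np.asarray(x, float)
        if len(x) < 8:
            raise ValueError("windows must have at least 8 samples")
        if not np.all(np.isfinite(x)):
            raise ValueError("window contains NaN or infinite samples")
        prev = prev_spectra[ch] if prev_spectra is not None else None
        tf = _time_features(x, fs)
        ff, mag = _freq_features(x, fs, prev)
        out.extend(tf + ff)
        spectra.append(mag)
    vec = np.asarray(out)
    if return_spectra:
        return vec, (spectra[0], spectra[1])
    return vec


@dataclass
class FeatureMatrix:
    """N windows x 36 features, with names and (optional) norm bounds."""

    X: np.ndarray
    names: tuple[str, ...] = FEATURE_NAMES
    norm_lo: np.ndarray | None = None
    norm_hi: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, float)
        if self.X.ndim != 2 or self.X.shape[1] != len(self.names):
            raise ValueError("X must be (n_windows, n_features) matching names")
        if len(set(self.names)) != len(self.names):
            raise ValueError("feature names must be unique")

    @property
    def n_windows(self) -> int:
        return self.X.shape[0]

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    def to_csv(self, path: str | Path, labels: np.ndarray | None = None) -> None:
        df = pd.DataFrame(self.X, columns=list(self.names))
        if labels is not None:
            df["label"] = np.asarray(labels, int)
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> tuple["FeatureMatrix", np.ndarray | None]:
        df = pd.read_csv(path)
        labels = None
        if "label" in df.columns:
            labels = df.pop("label").to_numpy(int)
        return cls(X=df.to_numpy(float), names=tuple(df.columns)), labels


def extract_features(
    segments: Sequence[WindowSegment], fs: float
) -> tuple[FeatureMatrix, np.ndarray]:
    """Extract features for a recording's window sequence.

    Spectral flux is chained across consecutive windows in the given
    order; windows labelled :data:`~steerwake.preprocess.DROPPED` are then
    excluded from the returned matrix and labels (after chaining, so flux
    still reflects true temporal adjacency).
    """
    rows: list[np.ndarray] = []
    labels: list[int] = []
    prev: tuple[np.ndarray, np.ndarray] | None = None
    for seg in segments:
        vec, prev = extract_window_features(seg, fs, prev, return_spectra=True)
        rows.append(vec)
        labels.append(seg.label)
    keep = [i for i, lab in enumerate(labels) if lab != DROPPED]
    X = np.asarray([rows[i] for i in keep]).reshape(len(keep), N_FEATURES)
    y = np.asarray([labels[i] for i in keep], int)
    return FeatureMatrix(X=X), y


@dataclass(frozen=True)
class MinMaxNormalizer:
    """Per-feature training min/max; constant features are flagged."""

    lo: np.ndarray
    hi: np.ndarray

    @property
    def constant_mask(self) -> np.ndarray:
        return self.hi == self.lo


def fit_normalizer(X: np.ndarray | FeatureMatrix) -> MinMaxNormalizer:
    """Learn per-feature min/max on training windows (needs N >= 2)."""
    if isinstance(X, FeatureMatrix):
        X = X.X
    X = np.asarray(X, float)
    if X.shape[0] < 2:
        raise ValueError("normalizer needs at least 2 training windows")
    return MinMaxNormalizer(lo=X.min(axis=0), hi=X.max(axis=0))


def apply_normalizer(
    X: np.ndarray | FeatureMatrix, norm: MinMaxNormalizer
) -> np.ndarray:
    """(x - lo)/(hi - lo), clipped to [0,1]; constant features map to 0.5."""
    if isinstance(X, FeatureMatrix):
        X = X.X
    X = np.asarray(X, float)
    span = np.where(norm.constant_mask, 1.0, norm.hi - norm.lo)
    out = np.clip((X - norm.lo) / span, 0.0, 1.0)
    if X.ndim == 1:
        out[norm.constant_mask] = 0.5
    else:
        out[:, norm.constant_mask] = 0.5
    return out
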