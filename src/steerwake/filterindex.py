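"""Per-feature filter statistics: Fisher, correlation, T-test, mutual information.

Each of the four indexes scores one feature column against the binary
label independently of any classifier.  The raw indexes live on wildly
different scales (the T statistic grows with sqrt(N), MI is bounded by
1 bit for a binary label), so before fuzzification each index vector is
min-max rescaled across the feature set to [0, 1]; correlation enters by
absolute value since only association strength matters for selection.

Degenerate perfect separators (both class variances zero but means
different) receive a large finite sentinel rather than infinity, which
rescaling maps to 1.0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "CAP_SENTINEL",
    "FilterIndexVector",
    "fisher_index",
    "correlation_index",
    "ttest_index",
    "mutual_information_index",
    "compute_indexes",
    "scale_indexes",
]

#: Finite stand-in for an infinite index (zero within-class variance with
#: separated means); min-max rescaling maps it to 1.0.
CAP_SENTINEL = 1e6

#: Default equal-width bin count for the mutual-information estimator.
MI_BINS = 10


def _class_split(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, float)
    y = np.asarray(y, int)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    x0, x1 = x[y == 0], x[y == 1]
    if len(x0) < 2 or len(x1) < 2:
        raise ValueError("both classes need at least 2 samples")
    return x0, x1


def fisher_index(x: np.ndarray, y: np.ndarray) -> float:
    """Fisher score (mu1 - mu0)^2 / (s1^2 + s0^2), sample variances."""
    x0, x1 = _class_split(x, y)
    num = (x1.mean() - x0.mean()) ** 2
    den = x0.var(ddof=1) + x1.var(ddof=1)
    if den == 0.0:
        return CAP_SENTINEL if num > 0.0 else 0.0
    return float(num / den)


def correlation_index(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson correlation of feature and label (point-biserial for binary y).

    The sign is retained here; rescaling for fuzzification uses |R|.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if np.std(x) == 0.0 or np.std(y) == 0.0:
        warnings.warn("zero-variance input; correlation defined as 0", stacklevel=2)
        return 0.0
    return float(np.corrcoef(x, y)[0, 1])


def ttest_index(x: np.ndarray, y: np.ndarray) -> float:
    """Welch T statistic |mu1 - mu0| / sqrt(s1^2/n1 + s0^2/n0)."""
    x0, x1 = _class_split(x, y)
    num = abs(x1.mean() - x0.mean())
    den = np.sqrt(x1.var(ddof=1) / len(x1) + x0.var(ddof=1) / len(x0))
    if den == 0.0:
        return CAP_SENTINEL if num > 0.0 else 0.0
    return float(num / den)


def mutual_information_index(
    x: np.ndarray, y: np.ndarray, n_bins: int = MI_BINS
) -> float:
    """Plug-in mutual information in bits after equal-width binning of x.

    x is discretized into ``n_bins`` equal-width bins over its observed
    range (a constant column carries no information and returns 0);
    empty joint cells contribute nothing.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, int)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    lo, hi = float(x.min()), float(x.max())
    if hi == lo:
        return 0.0
    edges = np.linspace(lo, hi, n_bins + 1)
    xb = np.clip(np.searchsorted(edges, x, side="right") - 1, 0, n_bins - 1)
    n = len(x)
    joint = np.zeros((n_bins, 2))
    for cls in (0, 1):
        counts = np.bincount(xb[y == cls], minlength=n_bins)
        joint[:, cls] = counts
    joint /= n
    px = joint.sum(axis=1, keepdims=True)
    py = joint.sum(axis=0, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = joint * np.log2(joint / (px * py))
    return float(np.nansum(terms))


@dataclass
class FilterIndexVector:
    """Raw per-feature index values plus their [0,1] rescaling."""

    fisher: np.ndarray
    corr: np.ndarray
    ttest: np.ndarray
    mi: np.ndarray

    @property
    def scaled(self) -> np.ndarray:
        """(M, 4) matrix of rescaled indexes in F, R, T, I column order."""
        return scale_indexes(self)

    def to_csv(self, path: str | Path, names: tuple[str, ...] | None = None) -> None:
        M = len(self.fisher)
        scaled = self.scaled
        df = pd.DataFrame(
            {
                "feature": list(names) if names is not None else list(range(M)),
                "fisher": self.fisher,
                "corr": self.corr,
                "ttest": self.ttest,
                "mi": self.mi,
                "fisher01": scaled[:, 0],
                "corr01": scaled[:, 1],
                "ttest01": scaled[:, 2],
                "mi01": scaled[:, 3],
            }
        )
        df.to_csv(path, index=False)


def compute_indexes(
    X: np.ndarray, y: np.ndarray, mi_bins: int = MI_BINS
) -> FilterIndexVector:
    """All four indexes for every column of the (N, M) feature matrix."""
    X = np.asarray(X, float)
    y = np.asarray(y, int)
    cols = range(X.shape[1])
    return FilterIndexVector(
        fisher=np.array([fisher_index(X[:, j], y) for j in cols]),
        corr=np.array([correlation_index(X[:, j], y) for j in cols]),
        ttest=np.array([ttest_index(X[:, j], y) for j in cols]),
        mi=np.array([mutual_information_index(X[:, j], y, mi_bins) for j in cols]),
    )


def _minmax01(v: np.ndarray) -> np.ndarray:
    lo, hi = float(v.min()), float(v.max())
    if hi == lo:
        return np.full_like(v, 0.5)
    return (v - lo) / (hi - lo)


def scale_indexes(v: FilterIndexVector) -> np.ndarray:
    """Rescale each index across the feature set to [0,1]; |R| for correlation.

    Returns an (M, 4) matrix in F, R, T, I column order — the fuzzifier's
    input domain.  An all-equal index vector maps to 0.5 everywhere.
    """
    return np.column_stack(
        [
            _minmax01(v.fisher),
            _minmax01(np.abs(v.corr)),
            _minmax01(v.ttest),
            _minmax01(v.mi),
        ]
    )
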