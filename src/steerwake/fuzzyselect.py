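"""Zero-order Takagi-Sugeno fuzzy system fusing the four filter indexes.

Each feature's four rescaled filter indexes (Fisher, |correlation|,
T-test, mutual information) are fuzzified through three Gaussian
membership functions per input — Low, Medium, High — and routed through
the full 3^4 = 81-rule base.  Every rule carries a singleton consequent
alpha in {0, 0.5, 1}; the system output, the feature's *importance
degree* (ID), is the firing-strength-weighted average of the consequents
using the product t-norm for AND.  Because Gaussians are strictly
positive, the normalizing sum never vanishes and no defuzzification step
is needed.  Features with ID strictly above a threshold (default 0.5)
are selected.

Rule order is the file-format contract: lexicographic over the
(F, R, T, I) antecedent labels with L < M < H, i.e. rule ``l`` has
antecedent levels given by the base-3 digits of ``l`` (F most
significant).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .filterindex import FilterIndexVector, compute_indexes, scale_indexes

__all__ = [
    "N_INPUTS",
    "N_MFS",
    "N_RULES",
    "RULE_ANTECEDENTS",
    "FuzzyParams",
    "SelectionResult",
    "default_params",
    "membership",
    "importance_degree",
    "importance_degrees",
    "select_features",
    "save_params",
    "load_params",
]

N_INPUTS = 4   # F, R, T, I
N_MFS = 3      # Low, Medium, High
N_RULES = N_MFS**N_INPUTS  # 81

#: (81, 4) antecedent level per rule and input; 0=L, 1=M, 2=H,
#: lexicographic with the first input (F) most significant.
RULE_ANTECEDENTS = np.array(
    list(itertools.product(range(N_MFS), repeat=N_INPUTS)), dtype=int
)

#: Consequent grid shared by initializer and PSO decoding.
ALPHA_LEVELS = (0.0, 0.5, 1.0)


@dataclass
class FuzzyParams:
    """Gaussian MF centres/widths (4x3 each) and 81 singleton consequents."""

    c: np.ndarray
    s: np.ndarray
    alpha: np.ndarray

    def __post_init__(self) -> None:
        self.c = np.asarray(self.c, float).reshape(N_INPUTS, N_MFS)
        self.s = np.asarray(self.s, float).reshape(N_INPUTS, N_MFS)
        self.alpha = np.asarray(self.alpha, float).reshape(N_RULES)
        if np.any(self.s <= 0.0):
            raise ValueError("membership widths s must be positive")
        if np.any(np.diff(self.c, axis=1) < 0):
            raise ValueError("MF centres must be ordered L <= M <= H per input")
        if not np.all(np.isin(self.alpha, ALPHA_LEVELS)):
            raise ValueError("consequents must be in {0, 0.5, 1}")


def default_params(s: float = 0.2125) -> FuzzyParams:
    """Initial system: L/M/H Gaussians at 0, 0.5, 1 on the unit domain.

    The shared width 0.2125 makes neighbouring membership functions cross
    near 0.5 membership.  Consequents start from an antecedent-majority
    heuristic — a rule whose antecedents are mostly High asserts high
    importance (alpha=1), mostly Low asserts none (alpha=0), anything
    mixed is neutral (alpha=0.5).  Training is expected to move all of
    these.
    """
    c = np.tile([0.0, 0.5, 1.0], (N_INPUTS, 1))
    widths = np.full((N_INPUTS, N_MFS), float(s))
    n_high = (RULE_ANTECEDENTS == 2).sum(axis=1)
    n_low = (RULE_ANTECEDENTS == 0).sum(axis=1)
    alpha = np.full(N_RULES, 0.5)
    alpha[n_high >= 3] = 1.0
    alpha[n_low >= 3] = 0.0
    return FuzzyParams(c=c, s=widths, alpha=alpha)


def membership(h: float | np.ndarray, c: float, s: float) -> float | np.ndarray:
    """Gaussian membership exp(-((h-c)/s)^2 / 2)."""
    if s <= 0:
        raise ValueError("membership width s must be positive")
    return np.exp(-0.5 * ((h - c) / s) ** 2)


def importance_degrees(scaled: np.ndarray, params: FuzzyParams) -> np.ndarray:
    """Importance degree for each row of an (M, 4) scaled-index matrix.

    ID = sum_l w_l alpha_l / sum_l w_l with w_l the product of the four
    antecedent memberships; the Gaussian MFs keep sum_l w_l > 0 for any
    input, so the ratio is always defined and lies in [min alpha, max alpha].
    """
    scaled = np.clip(np.atleast_2d(np.asarray(scaled, float)), 0.0, 1.0)
    if scaled.shape[1] != N_INPUTS:
        raise ValueError(f"expected {N_INPUTS} inputs per feature")
    # mu[k, j, i]: membership of feature k's input j in MF i
    mu = np.exp(
        -0.5 * ((scaled[:, :, None] - params.c[None]) / params.s[None]) ** 2
    )
    # w[k, l]: product over inputs of the antecedent membership of rule l
    j_idx = np.arange(N_INPUTS)
    w = mu[:, j_idx, RULE_ANTECEDENTS].prod(axis=2)
    return w @ params.alpha / w.sum(axis=1)


def importance_degree(scaled_indexes: np.ndarray, params: FuzzyParams) -> float:
    """ID of a single feature from its 4 scaled filter indexes."""
    return float(importance_degrees(np.asarray(scaled_indexes).reshape(1, 4), params)[0])


@dataclass
class SelectionResult:
    """Per-feature importance degrees and the thresholded selection."""

    importance: np.ndarray
    threshold: float
    selected: np.ndarray  # boolean mask, selected[i] <=> importance[i] > threshold
    indexes: FilterIndexVector | None = None

    @property
    def selected_indices(self) -> np.ndarray:
        return np.flatnonzero(self.selected)

    @property
    def n_selected(self) -> int:
        return int(self.selected.sum())


def select_features(
    X: np.ndarray,
    y: np.ndarray,
    params: FuzzyParams,
    threshold: float = 0.5,
) -> SelectionResult:
    """Full filter-to-selection path for a feature matrix.

    Computes the four filter indexes of every column, rescales them to
    [0,1] across the feature set, evaluates the fuzzy importance degree,
    and selects features with ID strictly above ``threshold``.  An empty
    selection is returned as-is (callers such as the trainer penalize it).
    """
    idx = compute_indexes(X, y)
    importance = importance_degrees(scale_indexes(idx), params)
    return SelectionResult(
        importance=importance,
        threshold=threshold,
        selected=importance > threshold,
        indexes=idx,
    )


def save_params(params: FuzzyParams, path: str | Path) -> None:
    """Serialize to YAML; rule order is the documented lexicographic contract."""
    payload = {
        "c": params.c.tolist(),
        "s": params.s.tolist(),
        "alpha": params.alpha.tolist(),
        "rule_order": "lexicographic over (F,R,T,I) antecedents, L<M<H",
    }
    Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))


def load_params(path: str | Path) -> FuzzyParams:
    payload = yaml.safe_load(Path(path).read_text())
    return FuzzyParams(
        c=np.array(payload["c"]), s=np.array(payload["s"]), alpha=np.array(payload["alpha"])
    )
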