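"""Global-best particle swarm training of the fuzzy selector.

The fuzzy system's 24 Gaussian parameters and 81 singleton consequents
form a 105-dimensional search position.  Consequents are relaxed to
[0, 1] during flight and snapped to the nearest of {0, 0.5, 1} at
decoding; membership centres are re-sorted per input so the L <= M <= H
ordering survives arbitrary moves.  The wrapper objective selects
features on a training split, fits the margin classifier on the
selected columns, and scores half the squared prediction error on a
held-out validation split — for binary labels, half the
misclassification rate.  An empty selection earns a fixed penalty.

The swarm uses the classic velocity rule
``v <- W*v + C1*R1*(pbest - x) + C2*R2*(gbest - x)`` with componentwise
uniform random matrices, box-clamped positions and a velocity clamp
that starts at ``v_clamp_frac`` of the box width and decays
geometrically per iteration (``v_clamp_decay``).  With the high inertia
used here (W=0.95, C1=C2=2) the swarm is variance-divergent under a
constant clamp and would orbit the optimum at the clamp scale forever;
the decaying clamp anneals that orbit so late iterations refine instead
of oscillate.  Set ``v_clamp_decay=1.0`` to recover the constant clamp.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from sklearn.model_selection import train_test_split

from .classeval import SVMConfig, train_classifier
from .filterindex import compute_indexes, scale_indexes
from .fuzzyselect import (
    ALPHA_LEVELS,
    N_INPUTS,
    N_MFS,
    N_RULES,
    FuzzyParams,
    default_params,
    importance_degrees,
    select_features,
)

__all__ = [
    "PSOConfig",
    "SplitConfig",
    "PSOHistory",
    "encode",
    "decode",
    "position_bounds",
    "objective",
    "pso_minimize",
    "optimize",
]

N_POSITION = 2 * N_INPUTS * N_MFS + N_RULES  # 24 + 81 = 105

S_MIN = 0.05  # lower box bound for MF widths; zero-width Gaussians are invalid


@dataclass(frozen=True)
class PSOConfig:
    """Swarm constants; defaults follow the common drowsiness-ANFIS setup."""

    c1: float = 2.0
    c2: float = 2.0
    n_particles: int = 50
    inertia: float = 0.95
    max_iter: int = 100
    v_clamp_frac: float = 0.2
    v_clamp_decay: float = 0.93
    seed: int = 0
    penalty_empty: float = 1.0
    stall_iters: int = 20
    stall_tol: float = 1e-6

    def __post_init__(self) -> None:
        if self.n_particles < 2:
            raise ValueError("need at least 2 particles")
        if self.max_iter <= 0:
            raise ValueError("max_iter must be positive")
        for name in ("c1", "c2", "inertia", "v_clamp_frac", "v_clamp_decay"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass(frozen=True)
class SplitConfig:
    """Stratified train/validation split used by the wrapper objective."""

    val_frac: float = 0.3
    seed: int = 0


@dataclass
class PSOHistory:
    gbest_cost: list[float] = field(default_factory=list)
    n_selected: list[int] = field(default_factory=list)


def position_bounds() -> tuple[np.ndarray, np.ndarray]:
    """Box bounds: centres in [0,1], widths in [S_MIN,1], relaxed alpha in [0,1]."""
    lo = np.concatenate(
        [np.zeros(N_INPUTS * N_MFS), np.full(N_INPUTS * N_MFS, S_MIN), np.zeros(N_RULES)]
    )
    hi = np.ones(N_POSITION)
    return lo, hi


def encode(params: FuzzyParams) -> np.ndarray:
    """Flatten (c, s, alpha) into a swarm position."""
    return np.concatenate([params.c.ravel(), params.s.ravel(), params.alpha])


def decode(position: np.ndarray) -> FuzzyParams:
    """Position -> valid FuzzyParams.

    Each input's centre triple is sorted ascending (L <= M <= H) and each
    relaxed consequent snaps to the nearest of {0, 0.5, 1}, ties toward
    the larger level (cutpoints at 0.25 and 0.75).
    """
    position = np.asarray(position, float)
    if position.shape != (N_POSITION,):
        raise ValueError(f"position must have length {N_POSITION}")
    nc = N_INPUTS * N_MFS
    c = np.sort(position[:nc].reshape(N_INPUTS, N_MFS), axis=1)
    s = np.maximum(position[nc : 2 * nc].reshape(N_INPUTS, N_MFS), S_MIN)
    relaxed = position[2 * nc :]
    alpha = np.where(relaxed >= 0.75, 1.0, np.where(relaxed >= 0.25, 0.5, 0.0))
    return FuzzyParams(c=c, s=s, alpha=alpha)


def objective(
    params: FuzzyParams,
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_val: np.ndarray,
    y_val: np.ndarray,
    threshold: float = 0.5,
    svm_cfg: SVMConfig | None = None,
    penalty_empty: float = 1.0,
) -> float:
    """Wrapper cost: mean over validation samples of (yhat - y)^2 / 2.

    Features are selected on the training split only; the classifier is
    fit on the selected training columns and scored on validation.  For
    binary predictions the cost equals half the misclassification rate,
    so 0 is perfect and 0.5 is a coin flip.  An empty selection (or a
    classifier failure) returns ``penalty_empty``.
    """
    sel = select_features(X_train, y_train, params, threshold)
    if sel.n_selected == 0:
        return penalty_empty
    cols = sel.selected_indices
    try:
        clf = train_classifier(X_train[:, cols], y_train, svm_cfg)
    except ValueError:
        import warnings

        warnings.warn("classifier training failed; returning empty-selection penalty")
        return penalty_empty
    pred = clf.predict(X_val[:, cols])
    return float(np.mean(0.5 * (pred - np.asarray(y_val)) ** 2))


def pso_minimize(
    fun: Callable[[np.ndarray], float],
    lo: np.ndarray,
    hi: np.ndarray,
    cfg: PSOConfig,
    init_position: np.ndarray | None = None,
    track_positions: bool = False,
) -> tuple[np.ndarray, float, list[float]] | tuple[np.ndarray, float, list[float], list[np.ndarray]]:
    """Generic global-best PSO over a box; returns (gbest, cost, trace).

    The gbest cost trace is non-increasing by construction of the
    pbest/gbest updates.  ``init_position`` warm-starts particle 0.
    With ``track_positions`` the per-iteration gbest position is returned
    as a fourth element.  Fully reproducible under ``cfg.seed``.
    """
    rng = np.random.default_rng(cfg.seed)
    lo = np.asarray(lo, float)
    hi = np.asarray(hi, float)
    P = len(lo)
    NP = cfg.n_particles
    pos = lo + (hi - lo) * rng.random((NP, P))
    if init_position is not None:
        pos[0] = np.clip(init_position, lo, hi)
    vel = np.zeros((NP, P))
    vmax0 = cfg.v_clamp_frac * (hi - lo)

    cost = np.array([fun(p) for p in pos])
    pbest = pos.copy()
    pbest_cost = cost.copy()
    g = int(np.argmin(pbest_cost))
    gbest, gbest_cost = pbest[g].copy(), float(pbest_cost[g])

    trace: list[float] = []
    gbest_trace: list[np.ndarray] = []
    stall = 0
    for it in range(cfg.max_iter):
        vmax = vmax0 * cfg.v_clamp_decay**it
        r1 = rng.random((NP, P))
        r2 = rng.random((NP, P))
        vel = (
            cfg.inertia * vel
            + cfg.c1 * r1 * (pbest - pos)
            + cfg.c2 * r2 * (gbest - pos)
        )
        np.clip(vel, -vmax, vmax, out=vel)
        pos = np.clip(pos + vel, lo, hi)
        cost = np.array([fun(p) for p in pos])
        improved = cost < pbest_cost
        pbest[improved] = pos[improved]
        pbest_cost[improved] = cost[improved]
        g = int(np.argmin(pbest_cost))
        if pbest_cost[g] < gbest_cost - cfg.stall_tol:
            stall = 0
        else:
            stall += 1
        if pbest_cost[g] < gbest_cost:
            gbest, gbest_cost = pbest[g].copy(), float(pbest_cost[g])
        trace.append(gbest_cost)
        if track_positions:
            gbest_trace.append(gbest.copy())
        if stall >= cfg.stall_iters:
            break
    if track_positions:
        return gbest, gbest_cost, trace, gbest_trace
    return gbest, gbest_cost, trace


def optimize(
    X: np.ndarray,
    y: np.ndarray,
    pso_cfg: PSOConfig | None = None,
    split_cfg: SplitConfig | None = None,
    threshold: float = 0.5,
    svm_cfg: SVMConfig | None = None,
    presplit: tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray] | None = None,
) -> tuple[FuzzyParams, PSOHistory]:
    """Train the fuzzy selector end to end on a feature matrix.

    Splits the data stratified by label (or uses ``presplit`` =
    ``(X_tr, y_tr, X_val, y_val)`` when the caller manages the split),
    precomputes the scaled filter indexes on the training split (they
    depend on the data only, not on the fuzzy parameters), and searches
    the 105-dimensional parameter box.  Because the cost depends on the particle's position only
    through the selected-feature mask, costs are memoized per mask —
    the expensive SVM fit runs once per distinct subset.  Particle 0 is
    warm-started at the default parameters, so the optimized cost never
    exceeds the default-parameter cost.
    """
    pso_cfg = pso_cfg or PSOConfig()
    split_cfg = split_cfg or SplitConfig()
    X = np.asarray(X, float)
    y = np.asarray(y, int)
    if len(np.unique(y)) < 2:
        raise ValueError("training data must contain both classes")

    if presplit is not None:
        X_tr, y_tr, X_val, y_val = presplit
    else:
        X_tr, X_val, y_tr, y_val = train_test_split(
            X,
            y,
            test_size=split_cfg.val_frac,
            stratify=y,
            random_state=split_cfg.seed,
        )
    scaled = scale_indexes(compute_indexes(X_tr, y_tr))

    mask_cost: dict[bytes, float] = {}

    def cost_of(position: np.ndarray) -> float:
        params = decode(position)
        importance = importance_degrees(scaled, params)
        mask = importance > threshold
        key = np.packbits(mask).tobytes()
        if key in mask_cost:
            return mask_cost[key]
        if not mask.any():
            value = pso_cfg.penalty_empty
        else:
            cols = np.flatnonzero(mask)
            try:
                clf = train_classifier(X_tr[:, cols], y_tr, svm_cfg)
                pred = clf.predict(X_val[:, cols])
                value = float(np.mean(0.5 * (pred - y_val) ** 2))
            except ValueError:
                value = pso_cfg.penalty_empty
        mask_cost[key] = value
        return value

    lo, hi = position_bounds()
    history = PSOHistory()

    gbest, gbest_cost, trace, gbest_positions = pso_minimize(
        cost_of,
        lo,
        hi,
        pso_cfg,
        init_position=encode(default_params()),
        track_positions=True,
    )
    best = decode(gbest)
    history.gbest_cost = trace
    history.n_selected = [
        int((importance_degrees(scaled, decode(p)) > threshold).sum())
        for p in gbest_positions
    ]
    return best, history
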