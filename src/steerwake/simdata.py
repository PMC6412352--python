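"""Synthetic steering-behaviour recordings with planted awake/drowsy structure.

No public driving-simulator corpus with steering angle + Karolinska
Sleepiness Scale (KSS) annotation exists, so this module generates one.
The generator plants the two regimes the drowsiness literature describes:

* **awake** — the driver holds the lane with frequent small corrective
  inputs, so the detrended steering signal flips sign often (high
  zero-crossing rate, small amplitude);
* **drowsy** — steering degrades to slow drift away from the lane centre
  terminated by sparse, large corrective jerks (sawtooth-like, low
  zero-crossing rate, large amplitude).

Both regimes ride on a deterministic sinusoidal "track" component standing
in for road curvature, which downstream windowed detrending removes.  A
monotone KSS step profile ties each sample to a sleepiness level 1-9.

The module also provides an abstract feature-matrix bench with planted
informative columns, used to exercise the selector stack without any
signal processing in the loop.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ScenarioConfig",
    "SignalTrace",
    "generate_trace",
    "generate_feature_bench",
    "default_kss_profile",
]


def default_kss_profile(duration_s: float) -> tuple[tuple[float, int], ...]:
    """Monotone KSS step profile covering both regimes.

    Roughly the first half of the drive is alert (KSS 2-6), a short
    transition sits at KSS 7 (dropped downstream), and the last third is
    drowsy (KSS 8-9) — mimicking an afternoon drive continued until the
    driver is too sleepy to go on.
    """
    T = duration_s
    return (
        (0.00 * T, 2),
        (0.20 * T, 4),
        (0.40 * T, 6),
        (0.55 * T, 7),
        (0.65 * T, 8),
        (0.85 * T, 9),
    )


@dataclass(frozen=True)
class ScenarioConfig:
    """Parameters of one synthetic drive.

    Amplitudes are in degrees of steering-wheel angle, rates in events per
    second.  The drowsy regime must be sparser and larger than the awake
    regime (that asymmetry *is* the planted effect), which is enforced at
    construction.
    """

    duration_s: float = 300.0
    fs: float = 60.0
    track_curve_amp: float = 15.0
    track_curve_period_s: float = 60.0
    awake_correction_rate: float = 4.0
    awake_correction_amp: float = 0.8
    drowsy_correction_rate: float = 0.25
    drowsy_correction_amp: float = 6.0
    drift_rate: float = 1.0
    noise_sd: float = 0.1
    kss_profile: tuple[tuple[float, int], ...] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration_s <= 0 or self.fs <= 0:
            raise ValueError("duration_s and fs must be positive")
        n = self.duration_s * self.fs
        if abs(n - round(n)) > 1e-9:
            raise ValueError(
                f"duration_s*fs = {n} is not an integer sample count"
            )
        if not self.drowsy_correction_rate < self.awake_correction_rate:
            raise ValueError("drowsy corrections must be sparser than awake")
        if not self.drowsy_correction_amp > self.awake_correction_amp:
            raise ValueError("drowsy corrections must be larger than awake")
        for lo, hi, name in (
            (self.noise_sd, None, "noise_sd"),
            (self.awake_correction_amp, None, "awake_correction_amp"),
        ):
            if lo < 0:
                raise ValueError(f"{name} must be nonnegative")
        profile = self.kss_profile
        if profile is not None:
            kss_vals = [k for _, k in profile]
            times = [t for t, _ in profile]
            if any(not 1 <= k <= 9 for k in kss_vals):
                raise ValueError("KSS levels must lie in 1..9")
            if sorted(times) != list(times) or sorted(kss_vals) != list(kss_vals):
                raise ValueError("kss_profile must be monotone in time and level")

    @property
    def n_samples(self) -> int:
        return round(self.duration_s * self.fs)

    def resolved_kss_profile(self) -> tuple[tuple[float, int], ...]:
        if self.kss_profile is not None:
            return tuple(self.kss_profile)
        return default_kss_profile(self.duration_s)


@dataclass
class SignalTrace:
    """A multichannel steering recording on a uniform time grid."""

    t: np.ndarray
    angle: np.ndarray
    velocity: np.ndarray
    kss: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        n = len(self.t)
        if not (len(self.angle) == len(self.velocity) == len(self.kss) == n):
            raise ValueError("all channels must have equal length")
        if np.any((self.kss < 1) | (self.kss > 9)):
            raise ValueError("KSS values must lie in 1..9")

    def __len__(self) -> int:
        return len(self.t)

    def to_csv(self, path: str | Path) -> None:
        """Write as ``time,angle,velocity,kss`` CSV (full float precision)."""
        df = pd.DataFrame(
            {
                "time": self.t,
                "angle": self.angle,
                "velocity": self.velocity,
                "kss": self.kss.astype(int),
            }
        )
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path, fs: float | None = None) -> "SignalTrace":
        """Read a ``time,angle[,velocity],kss`` CSV.

        A missing velocity column is derived by forward differencing of the
        angle channel.  ``fs`` is inferred from the time grid if omitted.
        """
        df = pd.read_csv(path)
        required = {"time", "angle", "kss"}
        if not required <= set(df.columns):
            raise ValueError(f"CSV must have columns {sorted(required)}")
        t = df["time"].to_numpy(float)
        angle = df["angle"].to_numpy(float)
        if fs is None:
            dt = np.diff(t)
            if len(dt) == 0 or not np.allclose(dt, dt[0], rtol=1e-6):
                raise ValueError("cannot infer fs from a non-uniform time grid")
            fs = 1.0 / dt[0]
        if "velocity" in df.columns:
            velocity = df["velocity"].to_numpy(float)
        else:
            velocity = _forward_difference(angle, fs)
        kss = df["kss"].to_numpy(int)
        return cls(t=t, angle=angle, velocity=velocity, kss=kss, fs=float(fs))


def _forward_difference(x: np.ndarray, fs: float) -> np.ndarray:
    """First-order forward difference scaled to units/s; last sample held."""
    v = np.empty_like(x, dtype=float)
    v[:-1] = np.diff(x) * fs
    v[-1] = v[-2] if len(x) > 1 else 0.0
    return v


def _kss_per_sample(cfg: ScenarioConfig) -> np.ndarray:
    t = np.arange(cfg.n_samples) / cfg.fs
    profile = cfg.resolved_kss_profile()
    kss = np.full(cfg.n_samples, profile[0][1], dtype=int)
    for start, level in profile:
        kss[t >= start - 1e-12] = level
    return kss


def generate_trace(cfg: ScenarioConfig) -> SignalTrace:
    """Simulate one drive under ``cfg``.

    The steering angle is the sum of a sinusoidal track-following
    component, a regime-dependent corrective process and white measurement
    noise.  The active regime at each sample follows the KSS trace:
    KSS >= 8 selects the drowsy drift-and-jerk process, anything below
    selects the awake small-correction process.  Regeneration with the same
    config (including seed) is bit-identical.
    """
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_samples
    t = np.arange(n) / cfg.fs
    kss = _kss_per_sample(cfg)

    track = cfg.track_curve_amp * np.sin(
        2.0 * math.pi * t / cfg.track_curve_period_s
    )

    # Corrective process: piecewise-constant re-targeting while awake,
    # linear drift punctuated by large opposing jumps while drowsy.
    p_awake = min(cfg.awake_correction_rate / cfg.fs, 1.0)
    p_drowsy = min(cfg.drowsy_correction_rate / cfg.fs, 1.0)
    events = rng.random(n)
    jitter = rng.uniform(-1.0, 1.0, n)
    corr = np.empty(n)
    e = 0.0
    drift_sign = 1.0
    for k in range(n):
        if kss[k] >= 8:
            e += drift_sign * cfg.drift_rate / cfg.fs
            if events[k] < p_drowsy:
                direction = math.copysign(1.0, e) if e != 0.0 else drift_sign
                e -= direction * cfg.drowsy_correction_amp * (
                    1.0 + 0.25 * jitter[k]
                )
                drift_sign = -math.copysign(1.0, e) if e != 0.0 else -drift_sign
        else:
            if events[k] < p_awake:
                e = cfg.awake_correction_amp * jitter[k]
        corr[k] = e

    noise = cfg.noise_sd * rng.standard_normal(n)
    angle = track + corr + noise
    velocity = _forward_difference(angle, cfg.fs)
    return SignalTrace(t=t, angle=angle, velocity=velocity, kss=kss, fs=cfg.fs)


def generate_feature_bench(
    n_samples: int,
    n_features: int = 36,
    n_informative: int = 5,
    effect_size: float = 2.0,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Abstract selector bench: Gaussian columns, a few shifted by class.

    Returns ``(X, y, informative_idx)``.  Labels are balanced; informative
    columns are N(0,1) under class 0 and N(effect_size,1) under class 1,
    the rest are label-independent N(0,1).  Columns are min-max scaled to
    [0,1], matching the scale the feature normalizer produces.
    """
    if n_informative > n_features:
        raise ValueError("n_informative must not exceed n_features")
    rng = np.random.default_rng(seed)
    y = np.zeros(n_samples, dtype=int)
    y[n_samples // 2 :] = 1
    rng.shuffle(y)
    X = rng.standard_normal((n_samples, n_features))
    informative = np.sort(rng.choice(n_features, size=n_informative, replace=False))
    X[:, informative] += effect_size * y[:, None]
    lo = X.min(axis=0)
    hi = X.max(axis=0)
    span = np.where(hi > lo, hi - lo, 1.0)
    X = (X - lo) / span
    return X, y, informative
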