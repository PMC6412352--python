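"""Windowing, road-curvature removal and KSS label binarization.

Steering angle depends on road geometry: on curves the raw signal is
dominated by track following, not by the driver's lane-keeping behaviour.
The pipeline therefore analyses the signal in short sliding windows and
subtracts each window's own mean from each channel, which removes the
locally near-constant curvature component and leaves the corrective
micro-behaviour that carries the drowsiness signature.

Windows are 3 s (180 samples at 60 Hz) with 50% overlap by default.
Each window receives a binary label from the KSS value at its centre
sample: 1-6 -> awake (0), 8-9 -> drowsy (1), 7 -> dropped (the
ambiguous transition level is excluded from all downstream stages).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .simdata import SignalTrace

__all__ = [
    "DROPPED",
    "WindowSpec",
    "WindowSegment",
    "slide_windows",
    "binarize_kss",
]

#: Sentinel label for windows centred on the excluded KSS level 7.
DROPPED = -1


@dataclass(frozen=True)
class WindowSpec:
    """Sliding-window geometry in samples.

    The default 180/90 corresponds to 3 s windows with 1.5 s overlap at
    60 Hz.  Use :meth:`from_seconds` to resolve a time-based config.
    """

    length_samples: int = 180
    overlap_samples: int = 90
    fs: float = 60.0

    def __post_init__(self) -> None:
        if not 0 <= self.overlap_samples < self.length_samples:
            raise ValueError("require 0 <= overlap_samples < length_samples")
        if self.fs <= 0:
            raise ValueError("fs must be positive")

    @property
    def step(self) -> int:
        return self.length_samples - self.overlap_samples

    @classmethod
    def from_seconds(
        cls, length_s: float = 3.0, overlap_frac: float = 0.5, fs: float = 60.0
    ) -> "WindowSpec":
        """Resolve a time-based window config, requiring exact sample counts."""
        length = length_s * fs
        if abs(length - round(length)) > 1e-9:
            raise ValueError(f"window.length_s*fs = {length} is not an integer")
        length = round(length)
        overlap = overlap_frac * length
        if abs(overlap - round(overlap)) > 1e-9:
            raise ValueError(f"overlap_frac*length = {overlap} is not an integer")
        return cls(length_samples=length, overlap_samples=round(overlap), fs=fs)


@dataclass
class WindowSegment:
    """One detrended analysis window with its binary label.

    ``label`` is 0 (awake), 1 (drowsy) or :data:`DROPPED`.  The window
    mean subtracted during detrending is not retained: only the residual
    corrective behaviour matters downstream.
    """

    index: int
    start_sample: int
    angle_detrended: np.ndarray
    velocity_detrended: np.ndarray
    label: int


def binarize_kss(segment_kss_values: Sequence[int] | np.ndarray) -> int:
    """Label a window from the KSS value at its centre sample.

    KSS 1-6 -> 0 (awake); 8-9 -> 1 (drowsy); 7 -> :data:`DROPPED`.
    """
    values = np.asarray(segment_kss_values)
    if np.any((values < 1) | (values > 9)):
        raise ValueError("KSS values must lie in 1..9")
    center = int(values[len(values) // 2])
    if center <= 6:
        return 0
    if center >= 8:
        return 1
    return DROPPED


def slide_windows(trace: SignalTrace, spec: WindowSpec) -> list[WindowSegment]:
    """Cut a trace into half-open windows ``[start, start+W)`` and detrend.

    Windows start at sample 0 and advance by ``length - overlap``; trailing
    samples that do not fill a whole window are discarded.  Each channel is
    detrended by subtracting its own within-window mean, independently per
    window.  A trace shorter than one window yields an empty list with a
    warning rather than an error.
    """
    n = len(trace)
    W = spec.length_samples
    if n < W:
        warnings.warn(
            f"trace of {n} samples is shorter than one {W}-sample window; "
            "no windows emitted",
            stacklevel=2,
        )
        return []
    segments: list[WindowSegment] = []
    for index, start in enumerate(range(0, n - W + 1, spec.step)):
        sl = slice(start, start + W)
        angle = trace.angle[sl]
        velocity = trace.velocity[sl]
        label = binarize_kss(trace.kss[sl])
        segments.append(
            WindowSegment(
                index=index,
                start_sample=start,
                angle_detrended=angle - angle.mean(),
                velocity_detrended=velocity - velocity.mean(),
                label=label,
            )
        )
    return segments
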