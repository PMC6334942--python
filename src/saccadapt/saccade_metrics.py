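"""Velocity-threshold saccade detection and kinematic metrics.

Implements the median-based velocity-threshold detector of Engbert &
Mergenthaler: eye velocity is estimated with a 5-sample moving-window
differentiator, a robust (median-based) velocity standard deviation sets
per-component thresholds η = λ·σ, and saccades are maximal runs of samples
outside the elliptic threshold (v_x/η_x)² + (v_y/η_y)² > 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "GazeRecording",
    "SaccadeEvent",
    "DegenerateTraceError",
    "compute_velocity",
    "robust_velocity_std",
    "detect_saccades",
    "saccade_latency",
]


class DegenerateTraceError(ValueError):
    """Raised when the robust velocity spread is zero and no threshold exists."""


@dataclass(frozen=True)
class GazeRecording:
    """Uniformly sampled monocular eye-position trace for one trial.

    Attributes
    ----------
    t_ms : ndarray
        Sample times in ms, strictly increasing with constant step
        1000/sample_rate.
    x, y : ndarray
        Gaze position in dva; may be NaN where ``valid`` is False
        (blinks / tracking loss).
    valid : ndarray of bool
    sample_rate : float
        In Hz (default 1000).
    """

    t_ms: np.ndarray
    x: np.ndarray
    y: np.ndarray
    valid: np.ndarray
    sample_rate: float = 1000.0

    def __post_init__(self) -> None:
        n = len(self.t_ms)
        if not (len(self.x) == len(self.y) == len(self.valid) == n):
            raise ValueError("all sample arrays must have equal length")
        if n >= 2:
            steps = np.diff(self.t_ms)
            expected = 1000.0 / self.sample_rate
            if np.any(steps <= 0) or np.max(np.abs(steps - expected)) > 1e-3:
                raise ValueError("t_ms must increase in constant steps of 1000/sample_rate")
        if np.any(~np.isfinite(self.x[self.valid])) or np.any(~np.isfinite(self.y[self.valid])):
            raise ValueError("x and y must be finite wherever valid")

    def __len__(self) -> int:
        return len(self.t_ms)

    @property
    def dt_ms(self) -> float:
        return 1000.0 / self.sample_rate


@dataclass(frozen=True)
class SaccadeEvent:
    """One detected saccade with its kinematic metrics."""

    onset_ms: float
    offset_ms: float
    amplitude: float  # dva, Euclidean start -> end
    peak_velocity: float  # deg/s
    duration: float  # ms, offset - onset
    start_pos: tuple[float, float]
    end_pos: tuple[float, float]
    latency: float = np.nan  # ms relative to the go signal; set per trial


def compute_velocity(trace: GazeRecording) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Eye velocity via the 5-sample moving-window differentiator.

    v(i) = (p(i+2) + p(i+1) − p(i−1) − p(i−2)) / (6·Δt) per component, in
    deg/s; edge samples are filled with the nearest interior value.  Samples
    within two positions of an invalid sample yield NaN.

    Returns ``(vx, vy, speed)`` with ``speed`` the Euclidean magnitude.
    """
    n = len(trace)
    if n < 5:
        raise ValueError("velocity estimation requires at least 5 samples")
    dt_s = trace.dt_ms / 1000.0
    x = np.where(trace.valid, trace.x, np.nan)
    y = np.where(trace.valid, trace.y, np.nan)

    def stencil(p: np.ndarray) -> np.ndarray:
        v = np.full(n, np.nan)
        v[2:-2] = (p[4:] + p[3:-1] - p[1:-3] - p[:-4]) / (6.0 * dt_s)
        v[0] = v[1] = v[2]
        v[-1] = v[-2] = v[-3]
        return v

    vx = stencil(x)
    vy = stencil(y)
    return vx, vy, np.hypot(vx, vy)


def robust_velocity_std(v) -> float:
    """Median-based estimate of the velocity standard deviation.

    σ = sqrt( median(v²) − median(v)² ), ignoring NaN samples.  Returns 0.0
    for all-identical input (the detection threshold is then undefined and
    must be handled by the caller).
    """
    v = np.asarray(v, dtype=float)
    v = v[np.isfinite(v)]
    if v.size < 2:
        raise ValueError("robust std requires at least 2 finite samples")
    var = np.median(v**2) - np.median(v) ** 2
    return float(np.sqrt(max(var, 0.0)))


def _threshold_runs(crit: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True as inclusive (start, stop) index pairs."""
    idx = np.flatnonzero(crit)
    if idx.size == 0:
        return []
    breaks = np.flatnonzero(np.diff(idx) > 1)
    starts = np.concatenate(([0], breaks + 1))
    stops = np.concatenate((breaks, [idx.size - 1]))
    return [(int(idx[a]), int(idx[b])) for a, b in zip(starts, stops)]


def detect_saccades(
    trace: GazeRecording,
    lambda_thresh: float = 6.0,
    min_duration_ms: float = 6.0,
    merge_gap_ms: float = 20.0,
) -> list[SaccadeEvent]:
    """Detect saccades with the median velocity-threshold algorithm.

    A candidate saccade is a maximal run of samples with
    (v_x/η_x)² + (v_y/η_y)² > 1 where η = λ·σ per component; runs separated
    by less than ``merge_gap_ms`` are merged, and merged runs spanning fewer
    than ``min_duration_ms`` worth of samples are discarded.  Detection is
    never attempted across invalid (blink) samples.

    Returns events sorted by onset, with amplitude (Euclidean start→end
    displacement), peak velocity and duration attached.

    Raises
    ------
    DegenerateTraceError
        If either component's robust velocity spread is zero.
    """
    vx, vy, _ = compute_velocity(trace)
    sx = robust_velocity_std(vx)
    sy = robust_velocity_std(vy)
    if sx == 0.0 or sy == 0.0:
        raise DegenerateTraceError(
            "robust velocity spread is zero; threshold undefined for this trace"
        )
    eta_x = lambda_thresh * sx
    eta_y = lambda_thresh * sy
    with np.errstate(invalid="ignore"):
        crit = (vx / eta_x) ** 2 + (vy / eta_y) ** 2 > 1.0
    crit &= np.isfinite(vx) & np.isfinite(vy)

    runs = _threshold_runs(crit)
    # merge runs separated by less than the merge gap
    merged: list[tuple[int, int]] = []
    for start, stop in runs:
        if merged and (trace.t_ms[start] - trace.t_ms[merged[-1][1]]) < merge_gap_ms:
            merged[-1] = (merged[-1][0], stop)
        else:
            merged.append((start, stop))

    min_samples = int(np.ceil(min_duration_ms * trace.sample_rate / 1000.0))
    events = []
    for start, stop in merged:
        if stop - start + 1 < min_samples:
            continue
        speed = np.hypot(vx[start : stop + 1], vy[start : stop + 1])
        x0, y0 = trace.x[start], trace.y[start]
        x1, y1 = trace.x[stop], trace.y[stop]
        events.append(
            SaccadeEvent(
                onset_ms=float(trace.t_ms[start]),
                offset_ms=float(trace.t_ms[stop]),
                amplitude=float(np.hypot(x1 - x0, y1 - y0)),
                peak_velocity=float(np.nanmax(speed)),
                duration=float(trace.t_ms[stop] - trace.t_ms[start]),
                start_pos=(float(x0), float(y0)),
                end_pos=(float(x1), float(y1)),
            )
        )
    return events


def saccade_latency(event: SaccadeEvent, go_signal_ms: float) -> float:
    """Saccade latency: onset relative to the go signal (flash onset), in ms.

    Negative latencies indicate anticipatory saccades; they are returned
    as-is (and flagged with a warning) so that downstream QC can act on
    them.
    """
    if go_signal_ms is None or not np.isfinite(go_signal_ms):
        raise ValueError("go-signal time is missing")
    latency = float(event.onset_ms - go_signal_ms)
    if latency < 0:
        warnings.warn(f"anticipatory saccade: latency {latency:.1f} ms", stacklevel=2)
    return latency
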