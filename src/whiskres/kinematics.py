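"""Whisker-angle filtering, event detection, and kinematics.

The whisker signal is the mean angle of all trackable whiskers, one sample
per video frame (1 kHz).  After a 30 Hz zero-phase Butterworth low-pass,
protractions (angle increases) and retractions (angle decreases) are read
off the local extrema of the trace: every consecutive extremum pair with an
excursion of at least 4 degrees is one movement event.  Brief sub-threshold
wiggles are merged into the surrounding sweep before events are emitted, so
contiguous events alternate in kind.  Events in turn define periods of
movement (events closer than one merge gap are one period) and carry
per-event kinematics (amplitude, duration, peak velocity).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import signal as _signal

__all__ = [
    "AngleTrace",
    "MovementEvent",
    "lowpass_angle",
    "detect_movements",
    "movement_periods",
    "event_kinematics",
    "count_cycles",
]


@dataclass(frozen=True)
class AngleTrace:
    """Uniformly sampled whisker angle in degrees."""

    values_deg: np.ndarray
    fs_hz: float = 1000.0
    lowpass_hz: float | None = None  # cutoff applied, if any

    def __post_init__(self) -> None:
        values = np.asarray(self.values_deg, dtype=float)
        object.__setattr__(self, "values_deg", values)
        if values.ndim != 1:
            raise ValueError("angle trace must be one-dimensional")
        if not np.all(np.isfinite(values)):
            raise ValueError("angle trace contains non-finite values")
        if self.fs_hz <= 0:
            raise ValueError("sampling rate must be positive")

    def __len__(self) -> int:
        return len(self.values_deg)

    @property
    def duration_ms(self) -> float:
        return len(self.values_deg) * 1000.0 / self.fs_hz


@dataclass(frozen=True)
class MovementEvent:
    """One protraction or retraction.

    ``start_idx``/``end_idx`` are 0-based sample indices of the bounding
    extrema (half-open span); amplitude is the absolute angle change between
    them; velocity is the largest per-sample angle step, in deg/ms.
    """

    kind: str  # "protraction" | "retraction"
    start_idx: int
    end_idx: int
    amplitude_deg: float
    duration_ms: float
    max_velocity_deg_per_ms: float

    def __post_init__(self) -> None:
        if self.kind not in ("protraction", "retraction"):
            raise ValueError(f"unknown event kind {self.kind!r}")
        if self.end_idx <= self.start_idx:
            raise ValueError("event must span at least one sample")


def lowpass_angle(trace: AngleTrace, cutoff_hz: float = 30.0, order: int = 4) -> AngleTrace:
    """Zero-phase Butterworth low-pass (default 30 Hz) of a whisker trace."""
    if not (0 < cutoff_hz < trace.fs_hz / 2):
        raise ValueError(f"cutoff {cutoff_hz} Hz invalid at fs={trace.fs_hz} Hz")
    sos = _signal.butter(order, cutoff_hz, btype="lowpass", fs=trace.fs_hz, output="sos")
    values = _signal.sosfiltfilt(sos, trace.values_deg)
    return AngleTrace(values_deg=values, fs_hz=trace.fs_hz, lowpass_hz=cutoff_hz)


def _turning_points(x: np.ndarray) -> list[int]:
    """Indices of local extrema of ``x``, endpoints included.

    Plateaus (runs of equal consecutive values) are resolved to their
    midpoint, except at the trace ends where the first/last sample stands in.
    """
    n = len(x)
    if n < 2:
        return []
    # compress runs of equal values to a single representative index
    change = np.flatnonzero(np.diff(x) != 0)
    if change.size == 0:
        return []
    starts = np.concatenate(([0], change + 1))          # run start indices
    ends = np.concatenate((change, [n - 1]))            # run end indices
    reps = (starts + ends) // 2
    # a flat lead/tail is represented by its sample nearest the motion
    reps[0], reps[-1] = ends[0], starts[-1]
    vals = x[reps]
    keep = [0]
    for i in range(1, len(reps) - 1):
        if (vals[i] - vals[i - 1]) * (vals[i + 1] - vals[i]) < 0:
            keep.append(i)
    keep.append(len(reps) - 1)
    return [int(reps[i]) for i in keep]


def _prune_extrema(
    idx: list[int], x: np.ndarray, threshold: float, max_span: int
) -> list[int]:
    """Merge sub-threshold wiggles into the surrounding sweep.

    Repeatedly deletes the *interior* adjacent extremum pair with the
    smallest excursion below ``threshold``, provided the sweep created by
    the merge stays shorter than ``max_span`` samples — merging is meant to
    heal brief interruptions of one sweep, not to bridge rest epochs.
    Pairs touching a trace end are left in place (they simply never become
    events).  Afterwards, points that are no longer turning points of the
    reduced polyline are removed.
    """
    pts = np.asarray(idx)
    while pts.size > 3:
        vals = x[pts]
        exc = np.abs(np.diff(vals))[1:-1]           # interior pairs
        span = pts[3:] - pts[:-3]                   # merged-sweep length
        mergeable = (exc < threshold) & (span <= max_span)
        if not mergeable.any():
            break
        k = int(np.argmin(np.where(mergeable, exc, np.inf))) + 1
        pts = np.delete(pts, (k, k + 1))
    # drop interior points that became monotone pass-throughs
    out = [int(pts[0])]
    for i in range(1, len(pts) - 1):
        if (x[pts[i]] - x[out[-1]]) * (x[pts[i + 1]] - x[pts[i]]) < 0:
            out.append(int(pts[i]))
    if len(pts) > 1:
        out.append(int(pts[-1]))
    return out


def event_kinematics(
    start_idx: int, end_idx: int, trace: AngleTrace
) -> tuple[float, float, float]:
    """Amplitude (deg), duration (ms), and peak speed (deg/ms) of the sweep
    between two sample indices of ``trace``."""
    if end_idx <= start_idx:
        raise ValueError("degenerate event: end must follow start")
    if start_idx < 0 or end_idx >= len(trace):
        raise ValueError("event indices outside the trace")
    x = trace.values_deg
    amplitude = float(abs(x[end_idx] - x[start_idx]))
    duration_ms = (end_idx - start_idx) * 1000.0 / trace.fs_hz
    step = np.abs(np.diff(x[start_idx : end_idx + 1]))
    max_velocity = float(step.max() * trace.fs_hz / 1000.0)
    return amplitude, duration_ms, max_velocity


def detect_movements(
    trace: AngleTrace, threshold_deg: float = 4.0, max_merge_span_ms: float = 300.0
) -> list[MovementEvent]:
    """Detect protraction/retraction events with the +-4 degree criterion.

    Local extrema of the (ideally low-passed) trace are found, sub-threshold
    wiggles briefer than ``max_merge_span_ms`` are merged into the
    surrounding sweep, and each remaining min->max sweep becomes a
    protraction, each max->min sweep a retraction, provided its excursion
    reaches ``threshold_deg``.  Returns time-ordered, non-overlapping events;
    an empty list for flat traces.
    """
    x = trace.values_deg
    ext = _turning_points(x)
    if len(ext) < 2:
        return []
    max_span = int(round(max_merge_span_ms * trace.fs_hz / 1000.0))
    ext = _prune_extrema(ext, x, threshold_deg, max_span)
    events: list[MovementEvent] = []
    for a, b in zip(ext[:-1], ext[1:]):
        delta = x[b] - x[a]
        if abs(delta) < threshold_deg:
            continue  # only possible adjacent to the trace ends
        amplitude, duration_ms, max_velocity = event_kinematics(a, b, trace)
        events.append(
            MovementEvent(
                kind="protraction" if delta > 0 else "retraction",
                start_idx=a,
                end_idx=b,
                amplitude_deg=amplitude,
                duration_ms=duration_ms,
                max_velocity_deg_per_ms=max_velocity,
            )
        )
    return events


def movement_periods(
    events: Sequence[MovementEvent], merge_gap_ms: float = 250.0, fs_hz: float = 1000.0
) -> list[tuple[int, int]]:
    """Union of event spans, merging events separated by less than
    ``merge_gap_ms``; half-open ``(start_idx, end_idx)`` intervals."""
    if not events:
        return []
    gap = merge_gap_ms * fs_hz / 1000.0
    periods: list[list[int]] = [[events[0].start_idx, events[0].end_idx]]
    for ev in events[1:]:
        if ev.start_idx - periods[-1][1] < gap:
            periods[-1][1] = max(periods[-1][1], ev.end_idx)
        else:
            periods.append([ev.start_idx, ev.end_idx])
    return [(int(a), int(b)) for a, b in periods]


def count_cycles(
    trace: AngleTrace,
    interval: tuple[int, int],
    threshold_deg: float = 4.0,
    events: Sequence[MovementEvent] | None = None,
) -> int:
    """Number of complete protraction-retraction cycles whose protraction
    starts inside the half-open sample ``interval``.

    ``events`` may be passed to avoid re-detecting on repeated calls over
    one trace.
    """
    if events is None:
        events = detect_movements(trace, threshold_deg)
    lo, hi = interval
    count = 0
    for ev, nxt in zip(events[:-1], events[1:]):
        if (
            ev.kind == "protraction"
            and nxt.kind == "retraction"
            and nxt.start_idx == ev.end_idx
            and lo <= ev.start_idx < hi
        ):
            count += 1
    return count
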