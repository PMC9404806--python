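"""Delimited-text readers and writers for all pipeline objects.

All tabular files are comma-separated with a header row; lines starting
with ``#`` are comments, and writers use them for small key=value metadata
(sampling rate, recording duration).  Readers validate the documented
schemas and report malformed rows with their line numbers.
"""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np
import pandas as pd

from .kinematics import AngleTrace, MovementEvent
from .protocol import StimTrain, Session
from .spectral import PowerSpectrum
from .spikes import RateTrace, SpikeTrain

__all__ = [
    "read_angle_trace",
    "write_angle_trace",
    "read_events",
    "write_events",
    "read_stim_log",
    "write_stim_log",
    "write_rate_trace",
    "write_movement_events",
    "write_spectrum",
]


class SchemaError(ValueError):
    """A file violated its documented schema."""


def _read_lines(path) -> tuple[list[tuple[int, list[str]]], dict[str, str]]:
    """Parse a delimited file into (line_number, fields) rows plus the
    ``# key=value`` metadata found in comments."""
    rows: list[tuple[int, list[str]]] = []
    meta: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            text = line.strip()
            if not text:
                continue
            if text.startswith("#"):
                body = text.lstrip("#").strip()
                if "=" in body:
                    key, _, value = body.partition("=")
                    meta[key.strip()] = value.strip()
                continue
            rows.append((lineno, [f.strip() for f in text.split(",")]))
    if not rows:
        raise SchemaError(f"{path}: empty file")
    return rows, meta


def _float(path, lineno: int, field: str, name: str) -> float:
    try:
        value = float(field)
    except ValueError:
        raise SchemaError(f"{path}:{lineno}: {name} {field!r} is not a number") from None
    if not math.isfinite(value):
        raise SchemaError(f"{path}:{lineno}: {name} must be finite")
    return value


# -- whisker angle -----------------------------------------------------------

def read_angle_trace(path) -> AngleTrace:
    """One column (angle_deg) or two (time_ms, angle_deg); with a time
    column, sampling must be uniform.  ``# fs_hz=...`` metadata overrides
    the default 1 kHz."""
    rows, meta = _read_lines(path)
    header = rows[0][1]
    if header and not _is_number(header[0]):
        rows = rows[1:]
        if not rows:
            raise SchemaError(f"{path}: header only, no samples")
    ncol = len(rows[0][1])
    if ncol not in (1, 2):
        raise SchemaError(f"{path}:{rows[0][0]}: expected 1 or 2 columns, got {ncol}")
    times, angles = [], []
    for lineno, fields in rows:
        if len(fields) != ncol:
            raise SchemaError(f"{path}:{lineno}: expected {ncol} fields, got {len(fields)}")
        if ncol == 2:
            times.append(_float(path, lineno, fields[0], "time_ms"))
        angles.append(_float(path, lineno, fields[-1], "angle_deg"))
    fs = float(meta.get("fs_hz", 1000.0))
    if ncol == 2 and len(times) > 1:
        dt = np.diff(times)
        if dt[0] <= 0 or not np.allclose(dt, dt[0], atol=1e-6):
            raise SchemaError(f"{path}: time column is not uniformly increasing")
        fs = 1000.0 / dt[0]
    return AngleTrace(values_deg=np.asarray(angles), fs_hz=fs)


def write_angle_trace(path, trace: AngleTrace) -> None:
    with open(path, "w") as fh:
        fh.write(f"# fs_hz={trace.fs_hz:g}\n")
        fh.write("time_ms,angle_deg\n")
        dt = 1000.0 / trace.fs_hz
        for i, v in enumerate(trace.values_deg):
            fh.write(f"{i * dt:.6g},{float(v)!r}\n")


def _is_number(s: str) -> bool:
    try:
        float(s)
        return True
    except ValueError:
        return False


# -- spike events ------------------------------------------------------------

def read_events(path, duration_ms: float | None = None, fs_hz: float = 1000.0) -> SpikeTrain:
    """Two columns: time_ms, label in {SS, CS}.  Times must be ascending
    within each label.  Duration comes from ``# duration_ms=`` metadata, the
    ``duration_ms`` argument, or (fallback) the last event time rounded up."""
    rows, meta = _read_lines(path)
    if not _is_number(rows[0][1][0]):
        rows = rows[1:]
        if not rows:
            raise SchemaError(f"{path}: header only, no events")
    ss, cs = [], []
    last = {"SS": (-np.inf, 0), "CS": (-np.inf, 0)}
    for lineno, fields in rows:
        if len(fields) != 2:
            raise SchemaError(f"{path}:{lineno}: expected 2 fields (time_ms,label)")
        t = _float(path, lineno, fields[0], "time_ms")
        label = fields[1].upper()
        if label not in ("SS", "CS"):
            raise SchemaError(f"{path}:{lineno}: label {fields[1]!r} not in {{SS, CS}}")
        prev_t, prev_line = last[label]
        if t < prev_t:
            raise SchemaError(
                f"{path}:{lineno}: {label} time {t} ms precedes the time on line {prev_line}"
            )
        last[label] = (t, lineno)
        (ss if label == "SS" else cs).append(t)
    if duration_ms is None:
        duration_ms = float(meta.get("duration_ms", 0)) or float(
            np.ceil(max(ss + cs, default=0.0) + 1.0)
        )
    return SpikeTrain(
        ss_times_ms=np.asarray(ss), cs_times_ms=np.asarray(cs),
        duration_ms=duration_ms, fs_hz=fs_hz,
    )


def write_events(path, train: SpikeTrain) -> None:
    rows = [(t, "SS") for t in train.ss_times_ms] + [(t, "CS") for t in train.cs_times_ms]
    rows.sort()
    with open(path, "w") as fh:
        fh.write(f"# duration_ms={train.duration_ms:g}\n")
        fh.write(f"# fs_hz={train.fs_hz:g}\n")
        fh.write("time_ms,label\n")
        for t, label in rows:
            fh.write(f"{float(t)!r},{label}\n")


# -- stimulus logs -----------------------------------------------------------

def read_stim_log(path, rest_ms: float = 10_000.0) -> Session:
    """Columns: onset_ms, pulse_ms, freq_label, train_index."""
    rows, _ = _read_lines(path)
    if not _is_number(rows[0][1][0]):
        rows = rows[1:]
        if not rows:
            raise SchemaError(f"{path}: header only, no pulses")
    by_train: dict[int, list[tuple[float, float, float]]] = {}
    prev = (-np.inf, 0)
    for lineno, fields in rows:
        if len(fields) != 4:
            raise SchemaError(f"{path}:{lineno}: expected 4 fields (onset_ms,pulse_ms,freq_label,train_index)")
        onset = _float(path, lineno, fields[0], "onset_ms")
        pulse = _float(path, lineno, fields[1], "pulse_ms")
        freq = _float(path, lineno, fields[2], "freq_label")
        idx = int(_float(path, lineno, fields[3], "train_index"))
        if onset < prev[0]:
            raise SchemaError(f"{path}:{lineno}: onset {onset} ms precedes the onset on line {prev[1]}")
        prev = (onset, lineno)
        by_train.setdefault(idx, []).append((onset, pulse, freq))
    trains = []
    for idx in sorted(by_train):
        pulses = by_train[idx]
        onsets = np.array([p[0] for p in pulses])
        freq = pulses[0][2]
        ipi = float(np.diff(onsets)[0]) if len(onsets) > 1 else 1000.0 / freq
        trains.append(StimTrain(freq_hz=freq, onsets_ms=onsets, ipi_ms=ipi, pulse_ms=pulses[0][1]))
    return Session(trains=tuple(trains), rest_ms=rest_ms)


def write_stim_log(path, session: Session) -> None:
    with open(path, "w") as fh:
        fh.write("onset_ms,pulse_ms,freq_label,train_index\n")
        for idx, train in enumerate(session.trains):
            for onset in train.onsets_ms:
                fh.write(f"{float(onset)!r},{train.pulse_ms:g},{train.freq_hz:g},{idx}\n")


# -- analysis products -------------------------------------------------------

def write_rate_trace(path, rate: RateTrace) -> None:
    df = pd.DataFrame(
        {"sample_index": np.arange(len(rate.values_hz)), "rate_hz": rate.values_hz}
    )
    with open(path, "w") as fh:
        fh.write(f"# fs_hz={rate.fs_hz:g}\n")
        if rate.band:
            fh.write(f"# band_hz={rate.band[0]:g}-{rate.band[1]:g}\n")
        df.to_csv(fh, index=False)


def write_movement_events(path, events: Sequence[MovementEvent], fs_hz: float = 1000.0) -> None:
    dt = 1000.0 / fs_hz
    df = pd.DataFrame(
        {
            "kind": [e.kind for e in events],
            "start_ms": [e.start_idx * dt for e in events],
            "end_ms": [e.end_idx * dt for e in events],
            "amplitude_deg": [e.amplitude_deg for e in events],
            "duration_ms": [e.duration_ms for e in events],
            "max_velocity_deg_per_ms": [e.max_velocity_deg_per_ms for e in events],
        }
    )
    df.to_csv(path, index=False)


def write_spectrum(path, spec: PowerSpectrum) -> None:
    with open(path, "w") as fh:
        fh.write(f"# peak_hz={spec.peak_hz:g}\n")
        fh.write(f"# normalized={spec.normalized}\n")
        pd.DataFrame({"freq_hz": spec.freqs_hz, "power": spec.power}).to_csv(fh, index=False)
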