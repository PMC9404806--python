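"""Optogenetic pulse-train protocol.

Seven nominal train frequencies (0.5–28 Hz) with a fixed 20 ms LED pulse.
Inter-pulse intervals (IPIs) and per-train pulse counts are stored as the
published lookup table, not derived from ``20 s / IPI``: the printed counts
deviate from exact division at the higher frequencies and fidelity to the
protocol as run wins.  A full session alternates ~20 s trains with ~10 s
rests, with the 0.5 and 14 Hz trains delivered twice.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "PULSE_MS",
    "PROTOCOL_TABLE",
    "DEFAULT_SESSION_ORDER",
    "StimTrain",
    "Session",
    "build_train",
    "build_session",
]

PULSE_MS = 20.0
TRAIN_TARGET_MS = 20_000.0

#: nominal frequency (Hz) -> (IPI in ms, pulse count).  IPIs follow the
#: printed table verbatim, including the rounded 77 and 35 ms values.
PROTOCOL_TABLE: dict[float, tuple[float, int]] = {
    0.5: (2000.0, 10),
    1.0: (1000.0, 20),
    2.0: (500.0, 40),
    4.0: (250.0, 80),
    8.0: (125.0, 140),
    14.0: (77.0, 280),
    28.0: (35.0, 660),
}

#: Frequencies in the order they are listed for the protocol, with the two
#: repeated trains (0.5 and 14 Hz) appended.  The true in-session order is
#: not documented; this default is overridable wherever it is consumed.
DEFAULT_SESSION_ORDER: tuple[float, ...] = (0.5, 2.0, 14.0, 8.0, 28.0, 4.0, 1.0, 0.5, 14.0)


@dataclass(frozen=True)
class StimTrain:
    """One train of equally spaced LED pulses.

    ``onsets_ms`` are absolute pulse-onset times; ``ipi_ms`` is the
    onset-to-onset interval; ``pulse_ms`` the LED-on duration.
    """

    freq_hz: float
    onsets_ms: np.ndarray
    ipi_ms: float
    pulse_ms: float = PULSE_MS

    def __post_init__(self) -> None:
        onsets = np.asarray(self.onsets_ms, dtype=float)
        object.__setattr__(self, "onsets_ms", onsets)
        if self.pulse_ms >= self.ipi_ms:
            raise ValueError(
                f"pulse duration {self.pulse_ms} ms must be shorter than the IPI {self.ipi_ms} ms"
            )
        if onsets.size > 1:
            gaps = np.diff(onsets)
            if not np.allclose(gaps, self.ipi_ms, atol=1e-6):
                raise ValueError("pulse onsets must be equally spaced at ipi_ms")

    @property
    def n_pulses(self) -> int:
        return int(self.onsets_ms.size)

    @property
    def end_ms(self) -> float:
        """End of the train's span: one IPI past the last onset."""
        return float(self.onsets_ms[-1] + self.ipi_ms) if self.n_pulses else 0.0

    def shifted(self, offset_ms: float) -> "StimTrain":
        return StimTrain(self.freq_hz, self.onsets_ms + offset_ms, self.ipi_ms, self.pulse_ms)


@dataclass(frozen=True)
class Session:
    """An ordered sequence of stimulus trains separated by rest periods."""

    trains: tuple[StimTrain, ...]
    rest_ms: float = 10_000.0

    def __post_init__(self) -> None:
        prev_end = -np.inf
        for train in self.trains:
            if train.n_pulses and train.onsets_ms[0] < prev_end:
                raise ValueError("session trains overlap")
            prev_end = train.end_ms

    @property
    def duration_ms(self) -> float:
        return self.trains[-1].end_ms if self.trains else 0.0


def build_train(freq_hz: float, start_ms: float = 0.0) -> StimTrain:
    """Construct the published pulse train for one nominal frequency.

    Onsets are ``start, start+ipi, ...`` with the printed pulse count.  A
    consistency warning (never an error) is emitted if count*IPI strays more
    than 20% from the ~20 s target train length.
    """
    key = float(freq_hz)
    if key not in PROTOCOL_TABLE:
        supported = sorted(PROTOCOL_TABLE)
        raise ValueError(f"unsupported train frequency {freq_hz}; supported: {supported}")
    ipi_ms, n_pulses = PROTOCOL_TABLE[key]
    span = n_pulses * ipi_ms
    if abs(span - TRAIN_TARGET_MS) > 0.2 * TRAIN_TARGET_MS:
        warnings.warn(
            f"{freq_hz} Hz train: {n_pulses} pulses x {ipi_ms} ms = {span / 1000:.1f} s, "
            "more than 20% away from the ~20 s target",
            stacklevel=2,
        )
    onsets = start_ms + ipi_ms * np.arange(n_pulses)
    return StimTrain(freq_hz=key, onsets_ms=onsets, ipi_ms=ipi_ms)


def build_session(
    order: "list[float] | tuple[float, ...]" = DEFAULT_SESSION_ORDER,
    rest_ms: float = 10_000.0,
) -> Session:
    """Concatenate trains in ``order`` with ``rest_ms`` between them.

    Each train starts one IPI plus the rest interval after the last onset of
    the preceding train.
    """
    if len(order) == 0:
        raise ValueError("session order must contain at least one frequency")
    trains: list[StimTrain] = []
    start = 0.0
    for freq in order:
        train = build_train(freq, start_ms=start)
        trains.append(train)
        start = train.end_ms + rest_ms
    return Session(trains=tuple(trains), rest_ms=rest_ms)
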