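"""Stimulus-evoked whisker responses: alignment, amplitudes, entrainment.

Two amplitude definitions coexist deliberately.  The *tuning-curve*
amplitude is max minus min of the stimulus-averaged mean whisker trace over
one inter-stimulus epoch; the *entrainment* amplitude is max minus min of
the raw (low-passed) single-trial trace between consecutive stimuli, taken
for the first 15 stimuli of a train (10 at 0.5 Hz, the total delivered).
For train frequencies below 4 Hz both use a 250 ms post-onset window
instead of the full inter-stimulus interval, excluding spontaneous whisks
between widely spaced stimuli.  Entrainment is quantified as the ordinary
least-squares slope of amplitude against stimulus number, and SS versus CF
drive are compared with a paired t-test across train frequencies.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence
import warnings

import numpy as np
from scipy import stats as _stats

from .kinematics import AngleTrace
from .protocol import StimTrain
from .spectral import PowerSpectrum, cwt_scalogram, mean_power_spectrum

__all__ = [
    "AlignedResponse",
    "EntrainmentResult",
    "SlopeComparison",
    "TuningCurve",
    "align_traces",
    "epoch_amplitude",
    "tuning_curve",
    "entrainment_amplitudes",
    "entrainment_slope",
    "compare_slopes",
    "post_stim_spectrum",
    "LOW_FREQ_WINDOW_MS",
    "N_ENTRAIN_STIMULI",
]

#: amplitude window for train frequencies strictly below this (Hz) ...
LOW_FREQ_CUTOFF_HZ = 4.0
#: ... is capped at this many ms after the stimulus onset
LOW_FREQ_WINDOW_MS = 250.0
N_ENTRAIN_STIMULI = 15


@dataclass(frozen=True)
class AlignedResponse:
    """Per-stimulus angle segments aligned to pulse onset."""

    trial_matrix: np.ndarray    # trials x samples
    mean_trace: np.ndarray
    dispersion: np.ndarray      # per-sample SD across trials
    window_ms: tuple[float, float]
    fs_hz: float

    @property
    def n_trials(self) -> int:
        return self.trial_matrix.shape[0]

    @property
    def sem(self) -> np.ndarray:
        return self.dispersion / np.sqrt(self.n_trials)


@dataclass(frozen=True)
class EntrainmentResult:
    """Single-trial amplitudes over the first stimuli of a train plus the
    straight-line slope of amplitude vs stimulus number (deg/stimulus)."""

    amplitudes_deg: np.ndarray
    slope: float
    freq_hz: float
    drive_type: str = ""  # "SS" | "CF" | ""


@dataclass(frozen=True)
class TuningCurve:
    amplitude_deg: dict[float, float]
    argmax_hz: float


@dataclass(frozen=True)
class SlopeComparison:
    t_statistic: float
    p_value: float
    higher: str          # "ss" | "cf" | "equal"
    degenerate: bool     # zero-variance differences (p collapses to 0 or 1)


def align_traces(
    trace: AngleTrace, train: StimTrain, window_ms: tuple[float, float]
) -> AlignedResponse:
    """Extract per-stimulus segments ``[onset - pre, onset + post)``.

    Raises (naming the stimulus index) if any window leaves the trace.
    """
    pre, post = window_ms
    fs = trace.fs_hz
    n_pre = int(round(pre * fs / 1000.0))
    n_post = int(round(post * fs / 1000.0))
    width = n_pre + n_post
    if width <= 0:
        raise ValueError("alignment window must be non-empty")
    rows = []
    for i, onset in enumerate(train.onsets_ms):
        c = int(round(onset * fs / 1000.0))
        a, b = c - n_pre, c + n_post
        if a < 0 or b > len(trace):
            raise ValueError(f"window for stimulus {i} ([{a}, {b})) exceeds the trace bounds")
        rows.append(trace.values_deg[a:b])
    matrix = np.asarray(rows)
    return AlignedResponse(
        trial_matrix=matrix,
        mean_trace=matrix.mean(axis=0),
        dispersion=matrix.std(axis=0, ddof=0),
        window_ms=(pre, post),
        fs_hz=fs,
    )


def _epoch_window_ms(train: StimTrain, i: int) -> tuple[float, float]:
    """Amplitude window for stimulus ``i``: onset to next onset for train
    frequencies >= 4 Hz (one IPI for the last stimulus), onset + 250 ms for
    lower frequencies."""
    if i < 0 or i >= train.n_pulses:
        raise IndexError(f"stimulus index {i} out of range for {train.n_pulses} pulses")
    start = float(train.onsets_ms[i])
    if train.freq_hz < LOW_FREQ_CUTOFF_HZ:
        return start, start + LOW_FREQ_WINDOW_MS
    end = float(train.onsets_ms[i + 1]) if i + 1 < train.n_pulses else start + train.ipi_ms
    return start, end


def epoch_amplitude(trace: AngleTrace, train: StimTrain, i: int) -> float:
    """Max minus min of ``trace`` over the amplitude window of stimulus ``i``."""
    start_ms, end_ms = _epoch_window_ms(train, i)
    fs = trace.fs_hz
    a = int(round(start_ms * fs / 1000.0))
    b = int(round(end_ms * fs / 1000.0))
    if a < 0 or b > len(trace):
        raise ValueError(f"epoch window for stimulus {i} exceeds the trace bounds")
    seg = trace.values_deg[a:b]
    return float(seg.max() - seg.min())


def _mean_trace_amplitude(trace: AngleTrace, train: StimTrain) -> float:
    """Tuning-curve amplitude: max - min of the stimulus-averaged mean trace
    over one epoch window (full IPI, or 250 ms below 4 Hz)."""
    window = min(train.ipi_ms, LOW_FREQ_WINDOW_MS) if train.freq_hz < LOW_FREQ_CUTOFF_HZ else train.ipi_ms
    aligned = align_traces(trace, train, (0.0, window))
    return float(aligned.mean_trace.max() - aligned.mean_trace.min())


def tuning_curve(
    traces: Mapping[float, AngleTrace], trains: Mapping[float, StimTrain]
) -> TuningCurve:
    """Amplitude of the mean whisker trace per train frequency and the
    frequency where it is maximal.  Frequencies present in ``trains`` but
    missing a trace yield a partial curve with a warning."""
    curve: dict[float, float] = {}
    for freq in sorted(trains):
        if freq not in traces:
            warnings.warn(f"no trace for {freq} Hz; tuning curve is partial", stacklevel=2)
            continue
        curve[freq] = _mean_trace_amplitude(traces[freq], trains[freq])
    if not curve:
        raise ValueError("no overlapping frequencies between traces and trains")
    argmax = max(curve, key=lambda f: curve[f])
    return TuningCurve(amplitude_deg=curve, argmax_hz=float(argmax))


def entrainment_amplitudes(
    trace: AngleTrace, train: StimTrain, drive_type: str = ""
) -> EntrainmentResult:
    """Single-trial amplitudes for the first 15 stimuli (10 at 0.5 Hz) and
    their fitted slope.  Uses the raw (low-passed) trace, not the mean."""
    if train.n_pulses < 10:
        raise ValueError(f"need at least 10 pulses, got {train.n_pulses}")
    n_use = 10 if train.freq_hz == 0.5 else min(N_ENTRAIN_STIMULI, train.n_pulses)
    amps = np.array([epoch_amplitude(trace, train, i) for i in range(n_use)])
    return EntrainmentResult(
        amplitudes_deg=amps,
        slope=entrainment_slope(amps),
        freq_hz=train.freq_hz,
        drive_type=drive_type,
    )


def entrainment_slope(amplitudes: Sequence[float]) -> float:
    """Ordinary least-squares slope of amplitude against stimulus number
    (1-based), in deg/stimulus."""
    y = np.asarray(amplitudes, dtype=float)
    if y.size < 3:
        raise ValueError("need at least 3 amplitudes for a slope")
    x = np.arange(1, y.size + 1, dtype=float)
    return float(np.polyfit(x, y, 1)[0])


def compare_slopes(
    ss_slopes: Sequence[float], cf_slopes: Sequence[float]
) -> SlopeComparison:
    """Two-sided paired t-test of SS vs CF entrainment slopes, paired by
    train frequency.  Zero-variance differences are reported as degenerate
    (t diverges; p pinned to 0, or 1 when the slopes are identical)."""
    ss = np.asarray(ss_slopes, dtype=float)
    cf = np.asarray(cf_slopes, dtype=float)
    if ss.shape != cf.shape:
        raise ValueError("paired slope vectors must have equal length")
    diff = ss - cf
    higher = "ss" if ss.mean() > cf.mean() else ("cf" if cf.mean() > ss.mean() else "equal")
    if np.allclose(diff.std(ddof=1) if diff.size > 1 else 0.0, 0.0):
        if np.allclose(diff, 0.0):
            return SlopeComparison(t_statistic=0.0, p_value=1.0, higher="equal", degenerate=True)
        sign = float(np.sign(diff.mean()))
        return SlopeComparison(t_statistic=sign * np.inf, p_value=0.0, higher=higher, degenerate=True)
    t, p = _stats.ttest_rel(ss, cf)
    return SlopeComparison(t_statistic=float(t), p_value=float(p), higher=higher, degenerate=False)


def post_stim_spectrum(
    trace: AngleTrace,
    train: StimTrain,
    window_ms: float = 1000.0,
    fmin: float = 2.0,
    fmax: float = 30.0,
    df: float = 0.1,
) -> tuple[PowerSpectrum, PowerSpectrum, bool]:
    """Whisker power spectra 1 s before vs 1 s after the last stimulus.

    The pre window is ``[last_onset - w, last_onset)``; the post window
    starts after the pulse, ``[last_onset + pulse, last_onset + pulse + w)``.
    Returns both spectra and whether the post-stimulation peak lies within
    one grid step of the train frequency (did the rhythm persist?).
    """
    fs = trace.fs_hz
    last = float(train.onsets_ms[-1])
    a_pre = int(round((last - window_ms) * fs / 1000.0))
    b_pre = int(round(last * fs / 1000.0))
    a_post = int(round((last + train.pulse_ms) * fs / 1000.0))
    b_post = a_post + (b_pre - a_pre)
    if a_pre < 0 or b_post > len(trace):
        raise ValueError(
            f"need {window_ms} ms on both sides of the last stimulus at {last} ms"
        )
    spectra = []
    for a, b in ((a_pre, b_pre), (a_post, b_post)):
        scal = cwt_scalogram(trace.values_deg[a:b], fs_hz=fs, fmin=fmin, fmax=fmax, df=df)
        spectra.append(mean_power_spectrum(scal))
    before, after = spectra
    same_peak = bool(abs(after.peak_hz - train.freq_hz) <= df + 1e-9)
    return before, after, same_peak
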