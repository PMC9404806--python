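"""Simple-spike rate estimation and single-unit quality control.

Spike event times are binned into a logical (0/1) vector at the video
sampling rate and convolved with a composite Gaussian kernel — the mean of
two Gaussians ``exp(-x^2 / 2 n^2)`` with ``n = 8`` and ``n = 20`` samples on
a 100-sample support — to obtain the instantaneous simple-spike frequency.
A 3–25 Hz zero-phase Butterworth band-pass isolates the whisking-band
modulation and cancels the 1/f background.

Quality control follows the single-unit acceptance criteria of the source
recordings: minimal simple-spike inter-spike interval of 3 ms, a pause of at
least 8 ms in simple-spike firing after every complex spike, stable spike
amplitude/width (no more than three consecutive spikes beyond 3 SD), and a
minimum duration of 40 s.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as _signal

__all__ = [
    "SpikeTrain",
    "RateTrace",
    "QCResult",
    "to_logical_vector",
    "gaussian_kernel",
    "composite_kernel",
    "instantaneous_frequency",
    "bandpass_rate",
    "qc_single_unit",
]

#: edge span (ms) of a rate trace regarded as convolution-contaminated
EDGE_MS = 50.0


@dataclass(frozen=True)
class SpikeTrain:
    """Simple-spike (SS) and complex-spike (CS) event times of one unit.

    Times are in ms from recording onset, strictly within
    ``[0, duration_ms)`` and ascending.  ``ss_amplitude``/``ss_width`` are
    optional per-SS waveform series used by the stability QC.
    """

    ss_times_ms: np.ndarray
    cs_times_ms: np.ndarray
    duration_ms: float
    fs_hz: float = 1000.0
    ss_amplitude: np.ndarray | None = None
    ss_width: np.ndarray | None = None

    def __post_init__(self) -> None:
        ss = np.asarray(self.ss_times_ms, dtype=float)
        cs = np.asarray(self.cs_times_ms, dtype=float)
        object.__setattr__(self, "ss_times_ms", ss)
        object.__setattr__(self, "cs_times_ms", cs)
        if self.duration_ms <= 0:
            raise ValueError("duration_ms must be positive")
        for name, times in (("SS", ss), ("CS", cs)):
            if times.size and (np.any(np.diff(times) < 0)):
                bad = times[1:][np.diff(times) < 0][0]
                raise ValueError(f"{name} times not ascending near t={bad} ms")
            if times.size:
                out = times[(times < 0) | (times >= self.duration_ms)]
                if out.size:
                    raise ValueError(
                        f"{name} time {out[0]} ms outside [0, {self.duration_ms}) ms"
                    )
        for name, series in (("ss_amplitude", self.ss_amplitude), ("ss_width", self.ss_width)):
            if series is not None:
                arr = np.asarray(series, dtype=float)
                object.__setattr__(self, name, arr)
                if arr.size != ss.size:
                    raise ValueError(f"{name} must have one value per SS")

    @property
    def n_samples(self) -> int:
        return int(round(self.duration_ms * self.fs_hz / 1000.0))


@dataclass(frozen=True)
class RateTrace:
    """Instantaneous firing frequency sampled at ``fs_hz`` (units: Hz).

    ``band`` records the band-pass applied, if any; ``edge_ms`` flags the
    span at each end that is contaminated by convolution/filter edges and
    should be excluded from spectral peak readouts.
    """

    values_hz: np.ndarray
    fs_hz: float = 1000.0
    band: tuple[float, float] | None = None
    edge_ms: float = EDGE_MS

    def __post_init__(self) -> None:
        values = np.asarray(self.values_hz, dtype=float)
        object.__setattr__(self, "values_hz", values)
        if not np.all(np.isfinite(values)):
            raise ValueError("rate trace contains non-finite values")

    def interior(self) -> np.ndarray:
        """Values with the edge-contaminated spans stripped."""
        k = int(round(self.edge_ms * self.fs_hz / 1000.0))
        return self.values_hz[k : len(self.values_hz) - k or None]


def to_logical_vector(train: SpikeTrain) -> np.ndarray:
    """Bin SS times into a logical vector: element ``k`` is 1 iff at least
    one SS falls in the half-open sample bin ``[k, k+1)`` (ms at 1 kHz)."""
    n = train.n_samples
    vec = np.zeros(n, dtype=np.int8)
    if train.ss_times_ms.size:
        idx = np.floor(train.ss_times_ms * train.fs_hz / 1000.0).astype(int)
        bad = train.ss_times_ms[(idx < 0) | (idx >= n)]
        if bad.size:
            raise ValueError(f"SS time {bad[0]} ms outside the recording")
        vec[idx] = 1  # logical, not count: coincident spikes collapse to 1
    return vec


def gaussian_kernel(n: float, length: int = 100) -> np.ndarray:
    """Unit-sum Gaussian kernel ``exp(-x^2 / 2 n^2)``.

    Evaluated on a symmetric grid of ``length`` points centred on zero; for
    even ``length`` the grid is offset by half a sample
    (x = -49.5 ... +49.5 for the default 100-point support) so the kernel is
    exactly symmetric.
    """
    if n <= 0:
        raise ValueError("kernel width n must be positive")
    if length < 3:
        raise ValueError("kernel support must be at least 3 samples")
    x = np.arange(length, dtype=float) - (length - 1) / 2.0
    k = np.exp(-(x**2) / (2.0 * n**2))
    return k / k.sum()


def composite_kernel(widths: tuple[float, float] = (8.0, 20.0), length: int = 100) -> np.ndarray:
    """Elementwise mean of the ``n = 8`` and ``n = 20`` Gaussian kernels.

    The mean of two unit-sum kernels keeps unit sum, so convolution output
    scaled by the sampling rate reads directly in Hz.
    """
    k = np.mean([gaussian_kernel(w, length) for w in widths], axis=0)
    return k


def instantaneous_frequency(
    vec: np.ndarray, kernel: np.ndarray, fs_hz: float = 1000.0
) -> RateTrace:
    """Convolve a logical spike vector with a unit-sum kernel, scaled to Hz.

    Same-length output with zero-padded edges.  A periodic spike train at
    ``r`` Hz reads ``~r`` Hz away from the edges, and the integral of the
    output over time equals the spike count (mass conservation) for spikes
    away from the edges.
    """
    vec = np.asarray(vec, dtype=float)
    kernel = np.asarray(kernel, dtype=float)
    if kernel.size > vec.size:
        raise ValueError(f"kernel ({kernel.size}) longer than signal ({vec.size})")
    if not np.isclose(kernel.sum(), 1.0, atol=1e-9):
        raise ValueError("kernel must be normalized to unit sum")
    values = np.convolve(vec, kernel, mode="same") * fs_hz
    return RateTrace(values_hz=values, fs_hz=fs_hz)


def bandpass_rate(
    rate: RateTrace, low_hz: float = 3.0, high_hz: float = 25.0, order: int = 4
) -> RateTrace:
    """Zero-phase Butterworth band-pass of an instantaneous-frequency trace.

    Fourth order, applied forward and backward (``sosfiltfilt``) so event
    timing is preserved for stimulus alignment.  Output is zero-mean.
    """
    if not (0 < low_hz < high_hz < rate.fs_hz / 2):
        raise ValueError(f"invalid band ({low_hz}, {high_hz}) at fs={rate.fs_hz}")
    sos = _signal.butter(order, [low_hz, high_hz], btype="bandpass", fs=rate.fs_hz, output="sos")
    values = _signal.sosfiltfilt(sos, rate.values_hz)
    return RateTrace(values_hz=values, fs_hz=rate.fs_hz, band=(low_hz, high_hz), edge_ms=rate.edge_ms)


@dataclass(frozen=True)
class QCResult:
    passed: bool
    violations: tuple[str, ...] = ()

    def __bool__(self) -> bool:
        return self.passed


def _unstable_runs(series: np.ndarray, n_sd: float, max_consecutive: int) -> bool:
    """True when more than ``max_consecutive`` successive values deviate more
    than ``n_sd`` standard deviations from the series mean."""
    sd = series.std()
    if sd == 0:
        return False
    outlier = np.abs(series - series.mean()) > n_sd * sd
    run = 0
    for flag in outlier:
        run = run + 1 if flag else 0
        if run > max_consecutive:
            return True
    return False


def qc_single_unit(
    train: SpikeTrain,
    min_isi_ms: float = 3.0,
    cs_pause_ms: float = 8.0,
    min_duration_ms: float = 40_000.0,
    stability_sd: float = 3.0,
    max_consecutive: int = 3,
) -> QCResult:
    """Apply the single-unit acceptance criteria; returns every violated
    criterion (never raises on recording content)."""
    violations: list[str] = []
    ss = train.ss_times_ms
    if ss.size > 1 and np.any(np.diff(ss) < min_isi_ms):
        violations.append(f"ISI < {min_isi_ms:g} ms")
    if train.cs_times_ms.size and ss.size:
        # an SS strictly inside (cs, cs + pause) breaks the post-CS pause
        pos = np.searchsorted(ss, train.cs_times_ms, side="right")
        ok = True
        for cs, j in zip(train.cs_times_ms, pos):
            if j < ss.size and ss[j] - cs < cs_pause_ms:
                ok = False
                break
        if not ok:
            violations.append(f"CS pause < {cs_pause_ms:g} ms")
    if train.ss_amplitude is not None and train.ss_amplitude.size > max_consecutive:
        if _unstable_runs(train.ss_amplitude, stability_sd, max_consecutive):
            violations.append(f"amplitude unstable (> {max_consecutive} consecutive > {stability_sd:g} SD)")
    if train.ss_width is not None and train.ss_width.size > max_consecutive:
        if _unstable_runs(train.ss_width, stability_sd, max_consecutive):
            violations.append(f"width unstable (> {max_consecutive} consecutive > {stability_sd:g} SD)")
    if train.duration_ms < min_duration_ms:
        violations.append(f"duration < {min_duration_ms / 1000:g} s")
    return QCResult(passed=not violations, violations=tuple(violations))
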