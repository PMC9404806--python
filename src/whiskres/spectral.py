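"""Morlet continuous-wavelet scalograms and power spectra.

Scalograms are computed with an analytic Morlet wavelet implemented as a
frequency-domain Gaussian filterbank: for each analysis frequency ``f`` the
signal spectrum is multiplied by ``2 exp(-omega0^2 (w/w_f - 1)^2 / 2)`` on
positive frequencies and transformed back.  This is the exact continuous
transform on the FFT grid, with amplitude (L1) normalization: a unit
amplitude tone yields unit magnitude at its own frequency regardless of
``f``, so powers are comparable across the spectrum.  ``omega0 = 6``
(six-cycle Morlet) is the classical time/frequency trade-off.

Mean power spectra are time averages of the scalogram, optionally
restricted to movement periods, with the cone of influence (one wavelet
e-folding time per edge, per frequency) excluded so boundary transients do
not inflate low-frequency power.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import fft as _fft

__all__ = [
    "Scalogram",
    "PowerSpectrum",
    "cwt_scalogram",
    "mean_power_spectrum",
    "normalize_spectrum",
    "peak_frequency",
]

MORLET_OMEGA0 = 6.0


@dataclass(frozen=True)
class Scalogram:
    """Time-frequency power (magnitude squared), frequencies x samples."""

    freqs_hz: np.ndarray
    power: np.ndarray
    fs_hz: float
    coi_samples: np.ndarray  # per-frequency edge exclusion width, samples

    def __post_init__(self) -> None:
        if self.power.shape != (len(self.freqs_hz), self.power.shape[1]):
            raise ValueError("power must be (n_freqs, n_samples)")
        if np.any(self.power < 0):
            raise ValueError("power must be non-negative")


@dataclass(frozen=True)
class PowerSpectrum:
    freqs_hz: np.ndarray
    power: np.ndarray
    peak_hz: float
    normalized: bool = False


def _morlet_filter(freqs_out: np.ndarray, fft_freqs: np.ndarray, omega0: float) -> np.ndarray:
    """Analytic Morlet transfer functions, one row per analysis frequency."""
    h = np.zeros((len(freqs_out), len(fft_freqs)))
    pos = fft_freqs > 0
    ratio = fft_freqs[pos][None, :] / freqs_out[:, None]
    h[:, pos] = 2.0 * np.exp(-0.5 * omega0**2 * (ratio - 1.0) ** 2)
    return h


def cwt_scalogram(
    signal: np.ndarray,
    fs_hz: float = 1000.0,
    fmin: float = 1.0,
    fmax: float = 30.0,
    df: float = 0.1,
    omega0: float = MORLET_OMEGA0,
) -> Scalogram:
    """Morlet CWT power on a regular frequency grid (default 1-30 Hz, 0.1 Hz).

    The time dimension is preserved; the signal must span at least one
    period of ``fmin``.  Signals are zero-padded for the FFT, and the
    per-frequency cone of influence (sqrt(2) wavelet standard deviations,
    i.e. one e-folding time ``sqrt(2) omega0 / (2 pi f)``) is recorded for
    downstream edge exclusion.
    """
    x = np.asarray(signal, dtype=float)
    n = x.size
    if n * fmin < fs_hz:
        raise ValueError(
            f"signal of {n} samples is shorter than one period of fmin={fmin} Hz"
        )
    n_grid = int(round((fmax - fmin) / df)) + 1
    freqs = np.linspace(fmin, fmax, n_grid)
    pad = int(np.ceil(np.sqrt(2) * omega0 / (2 * np.pi * fmin) * fs_hz))
    n_fft = _fft.next_fast_len(n + 2 * pad)
    spec = _fft.fft(x, n_fft)
    fft_freqs = _fft.fftfreq(n_fft, d=1.0 / fs_hz)
    filters = _morlet_filter(freqs, fft_freqs, omega0)
    power = np.empty((n_grid, n), dtype=float)
    for i in range(n_grid):
        w = _fft.ifft(spec * filters[i])[:n]
        power[i] = w.real**2 + w.imag**2
    coi = np.ceil(np.sqrt(2) * omega0 / (2 * np.pi * freqs) * fs_hz).astype(int)
    return Scalogram(freqs_hz=freqs, power=power, fs_hz=fs_hz, coi_samples=coi)


def mean_power_spectrum(
    scal: Scalogram, periods: "Sequence[tuple[int, int]] | None" = None
) -> PowerSpectrum:
    """Time-average of scalogram power over the union of half-open sample
    ``periods`` (whole signal if ``None``), excluding per-frequency cone-of-
    influence edges.  At frequencies where the exclusion would leave fewer
    than 20% of the selected samples, the exclusion is clipped so a central
    portion always survives."""
    n = scal.power.shape[1]
    mask = np.zeros(n, dtype=bool)
    if periods is None:
        mask[:] = True
    else:
        for a, b in periods:
            if a < 0 or b > n:
                raise ValueError(f"period ({a}, {b}) outside the signal span")
            mask[a:b] = True
    if not mask.any():
        raise ValueError("empty movement-period union")
    idx = np.arange(n)
    power = np.empty(len(scal.freqs_hz))
    max_coi = int(0.4 * n)
    for i, coi in enumerate(scal.coi_samples):
        c = min(int(coi), max_coi)
        valid = mask & (idx >= c) & (idx < n - c)
        if valid.sum() < max(1, 0.2 * mask.sum()):
            valid = mask
        power[i] = scal.power[i, valid].mean()
    peak = float(scal.freqs_hz[int(np.argmax(power))])
    return PowerSpectrum(freqs_hz=scal.freqs_hz.copy(), power=power, peak_hz=peak)


def normalize_spectrum(spec: PowerSpectrum, mode: str = "max") -> PowerSpectrum:
    """Divide power by its maximum (default) or by its area; the peak
    frequency is unchanged and the operation is idempotent."""
    if mode == "max":
        denom = spec.power.max()
    elif mode == "area":
        denom = np.trapezoid(spec.power, spec.freqs_hz)
    else:
        raise ValueError(f"unknown normalization mode {mode!r}")
    if denom <= 0:
        raise ValueError("cannot normalize an all-zero spectrum")
    return PowerSpectrum(
        freqs_hz=spec.freqs_hz, power=spec.power / denom, peak_hz=spec.peak_hz, normalized=True
    )


def peak_frequency(
    spec: PowerSpectrum, band: "tuple[float, float] | None" = None
) -> float:
    """Frequency of maximum power, optionally restricted to ``band``
    (inclusive).  Ties break to the lower frequency."""
    if band is None:
        sel = np.ones(len(spec.freqs_hz), dtype=bool)
    else:
        lo, hi = band
        sel = (spec.freqs_hz >= lo) & (spec.freqs_hz <= hi)
        if not sel.any():
            raise ValueError(f"band ({lo}, {hi}) contains no grid frequencies")
    freqs = spec.freqs_hz[sel]
    return float(freqs[int(np.argmax(spec.power[sel]))])
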