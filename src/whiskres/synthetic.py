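"""Synthetic recordings: resonant whisker plant and Purkinje spike trains.

The whisker "plant" (whisker plus musculature) is a linear second-order
underdamped oscillator resonant near 8 Hz.  ``resonance_freq_hz`` is the
*observed* ringing frequency (the damped frequency), so one free ring lasts
exactly ``1000 / resonance_freq_hz`` ms; with the default 8 Hz plant a ring
is 125 ms, matching the reverberation-loop period.  Every LED pulse injects
a rectangular 20 ms motor command; simple-spike-type (SS) drive additionally
injects echo commands ``echo_delay_ms`` later (the reverberant loop),
while climbing-fiber-type (CF) drive injects none, which is what produces
two whisker cycles per stimulus for SS drive versus one for CF drive.  An
optional per-stimulus gain growth emulates entrainment.

The spike generator draws simple spikes from a sinusoidally rate-modulated
point process (theta-band modulation) with an absolute refractory period,
plus Poisson complex spikes each enforcing a simple-spike pause, so every
generated train passes the single-unit QC by construction.

All generators are deterministic given a seed and return their ground truth
(command vectors, per-stimulus gains, bout intervals, true rate) alongside
the simulated object.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as _signal

from .kinematics import AngleTrace
from .protocol import StimTrain
from .spikes import SpikeTrain

__all__ = [
    "PlantParams",
    "SpikeGenParams",
    "PlantSimulation",
    "WhiskingSimulation",
    "SpikeSimulation",
    "ss_plant",
    "cf_plant",
    "simulate_plant",
    "simulate_spontaneous_whisking",
    "simulate_spike_train",
]


@dataclass(frozen=True)
class PlantParams:
    """Whisker-plant parameters.

    resonance_freq_hz
        Damped (observed) ringing frequency, Hz.  The free-ring period is
        exactly its inverse.
    damping_ratio
        Dimensionless, strictly in (0, 1): the plant must be underdamped so
        it can ring.  At the default 0.25 successive half-cycle excursions
        shrink by ~56%, leaving one supra-threshold cycle per command.
    drive_gain
        Steady-state deflection (degrees) for a unit sustained command.
    echo_delay_ms / echo_gain / n_echoes
        Reverberation loop: each pulse re-injects ``n_echoes`` scaled copies
        of its command, ``echo_delay_ms`` apart, with amplitude
        ``echo_gain**k`` for echo ``k``.  ``n_echoes=1`` is SS-type drive,
        ``0`` is CF-type.
    entrain_increment
        Fractional command-gain growth per successive stimulus (stimulus
        ``i``, counted from 0, is scaled by ``1 + entrain_increment * i``).
    noise_sd_deg
        SD of additive Gaussian measurement noise (camera/tracking).
    latency_ms
        Command latency from LED onset; the physiological value is unknown,
        so the default asserts none.
    """

    resonance_freq_hz: float = 8.0
    damping_ratio: float = 0.25
    drive_gain: float = 12.0
    echo_delay_ms: float = 125.0
    echo_gain: float = 0.7
    n_echoes: int = 1
    entrain_increment: float = 0.0
    noise_sd_deg: float = 0.2
    latency_ms: float = 0.0

    def __post_init__(self) -> None:
        if not (0.0 < self.damping_ratio < 1.0):
            raise ValueError("damping_ratio must lie strictly in (0, 1)")
        if not (0.0 <= self.echo_gain < 1.0):
            raise ValueError("echo_gain must lie in [0, 1)")
        if self.n_echoes < 0 or self.entrain_increment < 0 or self.noise_sd_deg < 0:
            raise ValueError("n_echoes, entrain_increment and noise_sd_deg must be >= 0")
        if self.resonance_freq_hz <= 0:
            raise ValueError("resonance_freq_hz must be positive")


def ss_plant(**overrides) -> PlantParams:
    """Default simple-spike-type plant: one 125 ms echo, mild entrainment."""
    params = dict(n_echoes=1, entrain_increment=0.01)
    params.update(overrides)
    return PlantParams(**params)


def cf_plant(**overrides) -> PlantParams:
    """Default climbing-fiber-type plant: no echoes, no entrainment."""
    params = dict(n_echoes=0, entrain_increment=0.0)
    params.update(overrides)
    return PlantParams(**params)


@dataclass(frozen=True)
class PlantSimulation:
    """Simulated whisker response plus its ground truth."""

    trace: AngleTrace
    command: np.ndarray          # degrees of commanded steady deflection
    stim_gains: np.ndarray       # per-stimulus entrainment gain factors
    params: PlantParams
    stim: StimTrain


def _plant_filter(params: PlantParams, fs_hz: float):
    """Exact zero-order-hold discretization of the second-order plant."""
    zeta = params.damping_ratio
    w_d = 2 * np.pi * params.resonance_freq_hz
    w_n = w_d / np.sqrt(1 - zeta**2)  # undamped natural frequency
    num = [w_n**2]
    den = [1.0, 2 * zeta * w_n, w_n**2]
    num_d, den_d, _dt = _signal.cont2discrete((num, den), dt=1.0 / fs_hz, method="zoh")
    return np.atleast_1d(np.squeeze(num_d)), np.atleast_1d(np.squeeze(den_d))


def simulate_plant(
    stim: StimTrain,
    params: PlantParams = PlantParams(),
    seed: int = 0,
    duration_ms: float | None = None,
    fs_hz: float = 1000.0,
) -> PlantSimulation:
    """Drive the plant with a pulse train and return the angle at 1 kHz.

    Each pulse contributes a rectangular command of one pulse width at its
    onset (plus latency) and ``n_echoes`` echoes at multiples of
    ``echo_delay_ms``, scaled by ``echo_gain**k``; stimulus ``i`` is further
    scaled by ``1 + entrain_increment * i``.  The linear plant is integrated
    with its exact discrete (zero-order-hold) update; Gaussian measurement
    noise is added last.
    """
    if fs_hz <= 0:
        raise ValueError("sampling rate must be positive")
    if params.n_echoes > 0 and params.echo_delay_ms < stim.pulse_ms:
        raise ValueError(
            f"echo delay {params.echo_delay_ms} ms shorter than the pulse width {stim.pulse_ms} ms"
        )
    if duration_ms is None:
        duration_ms = max(stim.end_ms + 1000.0, 1000.0)
    n = int(round(duration_ms * fs_hz / 1000.0))
    if stim.n_pulses:
        last_onset = stim.onsets_ms[-1] + params.latency_ms
        if stim.onsets_ms[0] < 0 or last_onset >= duration_ms:
            raise ValueError("stimulus onsets fall outside the requested duration")

    gains = 1.0 + params.entrain_increment * np.arange(stim.n_pulses)
    command = np.zeros(n)
    pulse_len = int(round(stim.pulse_ms * fs_hz / 1000.0))
    for i, onset in enumerate(stim.onsets_ms):
        for k in range(params.n_echoes + 1):
            t0 = onset + params.latency_ms + k * params.echo_delay_ms
            a = int(round(t0 * fs_hz / 1000.0))
            if a >= n:
                break
            command[a : min(a + pulse_len, n)] += gains[i] * params.echo_gain**k
    command *= params.drive_gain

    num_d, den_d = _plant_filter(params, fs_hz)
    angle = _signal.lfilter(num_d, den_d, command)
    rng = np.random.default_rng(seed)
    if params.noise_sd_deg > 0:
        angle = angle + rng.normal(0.0, params.noise_sd_deg, n)
    trace = AngleTrace(values_deg=angle, fs_hz=fs_hz)
    return PlantSimulation(trace=trace, command=command, stim_gains=gains, params=params, stim=stim)


@dataclass(frozen=True)
class WhiskingSimulation:
    """Spontaneous whisking trace with ground-truth bout intervals (ms)."""

    trace: AngleTrace
    bouts_ms: tuple[tuple[float, float], ...]
    rest_only: bool = False  # warning flag: duration too short for a bout


def simulate_spontaneous_whisking(
    bout_rate: float = 0.2,
    mod_freq_hz: float = 8.0,
    amp_deg: float = 6.0,
    duration_ms: float = 40_000.0,
    seed: int = 0,
    noise_sd_deg: float = 0.2,
    fs_hz: float = 1000.0,
) -> WhiskingSimulation:
    """Alternate rest epochs with whisking bouts.

    Rest durations are exponential with mean ``1 / bout_rate`` seconds; bout
    durations are uniform on 1.5-3 s.  A bout is an amplitude-modulated
    sinusoid at ``mod_freq_hz`` under a flat-topped (Tukey) envelope whose
    peak is ``amp_deg``, so peak-to-peak reaches ``2 * amp_deg`` at the bout
    centre.  ``bout_rate = 0`` or a too-short duration yields rest only,
    flagged on the result.
    """
    if amp_deg < 0:
        raise ValueError("amp_deg must be non-negative")
    rng = np.random.default_rng(seed)
    n = int(round(duration_ms * fs_hz / 1000.0))
    x = np.zeros(n)
    bouts: list[tuple[float, float]] = []
    if bout_rate > 0:
        t = 0.0
        while True:
            t += rng.exponential(1000.0 / bout_rate)
            bout_len = rng.uniform(1500.0, 3000.0)
            if t + bout_len >= duration_ms:
                break
            a, b = int(round(t * fs_hz / 1000.0)), int(round((t + bout_len) * fs_hz / 1000.0))
            env = _signal.windows.tukey(b - a, alpha=0.15)
            phase = rng.uniform(0, 2 * np.pi)
            tt = np.arange(b - a) / fs_hz
            x[a:b] += amp_deg * env * np.sin(2 * np.pi * mod_freq_hz * tt + phase)
            bouts.append((t, t + bout_len))
            t += bout_len
    if noise_sd_deg > 0:
        x += rng.normal(0.0, noise_sd_deg, n)
    return WhiskingSimulation(
        trace=AngleTrace(values_deg=x, fs_hz=fs_hz),
        bouts_ms=tuple(bouts),
        rest_only=not bouts,
    )


@dataclass(frozen=True)
class SpikeGenParams:
    """Spike-train generator parameters.

    The simple-spike rate is ``baseline * (1 + mod_depth * sin(2 pi f t))``
    (clipped at zero), thinned to an absolute refractory period; complex
    spikes are homogeneous Poisson and silence simple spikes for
    ``cs_pause_ms`` afterwards.  Defaults satisfy the single-unit QC by
    construction (refractory >= 3 ms, pause >= 8 ms, duration >= 40 s).
    """

    baseline_rate_hz: float = 60.0
    mod_freq_hz: float = 7.0
    mod_depth: float = 0.5
    cs_rate_hz: float = 1.0
    cs_pause_ms: float = 8.0
    refractory_ms: float = 3.0
    duration_ms: float = 40_000.0

    def __post_init__(self) -> None:
        if self.baseline_rate_hz <= 0:
            raise ValueError("baseline_rate_hz must be positive")
        if not (0.0 <= self.mod_depth <= 1.0):
            raise ValueError("mod_depth must lie in [0, 1]")
        if self.refractory_ms < 3.0:
            raise ValueError("refractory_ms below the 3 ms QC minimum")
        if self.cs_pause_ms < 8.0:
            raise ValueError("cs_pause_ms below the 8 ms QC minimum")


@dataclass(frozen=True)
class SpikeSimulation:
    """Simulated unit plus the true underlying rate (per 1 ms sample)."""

    train: SpikeTrain
    rate_hz: np.ndarray
    params: SpikeGenParams


def simulate_spike_train(params: SpikeGenParams = SpikeGenParams(), seed: int = 0) -> SpikeSimulation:
    """Draw SS/CS event times for one synthetic Purkinje unit.

    Simple spikes come from the modulated rate by thinning a homogeneous
    process at the rate maximum, then enforcing the refractory period;
    complex spikes are Poisson, and simple spikes within the post-CS pause
    are deleted.
    """
    rng = np.random.default_rng(seed)
    dur_s = params.duration_ms / 1000.0
    rmax = params.baseline_rate_hz * (1 + params.mod_depth)
    n_cand = rng.poisson(rmax * dur_s)
    cand = np.sort(rng.uniform(0.0, params.duration_ms, n_cand))
    rate_at = params.baseline_rate_hz * (
        1 + params.mod_depth * np.sin(2 * np.pi * params.mod_freq_hz * cand / 1000.0)
    )
    keep = rng.uniform(0.0, rmax, n_cand) < np.clip(rate_at, 0.0, None)
    ss = cand[keep]

    if ss.size:  # absolute refractory period
        accepted = [ss[0]]
        for t in ss[1:]:
            if t - accepted[-1] >= params.refractory_ms:
                accepted.append(t)
        ss = np.asarray(accepted)

    n_cs = rng.poisson(params.cs_rate_hz * dur_s)
    cs = np.sort(rng.uniform(0.0, params.duration_ms, n_cs))
    for t in cs:  # post-CS pause in SS firing
        ss = ss[(ss <= t) | (ss >= t + params.cs_pause_ms)]

    t_ms = np.arange(int(round(params.duration_ms)))
    rate = params.baseline_rate_hz * (
        1 + params.mod_depth * np.sin(2 * np.pi * params.mod_freq_hz * t_ms / 1000.0)
    )
    train = SpikeTrain(ss_times_ms=ss, cs_times_ms=cs, duration_ms=params.duration_ms)
    return SpikeSimulation(train=train, rate_hz=np.clip(rate, 0.0, None), params=params)
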