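"""End-to-end orchestration: QC -> rates -> kinematics -> spectra -> response.

``run_full_analysis`` executes the whole pipeline either on synthetic
recordings (generated from the configured seed) or on supplied files, and
writes every table plus a JSON summary keyed by a hash of the exact
configuration.  Any stage failure aborts with the stage name attached.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from . import io as _io
from .config import Config
from .kinematics import AngleTrace, detect_movements, lowpass_angle, movement_periods
from .protocol import PROTOCOL_TABLE, build_train
from .response import (
    compare_slopes,
    entrainment_amplitudes,
    post_stim_spectrum,
    tuning_curve,
)
from .spectral import cwt_scalogram, mean_power_spectrum, normalize_spectrum
from .spikes import (
    bandpass_rate,
    composite_kernel,
    instantaneous_frequency,
    qc_single_unit,
    to_logical_vector,
)
from .synthetic import (
    cf_plant,
    simulate_plant,
    simulate_spike_train,
    simulate_spontaneous_whisking,
    ss_plant,
)

__all__ = ["PipelineError", "run_full_analysis"]

#: lead time simulated before the first pulse of each train (ms)
TRAIN_PAD_MS = 1000.0


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r}: {message}")
        self.stage = stage


def _stage(name: str):
    def wrap(fn):
        def inner(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(name, str(exc)) from exc
        return inner
    return wrap


@_stage("spikes")
def _analyze_spikes(config: Config, train, out: Path) -> dict:
    qc = qc_single_unit(train)
    vec = to_logical_vector(train)
    kernel = composite_kernel(config.kernel_widths, config.kernel_support)
    rate = instantaneous_frequency(vec, kernel, config.fs_hz)
    banded = bandpass_rate(rate, *config.rate_band_hz, order=config.butter_order)
    _io.write_rate_trace(out / "ss_rate.csv", banded)
    scal = cwt_scalogram(
        banded.interior(), config.fs_hz, config.cwt_fmin_hz, config.cwt_fmax_hz,
        config.cwt_df_hz, config.morlet_omega0,
    )
    spec = mean_power_spectrum(scal)
    _io.write_spectrum(out / "ss_rate_spectrum.csv", spec)
    return {
        "qc_passed": qc.passed,
        "qc_violations": list(qc.violations),
        "n_ss": int(train.ss_times_ms.size),
        "n_cs": int(train.cs_times_ms.size),
        "rate_peak_hz": round(spec.peak_hz, 6),
    }


@_stage("whisker")
def _analyze_whisking(config: Config, trace: AngleTrace, out: Path) -> dict:
    filt = lowpass_angle(trace, config.angle_lowpass_hz, config.butter_order)
    events = detect_movements(filt, config.movement_threshold_deg)
    periods = movement_periods(events, config.merge_gap_ms, config.fs_hz)
    _io.write_movement_events(out / "whisk_events.csv", events, config.fs_hz)
    summary: dict = {
        "n_events": len(events),
        "n_movement_periods": len(periods),
    }
    if periods:
        scal = cwt_scalogram(
            filt.values_deg, config.fs_hz, config.cwt_fmin_hz, config.cwt_fmax_hz,
            config.cwt_df_hz, config.morlet_omega0,
        )
        spec = mean_power_spectrum(scal, periods)
        _io.write_spectrum(out / "whisk_spectrum.csv", normalize_spectrum(spec, config.spectrum_normalization))
        summary["movement_peak_hz"] = round(spec.peak_hz, 6)
    return summary


@_stage("stim-response")
def _analyze_drive(config: Config, drive: str, traces, trains, out: Path) -> dict:
    """Per-frequency amplitudes/spectra plus the tuning curve for one drive."""
    per_freq: dict = {}
    slopes: dict[float, float] = {}
    for freq, trace in sorted(traces.items()):
        train = trains[freq]
        ent = entrainment_amplitudes(trace, train, drive_type=drive.upper())
        slopes[freq] = ent.slope
        first = int(round(train.onsets_ms[0] * config.fs_hz / 1000.0))
        last = int(round(train.end_ms * config.fs_hz / 1000.0))
        scal = cwt_scalogram(
            trace.values_deg, config.fs_hz, config.cwt_fmin_hz, config.cwt_fmax_hz,
            config.cwt_df_hz, config.morlet_omega0,
        )
        spec = normalize_spectrum(
            mean_power_spectrum(scal, [(first, last)]), config.spectrum_normalization
        )
        _io.write_spectrum(out / f"{drive}_{freq:g}Hz_spectrum.csv", spec)
        _before, after, same_peak = post_stim_spectrum(
            trace, train, config.post_stim_window_ms,
            fmax=config.cwt_fmax_hz, df=config.cwt_df_hz,
        )
        per_freq[f"{freq:g}"] = {
            "entrain_amplitudes_deg": [round(a, 6) for a in ent.amplitudes_deg],
            "entrain_slope_deg_per_stim": round(ent.slope, 6),
            "stim_spectrum_peak_hz": round(spec.peak_hz, 6),
            "post_stim_peak_hz": round(after.peak_hz, 6),
            "post_peak_matches_drive": same_peak,
        }
    curve = tuning_curve(traces, trains)
    return {
        "per_frequency": per_freq,
        "tuning_amplitude_deg": {f"{f:g}": round(a, 6) for f, a in curve.amplitude_deg.items()},
        "tuning_argmax_hz": curve.argmax_hz,
        "_slopes": slopes,
    }


def _simulate_drive(config: Config, drive: str, freqs, seed: int):
    params = ss_plant() if drive == "ss" else cf_plant()
    traces, trains = {}, {}
    for freq in freqs:
        train = build_train(freq, start_ms=TRAIN_PAD_MS)
        sim = simulate_plant(
            train, params, seed=(seed + int(freq * 10)) % 2**31,
            duration_ms=train.end_ms + 2000.0, fs_hz=config.fs_hz,
        )
        traces[freq] = lowpass_angle(sim.trace, config.angle_lowpass_hz, config.butter_order)
        trains[freq] = train
    return traces, trains


def run_full_analysis(
    config: Config,
    out_dir,
    simulate: bool = True,
    freqs=None,
    angle_path=None,
    stim_path=None,
    events_path=None,
    drive: str = "ss",
) -> dict:
    """Run every stage and write tables plus ``summary.json`` to ``out_dir``.

    With ``simulate=True`` (default) all inputs are generated from
    ``config.seed``: one synthetic unit, one spontaneous-whisking trace, and
    stimulus-driven responses for both drive types across ``freqs`` (default:
    the seven protocol frequencies).  With files supplied instead, only the
    stages whose inputs are present run.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {"config_hash": config.content_hash(), "seed": config.seed}

    if simulate:
        freqs = tuple(freqs) if freqs is not None else tuple(sorted(PROTOCOL_TABLE))
        spike_sim = simulate_spike_train(seed=config.sub_seed("spikes"))
        summary["spikes"] = _analyze_spikes(config, spike_sim.train, out)
        whisk_sim = simulate_spontaneous_whisking(seed=config.sub_seed("whisking"))
        summary["whisking"] = _analyze_whisking(config, whisk_sim.trace, out)
        drive_slopes = {}
        for drv in ("ss", "cf"):
            result = _analyze_drive(
                config, drv,
                *_simulate_drive(config, drv, freqs, config.sub_seed(f"plant-{drv}")),
                out,
            )
            drive_slopes[drv] = result.pop("_slopes")
            summary[drv] = result
        common = sorted(set(drive_slopes["ss"]) & set(drive_slopes["cf"]))
        if len(common) >= 3:
            cmp = compare_slopes(
                [drive_slopes["ss"][f] for f in common],
                [drive_slopes["cf"][f] for f in common],
            )
            summary["slope_comparison"] = {
                "t_statistic": round(cmp.t_statistic, 6),
                "p_value": round(cmp.p_value, 6),
                "higher": cmp.higher,
                "degenerate": cmp.degenerate,
                "paired_frequencies_hz": [float(f) for f in common],
            }
    else:
        try:
            trace = _io.read_angle_trace(angle_path) if angle_path else None
            session = _io.read_stim_log(stim_path) if stim_path else None
            spikes = _io.read_events(events_path) if events_path else None
        except (OSError, ValueError) as exc:
            raise PipelineError("io", str(exc)) from exc
        if spikes is not None:
            summary["spikes"] = _analyze_spikes(config, spikes, out)
        if trace is not None and session is None:
            summary["whisking"] = _analyze_whisking(config, trace, out)
        if trace is not None and session is not None:
            filt = lowpass_angle(trace, config.angle_lowpass_hz, config.butter_order)
            traces = {t.freq_hz: filt for t in session.trains}
            trains = {t.freq_hz: t for t in session.trains}
            result = _analyze_drive(config, drive, traces, trains, out)
            result.pop("_slopes", None)
            summary[drive] = result

    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return summary
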