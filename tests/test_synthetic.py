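"""Synthetic generators: plant physics, whisking statistics, spike trains."""

import numpy as np
import pytest

from whiskres.kinematics import count_cycles, detect_movements, lowpass_angle, movement_periods
from whiskres.protocol import StimTrain, build_train
from whiskres.spectral import cwt_scalogram, mean_power_spectrum
from whiskres.spikes import (
    bandpass_rate,
    composite_kernel,
    instantaneous_frequency,
    qc_single_unit,
    to_logical_vector,
)
from whiskres.synthetic import (
    PlantParams,
    SpikeGenParams,
    cf_plant,
    simulate_plant,
    simulate_spike_train,
    simulate_spontaneous_whisking,
    ss_plant,
)


def one_pulse_train():
    return StimTrain(freq_hz=0.5, onsets_ms=np.array([500.0]), ipi_ms=2000.0)


# -- plant -------------------------------------------------------------------

def test_plant_is_linear_in_drive_gain():
    train = one_pulse_train()
    a = simulate_plant(train, cf_plant(noise_sd_deg=0.0), seed=0, duration_ms=3000.0)
    b = simulate_plant(train, cf_plant(noise_sd_deg=0.0, drive_gain=24.0), seed=0, duration_ms=3000.0)
    assert np.allclose(b.trace.values_deg, 2.0 * a.trace.values_deg, atol=1e-9)


def test_plant_seed_determinism():
    train = build_train(4.0, start_ms=500.0)
    a = simulate_plant(train, ss_plant(), seed=42)
    b = simulate_plant(train, ss_plant(), seed=42)
    assert np.array_equal(a.trace.values_deg, b.trace.values_deg)


def test_zero_stimuli_zero_trace():
    empty = StimTrain(freq_hz=1.0, onsets_ms=np.array([]), ipi_ms=1000.0)
    sim = simulate_plant(empty, cf_plant(noise_sd_deg=0.0), seed=0, duration_ms=2000.0)
    assert not sim.trace.values_deg.any()


def test_cf_single_pulse_one_cycle():
    # CF-type drive: one protraction-retraction cycle per light pulse
    sim = simulate_plant(one_pulse_train(), cf_plant(noise_sd_deg=0.0), seed=0, duration_ms=3000.0)
    filt = lowpass_angle(sim.trace)
    assert count_cycles(filt, (0, len(filt))) == 1


def test_ss_single_pulse_two_cycles():
    # the 125 ms echo adds a second supra-threshold cycle
    sim = simulate_plant(
        one_pulse_train(), ss_plant(noise_sd_deg=0.0, entrain_increment=0.0), seed=0, duration_ms=3000.0
    )
    filt = lowpass_angle(sim.trace)
    assert count_cycles(filt, (0, len(filt))) == 2


def test_free_ringing_frequency_matches_parameter():
    # noise off: ringing extrema of the 8 Hz plant are half a period apart
    sim = simulate_plant(one_pulse_train(), cf_plant(noise_sd_deg=0.0), seed=0, duration_ms=3000.0)
    events = detect_movements(lowpass_angle(sim.trace), threshold_deg=0.3)
    starts = [e.start_idx for e in events if e.kind == "protraction"]
    # the first protraction starts at the command onset; later ones at the
    # ringing troughs, one damped period apart
    assert len(starts) >= 3
    trough_aligned = np.diff(starts[1:])
    assert trough_aligned == pytest.approx(125.0, abs=2.0)


def test_plant_rejects_invalid_params():
    with pytest.raises(ValueError):
        PlantParams(damping_ratio=1.0)
    with pytest.raises(ValueError):
        PlantParams(damping_ratio=0.0)
    with pytest.raises(ValueError):
        PlantParams(echo_gain=1.0)
    with pytest.raises(ValueError):
        simulate_plant(one_pulse_train(), ss_plant(echo_delay_ms=10.0), seed=0)
    with pytest.raises(ValueError):
        simulate_plant(one_pulse_train(), cf_plant(), seed=0, fs_hz=0.0)
    with pytest.raises(ValueError):
        simulate_plant(one_pulse_train(), cf_plant(), seed=0, duration_ms=400.0)


def test_entrainment_gains_recorded_as_ground_truth():
    train = build_train(8.0, start_ms=500.0)
    sim = simulate_plant(train, ss_plant(entrain_increment=0.02), seed=0)
    assert sim.stim_gains[0] == 1.0
    assert sim.stim_gains[-1] == pytest.approx(1.0 + 0.02 * (train.n_pulses - 1))


# -- spontaneous whisking ----------------------------------------------------

def test_whisking_spectrum_peaks_at_generator_frequency():
    sim = simulate_spontaneous_whisking(amp_deg=8.0, mod_freq_hz=8.0, seed=5)
    filt = lowpass_angle(sim.trace)
    periods = movement_periods(detect_movements(filt))
    spec = mean_power_spectrum(cwt_scalogram(filt.values_deg), periods)
    assert abs(spec.peak_hz - 8.0) <= 0.5


def test_subthreshold_whisking_yields_no_events():
    sim = simulate_spontaneous_whisking(amp_deg=1.0, seed=2)
    assert detect_movements(lowpass_angle(sim.trace)) == []


def test_zero_bout_rate_rest_only():
    sim = simulate_spontaneous_whisking(bout_rate=0.0, seed=0)
    assert sim.rest_only and sim.bouts_ms == ()
    assert detect_movements(lowpass_angle(sim.trace)) == []


def test_too_short_duration_flags_rest_only():
    sim = simulate_spontaneous_whisking(duration_ms=500.0, seed=0)
    assert sim.rest_only


def test_whisking_seed_determinism():
    a = simulate_spontaneous_whisking(seed=9)
    b = simulate_spontaneous_whisking(seed=9)
    assert np.array_equal(a.trace.values_deg, b.trace.values_deg)
    assert a.bouts_ms == b.bouts_ms


def test_bout_center_reaches_double_amplitude():
    sim = simulate_spontaneous_whisking(amp_deg=6.0, seed=4, noise_sd_deg=0.0)
    a, b = sim.bouts_ms[0]
    seg = sim.trace.values_deg[int(a) : int(b)]
    assert seg.max() - seg.min() >= 2 * 6.0 * 0.99


# -- spike trains ------------------------------------------------------------

@pytest.mark.parametrize("seed", [0, 1, 2])
def test_spike_train_respects_refractoriness_and_pauses(seed):
    sim = simulate_spike_train(seed=seed)
    ss, cs = sim.train.ss_times_ms, sim.train.cs_times_ms
    assert np.diff(ss).min() >= 3.0
    for t in cs:
        after = ss[(ss > t) & (ss < t + 8.0)]
        assert after.size == 0
    assert qc_single_unit(sim.train).passed


def test_spike_train_seed_determinism():
    a = simulate_spike_train(seed=3)
    b = simulate_spike_train(seed=3)
    assert np.array_equal(a.train.ss_times_ms, b.train.ss_times_ms)
    assert np.array_equal(a.train.cs_times_ms, b.train.cs_times_ms)


def test_modulated_train_spectrum_peaks_at_mod_freq():
    sim = simulate_spike_train(SpikeGenParams(mod_freq_hz=7.0, mod_depth=0.5), seed=1)
    rate = bandpass_rate(instantaneous_frequency(to_logical_vector(sim.train), composite_kernel()))
    spec = mean_power_spectrum(cwt_scalogram(rate.interior()))
    assert abs(spec.peak_hz - 7.0) <= 1.0


def test_unmodulated_train_spectrum_is_flat():
    # no injected oscillation: peak power stays near the background level
    sim = simulate_spike_train(SpikeGenParams(mod_depth=0.0), seed=1)
    rate = bandpass_rate(instantaneous_frequency(to_logical_vector(sim.train), composite_kernel()))
    spec = mean_power_spectrum(cwt_scalogram(rate.interior()))
    assert spec.power.max() / np.median(spec.power) < 3.0


def test_invalid_baseline_rejected():
    with pytest.raises(ValueError):
        SpikeGenParams(baseline_rate_hz=0.0)
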