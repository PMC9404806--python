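"""Stimulus-aligned amplitudes, entrainment slopes, and spectra."""

import numpy as np
import pytest
from scipy import stats as sp_stats

from whiskres.kinematics import AngleTrace, lowpass_angle
from whiskres.protocol import StimTrain, build_train
from whiskres.response import (
    align_traces,
    compare_slopes,
    entrainment_amplitudes,
    entrainment_slope,
    epoch_amplitude,
    post_stim_spectrum,
    tuning_curve,
)
from whiskres.synthetic import cf_plant, simulate_plant, ss_plant

FS = 1000.0


def periodic_trace(period_ms=125, n_periods=40, amp=5.0):
    """A trace that repeats identically every period: 8 Hz by default."""
    t = np.arange(0, n_periods * period_ms) / 1000.0
    return AngleTrace(values_deg=amp * np.sin(2 * np.pi * (1000.0 / period_ms) * t), fs_hz=FS)


def train_at(freq, n, start=0.0, ipi=None):
    ipi = ipi if ipi is not None else 1000.0 / freq
    return StimTrain(freq_hz=freq, onsets_ms=start + ipi * np.arange(n), ipi_ms=ipi)


# -- alignment ---------------------------------------------------------------

def test_identical_responses_zero_dispersion():
    trace = periodic_trace()
    train = train_at(8.0, 30, start=500.0)
    aligned = align_traces(trace, train, (100.0, 125.0))
    assert np.max(aligned.dispersion) < 1e-9


def test_mean_trace_is_matrix_mean():
    trace = periodic_trace()
    train = train_at(8.0, 20, start=500.0)
    aligned = align_traces(trace, train, (0.0, 125.0))
    assert np.allclose(aligned.mean_trace, aligned.trial_matrix.mean(axis=0), atol=1e-12)


def test_out_of_bounds_window_names_stimulus():
    trace = periodic_trace(n_periods=10)
    train = train_at(8.0, 10, start=0.0)
    with pytest.raises(ValueError, match="stimulus 0"):
        align_traces(trace, train, (100.0, 125.0))


def test_ss_mean_trace_shows_two_cycles_per_epoch():
    # 4 Hz SS-type drive: the aligned mean shows the pulse cycle and the echo cycle
    train = build_train(4.0, start_ms=1000.0)
    sim = simulate_plant(train, ss_plant(), seed=2, duration_ms=train.end_ms + 2000.0)
    filt = lowpass_angle(sim.trace)
    aligned = align_traces(filt, train, (0.0, 250.0))
    mean = AngleTrace(values_deg=aligned.mean_trace, fs_hz=FS)
    from whiskres.kinematics import count_cycles

    assert count_cycles(mean, (0, len(mean))) == 2


# -- epoch amplitudes --------------------------------------------------------

def test_flat_trace_zero_amplitude():
    trace = AngleTrace(values_deg=np.zeros(5000), fs_hz=FS)
    assert epoch_amplitude(trace, train_at(8.0, 10, start=100.0), 3) == 0.0


def test_full_cycle_epoch_reads_peak_to_peak():
    trace = periodic_trace(amp=5.0)
    train = train_at(8.0, 30, start=250.0)
    for i in range(0, 30, 7):
        assert epoch_amplitude(trace, train, i) == pytest.approx(10.0, rel=1e-3)


def test_low_freq_window_excludes_late_whisks():
    # 1 Hz train; a large spontaneous whisk at +600 ms must not count
    x = np.zeros(6000)
    onset = 1000
    x[onset : onset + 100] = 3.0  # small evoked response
    x[onset + 600 : onset + 700] = 15.0  # spontaneous whisk
    trace = AngleTrace(values_deg=x, fs_hz=FS)
    train = train_at(1.0, 3, start=float(onset))
    assert epoch_amplitude(trace, train, 0) == pytest.approx(3.0)


def test_amplitude_offset_and_scale_behavior():
    trace = periodic_trace(amp=5.0)
    train = train_at(8.0, 20, start=250.0)
    base = epoch_amplitude(trace, train, 2)
    shifted = AngleTrace(values_deg=trace.values_deg + 31.0, fs_hz=FS)
    scaled = AngleTrace(values_deg=trace.values_deg * 3.0, fs_hz=FS)
    assert epoch_amplitude(shifted, train, 2) == pytest.approx(base)
    assert epoch_amplitude(scaled, train, 2) == pytest.approx(3.0 * base)


def test_epoch_index_out_of_range():
    with pytest.raises(IndexError):
        epoch_amplitude(periodic_trace(), train_at(8.0, 5, start=500.0), 5)


# -- entrainment -------------------------------------------------------------

def test_entrainment_lengths_follow_protocol():
    t14 = build_train(14.0, start_ms=500.0)
    sim = simulate_plant(t14, ss_plant(), seed=0, duration_ms=t14.end_ms + 1000.0)
    assert entrainment_amplitudes(lowpass_angle(sim.trace), t14).amplitudes_deg.size == 15
    t05 = build_train(0.5, start_ms=500.0)
    sim = simulate_plant(t05, ss_plant(), seed=0, duration_ms=t05.end_ms + 1000.0)
    assert entrainment_amplitudes(lowpass_angle(sim.trace), t05).amplitudes_deg.size == 10


def test_entrainment_requires_ten_pulses():
    train = train_at(8.0, 5, start=500.0)
    with pytest.raises(ValueError, match="10"):
        entrainment_amplitudes(periodic_trace(), train)


def test_entrained_amplitudes_increase_noise_free():
    train = build_train(1.0, start_ms=1000.0)
    sim = simulate_plant(
        train, ss_plant(entrain_increment=0.02, noise_sd_deg=0.0), seed=0,
        duration_ms=train.end_ms + 1000.0,
    )
    amps = entrainment_amplitudes(lowpass_angle(sim.trace), train).amplitudes_deg
    rho = sp_stats.spearmanr(np.arange(amps.size), amps).statistic
    assert rho > 0.8
    assert np.all(np.diff(amps) > 0)


def test_no_entrainment_constant_amplitudes():
    train = build_train(1.0, start_ms=1000.0)
    sim = simulate_plant(
        train, ss_plant(entrain_increment=0.0, noise_sd_deg=0.0), seed=0,
        duration_ms=train.end_ms + 1000.0,
    )
    res = entrainment_amplitudes(lowpass_angle(sim.trace), train)
    assert abs(res.slope) < 1e-3


def test_slope_exact_line():
    assert entrainment_slope([1.0, 2.0, 3.0, 4.0, 5.0]) == pytest.approx(1.0, abs=1e-12)
    assert entrainment_slope([2.5] * 8) == pytest.approx(0.0, abs=1e-12)


def test_slope_matches_closed_form():
    rng = np.random.default_rng(5)
    y = rng.normal(size=15)
    x = np.arange(1, 16, dtype=float)
    oracle = np.sum((x - x.mean()) * (y - y.mean())) / np.sum((x - x.mean()) ** 2)
    assert entrainment_slope(y) == pytest.approx(oracle, abs=1e-12)


def test_slope_needs_three_points():
    with pytest.raises(ValueError):
        entrainment_slope([1.0, 2.0])


# -- slope comparison --------------------------------------------------------

def test_equal_slopes_null_result():
    res = compare_slopes([0.1, 0.2, 0.3], [0.1, 0.2, 0.3])
    assert res.t_statistic == 0.0 and res.p_value == 1.0 and res.higher == "equal"


def test_constant_shift_is_degenerate_significant():
    ss = [0.1, 0.2, 0.3, 0.15, 0.22, 0.18, 0.25]
    cf = [s - 0.05 for s in ss]
    res = compare_slopes(ss, cf)
    assert res.degenerate and res.p_value == 0.0 and res.higher == "ss"


def test_matches_textbook_paired_t():
    rng = np.random.default_rng(11)
    ss = rng.normal(0.2, 0.05, 7)
    cf = rng.normal(0.1, 0.05, 7)
    res = compare_slopes(ss, cf)
    d = ss - cf
    t_oracle = d.mean() / (d.std(ddof=1) / np.sqrt(d.size))
    p_oracle = 2 * sp_stats.t.sf(abs(t_oracle), d.size - 1)
    assert res.t_statistic == pytest.approx(t_oracle, abs=1e-12)
    assert res.p_value == pytest.approx(p_oracle, abs=1e-12)


def test_mismatched_lengths_rejected():
    with pytest.raises(ValueError):
        compare_slopes([0.1, 0.2], [0.1])


# -- tuning curve ------------------------------------------------------------

def test_moved_resonance_moves_tuning_argmax():
    # control: with the plant resonant at 14 Hz the tuning curve peaks at 14
    traces, trains = {}, {}
    for f in (4.0, 8.0, 14.0):
        train = build_train(f, start_ms=1000.0)
        sim = simulate_plant(
            train, ss_plant(resonance_freq_hz=14.0, echo_delay_ms=1000.0 / 14.0),
            seed=int(f), duration_ms=train.end_ms + 2000.0,
        )
        traces[f], trains[f] = lowpass_angle(sim.trace), train
    assert tuning_curve(traces, trains).argmax_hz == 14.0


def test_missing_frequency_warns_partial_curve():
    train = build_train(8.0, start_ms=1000.0)
    sim = simulate_plant(train, ss_plant(), seed=0, duration_ms=train.end_ms + 2000.0)
    with pytest.warns(UserWarning, match="partial"):
        curve = tuning_curve({8.0: lowpass_angle(sim.trace)}, {8.0: train, 4.0: build_train(4.0)})
    assert list(curve.amplitude_deg) == [8.0]


# -- post-stimulation spectra ------------------------------------------------

def test_plant_ringing_does_not_carry_drive_frequency():
    train = build_train(14.0, start_ms=1500.0)
    sim = simulate_plant(train, ss_plant(), seed=5, duration_ms=train.end_ms + 2000.0)
    _before, after, same = post_stim_spectrum(lowpass_angle(sim.trace), train)
    assert not same
    assert after.peak_hz != pytest.approx(14.0, abs=0.1)


def test_persistent_oscillation_is_detected():
    # positive control: a trace that keeps oscillating at the drive frequency
    t = np.arange(0, 40.0, 1 / FS)
    trace = AngleTrace(values_deg=6.0 * np.sin(2 * np.pi * 14.0 * t), fs_hz=FS)
    train = train_at(14.0, 20, start=20_000.0, ipi=77.0)
    _before, after, same = post_stim_spectrum(trace, train)
    assert same and after.peak_hz == pytest.approx(14.0, abs=0.1)


def test_flat_post_window_not_a_match():
    x = np.concatenate([6.0 * np.sin(2 * np.pi * 8.0 * np.arange(0, 4.0, 1 / FS)), np.zeros(3000)])
    trace = AngleTrace(values_deg=x, fs_hz=FS)
    train = train_at(8.0, 10, start=2875.0)
    _before, after, same = post_stim_spectrum(trace, train)
    assert not same
    assert after.power.max() < 1e-6


def test_insufficient_samples_rejected():
    trace = periodic_trace(n_periods=10)
    train = train_at(8.0, 9, start=100.0)
    with pytest.raises(ValueError, match="side"):
        post_stim_spectrum(trace, train)
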