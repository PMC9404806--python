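# Methods

This note documents the models, estimators, and numerical choices behind
`whiskres`, in the order the pipeline applies them.

## Instantaneous simple-spike frequency

Simple-spike (SS) event times are binned into a *logical* vector at the
video rate (1 kHz): sample `k` is 1 if at least one SS falls in the
half-open millisecond bin `[k, k+1)`.  A logical rather than a count vector
is used; with a 3 ms refractory period the two coincide.

The rate estimate is the convolution of this vector with a composite
Gaussian kernel: the elementwise mean of `exp(-x²/2n²)` for `n = 8` and
`n = 20` samples, evaluated on a 100-sample support.  Because 100 is even,
the grid is offset by half a sample (x = −49.5 … +49.5) so the kernel is
exactly symmetric with exactly 100 points.  Each kernel is normalized to
unit sum before averaging, and the convolution is multiplied by the
sampling rate, so the output is in Hz — the only convention under which a
periodic r-Hz spike train reads r Hz.  The narrow component tracks fast
rate transients; the wide component stabilizes the theta-band estimate.
Convolution uses zero-padded edges; the first and last 50 ms (half the
kernel support) of any rate trace are flagged as edge-contaminated and
excluded from spectral readouts (`RateTrace.interior()`).

A useful exact property: for a periodic train at rate `f₀`, the estimator's
ripple around `f₀` is `2 f₀ Σₘ |K̂(m f₀)|` where `K̂` is the kernel's
transfer function.  At 50 Hz this is ≈ 2.1 Hz (dominated by the `n = 8`
component) — the tests assert this computed bound, not a nominal one.

The rate is band-passed 3–25 Hz with a 4th-order Butterworth filter applied
forward and backward (`sosfiltfilt`): the order is a conventional choice,
and zero-phase filtering preserves event timing for stimulus alignment.
Band-passing removes the 1/f background so spectral peaks reflect
oscillatory modulation.

## Single-unit quality control

A recording passes QC when all of the following hold: minimal SS
inter-spike interval 3 ms; every complex spike (CS) followed by ≥ 8 ms
without SS; when per-spike amplitude/width series are available, no more
than three consecutive spikes deviating > 3 SD from their mean; duration
≥ 40 s.  QC returns *all* violated criteria by name and never raises on
recording content.

## Whisker kinematics

The whisker signal is the mean angle of all trackable whiskers per frame.
It is low-passed at 30 Hz (4th-order zero-phase Butterworth) before event
detection.

Events are defined on local extrema: every consecutive extremum pair whose
excursion reaches 4° becomes one protraction (angle increase) or
retraction (decrease).  Extrema are sign changes of the first difference;
plateaus resolve to their midpoint (trace-end plateaus to the sample
nearest the motion).  Sub-threshold wiggles are merged into the
surrounding sweep by iteratively deleting the smallest sub-threshold
adjacent extremum pair — but only when the merged sweep stays shorter than
`max_merge_span_ms` (default 300 ms, about twice the half-cycle of the
slowest whisking-band component).  The cap matters: unconstrained merging
would bridge multi-second rest epochs and fuse separate whisking bouts
into single pseudo-events.  A consequence is that alternation of event
kinds is guaranteed only for contiguous events (those sharing a bounding
extremum); events separated by sub-threshold rest stretches are
independent sweeps and may repeat kind.

Whether the ±4° criterion applies to extremum-to-extremum excursions (as
here) or to a derivative-based onset definition is ambiguous in the
source description; the excursion reading is the simpler and is applied
uniformly.

Movement periods are the union of event spans, merging events separated by
less than 250 ms (one inter-pulse interval at 4 Hz; exposed in the
config).  Per-event kinematics: amplitude = |angle change| between the
bounding extrema; duration = span / rate; peak velocity = max |first
difference| × rate, in deg/ms, with no extra smoothing (the 30 Hz low-pass
already suppresses frame noise).  A complete *cycle* is a protraction
immediately followed by its retraction; `count_cycles` counts cycles whose
protraction starts in a given interval.

## Morlet scalograms and spectra

Scalograms use an analytic Morlet wavelet with ω₀ = 6 cycles, implemented
as an exact frequency-domain Gaussian filterbank: for each analysis
frequency `f`, the signal spectrum is multiplied by
`2·exp(−ω₀²(ω/ω_f − 1)²/2)` on positive frequencies and inverse
transformed.  Amplitude (L1) normalization is used — a unit-amplitude tone
yields unit magnitude at its own frequency regardless of `f` — matching
the convention of the MATLAB wavelet toolbox; with energy (L2)
normalization the implicit 1/f weighting distorts comparisons between
low-frequency drive lines and the 8 Hz resonance.  The filterbank form was
chosen over an off-the-shelf integrated-wavelet approximation because the
latter carries a ~1 % scale-dependent amplitude tilt, enough to displace
the argmax for a pure 14 Hz tone by 0.3 Hz; the exact filterbank recovers
integer-frequency tones exactly on the grid.  The approximate
implementation (PyWavelets) is retained in the test suite as an
independent cross-check, as is the periodogram.

The frequency grid is 1–30 Hz in 0.1 Hz steps — fine enough to express
sub-integer peaks; signals must span at least one period of the lowest
frequency.  Mean power spectra are time averages of the scalogram,
optionally restricted to movement periods.  Per frequency, one cone of
influence (√2 wavelet standard deviations, ≈ `√2·ω₀/2πf` seconds) is
excluded at each edge so boundary transients do not inflate low-frequency
power; if the exclusion would leave fewer than 20 % of the selected
samples (short windows at low frequency), it is clipped so a central
portion always survives.  Normalization divides by the maximum (unit-peak
spectra); area normalization is available.  Peak frequencies break ties
toward the lower frequency.

## Stimulation protocol

Seven train frequencies with 20 ms pulses; inter-pulse intervals and pulse
counts are stored as the published lookup table — 0.5 Hz/2000 ms/10,
1 Hz/1000 ms/20, 2 Hz/500 ms/40, 4 Hz/250 ms/80, 8 Hz/125 ms/140,
14 Hz/77 ms/280, 28 Hz/35 ms/660 — rather than derived from 20 s / IPI,
because the printed counts deviate from exact division at the higher
frequencies and fidelity to the protocol as run wins.  A consistency
warning (never an error) fires if count × IPI strays more than 20 % from
20 s.  Sessions alternate trains with ~10 s rests; the in-session order is
not documented, so the default uses the listed order with the two repeated
trains (0.5 and 14 Hz) appended, overridable everywhere.

## Stimulus-response quantification

Whisker traces are aligned to pulse onsets.  Two amplitude definitions
coexist deliberately, mirroring the two questions asked of the data:

- *Tuning-curve amplitude*: max − min of the stimulus-averaged mean trace
  over one epoch window.  Averaged traces suppress spontaneous movement,
  so this is the cleaner measure of the evoked response per frequency.
- *Entrainment amplitude*: max − min of the raw (low-passed) single-trial
  trace between consecutive stimuli, for the first 15 stimuli (10 at
  0.5 Hz — all that are delivered).  Growth across stimuli is what
  entrainment means, so single trials are required.

For train frequencies strictly below 4 Hz both use a 250 ms post-onset
window instead of the full inter-stimulus interval, excluding spontaneous
whisks between widely spaced stimuli (at 4 Hz the IPI is 250 ms anyway, so
the boundary is inert).  The last stimulus of a train uses one nominal IPI
after its onset.  Entrainment slopes are ordinary least-squares fits of
amplitude against 1-based stimulus number (deg/stimulus); SS vs CF slopes
are compared with a two-sided paired t-test, paired by train frequency
(zero-variance differences are reported with a degenerate flag rather than
a numerical blow-up).  Pre/post-train spectra compare 1 s before the last
onset with 1 s starting after its pulse; these short windows use a 2 Hz
lower grid edge (a 1 s segment cannot support 1 Hz), which is safely below
every train frequency of interest.

## The synthetic whisker plant

The plant is a linear second-order underdamped oscillator,
`θ̈ + 2ζω_n θ̇ + ω_n² θ = ω_n² u(t)`, integrated with its exact
zero-order-hold discretization at 1 kHz (poles mapped exactly; stable at
arbitrary durations, unlike naive Euler).  Parameters and defaults:

| parameter | default | meaning |
|---|---|---|
| `resonance_freq_hz` | 8 | observed (damped) ringing frequency |
| `damping_ratio` | 0.25 | underdamped; successive half-cycles shrink ×0.44 |
| `drive_gain` | 12 | steady deflection (deg) per unit command |
| `echo_delay_ms` | 125 | reverberation-loop period |
| `echo_gain` | 0.7 | relative echo amplitude |
| `n_echoes` | 1 (SS) / 0 (CF) | reverberant echoes per pulse |
| `entrain_increment` | 0.01 (SS) / 0 (CF) | fractional gain growth per stimulus |
| `noise_sd_deg` | 0.2 | Gaussian measurement noise |
| `latency_ms` | 0 | LED-to-command latency (physiological value unknown) |

`resonance_freq_hz` is deliberately the *damped* frequency: the ringing
period is then exactly 125 ms at 8 Hz, so pulse responses, echoes, and
4 Hz drive (two ring periods) are mutually phase-locked.  This is what
makes the within-epoch protraction-onset interval exactly one loop period
and the cycle dichotomy sharp.  A consequence of heavy damping is that the
*spectral* peak of free ringing sits below the ringing frequency by the
closed-form factor `√((1−2ζ²)/(1−ζ²))` ≈ 0.966 at ζ = 0.25; parameter
recovery therefore inverts this known factor when estimating the ringing
frequency from a spectrum.

Each pulse injects a rectangular 20 ms command (the LED pulse width) of
amplitude `drive_gain · (1 + entrain_increment · i)` for stimulus `i`
(0-based), plus `n_echoes` echoes at multiples of `echo_delay_ms` scaled
by `echo_gainᵏ`.  `drive_gain = 12` places single-pulse responses at
~8–12° peak-to-peak, inside the observed range of voluntary whisk
amplitudes (8–14°).  The multiplicative per-stimulus gain is the simplest
mechanism producing the linear amplitude trend that a straight-line fit
quantifies.

What the generator reproduces: one supra-threshold cycle per CF pulse
versus two per SS pulse; whisker spectra during 2/4/8 Hz SS drive peaking
at 8 Hz; maximal evoked amplitude at 8 Hz drive for both types; positive
entrainment slopes under SS drive.  What it does not: even without echoes
a ζ = 0.25 plant ringing at 8 Hz concentrates *spectral* energy near 8 Hz,
so CF-driven spectra also peak near 8 Hz — the dichotomy that survives in
the spectrum is the *relative* power at the drive frequency, which is
substantially higher for CF than for SS drive (the echo selectively
boosts 8 Hz).  Tests assert that relative signature rather than a
drive-frequency argmax for CF.

Spontaneous whisking alternates exponential rest epochs (mean
1/`bout_rate`, default 5 s) with 1.5–3 s bouts: a sinusoid at
`mod_freq_hz` (default 8) under a flat-topped Tukey envelope (α = 0.15,
chosen so ≥ 90 % of each bout exceeds the ±4° detection threshold at the
default 6° amplitude), peak-to-peak 2 × `amp_deg` at the bout centre.
It emulates the bout/rest structure and theta-band rhythm of voluntary
whisking, not its amplitude drift, frequency jitter within bouts, or
asymmetric protraction/retraction speeds — passing tests show the
pipeline recovers bout structure and rhythm, not that it handles every
idiosyncrasy of real tracking data.

Synthetic spike trains draw SS candidates by thinning a homogeneous
process at the rate ceiling against
`r(t) = baseline · (1 + mod_depth · sin(2π f_mod t))` (clipped at 0),
then enforce a 3 ms absolute refractory period; CS are homogeneous Poisson
(1 Hz) and delete SS within the 8 ms post-CS pause.  Defaults
(baseline 60 Hz, depth 0.5, f_mod 7 Hz, 40 s) give theta-band-modulated
trains that pass the single-unit QC by construction.  Refractory thinning
lowers the realized mean rate below `baseline` (~15 % at defaults) but
leaves the modulation frequency — the recovered quantity — untouched.

## Problem sizes and determinism

Simulations follow the published protocol sizes (full trains: 10–660
pulses, ~20 s at 1 kHz; spike trains 40 s — the QC minimum).  Every
generator takes an explicit seed; identical seeds give bit-identical
outputs.  The pipeline derives per-module sub-seeds from one global seed
by stable hashing of the consumer's name, so adding a stage never shifts
another stage's stream.  `scripts/acceptance.py` regenerates everything
from scratch for a given `--seed`; its two reported quantities (common
8 Hz spectral peak across 2/4/8 Hz SS drive; 125 ms median within-epoch
protraction-onset interval at 4 Hz) are stable across seeds because they
are structural properties of the phase-locked plant, not tuned values.

## Known limitations

- The plant is linear and time-invariant; real whisker dynamics saturate,
  adapt, and vary across animals.  Only one whisker-average angle is
  modelled, as in the tracked data the pipeline consumes.
- Entrainment sign recovery is evaluated at low train frequencies
  (epochs separated by more than the ring-down time); at 14–28 Hz the
  off-resonant interference transient over the first stimuli can dominate
  the small per-stimulus gain growth, producing negative raw slopes for
  both drive types (their ordering in `entrain_increment` is preserved).
- The CWT grid starts at 1 Hz (2 Hz for the 1 s pre/post windows); slower
  phenomena are out of scope, as the rate signal is band-passed at 3 Hz
  anyway.
- The paired t-test on synthetic slopes has n = 7 (frequencies); the
  pipeline reports it, but significance on synthetic data depends on the
  chosen entrainment increment and is not a calibrated reproduction of
  empirical values.
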