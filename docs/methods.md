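# Methods

`flickerkit` implements the software side of audiovisual flicker
stimulation: synthesis and verification of the control signals, experiment
scheduling with a blinded-assignment protocol, the neural analysis chain
used to decide whether a recording is entrained, and the open-field
behavioral controls. Everything is validated against a built-in
synthetic-data generator, so no hardware or recordings are required.

## Stimulus model

A flicker stimulus is a periodic (or randomized) on/off gating of a light or
a tone. The canonical gamma stimulus is a 40-Hz square wave with a 50% duty
cycle, i.e. a 12.5-ms on-phase per 25-ms cycle. Auditory stimuli gate a pure
carrier tone — 10 kHz for mice, 7–8 kHz for humans — with the same square
envelope; audio-only stimulation uses a 4% duty cycle (a 1-ms click per
cycle) to match auditory steady-state-response click-train paradigms.
Amplitudes are unitless in [0, 1]: drive voltage and lux/dB calibration are
hardware properties, recorded at most as configuration metadata.

Sample-boundary convention: a sample is "on" iff its fractional cycle phase
lies in [0, duty), so the first sample of every cycle is on (rising edge at
the cycle start). On/off edges are derived from integer cycle-edge indices
rather than a per-sample floating-point modulo; this makes boundary samples
classify identically in every cycle. A partial final cycle is truncated and
excluded from the cycle log's duty statistics.

The randomized (aperiodic control) condition keeps every on-phase at exactly
12.5 ms and draws off-intervals i.i.d. uniform on [0, 25] ms, quantized to
the sample grid, from a seeded `numpy` generator. Per-cycle duty therefore
lies in [1/3, 1]; the nominal 33–99% duty range excludes off-intervals that
round to zero, which the uniform distribution does occasionally produce —
we keep the stated off-range rather than silently resampling and simply
report the observed minimum duty (33%).

Default sample rates are 40 kHz for visual control signals and 44.1 kHz for
audio (keeping the 10-kHz mouse carrier below Nyquist and allowing direct
16-bit-PCM WAV export). Inter-modal delays are quantized to the nearest
sample and the quantization error is recorded on the waveform.

`measure_waveform` is the in-software oscilloscope: it thresholds the
signal (or, for bipolar carrier-modulated audio, its Hilbert envelope
smoothed over one carrier period) at half the peak amplitude, takes the
fundamental from the median inter-onset interval of rising edges, and the
duty cycle as the mean per-cycle fraction of above-threshold samples. The
half-amplitude threshold is the standard oscilloscope convention. A constant
signal has an undefined fundamental, reported as `None`.

## Scheduling and blinding

The four preprogrammed tasks (classical, frequency, duration, single-pulse)
are plain trial lists; durations and rest periods are configurable because
the protocol does not fix them (defaults: 10-s trials, 30-s rests). Trial
order in the classical task is shuffled by the same seeded generator family
used everywhere else.

Blinded sessions resolve a subject id through an assignment table written by
a non-blinded third party. The resolved schedule is: a fixed test sequence
(2 s of 1-Hz light+tone pulses — the protocol specifies the sequence's
existence, not its content), a pause during which the experimenter leaves,
then the condition block. The test sequence and pause are byte-identical
across conditions, so the experimenter-observable prefix carries zero
condition information; logs written during the session store the condition
only as a salted SHA-256 code, with a separate unblinding key file.

## Synthetic data

The generator produces data with exactly the statistical structure the
analyses assume — no more:

* **Recordings** are unit-variance 1/f^β colored noise per channel
  (spectrally shaped white noise, default β = 1), with an additive sinusoid
  at the stimulation frequency, phase-locked to the stimulus onsets, from
  onset time onward. A pure sinusoid is the minimal steady-state-response
  surrogate; an optional harmonic stack is available but off by default.
  What this does **not** model: volume conduction, artifacts,
  non-stationarity, alpha rhythms, or realistic channel covariance — so
  passing tests demonstrate the correctness of the analysis chain, not its
  performance on real EEG.
* **Spike trains** are inhomogeneous Poisson with rate
  λ(t) = r·(1 + m·cos(2πft − φ)), simulated by thinning (exact for a
  bounded rate). The asymptotic vector strength for m = 1 is exactly 1/2,
  the first circular moment of (1 + cos θ)/2π — a closed-form oracle.
* **Trajectories** are built from a bout plan. "Still" bouts hold one
  position (jitter confined to a 0.02-cm disc, orders of magnitude below
  the 0.01%-arena criterion) for frames spanning exactly the requested
  duration. "Move" steps are ~1 cm/frame (30 cm/s at 30 fps) with both
  coordinate displacements bounded away from zero, so an interval
  containing any walking frame always violates the confinement criterion —
  this is what makes the 0.5-s boundary recovery exact.

All generators are bit-reproducible under a fixed seed.

## Preprocessing and spectral estimation

The chain runs in a fixed order, enforced by `preprocess`: polyphase
downsampling to 2 kHz → zero-phase band-pass (1–100 Hz for scalp EEG;
2–300 Hz or 300–6000 Hz variants are parameters) → optional Laplacian
re-reference → per-12-s-segment mean subtraction.

Numerical choices:

* The Hamming-window FIR band-pass uses a transition width of 25% of the
  low cutoff and is applied once with center alignment — a symmetric
  linear-phase kernel applied this way is exactly zero-phase, without
  squaring the magnitude response as forward–backward filtering would.
  The IIR option (4th-order Butterworth) is applied forward–backward.
  A 1-Hz low edge at 2048 Hz implies ~27k taps; the kernel is capped at a
  third of the record length (with a warning) so short segments remain
  filterable, at the cost of a wider transition band.
* Baseline correction is per-segment DC (mean) subtraction; a trailing
  partial segment is corrected by its own mean.
* Laplacian re-referencing treats each hemisphere's contacts (ordered by
  `contact_order`) as one shank: interior contact *i* becomes
  x_i − (x_{i−1} + x_{i+1})/2. Edge contacts get the one-sided difference
  x_0 − x_1 and are flagged in a `laplacian_edge` metadata column rather
  than dropped, to preserve hemisphere coverage.
* The multitaper PSD uses `scipy` DPSS tapers with time-bandwidth product 3
  and 5 tapers over 2–100 Hz. Normalization is one-sided power per unit
  frequency, so the band-integrated PSD of a unit-variance signal recovers
  the variance. Power is reported as 10·log10 of (input units)²/Hz; the
  reference is arbitrary but consistent, and every downstream statistic is
  shift-invariant in dB. Zero power is floored at −300 dB.

## Modulation statistics

The channel criterion z-scores the dB power at the stimulation-frequency
bin against all bins whose centers fall in 31–39 or 41–49 Hz (inclusive);
a channel is modulated iff z ≥ 3 (inclusive, "at least three standard
deviations"). z-scoring on dB matches the units in which power is reported;
a linear-power option is provided. The subject criterion requires at least
3 modulated channels **and** at least one modulated channel in each
hemisphere; the source protocol states "either hemisphere" in one place and
"each hemisphere" in another, so the stricter reading is the default and
`hemisphere_rule="either"` gives the permissive one.

Detection latency grows a window anchored at stimulus onset in 1-s steps
and reports the first window length at which the subject criterion holds.
Note a resolution floor: with time-bandwidth 3, a window of T seconds has a
half-bandwidth of 3/T Hz, so windows shorter than 3 s leak the 40-Hz
mainlobe into the neighbor bands and cannot pass the criterion regardless
of response amplitude. The earliest achievable latency is therefore 3 s at
these estimator settings; on calibrated synthetic EEG (per-channel z ≈ 6 at
10-s windows) the detector typically fires at 2–4 s window lengths, well
inside the 10-s benchmark. The response amplitude for that benchmark is not
hard-coded: `calibrate_response_amplitude` bisects on log-amplitude against
the measured median z at 10-s windows.

Condition contrasts report paired t, Wilcoxon signed-rank, Cohen's d
computed on the paired differences (mean/SD of differences), and
per-condition medians and quartiles of power at the stimulation frequency.

Spike phase locking: each spike's phase is 2π·frac((t − onset)·f) relative
to the nearest preceding stimulus onset; the vector strength is the mean
resultant length and uniformity is tested with the Rayleigh test (Wilkie's
approximation). The protocol names no spike statistic; vector strength plus
Rayleigh is the field-standard operationalization of "firing at a
particular phase". Fewer than 10 spikes yields an insufficient-data flag
rather than unstable estimates.

The occluded-condition check runs the channel criterion on a recording made
while the subject is shielded from the stimuli; any modulated channel means
stimulation-frequency pickup that cannot be sensory, i.e. a suspected
electrical artifact.

## Behavioral analysis

Inactivity is a maximal interval whose positions stay within 0.01% of the
total arena area for strictly longer than 0.5 s. The commercial tracker's
internal "activity" definition is proprietary; we operationalize the
confinement test as the bounding box of the interval's positions (a
rotation-invariant bounding-disc variant is available), computed in O(n)
with monotonic deques, with tracking gaps (> 1.5× the median frame
interval) splitting candidates. Percent time active is
100·(1 − bout time / record time), so active + inactive = 100 exactly.
The center zone defaults to the central rectangle of 50% linear dimensions
(the protocol shows but does not dimension it) and occupancy counts frames
with boundary-inclusive containment. Condition comparisons use a one-way
repeated-measures ANOVA (statsmodels `AnovaRM`), which rejects unbalanced
designs.

## Problem sizes used in validation

The test suite and the acceptance script run at desk scale by design:
10,000 random-flicker cycles for the duty/off-interval bounds; 200 seeded
12-s single-channel runs for the false-positive rate of the 3-SD rule;
twenty 32-channel, 35-s recordings at 2048 Hz for the latency benchmark;
600-s spike trains at 50 Hz for the vector-strength closed form; and 10-s,
30-fps trajectories for the inactivity boundary scan. These sizes give
Monte-Carlo error comfortably inside the tolerances asserted.

## Known limitations

* The synthetic background is stationary Gaussian 1/f noise; false-positive
  rates of the 3-SD rule on real EEG (line noise, muscle, alpha) will
  differ.
* `measure_waveform` assumes an on/off-gated signal; it is not a general
  fundamental estimator.
* The Laplacian assumes one linear shank per hemisphere; grid or mixed
  geometries need explicit contact ordering.
* Latency is quantized to the window step (1 s default) and bounded below
  by the taper-bandwidth floor described above.
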