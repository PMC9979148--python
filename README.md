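# flickerkit

Audio/visual **flicker** — lights and tones switched on and off at a precise
rate — entrains neural oscillations noninvasively, reaching deep structures
such as the hippocampus, and is being explored as a therapy in
neurodegenerative disease. `flickerkit` is a Python toolkit for the software
side of such experiments, for researchers running flicker studies in mice or
humans:

* **Stimulus synthesis** with millisecond precision: square-wave visual
  flicker with an exact duty cycle, carrier-modulated audio (click trains),
  randomized aperiodic control flicker, single evoked-potential pulses,
  inter-modal delays, and an in-software "oscilloscope"
  (`measure_waveform`) that verifies frequency and duty of any generated
  signal. WAV and delimited-text export.
* **Experiment scheduling**: the four standard task types (classical,
  frequency, duration, single-pulse) and a blinded condition-assignment
  protocol whose experimenter-observable test sequence is identical across
  conditions and whose logs store the condition only as a salted code.
* **Entrainment analysis**: the EEG/LFP preprocessing chain (2-kHz
  polyphase downsampling, zero-phase Hamming-FIR band-pass, per-shank
  Laplacian re-reference, 12-s baseline correction), multitaper PSD
  (time-bandwidth 3, 5 DPSS tapers, 2–100 Hz), and the modulation criteria,
  plus detection latency, condition contrasts, spike phase locking, and an
  occluded-condition artifact check.
* **Behavioral controls**: open-field inactivity classification
  (confinement to 0.01% of the arena for > 0.5 s), center-zone occupancy,
  and repeated-measures ANOVA across stimulation conditions.
* **Synthetic data**: seeded generators for 1/f EEG with an additive
  steady-state response, cosine-modulated Poisson spike trains, and
  open-field trajectories — every analysis is testable without hardware.

## The statistics at the core

A channel is **modulated** when its power at the stimulation frequency f
stands out from the neighboring spectrum:

    z = (P(f) − mean P(31–39, 41–49 Hz)) / sd P(31–39, 41–49 Hz),   modulated ⟺ z ≥ 3

on dB-scale multitaper power. A **subject** is modulated with ≥ 3 modulated
channels including ≥ 1 in each hemisphere. **Detection latency** is the
smallest growing window after stimulus onset (1-s steps) satisfying the
subject criterion. **Spike phase locking** is the vector strength
R = |⟨e^{iθ}⟩| of spike phases θ relative to the stimulus cycle, tested for
uniformity with the Rayleigh test; for a Poisson train with rate
∝ 1 + cos θ, R → 1/2 exactly.

## Worked example

```python
from flickerkit import (square_wave, modulated_tone, measure_waveform,
                        gen_ssep_recording, bandpass, detection_latency,
                        calibrate_response_amplitude, gen_phase_locked_spikes,
                        spike_phase_locking)

# the canonical gamma stimulus: 40 Hz, 50% duty
w = square_wave(40, 0.5, duration=1.0)
print(measure_waveform(w))
# {'fundamental_freq': 40.0, 'duty': 0.5, 'onset_phase_ms': 0.0}
print(w.cycle_log.head(2))
#    cycle  on_ms  off_ms  duty
# 0      0   12.5    12.5   0.5     <- the 12.5-ms on-phase per 25-ms cycle
# 1      1   12.5    12.5   0.5

# audio-only click train: 8-kHz tone gated at 40 Hz with 4% duty
print(measure_waveform(modulated_tone(8000, 40, 0.04, 1.0))["duty"])
# 0.0404  (4% duty recovered by the half-amplitude threshold method)

# synthetic 32-channel EEG entrained from t = 20 s; amplitude calibrated so
# per-channel z ~ 6 on 10-s windows, then ask when the subject criterion fires
amp = calibrate_response_amplitude(target_z=6.0, seed=1)   # -> 0.191
rec = bandpass(gen_ssep_recording(n_channels=32, duration=35, stim_onset=20,
                                  response_amplitude=amp, seed=42), 1, 100)
print(detection_latency(rec, stim_onset=20.0))
# 3.0   (seconds after onset; well inside the 10-s benchmark)

# fully modulated Poisson spiking locks at vector strength 1/2
spk = gen_phase_locked_spikes(base_rate=50, mod_depth=1.0, duration=600, seed=2)
print(spike_phase_locking(spk, 40.0).vector_strength)
# 0.501  (closed-form limit: 0.5)
```

The calibrated amplitude (0.191) is the steady-state response amplitude, in
units of the background-noise standard deviation, that yields a channel
z-score of about 6 on 10-s windows; the latency of 3.0 s means the
3-channel/both-hemisphere criterion was met on the third 1-s growing window
after stimulus onset.

There is also a CLI:

```bash
flickerkit gen --modality audio --freq 40 --duty 0.04 --carrier 8000 --out tone
flickerkit task --type classical --modality visual --modality audio --out sched.csv
flickerkit run --blind --table assignments.csv --id m01 --out session/
flickerkit simulate --kind recording --seed 2 --duration 18 --amplitude 2 --out rec
flickerkit psd --rec rec --out psd.csv
flickerkit modulation --rec rec --out mod.csv
```

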