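"""Flicker stimulus waveform synthesis and measurement.

Control signals for audio/visual flicker stimulation: square waves with a
prescribed duty cycle, carrier-modulated tones (click trains), randomized
aperiodic flicker with fixed on-phases, single evoked-potential pulses, and
inter-modal delays.  Every generator returns a :class:`StimulusWaveform`
carrying the sampled signal, the commanded cycle-onset times, and a per-cycle
log of on/off durations and duty, so that stimuli can be verified after the
fact with :func:`measure_waveform` (the software analogue of checking the
device output on an oscilloscope).

Amplitudes are unitless in [0, 1]; drive voltage, illuminance, and sound
level are properties of the hardware chain, not of the control signal.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from scipy.io import wavfile
from scipy.signal import hilbert

__all__ = [
    "Modality",
    "Condition",
    "WaveformSpec",
    "StimulusWaveform",
    "square_wave",
    "modulated_tone",
    "random_flicker",
    "single_pulse",
    "pair_with_delay",
    "measure_waveform",
    "generate",
    "DEFAULT_VISUAL_RATE",
    "DEFAULT_AUDIO_RATE",
]

#: Default sample rate for visual control signals (Hz).
DEFAULT_VISUAL_RATE = 40_000.0
#: Default sample rate for audio signals (Hz); keeps a 10-kHz carrier below Nyquist.
DEFAULT_AUDIO_RATE = 44_100.0


class Modality(str, Enum):
    VISUAL = "visual"
    AUDIO = "audio"
    AUDIOVISUAL = "audiovisual"


class Condition(str, Enum):
    PERIODIC = "periodic"
    RANDOM = "random"
    CONSTANT = "constant"
    SINGLE_PULSE = "single_pulse"


class ParameterError(ValueError):
    """A stimulus parameter violates its contract."""


@dataclass
class WaveformSpec:
    """Full specification of a flicker stimulus.

    Parameters mirror what an experimenter sets on the device: modality,
    flicker frequency, duty cycle, carrier tone (audio only), amplitude,
    duration, and the condition (periodic / random / constant / single pulse).
    """

    modality: Modality = Modality.VISUAL
    flicker_freq: float = 40.0
    duty: float = 0.5
    carrier_freq: Optional[float] = None
    amplitude: float = 1.0
    duration: float = 1.0
    sample_rate: Optional[float] = None
    condition: Condition = Condition.PERIODIC
    audio_visual_delay_ms: float = 0.0
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        self.modality = Modality(self.modality)
        self.condition = Condition(self.condition)
        if self.sample_rate is None:
            self.sample_rate = (
                DEFAULT_VISUAL_RATE
                if self.modality is Modality.VISUAL
                else DEFAULT_AUDIO_RATE
            )
        if not 0.0 <= self.duty <= 1.0:
            raise ParameterError(f"duty must lie in [0, 1], got {self.duty}")
        if self.duration <= 0:
            raise ParameterError("duration must be positive")
        if self.flicker_freq >= self.sample_rate / 2:
            raise ParameterError("flicker_freq must be below Nyquist")
        if self.carrier_freq is not None and self.carrier_freq >= self.sample_rate / 2:
            raise ParameterError("carrier_freq must be below Nyquist")
        if not 0.0 <= self.amplitude <= 1.0:
            raise ParameterError("amplitude must lie in [0, 1]")


def _empty_cycle_log() -> pd.DataFrame:
    return pd.DataFrame(columns=["cycle", "on_ms", "off_ms", "duty"]).astype(
        {"cycle": int, "on_ms": float, "off_ms": float, "duty": float}
    )


def _cycle_log(on_samples: np.ndarray, off_samples: np.ndarray, fs: float) -> pd.DataFrame:
    on_ms = np.asarray(on_samples, float) / fs * 1e3
    off_ms = np.asarray(off_samples, float) / fs * 1e3
    with np.errstate(invalid="ignore"):
        duty = np.where(on_ms + off_ms > 0, on_ms / (on_ms + off_ms), np.nan)
    return pd.DataFrame(
        {"cycle": np.arange(len(on_ms)), "on_ms": on_ms, "off_ms": off_ms, "duty": duty}
    )


@dataclass
class StimulusWaveform:
    """A sampled flicker control signal plus its timing bookkeeping.

    Attributes
    ----------
    samples : ndarray
        Signal values, |sample| <= amplitude.
    sample_rate : float
        Hz.
    onsets : ndarray
        Strictly increasing on-phase start times in seconds (commanded
        cycle starts, first at t = 0 for periodic stimuli).
    cycle_log : DataFrame
        One row per complete cycle: ``cycle, on_ms, off_ms, duty``.
        A partial cycle truncated by the end of the record is excluded.
    """

    samples: np.ndarray
    sample_rate: float
    onsets: np.ndarray
    cycle_log: pd.DataFrame
    amplitude: float = 1.0
    modality: Modality = Modality.VISUAL
    meta: dict = field(default_factory=dict)

    @property
    def duration(self) -> float:
        return len(self.samples) / self.sample_rate

    @property
    def times(self) -> np.ndarray:
        return np.arange(len(self.samples)) / self.sample_rate

    # ------------------------------------------------------------------ export
    def to_wav(self, path) -> None:
        """Write 16-bit PCM WAV (sample values clipped to [-1, 1])."""
        pcm = np.int16(np.clip(self.samples, -1.0, 1.0) * 32767)
        wavfile.write(str(path), int(round(self.sample_rate)), pcm)

    def to_csv(self, path) -> None:
        """Write the sampled control signal as delimited text (time_s, value)."""
        pd.DataFrame({"time_s": self.times, "value": self.samples}).to_csv(
            path, index=False
        )

    def cycle_log_to_csv(self, path) -> None:
        self.cycle_log.rename(columns={"cycle": "cycle_index"}).to_csv(path, index=False)

    def onsets_to_csv(self, path, label: str = "on") -> None:
        """Write onset times as an event file (time_s, label)."""
        pd.DataFrame({"time_s": self.onsets, "label": label}).to_csv(path, index=False)


# --------------------------------------------------------------------------
# generators
# --------------------------------------------------------------------------

def _square_envelope(flicker_freq: float, duty: float, n: int, fs: float) -> np.ndarray:
    # A sample at index k is "on" iff its fractional cycle phase lies in
    # [0, duty): the first sample of every cycle is on (rising edge at cycle
    # start, as drawn on the oscilloscope traces).  Edges are computed from
    # integer cycle indices rather than a per-sample float modulo, so
    # boundary samples are classified identically in every cycle.
    if duty >= 1.0:
        return np.ones(n)
    if duty <= 0.0:
        return np.zeros(n)
    period = fs / flicker_freq
    env = np.zeros(n)
    for c in range(int(math.ceil(n / period))):
        a = int(math.ceil(c * period - 1e-9))
        b = int(math.ceil(c * period + duty * period - 1e-9))
        env[a : min(b, n)] = 1.0
    return env


def _periodic_bookkeeping(
    flicker_freq: float, duty: float, n: int, fs: float
) -> tuple[np.ndarray, pd.DataFrame]:
    period = fs / flicker_freq  # samples, possibly fractional
    n_full = int(math.floor(n / period + 1e-9))
    cycles = np.arange(n_full)
    starts = np.ceil(cycles * period - 1e-9).astype(int)
    ends = np.ceil((cycles + 1) * period - 1e-9).astype(int)
    on_ends = np.ceil(cycles * period + duty * period - 1e-9).astype(int)
    on_counts = on_ends - starts
    off_counts = ends - on_ends
    onsets = starts / fs
    return onsets, _cycle_log(on_counts, off_counts, fs)


def square_wave(
    flicker_freq: float,
    duty: float,
    duration: float,
    sample_rate: float = DEFAULT_VISUAL_RATE,
    amplitude: float = 1.0,
) -> StimulusWaveform:
    """Periodic square-wave flicker control signal.

    Each cycle is high (= ``amplitude``) for ``duty / flicker_freq`` seconds
    from the cycle start and zero for the remainder.  The canonical gamma
    stimulus is a 40-Hz square wave with a 50% duty cycle (12.5-ms on-phase);
    ``duty=1`` degenerates to the constant-light control.
    """
    spec = WaveformSpec(
        flicker_freq=flicker_freq,
        duty=duty,
        duration=duration,
        sample_rate=sample_rate,
        amplitude=amplitude,
    )
    fs = spec.sample_rate
    n = int(round(duration * fs))
    env = _square_envelope(flicker_freq, duty, n, fs)
    onsets, log = _periodic_bookkeeping(flicker_freq, duty, n, fs)
    if duty == 0.0:
        onsets = np.empty(0)
    return StimulusWaveform(
        samples=amplitude * env,
        sample_rate=fs,
        onsets=onsets,
        cycle_log=log,
        amplitude=amplitude,
        modality=Modality.VISUAL,
    )


def modulated_tone(
    carrier_freq: float,
    flicker_freq: float,
    duty: float,
    duration: float,
    sample_rate: float = DEFAULT_AUDIO_RATE,
    amplitude: float = 1.0,
) -> StimulusWaveform:
    """Pure sinusoid tone gated by a square-wave envelope.

    The auditory flicker signal: a carrier tone (10 kHz for mice, 7-8 kHz for
    humans) switched on and off by a square wave of the flicker frequency.
    A 50% duty cycle is used for audiovisual stimulation; a 4% duty cycle
    makes the audio-only click train used to match auditory steady-state
    response paradigms.
    """
    if carrier_freq <= flicker_freq:
        raise ParameterError("carrier_freq must exceed flicker_freq")
    spec = WaveformSpec(
        modality=Modality.AUDIO,
        flicker_freq=flicker_freq,
        duty=duty,
        carrier_freq=carrier_freq,
        duration=duration,
        sample_rate=sample_rate,
        amplitude=amplitude,
    )
    fs = spec.sample_rate
    n = int(round(duration * fs))
    t = np.arange(n) / fs
    env = _square_envelope(flicker_freq, duty, n, fs)
    onsets, log = _periodic_bookkeeping(flicker_freq, duty, n, fs)
    if duty == 0.0:
        onsets = np.empty(0)
    return StimulusWaveform(
        samples=amplitude * np.sin(2 * np.pi * carrier_freq * t) * env,
        sample_rate=fs,
        onsets=onsets,
        cycle_log=log,
        amplitude=amplitude,
        modality=Modality.AUDIO,
        meta={"carrier_freq": carrier_freq},
    )


def random_flicker(
    on_ms: float = 12.5,
    off_range_ms: tuple[float, float] = (0.0, 25.0),
    duration: float = 60.0,
    sample_rate: float = DEFAULT_VISUAL_RATE,
    amplitude: float = 1.0,
    seed: int = 0,
) -> StimulusWaveform:
    """Aperiodic control flicker: fixed on-phase, randomized off-intervals.

    Every on-phase lasts exactly ``on_ms`` (12.5 ms by default, matching the
    total light-on time of the 40-Hz condition) while off-intervals are drawn
    i.i.d. uniform on ``off_range_ms`` (0-25 ms by default).  Off-intervals
    are quantized to the sample grid; the cycle log records the quantized
    values.  Identical seeds give bit-identical output.
    """
    if on_ms <= 0:
        raise ParameterError("on_ms must be positive")
    off_min, off_max = off_range_ms
    if off_max < off_min or off_min < 0:
        raise ParameterError("off range must satisfy 0 <= off_min <= off_max")
    fs = float(sample_rate)
    n = int(round(duration * fs))
    on_n = int(round(on_ms / 1e3 * fs))
    if on_n < 1:
        raise ParameterError("on_ms shorter than one sample period")

    rng = np.random.default_rng(seed)
    samples = np.zeros(n)
    onsets: list[float] = []
    on_counts: list[int] = []
    off_counts: list[int] = []
    pos = 0
    while pos + on_n <= n:
        samples[pos : pos + on_n] = amplitude
        onsets.append(pos / fs)
        off = rng.uniform(off_min, off_max)
        off_n = int(round(off / 1e3 * fs))
        if pos + on_n + off_n <= n:  # complete cycle fits
            on_counts.append(on_n)
            off_counts.append(off_n)
        pos += on_n + off_n
    return StimulusWaveform(
        samples=samples,
        sample_rate=fs,
        onsets=np.asarray(onsets),
        cycle_log=_cycle_log(np.asarray(on_counts), np.asarray(off_counts), fs),
        amplitude=amplitude,
        modality=Modality.VISUAL,
        meta={"seed": seed, "on_ms": on_ms, "off_range_ms": tuple(off_range_ms)},
    )


def single_pulse(
    modality: Modality | str = Modality.VISUAL,
    width_ms: float = 12.5,
    sample_rate: Optional[float] = None,
    carrier_freq: Optional[float] = None,
    duration: float = 1.0,
    amplitude: float = 1.0,
) -> StimulusWaveform:
    """A single 12.5-ms (by default) pulse for evoked-potential tasks.

    Exactly one on-phase starting at t = 0; audio modalities carry the
    carrier sinusoid inside the pulse.
    """
    modality = Modality(modality)
    if width_ms <= 0:
        raise ParameterError("width_ms must be positive")
    if sample_rate is None:
        sample_rate = (
            DEFAULT_VISUAL_RATE if modality is Modality.VISUAL else DEFAULT_AUDIO_RATE
        )
    if duration * 1e3 < width_ms:
        raise ParameterError("duration shorter than pulse width")
    fs = float(sample_rate)
    n = int(round(duration * fs))
    on_n = int(round(width_ms / 1e3 * fs))
    samples = np.zeros(n)
    if modality is Modality.VISUAL:
        samples[:on_n] = amplitude
    else:
        if carrier_freq is None:
            raise ParameterError("audio pulse requires carrier_freq")
        if carrier_freq >= fs / 2:
            raise ParameterError("carrier_freq must be below Nyquist")
        t = np.arange(on_n) / fs
        samples[:on_n] = amplitude * np.sin(2 * np.pi * carrier_freq * t)
    log = _cycle_log(np.array([on_n]), np.array([n - on_n]), fs)
    return StimulusWaveform(
        samples=samples,
        sample_rate=fs,
        onsets=np.array([0.0]),
        cycle_log=log,
        amplitude=amplitude,
        modality=modality,
        meta={"width_ms": width_ms, "carrier_freq": carrier_freq},
    )


def pair_with_delay(
    visual: StimulusWaveform, audio: StimulusWaveform, delay_ms: float
) -> tuple[StimulusWaveform, StimulusWaveform]:
    """Offset the audio stimulus relative to the visual one.

    Positive ``delay_ms`` makes the audio lag the visual stream.  The delay
    is quantized to the nearest sample; the applied (quantized) delay and the
    quantization error are recorded in the returned audio waveform's ``meta``.
    The record length is preserved (samples shifted out are dropped, vacated
    samples are zero).
    """
    if visual.sample_rate != audio.sample_rate:
        raise ParameterError("sample rates must match to pair modalities")
    fs = audio.sample_rate
    shift = int(round(delay_ms / 1e3 * fs))
    applied_ms = shift / fs * 1e3
    samples = np.zeros_like(audio.samples)
    if shift >= 0:
        if shift < len(samples):
            samples[shift:] = audio.samples[: len(samples) - shift]
    else:
        samples[:shift] = audio.samples[-shift:]
    onsets = audio.onsets + shift / fs
    onsets = onsets[(onsets >= 0) & (onsets < audio.duration)]
    shifted = StimulusWaveform(
        samples=samples,
        sample_rate=fs,
        onsets=onsets,
        cycle_log=audio.cycle_log.copy(),
        amplitude=audio.amplitude,
        modality=audio.modality,
        meta={
            **audio.meta,
            "delay_ms_requested": delay_ms,
            "delay_ms_applied": applied_ms,
            "delay_quantization_ms": delay_ms - applied_ms,
        },
    )
    return visual, shifted


# --------------------------------------------------------------------------
# measurement (verification path for every generator)
# --------------------------------------------------------------------------

def _binary_envelope(w: StimulusWaveform) -> np.ndarray:
    """Threshold the (envelope of the) signal at half its peak amplitude."""
    x = np.asarray(w.samples, float)
    peak = np.max(np.abs(x))
    if peak == 0:
        return np.zeros(len(x), dtype=bool)
    if np.min(x) < -0.05 * peak:  # bipolar: carrier-modulated audio
        env = np.abs(hilbert(x))
        # one-carrier-period smoothing knocks down edge ringing
        carrier = w.meta.get("carrier_freq")
        if carrier:
            k = max(3, int(round(w.sample_rate / carrier)))
            kernel = np.ones(k) / k
            env = np.convolve(env, kernel, mode="same")
    else:
        env = x
    return env > peak / 2


def measure_waveform(w: StimulusWaveform) -> dict:
    """Measure fundamental frequency, duty cycle, and onset phase of a stimulus.

    The software analogue of putting the device output on an oscilloscope:
    the signal envelope is thresholded at half the peak amplitude, the
    fundamental is taken from the inter-onset intervals of the rising edges,
    and the duty cycle is the mean per-cycle fraction of above-threshold
    samples.  A constant signal has no fundamental (reported as ``None``)
    and a duty of 1 (constant on) or 0 (silence).
    """
    x = np.asarray(w.samples, float)
    if len(x) == 0:
        raise ParameterError("waveform is empty")
    peak = float(np.max(np.abs(x)))
    if peak == 0:
        return {"fundamental_freq": None, "duty": 0.0, "onset_phase_ms": None}
    on = _binary_envelope(w)
    if on.all():
        return {"fundamental_freq": None, "duty": 1.0, "onset_phase_ms": 0.0}
    rising = np.flatnonzero(~on[:-1] & on[1:]) + 1
    if on[0]:
        rising = np.concatenate([[0], rising])
    fs = w.sample_rate
    if len(rising) < 2:
        duty = float(on.mean())
        onset_ms = rising[0] / fs * 1e3 if len(rising) else None
        return {"fundamental_freq": None, "duty": duty, "onset_phase_ms": onset_ms}
    intervals = np.diff(rising) / fs
    fundamental = 1.0 / float(np.median(intervals))
    duties = [
        float(on[a:b].mean()) for a, b in zip(rising[:-1], rising[1:])
    ]
    return {
        "fundamental_freq": fundamental,
        "duty": float(np.mean(duties)),
        "onset_phase_ms": rising[0] / fs * 1e3,
    }


def generate(spec: WaveformSpec) -> StimulusWaveform:
    """Dispatch a :class:`WaveformSpec` to the matching generator.

    The random condition maps duty/frequency to the fixed-on randomized
    scheme: on-phase = duty / flicker_freq, off-intervals uniform on
    [0, 2 x (1 - duty) / flicker_freq] so the mean period matches the
    periodic condition (40 Hz at 50% duty gives on = 12.5 ms, off in
    [0, 25] ms).
    """
    if spec.condition is Condition.PERIODIC:
        if spec.modality is Modality.VISUAL:
            return square_wave(
                spec.flicker_freq, spec.duty, spec.duration, spec.sample_rate,
                spec.amplitude,
            )
        carrier = spec.carrier_freq or 8000.0
        return modulated_tone(
            carrier, spec.flicker_freq, spec.duty, spec.duration, spec.sample_rate,
            spec.amplitude,
        )
    if spec.condition is Condition.CONSTANT:
        return square_wave(
            spec.flicker_freq, 1.0, spec.duration, spec.sample_rate, spec.amplitude
        )
    if spec.condition is Condition.RANDOM:
        on_ms = spec.duty / spec.flicker_freq * 1e3
        off_max = 2 * (1 - spec.duty) / spec.flicker_freq * 1e3
        return random_flicker(
            on_ms, (0.0, off_max), spec.duration, spec.sample_rate, spec.amplitude,
            seed=spec.seed if spec.seed is not None else 0,
        )
    if spec.condition is Condition.SINGLE_PULSE:
        return single_pulse(
            spec.modality,
            sample_rate=spec.sample_rate,
            carrier_freq=spec.carrier_freq,
            duration=spec.duration,
            amplitude=spec.amplitude,
        )
    raise ParameterError(f"unhandled condition {spec.condition}")
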