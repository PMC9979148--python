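"""Synthetic neural and behavioral data with the structure the analyses assume.

Three generators, all bit-reproducible under a fixed seed:

* :func:`gen_ssep_recording` — multichannel EEG/LFP surrogate: 1/f colored
  background noise plus, after stimulus onset, a sinusoidal steady-state
  evoked response phase-locked to the stimulus cycle onsets.  A pure
  sinusoid is the minimal surrogate for the steady-state response; an
  optional harmonic stack can be added.
* :func:`gen_phase_locked_spikes` — inhomogeneous Poisson spike train with
  rate ``base_rate * (1 + m * cos(2*pi*f*t - phi))``, simulated by thinning
  (exact for a bounded rate).
* :func:`gen_trajectory` — open-field trajectory built from a bout plan of
  "move" (random walk) and "still" (held position with sub-resolution
  jitter) segments.

The module also owns the delimited-text readers/writers for recordings,
spike trains, and trajectories that the analysis modules consume.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Recording",
    "SpikeTrain",
    "Trajectory",
    "gen_ssep_recording",
    "gen_phase_locked_spikes",
    "gen_trajectory",
    "powerlaw_noise",
    "write_recording",
    "read_recording",
    "write_spikes",
    "read_spikes",
    "write_trajectory",
    "read_trajectory",
]


@dataclass
class Recording:
    """Multichannel neural trace with channel metadata and stimulus events.

    ``channels`` has one row per data row: ``channel_id``, ``hemisphere``
    ("L"/"R"), ``contact_order`` (position along the electrode shank).
    ``events`` are stimulus cycle-onset times in seconds.
    """

    data: np.ndarray  # (n_channels, n_samples)
    sample_rate: float
    channels: pd.DataFrame
    events: np.ndarray = field(default_factory=lambda: np.empty(0))
    condition: Optional[str] = None

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data, float))
        if len(self.channels) != self.data.shape[0]:
            raise ValueError("channel metadata rows must match channel count")
        if len(self.events) and (
            np.min(self.events) < 0 or np.max(self.events) > self.duration
        ):
            raise ValueError("event times must lie within the record span")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.sample_rate


@dataclass
class SpikeTrain:
    """Sorted spike times of one unit (seconds, strictly increasing)."""

    times: np.ndarray
    unit_id: str = "unit0"

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, float)
        if len(self.times) and np.min(self.times) < 0:
            raise ValueError("spike times must be non-negative")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("spike times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.times)


def default_center_zone(width: float, height: float, linear_fraction: float = 0.5):
    """Central rectangle covering ``linear_fraction`` of each arena dimension."""
    dx = width * (1 - linear_fraction) / 2
    dy = height * (1 - linear_fraction) / 2
    return (dx, dy, width - dx, height - dy)


@dataclass
class Trajectory:
    """Timestamped 2-D positions in a rectangular arena (cm)."""

    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    arena_width: float
    arena_height: float
    center_zone: Optional[tuple] = None  # (x0, y0, x1, y1)

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, float)
        self.x = np.asarray(self.x, float)
        self.y = np.asarray(self.y, float)
        if self.arena_width <= 0 or self.arena_height <= 0:
            raise ValueError("arena dimensions must be positive")
        if np.any(np.diff(self.t) <= 0):
            raise ValueError("trajectory times must be strictly increasing")
        eps = 1e-9
        if np.any(self.x < -eps) or np.any(self.x > self.arena_width + eps) or np.any(
            self.y < -eps
        ) or np.any(self.y > self.arena_height + eps):
            raise ValueError("positions must lie within the arena")
        if self.center_zone is None:
            self.center_zone = default_center_zone(self.arena_width, self.arena_height)

    @property
    def arena_area(self) -> float:
        return self.arena_width * self.arena_height

    @property
    def duration(self) -> float:
        return float(self.t[-1] - self.t[0])


# --------------------------------------------------------------------------
# generators
# --------------------------------------------------------------------------

def powerlaw_noise(
    n: int, exponent: float, sample_rate: float, rng: np.random.Generator
) -> np.ndarray:
    """Unit-variance noise with power spectral density proportional to 1/f^exponent.

    White Gaussian noise is shaped in the frequency domain by f^(-exponent/2)
    (DC removed) and normalized to unit variance.
    """
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, 1.0 / sample_rate)
    shape = np.zeros_like(f)
    shape[1:] = f[1:] ** (-exponent / 2.0)
    x = np.fft.irfft(spec * shape, n)
    return x / x.std()


def gen_ssep_recording(
    n_channels: int = 32,
    hemisphere_map: Optional[Sequence[str]] = None,
    sample_rate: float = 2048.0,
    duration: float = 60.0,
    stim_freq: float = 40.0,
    stim_onset: float = 20.0,
    response_amplitude: float | Sequence[float] = 0.0,
    background_exponent: float = 1.0,
    harmonics: Sequence[float] = (),
    seed: int = 0,
    condition: Optional[str] = None,
) -> Recording:
    """Synthetic steady-state evoked response recording.

    Each channel is unit-variance 1/f^``background_exponent`` noise; from
    ``stim_onset`` onward a sinusoid at ``stim_freq`` phase-locked to the
    stimulus cycle onsets is added with the channel's ``response_amplitude``
    (scalar applies to every channel).  ``harmonics`` gives relative
    amplitudes of integer harmonics above the fundamental.  Channel metadata
    splits channels evenly into left/right hemispheres unless a
    ``hemisphere_map`` is given.
    """
    if stim_onset >= duration:
        raise ValueError("stim_onset must fall before the end of the record")
    amp = np.broadcast_to(np.asarray(response_amplitude, float), (n_channels,)).copy()
    if np.asarray(response_amplitude).ndim == 1 and len(
        np.atleast_1d(response_amplitude)
    ) not in (1, n_channels):
        raise ValueError("response_amplitude length must equal channel count")
    if hemisphere_map is None:
        hemisphere_map = ["L"] * (n_channels // 2) + ["R"] * (n_channels - n_channels // 2)
    if len(hemisphere_map) != n_channels:
        raise ValueError("hemisphere_map length must equal channel count")

    rng = np.random.default_rng(seed)
    n = int(round(duration * sample_rate))
    t = np.arange(n) / sample_rate
    stim_mask = t >= stim_onset
    response = np.sin(2 * np.pi * stim_freq * (t - stim_onset)) * stim_mask
    for k, h_amp in enumerate(harmonics, start=2):
        response = response + h_amp * np.sin(
            2 * np.pi * k * stim_freq * (t - stim_onset)
        ) * stim_mask

    data = np.empty((n_channels, n))
    for c in range(n_channels):
        data[c] = powerlaw_noise(n, background_exponent, sample_rate, rng)
        data[c] += amp[c] * response

    # contact_order restarts within each hemisphere (one shank per hemisphere)
    order = []
    counts: dict[str, int] = {}
    for h in hemisphere_map:
        counts[h] = counts.get(h, 0) + 1
        order.append(counts[h] - 1)
    channels = pd.DataFrame(
        {
            "channel_id": [f"ch{c:02d}" for c in range(n_channels)],
            "hemisphere": list(hemisphere_map),
            "contact_order": order,
        }
    )
    events = stim_onset + np.arange(int(np.floor((duration - stim_onset) * stim_freq))) / stim_freq
    return Recording(data, sample_rate, channels, events=events, condition=condition)


def gen_phase_locked_spikes(
    base_rate: float,
    mod_depth: float,
    stim_freq: float = 40.0,
    preferred_phase: float = 0.0,
    duration: float = 600.0,
    seed: int = 0,
    unit_id: str = "unit0",
) -> SpikeTrain:
    """Cosine-modulated inhomogeneous Poisson spike train (thinning algorithm).

    Rate: ``base_rate * (1 + mod_depth * cos(2*pi*stim_freq*t - preferred_phase))``.
    With ``mod_depth = 1`` the asymptotic vector strength is exactly 1/2
    (the first circular moment of (1 + cos)/2pi); with ``mod_depth = 0`` the
    train is homogeneous Poisson and the vector strength decays as
    ~ sqrt(pi)/(2 sqrt(N)).
    """
    if base_rate <= 0:
        raise ValueError("base_rate must be positive")
    if not 0.0 <= mod_depth <= 1.0:
        raise ValueError("mod_depth must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    lam_max = base_rate * (1.0 + mod_depth)
    n_cand = rng.poisson(lam_max * duration)
    cand = np.sort(rng.uniform(0.0, duration, n_cand))
    rate = base_rate * (
        1.0 + mod_depth * np.cos(2 * np.pi * stim_freq * cand - preferred_phase)
    )
    keep = rng.uniform(0.0, lam_max, n_cand) < rate
    times = cand[keep]
    times = times[np.concatenate([[True], np.diff(times) > 0])]  # drop exact ties
    return SpikeTrain(times=times, unit_id=unit_id)


def gen_trajectory(
    arena: tuple[float, float] = (30.0, 30.0),
    duration: float = 60.0,
    frame_rate: float = 30.0,
    bout_plan: Optional[Sequence[tuple[str, float]]] = None,
    seed: int = 0,
    step_cm: float = 1.0,
    jitter_cm: float = 0.02,
    center_zone: Optional[tuple] = None,
) -> Trajectory:
    """Open-field trajectory from a plan of ("move"|"still", duration_s) bouts.

    "move" bouts take random-walk steps whose x and y displacements are both
    bounded away from zero (magnitude ~ ``step_cm / sqrt(2)``), reflecting
    off the walls, so any interval containing a walking frame has a bounding
    box far larger than the stationarity footprint.  "still" bouts take one
    step and then hold that position — with jitter confined to a disc of
    radius ``jitter_cm``, far below 0.01% of the arena area — for frames
    spanning exactly the requested bout duration.  Frames not covered by the
    plan are "move".
    """
    width, height = arena
    if width <= 0 or height <= 0:
        raise ValueError("arena dimensions must be positive")
    n_frames = int(round(duration * frame_rate))
    if bout_plan is None:
        bout_plan = []
    planned = sum(d for _, d in bout_plan)
    if planned > duration + 1e-9:
        raise ValueError("bout durations exceed the trajectory duration")

    # expand the plan to a per-frame state sequence; a still bout of duration
    # d holds one position for round(d * frame_rate) + 1 frames so that the
    # time between the first and last held frame is exactly d.
    states: list[str] = []
    for state, d in bout_plan:
        if state not in ("move", "still"):
            raise ValueError(f"unknown bout state {state!r}")
        n_bout = int(round(d * frame_rate)) + (1 if state == "still" else 0)
        states.extend([state] * n_bout)
    states = states[:n_frames]
    states.extend(["move"] * (n_frames - len(states)))

    rng = np.random.default_rng(seed)
    pos = np.empty((n_frames, 2))
    p = np.array([width / 2.0, height / 2.0])
    comp = step_cm / np.sqrt(2.0)
    hold = False
    hold_center = p.copy()
    for k, state in enumerate(states):
        if state == "move" or not hold:
            step = comp * rng.uniform(0.8, 1.2, 2) * rng.choice([-1.0, 1.0], 2)
            p = p + step
            # reflect at walls
            p[0] = np.clip(np.abs(p[0]), 0, None)
            p[1] = np.clip(np.abs(p[1]), 0, None)
            if p[0] > width:
                p[0] = 2 * width - p[0]
            if p[1] > height:
                p[1] = 2 * height - p[1]
            p = np.clip(p, [0, 0], [width, height])
        if state == "still":
            if not hold:
                hold = True
                hold_center = p.copy()
            if jitter_cm > 0:
                r = jitter_cm * np.sqrt(rng.uniform())
                ang = rng.uniform(0, 2 * np.pi)
                q = hold_center + r * np.array([np.cos(ang), np.sin(ang)])
            else:
                q = hold_center
            pos[k] = np.clip(q, [0, 0], [width, height])
        else:
            hold = False
            pos[k] = p
    t = np.arange(n_frames) / frame_rate
    return Trajectory(
        t=t, x=pos[:, 0], y=pos[:, 1],
        arena_width=width, arena_height=height, center_zone=center_zone,
    )


# --------------------------------------------------------------------------
# delimited-text I/O (shared formats across analysis modules)
# --------------------------------------------------------------------------

def write_recording(rec: Recording, prefix) -> None:
    """Write ``<prefix>_data.csv``, ``<prefix>_channels.csv``, ``<prefix>_events.csv``."""
    prefix = Path(prefix)
    df = pd.DataFrame(rec.data.T, columns=rec.channels["channel_id"])
    df.insert(0, "time_s", np.arange(rec.n_samples) / rec.sample_rate)
    df.to_csv(prefix.with_name(prefix.name + "_data.csv"), index=False)
    meta = rec.channels.copy()
    meta.attrs["sample_rate"] = rec.sample_rate
    meta.to_csv(prefix.with_name(prefix.name + "_channels.csv"), index=False)
    pd.DataFrame({"time_s": rec.events, "label": rec.condition or "stim"}).to_csv(
        prefix.with_name(prefix.name + "_events.csv"), index=False
    )


def read_recording(prefix) -> Recording:
    prefix = Path(prefix)
    df = pd.read_csv(prefix.with_name(prefix.name + "_data.csv"))
    t = df.pop("time_s").to_numpy()
    sample_rate = 1.0 / float(np.median(np.diff(t)))
    channels = pd.read_csv(prefix.with_name(prefix.name + "_channels.csv"))
    ev_path = prefix.with_name(prefix.name + "_events.csv")
    events = np.empty(0)
    condition = None
    if ev_path.exists():
        ev = pd.read_csv(ev_path)
        events = ev["time_s"].to_numpy()
        if len(ev):
            condition = str(ev["label"].iloc[0])
    return Recording(df.to_numpy().T, sample_rate, channels, events=events, condition=condition)


def write_spikes(spikes: SpikeTrain, path) -> None:
    """One spike time (s) per line."""
    np.savetxt(path, spikes.times, fmt="%.9f")


def read_spikes(path, unit_id: str = "unit0") -> SpikeTrain:
    times = np.atleast_1d(np.loadtxt(path))
    return SpikeTrain(times=times, unit_id=unit_id)


def write_trajectory(traj: Trajectory, path) -> None:
    df = pd.DataFrame({"t": traj.t, "x": traj.x, "y": traj.y})
    header = (
        f"# arena_width={traj.arena_width} arena_height={traj.arena_height} "
        f"center_zone={','.join(f'{v:g}' for v in traj.center_zone)}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        df.to_csv(fh, index=False)


def read_trajectory(path) -> Trajectory:
    with open(path) as fh:
        header = fh.readline()
        df = pd.read_csv(fh)
    meta = dict(item.split("=") for item in header.lstrip("# ").split())
    zone = tuple(float(v) for v in meta["center_zone"].split(","))
    return Trajectory(
        t=df["t"].to_numpy(), x=df["x"].to_numpy(), y=df["y"].to_numpy(),
        arena_width=float(meta["arena_width"]),
        arena_height=float(meta["arena_height"]),
        center_zone=zone,
    )
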