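"""Experiment task schedules and the blinded condition-assignment protocol.

Four preprogrammed task types: a classical flicker task (every modality x
{5.5 Hz, 40 Hz, 80 Hz, random} combination in shuffled order), a frequency
task (up to 26 distinct frequencies of one modality), a duration task (one
long block of a single modality/frequency), and a single-pulse evoked
potential task.

Blinding: animals are assigned to conditions by a non-blinded third party in
a two-column table (subject_id, condition).  A blinded experimenter resolves
a subject id to its schedule; the resolved schedule starts with a fixed test
sequence (identical for every condition, so watching it carries no condition
information) followed by a pause during which the experimenter leaves the
room.  Session logs store the condition only as a salted hash code.
"""

from __future__ import annotations

import hashlib
import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .stimgen import Modality

__all__ = [
    "Trial",
    "TaskSchedule",
    "BlindingTable",
    "BlindedSession",
    "CLASSICAL_FREQUENCIES",
    "MAX_FREQUENCY_TRIALS",
    "build_classical_task",
    "build_frequency_task",
    "build_duration_task",
    "build_pulse_task",
    "resolve_blinded_condition",
    "condition_code",
]

#: Frequencies of the classical flicker task: theta-like, gamma-like, 80 Hz,
#: and the random non-periodic condition.
CLASSICAL_FREQUENCIES: tuple = (5.5, 40.0, 80.0, "random")
#: The frequency task accepts at most this many distinct frequencies.
MAX_FREQUENCY_TRIALS = 26
#: Default rest period between trials (s); configurable everywhere it is used.
DEFAULT_REST_S = 30.0


@dataclass(frozen=True)
class Trial:
    label: str
    modality: str
    frequency: Union[float, str]  # Hz or "random" / "pulse" / "constant"
    start_s: float
    duration_s: float


@dataclass
class TaskSchedule:
    """An ordered, non-overlapping sequence of stimulation trials."""

    trials: list[Trial] = field(default_factory=list)
    rest_s: float = DEFAULT_REST_S

    def __post_init__(self) -> None:
        starts = [t.start_s for t in self.trials]
        if sorted(starts) != starts:
            raise ValueError("trial start times must be increasing")
        for a, b in zip(self.trials[:-1], self.trials[1:]):
            if a.start_s + a.duration_s > b.start_s + 1e-12:
                raise ValueError(f"trials overlap: {a.label} and {b.label}")

    @property
    def total_duration(self) -> float:
        if not self.trials:
            return 0.0
        last = self.trials[-1]
        return last.start_s + last.duration_s

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "trial": i,
                    "label": t.label,
                    "modality": t.modality,
                    "frequency": str(t.frequency),
                    "start_s": t.start_s,
                    "duration_s": t.duration_s,
                }
                for i, t in enumerate(self.trials)
            ]
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, rest_s: float = DEFAULT_REST_S) -> "TaskSchedule":
        df = pd.read_csv(path, dtype={"frequency": str})
        trials = []
        for _, row in df.iterrows():
            freq: Union[float, str] = row["frequency"]
            try:
                freq = float(freq)
            except ValueError:
                pass
            trials.append(
                Trial(
                    label=row["label"],
                    modality=row["modality"],
                    frequency=freq,
                    start_s=float(row["start_s"]),
                    duration_s=float(row["duration_s"]),
                )
            )
        return cls(trials=trials, rest_s=rest_s)


def _sequence(entries, trial_duration: float, rest: float, t0: float = 0.0) -> list[Trial]:
    trials = []
    t = t0
    for label, modality, freq, dur in entries:
        trials.append(Trial(label, modality, freq, t, dur))
        t += dur + rest
    return trials


def build_classical_task(
    modalities: Iterable[Union[Modality, str]],
    trial_duration_s: float = 10.0,
    rest_s: float = DEFAULT_REST_S,
    order_seed: int = 0,
    frequencies: Sequence = CLASSICAL_FREQUENCIES,
) -> TaskSchedule:
    """Classical flicker task: every modality x frequency combination, shuffled.

    With all three modalities and the default frequency set this yields
    3 x 4 = 12 trial conditions in a seed-determined order.
    """
    modalities = [Modality(m).value for m in modalities]
    if not modalities:
        raise ValueError("at least one modality required")
    if trial_duration_s <= 0:
        raise ValueError("trial_duration_s must be positive")
    combos = [(m, f) for m in modalities for f in frequencies]
    rng = np.random.default_rng(order_seed)
    order = rng.permutation(len(combos))
    entries = [
        (f"{combos[i][0]}-{combos[i][1]}", combos[i][0], combos[i][1], trial_duration_s)
        for i in order
    ]
    return TaskSchedule(_sequence(entries, trial_duration_s, rest_s), rest_s)


def build_frequency_task(
    freqs: Sequence[float],
    modality: Union[Modality, str] = Modality.VISUAL,
    trial_duration_s: float = 10.0,
    rest_s: float = DEFAULT_REST_S,
) -> TaskSchedule:
    """Frequency task: one trial per frequency, at most 26 distinct frequencies."""
    modality = Modality(modality).value
    if not 1 <= len(freqs) <= MAX_FREQUENCY_TRIALS:
        raise ValueError(
            f"frequency task takes 1-{MAX_FREQUENCY_TRIALS} frequencies, got {len(freqs)}"
        )
    if len(set(freqs)) != len(freqs):
        raise ValueError("frequencies must be distinct")
    if trial_duration_s <= 0:
        raise ValueError("trial_duration_s must be positive")
    entries = [(f"{modality}-{f}", modality, float(f), trial_duration_s) for f in freqs]
    return TaskSchedule(_sequence(entries, trial_duration_s, rest_s), rest_s)


def build_duration_task(
    modality: Union[Modality, str] = Modality.AUDIOVISUAL,
    freq: Union[float, str] = 40.0,
    total_minutes: float = 60.0,
) -> TaskSchedule:
    """Duration task: one uninterrupted block (e.g. the 1-h mouse protocol)."""
    modality = Modality(modality).value
    if total_minutes <= 0:
        raise ValueError("total_minutes must be positive")
    trial = Trial(f"{modality}-{freq}", modality, freq, 0.0, total_minutes * 60.0)
    return TaskSchedule([trial], rest_s=0.0)


def build_pulse_task(
    modalities: Iterable[Union[Modality, str]],
    n_pulses: int,
    inter_pulse_interval_s: float = 2.0,
    width_ms: float = 12.5,
) -> TaskSchedule:
    """Single-pulse evoked potential task: 12.5-ms pulses at fixed intervals.

    ``n_pulses`` pulses per modality; modality blocks follow one another.
    Zero pulses gives an empty schedule.
    """
    modalities = [Modality(m).value for m in modalities]
    if n_pulses < 0:
        raise ValueError("n_pulses must be non-negative")
    if inter_pulse_interval_s <= 0:
        raise ValueError("inter_pulse_interval_s must be positive")
    width_s = width_ms / 1e3
    trials: list[Trial] = []
    t = 0.0
    for m in modalities:
        for k in range(n_pulses):
            trials.append(Trial(f"{m}-pulse", m, "pulse", t, width_s))
            t += inter_pulse_interval_s
    return TaskSchedule(trials, rest_s=inter_pulse_interval_s - width_s)


# --------------------------------------------------------------------------
# blinding
# --------------------------------------------------------------------------

@dataclass
class BlindingTable:
    """Subject-to-condition assignments made by a non-blinded third party."""

    assignments: dict[str, str]
    source: Optional[str] = None

    @classmethod
    def from_csv(cls, path) -> "BlindingTable":
        df = pd.read_csv(path, dtype=str)
        if list(df.columns[:2]) != ["subject_id", "condition"]:
            df.columns = ["subject_id", "condition", *df.columns[2:]]
        dupes = df["subject_id"][df["subject_id"].duplicated()].tolist()
        if dupes:
            raise ValueError(f"duplicate subject ids in blinding table: {dupes}")
        return cls(dict(zip(df["subject_id"], df["condition"])), source=str(path))

    def lookup(self, subject_id: str) -> str:
        if subject_id not in self.assignments:
            raise KeyError(f"subject id {subject_id!r} not found in blinding table")
        return self.assignments[subject_id]


def condition_code(condition: str, salt: str = "flickerkit") -> str:
    """Salted hash code standing in for the condition in observable logs."""
    return hashlib.sha256(f"{salt}:{condition}".encode()).hexdigest()[:8]


def _test_sequence_trials(duration_s: float = 2.0, pulse_rate_hz: float = 1.0) -> list[Trial]:
    # Identical for every condition: brief 1-Hz light+tone pulses so the
    # experimenter can confirm the LEDs and speaker work.
    n = int(round(duration_s * pulse_rate_hz))
    return [
        Trial("test-pulse", Modality.AUDIOVISUAL.value, "pulse", k / pulse_rate_hz, 0.0125)
        for k in range(n)
    ]


def _condition_trial(condition: str, start_s: float, duration_s: float, label: str) -> Trial:
    cond = condition.strip()
    low = cond.lower()
    if low in {"random", "constant"}:
        freq: Union[float, str] = low
    elif low.endswith("hz"):
        freq = float(low[:-2].strip())
    else:
        freq = float(cond)
    return Trial(label, Modality.AUDIOVISUAL.value, freq, start_s, duration_s)


@dataclass
class BlindedSession:
    """A resolved blinded session: test sequence, exit pause, stimulation block.

    ``schedule`` holds the full (unblinded) trial list needed to drive the
    device; anything written where the experimenter can read it must go
    through :meth:`write_log`, which replaces the condition with its salted
    code.
    """

    subject_id: str
    condition: str  # device-internal; never serialized by write_log
    code: str
    schedule: TaskSchedule
    salt: str = "flickerkit"

    def public_frame(self) -> pd.DataFrame:
        """Schedule view safe to show a blinded experimenter."""
        df = self.schedule.to_frame()
        stim = df["label"] == "stimulation"
        df.loc[stim, "frequency"] = f"coded:{self.code}"
        df.loc[stim, "label"] = f"cond-{self.code}"
        return df[["trial", "label", "start_s", "duration_s", "frequency"]]

    def serialize_public(self) -> str:
        buf = io.StringIO()
        self.public_frame().to_csv(buf, index=False)
        return buf.getvalue()

    def write_log(self, path) -> None:
        Path(path).write_text(self.serialize_public())

    def write_unblinding_key(self, path) -> None:
        """Write code -> condition mapping; keep away from blinded personnel."""
        pd.DataFrame(
            [{"subject_id": self.subject_id, "code": self.code, "condition": self.condition}]
        ).to_csv(path, index=False)


def resolve_blinded_condition(
    table: BlindingTable,
    subject_id: str,
    stimulation_duration_s: float = 3600.0,
    pause_s: float = 60.0,
    test_sequence_s: float = 2.0,
    salt: str = "flickerkit",
) -> BlindedSession:
    """Look up a subject's condition and build its blinded session schedule.

    The schedule is: fixed test sequence (byte-identical across conditions),
    a pause during which the experimenter exits, then the condition-specific
    stimulation block.  Unknown subject ids raise ``KeyError``.
    """
    condition = table.lookup(subject_id)
    code = condition_code(condition, salt)
    trials = _test_sequence_trials(test_sequence_s)
    stim_start = test_sequence_s + pause_s
    trials.append(_condition_trial(condition, stim_start, stimulation_duration_s, "stimulation"))
    return BlindedSession(
        subject_id=subject_id,
        condition=condition,
        code=code,
        schedule=TaskSchedule(trials, rest_s=0.0),
        salt=salt,
    )
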