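"""Entrainment statistics: modulation criteria, latency, contrasts, phase locking.

Channel criterion: a channel is modulated when its power at the stimulation
frequency is at least three standard deviations above the mean power in the
neighboring frequencies (31-39 and 41-49 Hz for 40-Hz stimulation).  Subject
criterion: at least three modulated channels, with modulated channels in both
hemispheres (the stricter of the two readings reported; a permissive
``hemisphere_rule="either"`` switch is provided).  Detection latency is the
smallest growing window anchored at stimulus onset for which the subject
criterion holds.  Spike phase locking is quantified by the vector strength
(mean resultant length of spike phases) with a Rayleigh uniformity test.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .spectral import PSDResult, bandpass, baseline_correct, multitaper_psd
from .synthneuro import Recording, SpikeTrain, gen_ssep_recording

__all__ = [
    "ModulationReport",
    "SpikePhaseStats",
    "channel_modulation",
    "subject_modulation",
    "detection_latency",
    "condition_contrast",
    "spike_phase_locking",
    "occluded_check",
    "calibrate_response_amplitude",
    "DEFAULT_NEIGHBOR_BANDS",
]

DEFAULT_NEIGHBOR_BANDS = ((31.0, 39.0), (41.0, 49.0))
DEFAULT_SD_THRESHOLD = 3.0
DEFAULT_MIN_CHANNELS = 3


@dataclass
class ModulationReport:
    """Per-channel modulation flags plus the subject-level decision."""

    channels: pd.DataFrame  # channel_id, hemisphere, power_at_stim, neighbor_mean, neighbor_sd, z_score, modulated
    hemisphere_counts: dict[str, int]
    subject_modulated: bool
    latency_s: Optional[float] = None
    params: dict = field(default_factory=dict)

    @property
    def n_modulated(self) -> int:
        return int(self.channels["modulated"].sum())

    def to_csv(self, path) -> None:
        self.channels.to_csv(path, index=False)

    def summary(self) -> str:
        lat = "n/a" if self.latency_s is None else f"{self.latency_s:g} s"
        return (
            f"subject_modulated={self.subject_modulated} "
            f"n_modulated={self.n_modulated} "
            f"hemispheres={self.hemisphere_counts} latency={lat}"
        )


@dataclass
class SpikePhaseStats:
    """Vector strength, preferred phase, and Rayleigh uniformity test."""

    vector_strength: float
    preferred_phase: float
    n_spikes: int
    uniformity_p: float
    sufficient: bool = True


def channel_modulation(
    psd: PSDResult,
    stim_freq: float = 40.0,
    neighbor_bands: Sequence[tuple[float, float]] = DEFAULT_NEIGHBOR_BANDS,
    sd_threshold: float = DEFAULT_SD_THRESHOLD,
    scale: str = "db",
) -> pd.DataFrame:
    """Z-score the power at the stimulation frequency against neighbor bands.

    ``z = (P(stim) - mean(P_neighbors)) / sd(P_neighbors)`` per channel, on
    the dB scale by default (``scale="linear"`` z-scores linear power).
    A channel is modulated iff ``z >= sd_threshold`` (inclusive).  The stim
    bin is the grid bin nearest ``stim_freq``; neighbor bins are all bins
    whose centers fall inside the (inclusive) neighbor bands.
    """
    freqs = psd.freqs
    if scale == "db":
        power = psd.power_db
    elif scale == "linear":
        power = psd.power_linear
    else:
        raise ValueError(f"unknown scale {scale!r}")
    if stim_freq < freqs[0] or stim_freq > freqs[-1]:
        raise ValueError("PSD grid does not cover the stimulation frequency")
    stim_bin = int(np.argmin(np.abs(freqs - stim_freq)))
    neighbor = np.zeros(len(freqs), dtype=bool)
    for lo, hi in neighbor_bands:
        if lo < freqs[0] or hi > freqs[-1]:
            raise ValueError("PSD grid does not cover the neighbor bands")
        neighbor |= (freqs >= lo) & (freqs <= hi)
    neighbor[stim_bin] = False
    if neighbor.sum() < 2:
        raise ValueError("neighbor bands contain fewer than 2 bins; sd undefined")

    p_stim = power[:, stim_bin]
    nb = power[:, neighbor]
    mean = nb.mean(axis=1)
    sd = nb.std(axis=1, ddof=1)
    z = (p_stim - mean) / sd
    out = pd.DataFrame(
        {
            "channel_id": psd.channels["channel_id"].to_numpy(),
            "power_at_stim": p_stim,
            "neighbor_mean": mean,
            "neighbor_sd": sd,
            "z_score": z,
            "modulated": z >= sd_threshold,
        }
    )
    if "hemisphere" in psd.channels.columns:
        out.insert(1, "hemisphere", psd.channels["hemisphere"].to_numpy())
    return out


def subject_modulation(
    channels: pd.DataFrame,
    hemispheres: Optional[Sequence[str]] = None,
    min_channels: int = DEFAULT_MIN_CHANNELS,
    hemisphere_rule: str = "each",
) -> ModulationReport:
    """Subject-level modulation decision from per-channel flags.

    ``hemisphere_rule="each"`` (default): at least ``min_channels`` modulated
    channels AND at least one modulated channel in each hemisphere.
    ``"either"``: the count condition alone (any hemisphere placement).
    """
    df = channels.copy()
    if hemispheres is not None:
        df["hemisphere"] = list(hemispheres)
    if "hemisphere" not in df.columns or df["hemisphere"].isna().any():
        raise ValueError("every channel needs a hemisphere label")
    mod = df[df["modulated"]]
    counts = mod.groupby("hemisphere").size().to_dict()
    for h in df["hemisphere"].unique():
        counts.setdefault(h, 0)
    enough = len(mod) >= min_channels
    if hemisphere_rule == "each":
        decided = enough and all(
            counts.get(h, 0) >= 1 for h in df["hemisphere"].unique()
        )
    elif hemisphere_rule == "either":
        decided = enough and any(v >= 1 for v in counts.values())
    else:
        raise ValueError(f"unknown hemisphere_rule {hemisphere_rule!r}")
    return ModulationReport(
        channels=df,
        hemisphere_counts=counts,
        subject_modulated=bool(decided),
        params={"min_channels": min_channels, "hemisphere_rule": hemisphere_rule},
    )


def _window_report(
    rec: Recording,
    start: float,
    stop: float,
    stim_freq: float,
    neighbor_bands,
    sd_threshold: float,
    min_channels: int,
    hemisphere_rule: str,
    psd_band: tuple[float, float],
) -> ModulationReport:
    i0 = int(round(start * rec.sample_rate))
    i1 = int(round(stop * rec.sample_rate))
    seg = rec.data[:, i0:i1]
    seg = seg - seg.mean(axis=1, keepdims=True)
    psd = multitaper_psd(seg, sample_rate=rec.sample_rate, band=psd_band,
                         channels=rec.channels)
    flags = channel_modulation(psd, stim_freq, neighbor_bands, sd_threshold)
    return subject_modulation(flags, min_channels=min_channels,
                              hemisphere_rule=hemisphere_rule)


def detection_latency(
    rec: Recording,
    stim_onset: float,
    stim_freq: float = 40.0,
    window_step: float = 1.0,
    max_window: Optional[float] = None,
    neighbor_bands=DEFAULT_NEIGHBOR_BANDS,
    sd_threshold: float = DEFAULT_SD_THRESHOLD,
    min_channels: int = DEFAULT_MIN_CHANNELS,
    hemisphere_rule: str = "each",
    psd_band: tuple[float, float] = (2.0, 100.0),
) -> Optional[float]:
    """Smallest growing window after onset that satisfies the subject criterion.

    Windows are anchored at ``stim_onset`` and grow in ``window_step``
    increments; returns the window length in seconds, or ``None`` if the
    criterion is never met within the record.
    """
    if not 0 <= stim_onset < rec.duration:
        raise ValueError("stimulus onset lies outside the record")
    limit = rec.duration - stim_onset
    if max_window is not None:
        limit = min(limit, max_window)
    t = window_step
    while t <= limit + 1e-9:
        report = _window_report(
            rec, stim_onset, stim_onset + t, stim_freq, neighbor_bands,
            sd_threshold, min_channels, hemisphere_rule, psd_band,
        )
        if report.subject_modulated:
            return t
        t += window_step
    return None


def _power_at(trial, stim_freq: float) -> float:
    if isinstance(trial, PSDResult):
        stim_bin = int(np.argmin(np.abs(trial.freqs - stim_freq)))
        return float(trial.power_db[:, stim_bin].mean())
    return float(trial)


def condition_contrast(
    stim_trials: Sequence,
    control_trials: Sequence,
    stim_freq: float = 40.0,
) -> dict:
    """Paired statistics on per-trial power at the stimulation frequency.

    Trials may be :class:`PSDResult` objects (channel-averaged dB power at
    the nearest stim bin is used) or plain per-trial power values.  Returns
    paired t and Wilcoxon signed-rank p values, Cohen's d on the paired
    differences, and per-condition medians and quartiles.
    """
    a = np.array([_power_at(t, stim_freq) for t in stim_trials], float)
    b = np.array([_power_at(t, stim_freq) for t in control_trials], float)
    if len(a) != len(b):
        raise ValueError("paired tests need equal trial counts")
    if len(a) < 2:
        raise ValueError("need at least 2 trials")
    diff = a - b
    if np.allclose(diff, diff[0]) and np.isclose(diff[0], 0):
        t_p, w_p, d = 1.0, 1.0, 0.0
    else:
        t_res = stats.ttest_rel(a, b)
        t_p = float(t_res.pvalue)
        try:
            w_p = float(stats.wilcoxon(a, b).pvalue)
        except ValueError:  # all differences zero
            w_p = 1.0
        sd = diff.std(ddof=1)
        d = float(diff.mean() / sd) if sd > 0 else np.inf * np.sign(diff.mean())
    q = lambda x: (float(np.median(x)), float(np.percentile(x, 25)), float(np.percentile(x, 75)))
    med_a, lo_a, hi_a = q(a)
    med_b, lo_b, hi_b = q(b)
    return {
        "paired_t_p": t_p,
        "wilcoxon_p": w_p,
        "cohens_d": d,
        "stim_median": med_a,
        "stim_quartiles": (lo_a, hi_a),
        "control_median": med_b,
        "control_quartiles": (lo_b, hi_b),
        "n": len(a),
    }


def _rayleigh_p(n: int, r: float) -> float:
    # Wilkie (1983) approximation to the Rayleigh test p-value
    z = n * r * r
    p = np.exp(-z) * (
        1
        + (2 * z - z * z) / (4 * n)
        - (24 * z - 132 * z**2 + 76 * z**3 - 9 * z**4) / (288 * n * n)
    )
    return float(min(max(p, 0.0), 1.0))


def spike_phase_locking(
    spikes: SpikeTrain,
    stim_freq: float = 40.0,
    stim_onsets: Optional[np.ndarray] = None,
    min_spikes: int = 10,
) -> SpikePhaseStats:
    """Vector strength and Rayleigh test of spike phases against the stimulus.

    Each spike's phase is ``2*pi * frac((t - onset) * stim_freq)`` relative
    to the nearest preceding stimulus onset (or to t=0 if no onsets are
    given; spikes before the first onset are discarded).  Fewer than
    ``min_spikes`` spikes sets ``sufficient=False`` with NaN statistics.
    """
    times = spikes.times
    if stim_onsets is not None and len(stim_onsets):
        stim_onsets = np.asarray(stim_onsets, float)
        idx = np.searchsorted(stim_onsets, times, side="right") - 1
        keep = idx >= 0
        times = times[keep]
        rel = times - stim_onsets[idx[keep]]
    else:
        rel = times
    n = len(rel)
    if n < min_spikes:
        return SpikePhaseStats(np.nan, np.nan, n, np.nan, sufficient=False)
    phases = 2 * np.pi * np.mod(rel * stim_freq, 1.0)
    resultant = np.exp(1j * phases).mean()
    r = float(np.abs(resultant))
    return SpikePhaseStats(
        vector_strength=r,
        preferred_phase=float(np.angle(resultant)),
        n_spikes=n,
        uniformity_p=_rayleigh_p(n, r),
        sufficient=True,
    )


def occluded_check(
    psd_occluded: PSDResult,
    stim_freq: float = 40.0,
    neighbor_bands=DEFAULT_NEIGHBOR_BANDS,
    sd_threshold: float = DEFAULT_SD_THRESHOLD,
) -> bool:
    """Screen an occluded-condition recording for electrical artifacts.

    With the subject shielded from the stimuli (eye mask, earplugs), any
    channel passing the modulation criterion indicates stimulation-frequency
    pickup that cannot be sensory: returns True (artifact suspected).
    """
    flags = channel_modulation(psd_occluded, stim_freq, neighbor_bands, sd_threshold)
    return bool(flags["modulated"].any())


def calibrate_response_amplitude(
    target_z: float = 6.0,
    window_s: float = 10.0,
    stim_freq: float = 40.0,
    sample_rate: float = 2048.0,
    background_exponent: float = 1.0,
    band: tuple[float, float] = (1.0, 100.0),
    n_probe_seeds: int = 3,
    seed: int = 0,
    tol: float = 0.25,
    max_iter: int = 24,
) -> float:
    """Find the response amplitude giving per-channel z ~ ``target_z``.

    Bisects on log-amplitude, measuring the median channel z-score on
    ``window_s`` windows of single-channel synthetic recordings (band-pass
    filtered as in the analysis chain) over ``n_probe_seeds`` seeds.
    """

    def median_z(amp: float) -> float:
        zs = []
        for k in range(n_probe_seeds):
            rec = gen_ssep_recording(
                n_channels=1, hemisphere_map=["L"], sample_rate=sample_rate,
                duration=window_s + 1.0, stim_onset=0.5, stim_freq=stim_freq,
                response_amplitude=amp, background_exponent=background_exponent,
                seed=seed * 1009 + k,
            )
            rec = bandpass(rec, band[0], band[1])
            i0 = int(round(0.5 * sample_rate))
            i1 = i0 + int(round(window_s * sample_rate))
            seg = rec.data[:, i0:i1]
            seg = seg - seg.mean(axis=1, keepdims=True)
            psd = multitaper_psd(seg, sample_rate=sample_rate)
            zs.append(channel_modulation(psd, stim_freq)["z_score"].iloc[0])
        return float(np.median(zs))

    lo, hi = 1e-4, 10.0
    z_lo, z_hi = median_z(lo), median_z(hi)
    for _ in range(max_iter):
        mid = float(np.sqrt(lo * hi))
        z_mid = median_z(mid)
        if abs(z_mid - target_z) <= tol:
            return mid
        if z_mid < target_z:
            lo, z_lo = mid, z_mid
        else:
            hi, z_hi = mid, z_mid
    return float(np.sqrt(lo * hi))
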