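"""Entrainment statistics: modulation criteria, latency, contrasts, phase locking."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from flickerkit import modulation as md
from flickerkit import spectral as sp
from flickerkit import synthneuro as sn


class TestChannelModulation:
    def test_constructed_z_score(self, constructed_psd):
        # neighbors: mean 10 dB, sd 1 dB; P(40) = 14 dB -> z = 4
        flags = md.channel_modulation(constructed_psd(14.0))
        assert flags["z_score"].iloc[0] == pytest.approx(4.0)
        assert bool(flags["modulated"].iloc[0])

    def test_power_equal_to_neighbors_not_modulated(self, constructed_psd):
        flags = md.channel_modulation(constructed_psd(10.0))
        assert flags["z_score"].iloc[0] == pytest.approx(0.0)
        assert not bool(flags["modulated"].iloc[0])

    def test_threshold_boundary_inclusive(self, constructed_psd):
        # scan P(40): the flag flips exactly at mean + 3 sd, inclusive
        at = md.channel_modulation(constructed_psd(13.0))
        below = md.channel_modulation(constructed_psd(13.0 - 1e-9))
        above = md.channel_modulation(constructed_psd(13.0 + 1e-9))
        assert bool(at["modulated"].iloc[0])
        assert not bool(below["modulated"].iloc[0])
        assert bool(above["modulated"].iloc[0])

    def test_boundary_scan_recovers_3sd_threshold(self, constructed_psd):
        grid = np.arange(10.0, 16.0, 0.25)
        flips = [p for p in grid
                 if bool(md.channel_modulation(constructed_psd(p))["modulated"].iloc[0])]
        assert min(flips) == pytest.approx(13.0)  # mean 10 + 3 x sd 1

    def test_shift_invariance(self, constructed_psd):
        a = md.channel_modulation(constructed_psd(14.0))
        psd_shifted = constructed_psd(14.0)
        psd_shifted.power_db = psd_shifted.power_db + 17.3
        b = md.channel_modulation(psd_shifted)
        assert a["z_score"].iloc[0] == pytest.approx(b["z_score"].iloc[0])

    def test_narrow_neighbor_bands_rejected(self, constructed_psd):
        with pytest.raises(ValueError):
            md.channel_modulation(constructed_psd(14.0),
                                  neighbor_bands=((39.5, 39.6),))

    def test_false_positive_rate_of_3sd_rule_on_pink_noise(self):
        # empirical tail of the criterion under the null (no response)
        hits = 0
        n_runs = 200
        for seed in range(n_runs):
            rec = sn.gen_ssep_recording(
                n_channels=1, hemisphere_map=["L"], sample_rate=512.0,
                duration=12.0, stim_onset=11.0, response_amplitude=0.0,
                background_exponent=1.0, seed=seed,
            )
            psd = sp.multitaper_psd(rec.data, sample_rate=512.0)
            flags = md.channel_modulation(psd)
            hits += int(flags["modulated"].iloc[0])
        assert hits / n_runs <= 0.05


def make_flags(hemis, modulated):
    return pd.DataFrame(
        {
            "channel_id": [f"ch{i}" for i in range(len(hemis))],
            "hemisphere": hemis,
            "modulated": modulated,
        }
    )


class TestSubjectModulation:
    def test_two_left_one_right_is_modulated(self):
        flags = make_flags(["L", "L", "R", "R"], [True, True, True, False])
        assert md.subject_modulation(flags).subject_modulated

    def test_three_left_zero_right_fails_each_hemisphere_rule(self):
        flags = make_flags(["L", "L", "L", "R"], [True, True, True, False])
        report = md.subject_modulation(flags)
        assert not report.subject_modulated
        # permissive "either" reading accepts the same configuration
        assert md.subject_modulation(flags, hemisphere_rule="either").subject_modulated

    def test_two_modulated_total_below_count_threshold(self):
        flags = make_flags(["L", "R", "L", "R"], [True, True, False, False])
        assert not md.subject_modulation(flags).subject_modulated

    def test_boundary_scan_recovers_3_channel_threshold(self):
        # grow modulated channels alternating hemispheres: decision flips at 3
        decisions = []
        for k in range(1, 6):
            hemis = ["L", "R"] * 5
            mods = [True] * k + [False] * (10 - k)
            decisions.append(md.subject_modulation(make_flags(hemis, mods)).subject_modulated)
        assert decisions == [False, False, True, True, True]

    def test_missing_hemisphere_label_rejected(self):
        flags = make_flags(["L", None, "R"], [True, True, True])
        with pytest.raises(ValueError):
            md.subject_modulation(flags)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.tuples(st.sampled_from(["L", "R"]), st.booleans()),
                    min_size=2, max_size=12))
    def test_monotone_in_added_modulated_channel(self, rows):
        """Adding a modulated channel never un-modulates a subject."""
        hemis = [h for h, _ in rows]
        mods = [m for _, m in rows]
        base = md.subject_modulation(make_flags(hemis, mods)).subject_modulated
        for h in ("L", "R"):
            grown = md.subject_modulation(
                make_flags(hemis + [h], mods + [True])
            ).subject_modulated
            assert grown or not base


class TestDetectionLatency:
    def test_null_recording_never_detects(self):
        rec = sn.gen_ssep_recording(n_channels=8, duration=30.0, stim_onset=10.0,
                                    response_amplitude=0.0, seed=21)
        rec = sp.bandpass(rec, 1.0, 100.0)
        assert md.detection_latency(rec, 10.0) is None

    def test_saturating_amplitude_detected_at_first_feasible_window(self):
        # oracle: direct evaluation of the detector on each growing window.
        # Windows shorter than 3 s cannot pass: the multitaper half-bandwidth
        # NW/T exceeds 1 Hz, so the 40-Hz mainlobe leaks into the 31-39 /
        # 41-49 Hz neighbor bands and deflates the z-score no matter how
        # strong the response is.
        rec = sn.gen_ssep_recording(n_channels=8, duration=30.0, stim_onset=10.0,
                                    response_amplitude=50.0, seed=22)
        rec = sp.bandpass(rec, 1.0, 100.0)
        direct = []
        for t in (1.0, 2.0, 3.0, 4.0):
            report = md._window_report(
                rec, 10.0, 10.0 + t, 40.0, md.DEFAULT_NEIGHBOR_BANDS, 3.0, 3,
                "each", (2.0, 100.0),
            )
            direct.append(report.subject_modulated)
        first = (direct.index(True) + 1) * 1.0
        assert md.detection_latency(rec, 10.0) == first == 3.0

    def test_onset_outside_record_rejected(self):
        rec = sn.gen_ssep_recording(n_channels=4, duration=5.0, stim_onset=2.0, seed=0)
        with pytest.raises(ValueError):
            md.detection_latency(rec, 10.0)

    def test_latency_non_increasing_in_amplitude(self):
        # identical noise, stronger response: z rises at every window, so the
        # first passing window can only move earlier
        amp = 0.1
        for seed in range(3):
            lats = []
            for scale in (1.0, 4.0):
                rec = sn.gen_ssep_recording(n_channels=16, duration=40.0,
                                            stim_onset=15.0,
                                            response_amplitude=amp * scale,
                                            seed=100 + seed)
                rec = sp.bandpass(rec, 1.0, 100.0)
                lats.append(md.detection_latency(rec, 15.0))
            lo, hi = lats
            if lo is not None:
                assert hi is not None and hi <= lo


class TestConditionContrast:
    def test_identical_trials_null_effect(self):
        res = md.condition_contrast([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res["cohens_d"] == 0.0
        assert res["paired_t_p"] == pytest.approx(1.0)

    def test_hand_computed_paired_statistics(self):
        # pairs (2,1), (3,1), (4,1): diffs 1,2,3 -> mean 2, sd 1, d = 2
        res = md.condition_contrast([2.0, 3.0, 4.0], [1.0, 1.0, 1.0])
        assert res["cohens_d"] == pytest.approx(2.0)
        # paired t = mean / (sd / sqrt(n)) = 2 / (1/sqrt(3)) -> p from t(2)
        from scipy import stats as sps
        t = 2.0 / (1.0 / np.sqrt(3.0))
        assert res["paired_t_p"] == pytest.approx(2 * sps.t.sf(t, df=2))
        assert res["stim_median"] == 3.0
        assert res["stim_quartiles"] == (2.5, 3.5)

    def test_effect_sign_antisymmetry(self):
        a = [2.0, 3.0, 4.0, 5.0]
        up = md.condition_contrast(a, [x + 1 for x in a])
        down = md.condition_contrast(a, [x - 1 for x in a])
        assert up["cohens_d"] < 0 < down["cohens_d"]

    def test_unequal_counts_rejected(self):
        with pytest.raises(ValueError):
            md.condition_contrast([1.0, 2.0], [1.0])

    def test_accepts_psd_results(self):
        fs = 512.0
        t = np.arange(int(fs * 4)) / fs
        stim = [sp.multitaper_psd((np.sin(2 * np.pi * 40 * t) * a)[None, :],
                                  sample_rate=fs) for a in (1.0, 1.1, 0.9)]
        ctrl = [sp.multitaper_psd((0.05 * np.sin(2 * np.pi * 40 * t))[None, :],
                                  sample_rate=fs) for _ in range(3)]
        res = md.condition_contrast(stim, ctrl)
        assert res["stim_median"] > res["control_median"]


class TestSpikePhaseLocking:
    def test_identical_phases_give_unit_vector_strength(self):
        times = 0.001 + np.arange(50) / 40.0  # one spike per cycle, same phase
        stats = md.spike_phase_locking(sn.SpikeTrain(times), 40.0)
        assert stats.vector_strength == pytest.approx(1.0)
        assert stats.uniformity_p < 1e-6

    def test_uniform_phases_near_zero(self):
        rng = np.random.default_rng(30)
        times = np.sort(rng.uniform(0, 100, 4000))
        times = times[np.diff(times, prepend=-1) > 0]
        stats = md.spike_phase_locking(sn.SpikeTrain(times), 40.0)
        assert stats.vector_strength < 0.05
        assert stats.uniformity_p > 0.01

    def test_insufficient_spikes_flagged(self):
        stats = md.spike_phase_locking(sn.SpikeTrain(np.arange(5) * 0.1), 40.0)
        assert not stats.sufficient
        assert np.isnan(stats.vector_strength)

    def test_phases_relative_to_preceding_onset(self):
        # spikes at fixed offset after each onset: perfectly locked
        onsets = np.arange(0, 10, 0.5)
        times = onsets + 0.01
        stats = md.spike_phase_locking(sn.SpikeTrain(times), 40.0, stim_onsets=onsets)
        assert stats.vector_strength == pytest.approx(1.0)

    def test_rayleigh_p_matches_independent_oracle(self):
        pingouin = pytest.importorskip("pingouin")
        spk = sn.gen_phase_locked_spikes(20.0, 0.3, duration=30.0, seed=31)
        stats = md.spike_phase_locking(spk, 40.0)
        phases = 2 * np.pi * np.mod(spk.times * 40.0, 1.0)
        _, p_ref = pingouin.circ_rayleigh(phases)
        assert stats.uniformity_p == pytest.approx(p_ref, abs=1e-3)


class TestOccludedCheck:
    def test_null_recording_clean(self):
        rec = sn.gen_ssep_recording(n_channels=4, duration=24.0, stim_onset=23.0,
                                    response_amplitude=0.0, seed=40)
        psd = sp.multitaper_psd(rec.data[:, : int(12 * 2048)], sample_rate=2048.0,
                                channels=rec.channels)
        assert md.occluded_check(psd) is False

    def test_injected_artifact_flagged_and_frequency_specific(self):
        rec = sn.gen_ssep_recording(n_channels=4, duration=12.0, stim_onset=11.0,
                                    response_amplitude=0.0, seed=41)
        t = np.arange(rec.n_samples) / rec.sample_rate
        rec.data[2] += 2.0 * np.sin(2 * np.pi * 40.0 * t)  # line-like pickup
        psd = sp.multitaper_psd(rec)
        assert md.occluded_check(psd, stim_freq=40.0) is True
        assert md.occluded_check(psd, stim_freq=80.0) is False
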