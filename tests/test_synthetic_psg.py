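"""Generator tests: hypnogram dynamics, signal structure, reproducibility."""

from __future__ import annotations

from collections import Counter

import numpy as np
import pytest

from somnostage import synthetic_psg as sp
from somnostage.core import STAGES
from somnostage.features import emg_power, welch_psd


class TestGenerateHypnogram:
    def test_absorbing_wake_dynamics_stay_in_wake(self):
        all_to_w = np.zeros((5, 5))
        all_to_w[:, 0] = 1.0  # every stage falls back to W; W is absorbing
        dyn = sp.StageDynamics(transition_weights=all_to_w, mean_bout_epochs=np.ones(5))
        proto = sp.Protocol(kind="night", total_duration_min=5)
        hyp = sp.generate_hypnogram(dyn, proto, 30, seed=0)
        assert hyp.stages == ["W"] * 10

    @pytest.mark.parametrize("seed", range(5))
    def test_night_starts_awake_and_never_in_rem(self, night_dynamics, seed):
        proto = sp.default_protocol("night")
        hyp = sp.generate_hypnogram(night_dynamics, proto, 30, seed=seed)
        assert hyp.stages[0] == "W"
        assert hyp.stages[1] != "R"  # sleep is entered through N1

    def test_all_zero_transition_row_rejected(self):
        w = np.ones((5, 5))
        w[2] = 0.0
        dyn = sp.StageDynamics(transition_weights=w, mean_bout_epochs=np.ones(5))
        with pytest.raises(ValueError, match="non-normalizable"):
            sp.generate_hypnogram(dyn, sp.default_protocol("night"), 30, seed=0)

    def test_cycle_period_matches_ninety_minutes(self, night_dynamics):
        """Mean NREM-REM cycle over 200 simulated nights sits near 90 min."""
        proto = sp.default_protocol("night")
        periods = []
        for seed in range(200):
            hyp = sp.generate_hypnogram(night_dynamics, proto, 30, seed=seed)
            periods.extend(sp.detect_cycle_periods(hyp))
        assert 70.0 <= np.mean(periods) <= 110.0

    def test_only_valid_stage_alphabet(self, night_dynamics):
        hyp = sp.generate_hypnogram(night_dynamics, sp.default_protocol("night"), 20, seed=3)
        assert set(hyp.stages) <= set(STAGES)

    def test_healthy_stage_proportions(self, night_dynamics):
        """N2 is the modal sleep stage and N1 stays scarce over 100 nights."""
        counts = Counter()
        proto = sp.default_protocol("night")
        for seed in range(100):
            counts.update(sp.generate_hypnogram(night_dynamics, proto, 30, seed=1000 + seed).stages)
        total = sum(counts.values())
        assert max(counts, key=counts.get) == "N2"
        assert counts["N1"] / total < 0.15


class TestSynthesizeEpoch:
    def test_zero_amplitude_profile_gives_zero_eeg(self, signal_profile):
        import dataclasses

        zeros = {s: 0.0 for s in STAGES}
        prof = dataclasses.replace(
            signal_profile,
            background_rms=zeros,
            alpha_rms=zeros,
            theta_rms=zeros,
            slow_rms=zeros,
            spindle_amp=zeros,
            sawtooth_amp=zeros,
            blink_rate=zeros,
            sem_rate=zeros,
            rem_event_rate=zeros,
            eog_noise_rms=0.0,
            emg_tone_var={"W": 5e-12, "N1": 4e-12, "N2": 3e-12, "N3": 2e-12, "R": 1e-12},
            amplitude_jitter_sd=0.0,
        )
        block = sp.synthesize_epoch("N2", prof, 128, 20, np.random.default_rng(0))
        assert np.allclose(block["EEG"], 0.0)
        assert np.allclose(block["EOG_L"], 0.0)

    def test_unknown_stage_rejected(self, signal_profile):
        with pytest.raises(ValueError, match="unknown sleep stage"):
            sp.synthesize_epoch("S5", signal_profile, 128, 20, np.random.default_rng(0))

    def test_slow_wave_power_separates_deep_sleep_from_wake(self, signal_profile, rng):
        n3 = np.mean(
            [welch_psd(sp.synthesize_epoch("N3", signal_profile, 128, 20, rng)["EEG"], 128).band_power(0.5, 4) for _ in range(20)]
        )
        w = np.mean(
            [welch_psd(sp.synthesize_epoch("W", signal_profile, 128, 20, rng)["EEG"], 128).band_power(0.5, 4) for _ in range(20)]
        )
        assert n3 > 3 * w

    def test_rem_atonia_reduces_emg_power(self, signal_profile, rng):
        r = emg_power(sp.synthesize_epoch("R", signal_profile, 128, 20, rng)["EMG"], 128)
        w = emg_power(sp.synthesize_epoch("W", signal_profile, 128, 20, rng)["EMG"], 128)
        assert r < w

    def test_atonia_ordering_holds_for_most_epoch_pairs(self, signal_profile, rng):
        pw = np.array([emg_power(sp.synthesize_epoch("W", signal_profile, 128, 20, rng)["EMG"], 128) for _ in range(40)])
        pr = np.array([emg_power(sp.synthesize_epoch("R", signal_profile, 128, 20, rng)["EMG"], 128) for _ in range(40)])
        assert (pw[:, None] > pr[None, :]).mean() >= 0.99

    def test_eog_events_mirror_with_opposite_polarity(self, signal_profile):
        """REM bursts anti-correlate across the two EOG channels."""
        import dataclasses

        prof = dataclasses.replace(signal_profile, eog_crosstalk=0.0, eog_noise_rms=0.5)
        rng = np.random.default_rng(5)
        corrs = []
        for _ in range(10):
            block = sp.synthesize_epoch("R", prof, 128, 20, rng)
            corrs.append(np.corrcoef(block["EOG_L"], block["EOG_R"])[0, 1])
        assert np.mean(corrs) < -0.5


class TestGenerateRecording:
    def test_sample_count_is_exact(self, night_dynamics, signal_profile):
        proto = sp.Protocol(kind="night", total_duration_min=5)  # 10 x 30 s
        rec, hyp = sp.generate_recording(night_dynamics, signal_profile, proto, 128, 30, seed=0)
        assert len(hyp) == 10
        assert rec.channel("EEG").samples.size == 38_400

    def test_same_seed_is_bit_identical(self, night_dynamics, signal_profile):
        proto = sp.Protocol(kind="night", total_duration_min=5)
        a = sp.generate_recording(night_dynamics, signal_profile, proto, 128, 30, seed=9)
        b = sp.generate_recording(night_dynamics, signal_profile, proto, 128, 30, seed=9)
        assert a[1].stages == b[1].stages
        for ca, cb in zip(a[0].channels, b[0].channels):
            assert np.array_equal(ca.samples, cb.samples)

    def test_mslt_sleep_confined_to_nap_windows(self):
        dyn = sp.default_dynamics(30, "patient")
        proto = sp.Protocol(kind="mslt", total_duration_min=540, nap_count=4)
        hyp = sp.generate_hypnogram(dyn, proto, 30, seed=4)
        windows = proto.nap_windows_min()
        for i, stage in enumerate(hyp.stages):
            if stage != "W":
                t = i * 30 / 60.0
                assert any(lo <= t < hi for lo, hi in windows)


class TestGenerateDataset:
    def test_roster_shape_matches_study_design(self):
        """18 subjects with three nights each yields 54 recordings."""
        roster = sp.generate_dataset(18, 3, "healthy", seed=0, duration_min=2)
        assert len(roster) == 54
        per_subject = Counter(e.subject_id for e in roster)
        assert len(per_subject) == 18
        assert set(per_subject.values()) == {3}
        assert len({e.recording_id for e in roster}) == 54

    def test_mslt_contains_sleep_but_is_mostly_wake(self):
        roster = sp.generate_dataset(1, 1, "patient_mslt", seed=2)
        hyp = roster[0].hypnogram
        frac_w = sum(s == "W" for s in hyp.stages) / len(hyp)
        assert frac_w > 0.5
        assert any(s != "W" for s in hyp.stages)

    def test_unknown_profile_rejected(self):
        with pytest.raises(ValueError, match="unknown profile"):
            sp.generate_dataset(1, 1, "insomnia", seed=0)

    def test_dataset_reproducible_from_master_seed(self):
        a = sp.generate_dataset(2, 1, "healthy", seed=5, duration_min=4)
        b = sp.generate_dataset(2, 1, "healthy", seed=5, duration_min=4)
        for ea, eb in zip(a, b):
            assert ea.hypnogram.stages == eb.hypnogram.stages
            assert np.array_equal(ea.recording.channel("EEG").samples, eb.recording.channel("EEG").samples)

    def test_hypnogram_length_matches_recording(self, small_roster):
        for e in small_roster:
            assert e.hypnogram.duration_s == pytest.approx(e.recording.duration_s)
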