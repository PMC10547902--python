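"""Generator contracts: parameter validation, synthesis oracles, determinism."""
import numpy as np
import pandas as pd
import pytest

from cryscope import (
    CryParams, ConditionProfile, default_profiles,
    synth_cry_unit, synth_episode, synth_eeg, synth_nirs, synth_comfort,
    synth_session, SimulateConfig,
)
from cryscope.simulate import AUDIO_FS, NIRS_DT
from cryscope import cry_acoustics as ca
from cryscope import nirs_clean

SEED = 424242


class TestCryParamsValidation:
    def test_rejects_formants_above_nyquist(self):
        p = CryParams(formants=(1400.0, 3500.0, 30000.0))
        with pytest.raises(ValueError):
            synth_cry_unit(p, 0.5, 0)

    def test_rejects_hnr_out_of_range(self):
        with pytest.raises(ValueError):
            synth_cry_unit(CryParams(hnr_db=60.0), 0.5, 0)

    @pytest.mark.parametrize("kwargs", [
        {"f0_mean": 150.0}, {"jitter_frac": 0.5}, {"shimmer_frac": -0.1},
        {"formants": (3500.0, 1400.0, 5900.0)}, {"unit_dur_range": (0.0, 0.5)},
    ])
    def test_invariants_enforced(self, kwargs):
        with pytest.raises(ValueError):
            CryParams(**kwargs).validate()

    def test_profile_validation(self):
        prof = ConditionProfile("resting", eeg_band_gains={"delta": -1.0},
                                nirs_levels={"SpO2": 97.0})
        with pytest.raises(ValueError):
            prof.validate()


class TestCryUnitSynthesis:
    def test_unperturbed_pulse_train_has_exact_f0(self):
        p = CryParams(f0_mean=500.0, f0_sd=0.0, f0_contour_shape="flat",
                      jitter_frac=0.0, shimmer_frac=0.0, hnr_db=40.0)
        x = synth_cry_unit(p, 1.0, SEED)
        contour = ca.f0_contour(x, AUDIO_FS)
        f0 = contour.f0[contour.voiced]
        assert abs(np.mean(f0) - 500.0) < 1.0

    def test_hnr_zero_matches_analytic_ratio(self):
        p = CryParams(f0_mean=500.0, f0_sd=0.0, f0_contour_shape="flat",
                      jitter_frac=0.0, shimmer_frac=0.0, hnr_db=0.0)
        x = synth_cry_unit(p, 1.0, SEED)
        assert abs(ca.hnr(x, AUDIO_FS)) < 1.0

    def test_table_calibrated_formants_recovered(self, profiles):
        p = CryParams(**{**profiles["cry"].cry_params.__dict__,
                         "f0_sd": 0.0, "f0_contour_shape": "flat"})
        x = synth_cry_unit(p, 1.2, SEED)
        f1, f2, f3 = ca.formants(x, AUDIO_FS)
        for est, true in zip((f1, f2, f3), p.formants):
            assert abs(est - true) / true < 0.05

    def test_peak_normalised(self):
        x = synth_cry_unit(CryParams(), 0.8, SEED)
        assert np.max(np.abs(x)) <= 0.99 + 1e-9

    def test_waveform_deterministic(self):
        p = CryParams()
        a = synth_cry_unit(p, 0.7, 1234)
        b = synth_cry_unit(p, 0.7, 1234)
        np.testing.assert_array_equal(a, b)


class TestEpisodeSynthesis:
    def test_truth_durations_additive(self, profiles):
        prof = profiles["distress"]
        prof.cry_params.n_units = 3
        wav, truth = synth_episode(prof, SEED)
        cry = sum(e - s for s, e in truth["units"])
        unv = sum(e - s for s, e in truth["gaps"])
        assert truth["cryCE"] == pytest.approx(cry)
        assert truth["unvoicedCE"] == pytest.approx(unv)
        assert len(wav) / AUDIO_FS == pytest.approx(cry + unv, abs=1e-6)

    def test_resting_profile_refused(self, profiles):
        with pytest.raises(ValueError):
            synth_episode(profiles["resting"], SEED)

    def test_distress_defaults_recover_voice_quality(self, profiles):
        """Mean jitter/shimmer across many units match the distress targets."""
        prof = default_profiles()["distress"]
        prof.cry_params.n_units = 5
        rng = np.random.default_rng(SEED)
        jits, shims = [], []
        for _ in range(8):
            wav, truth = synth_episode(prof, rng)
            for s, e in truth["units"]:
                fv = ca.analyze_unit(wav[int(s * AUDIO_FS): int(e * AUDIO_FS)], AUDIO_FS)
                if fv.valid and np.isfinite(fv.jitter_local):
                    jits.append(fv.jitter_local)
                    shims.append(fv.shimmer_local)
        assert len(jits) >= 30
        assert abs(np.mean(jits) - 0.022) < 0.2 * 0.022 + 1e-9
        assert abs(np.mean(shims) - 0.143) < 0.2 * 0.143 + 1e-9


class TestEEGSynthesis:
    def test_equal_gains_give_zero_percent_change(self, profiles):
        from cryscope import eeg_power
        gains = {"delta": 15.0, "theta": 15.0, "alpha": 15.0}
        profs = default_profiles()
        for p in profs.values():
            p.eeg_band_gains = dict(gains)
        timeline = [(0.0, 120.0, "resting"), (120.0, 240.0, "cry")]
        data = synth_eeg(timeline, profs, SEED)
        rec = eeg_power.preprocess(eeg_power.EEGRecording(data))
        epochs = eeg_power.epoch_and_reject(rec, timeline)
        table = eeg_power.band_power_table(epochs)
        pc = eeg_power.percent_change(
            table[table["condition"] == "cry"],
            table[table["condition"] == "resting"])
        band_means = pc.groupby("band")["percent_change"].mean()
        assert np.abs(band_means).max() < 8.0

    def test_timeline_with_gap_rejected(self, profiles):
        with pytest.raises(ValueError):
            synth_eeg([(0.0, 10.0, "resting"), (12.0, 20.0, "cry")], profiles, SEED)

    def test_no_artifacts_means_no_rejected_epochs(self, profiles):
        from cryscope import eeg_power
        timeline = [(0.0, 60.0, "resting")]
        data = synth_eeg(timeline, profiles, SEED, artifact_rate_per_min=0.0)
        rec = eeg_power.preprocess(eeg_power.EEGRecording(data))
        epochs = eeg_power.epoch_and_reject(rec, timeline)
        assert all(e.quality == "good" for e in epochs)

    def test_flat_channel_injection(self, profiles):
        from cryscope import eeg_power
        data = synth_eeg([(0.0, 30.0, "resting")], profiles, SEED, flat_channel="T8")
        bad = eeg_power.detect_bad_channels(eeg_power.EEGRecording(data))
        assert bad == {"T8"}


class TestNirsComfortSynthesis:
    def test_clean_resting_survives_spo2_floor(self, profiles):
        timeline = [(0.0, 400.0, "resting")]
        df = synth_nirs(timeline, profiles, SEED, noise_sd={"rSO2": 1.0, "SpO2": 1.0, "PR": 3.0})
        cleaned = nirs_clean.clean(df)
        segs = nirs_clean.segment(cleaned, timeline)
        keep = nirs_clean.threshold_filter(segs[0])
        assert keep == {"rSO2": True, "SpO2": True, "PR": True}

    def test_flat_dropout_run_removed(self, profiles):
        timeline = [(0.0, 600.0, "resting")]
        df = synth_nirs(timeline, profiles, SEED, dropout_runs=[(200.0, 300.0)])
        cleaned = nirs_clean.clean(df)
        # samples whose whole 60-s SD window lies inside the dropout
        run = cleaned[(cleaned["t_s"] >= 232) & (cleaned["t_s"] < 268)]
        assert run["rSO2"].isna().all()

    def test_comfort_distress_scores_exceed_resting(self, profiles):
        rng = np.random.default_rng(SEED)
        rest = [sum(synth_comfort(profiles["resting"], rng)) for _ in range(25)]
        dist = [sum(synth_comfort(profiles["distress"], rng)) for _ in range(25)]
        assert np.mean(dist) > np.mean(rest)

    def test_comfort_items_on_integer_scale(self, profiles):
        rng = np.random.default_rng(SEED)
        for _ in range(50):
            items = synth_comfort(profiles["distress"], rng)
            assert all(isinstance(v, int) and 1 <= v <= 5 for v in items)


class TestSessionBundle:
    def test_streams_span_equal_duration(self, small_session):
        s = small_session
        audio_dur = len(s.audio) / s.fs
        eeg_dur = s.eeg.shape[1] / s.eeg_fs
        nirs_dur = s.nirs["t_s"].iloc[-1] + NIRS_DT
        ann_dur = s.annotations[-1][1]
        for dur in (eeg_dur, nirs_dur, ann_dur):
            assert abs(dur - audio_dur) <= NIRS_DT

    def test_annotations_sorted_non_overlapping(self, small_session):
        ann = small_session.annotations
        for (s0, e0, _), (s1, e1, _) in zip(ann, ann[1:]):
            assert e0 <= s1 + 1e-9
            assert e0 > s0

    def test_every_episode_has_comfort_record(self, small_session):
        n_episodes = sum(1 for *_, lab in small_session.annotations
                         if lab in ("cry", "distress"))
        assert len(small_session.comfort) == n_episodes
        assert set(small_session.comfort["condition"]) <= {"cry", "distress"}

    def test_bundle_deterministic(self):
        sim = SimulateConfig(n_cry_episodes=1, n_distress_episodes=1,
                             resting_block_s=20.0, units_per_episode=3)
        a = synth_session(77, sim=sim)
        b = synth_session(77, sim=sim)
        np.testing.assert_array_equal(a.audio, b.audio)
        np.testing.assert_array_equal(a.eeg, b.eeg)
        pd.testing.assert_frame_equal(a.nirs, b.nirs)
        pd.testing.assert_frame_equal(a.comfort, b.comfort)
        assert a.annotations == b.annotations

    def test_roundtrip_to_dir(self, small_session, tmp_path):
        from cryscope import io as cio
        small_session.to_dir(tmp_path)
        audio, fs = cio.read_wav(tmp_path / "audio.wav")
        assert fs == small_session.fs
        assert np.max(np.abs(audio - small_session.audio)) < 2.0 / 2**23
        ann = cio.read_annotations(tmp_path / "annotations.tsv")
        assert len(ann) == len(small_session.annotations)
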