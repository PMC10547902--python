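"""Acoustic feature extraction: segmentation, pitch, voice quality, formants."""
import numpy as np
import pytest
from scipy import signal as sps

from cryscope import CryParams, synth_cry_unit, synth_episode, default_profiles
from cryscope import cry_acoustics as ca
from cryscope.cry_acoustics import CryEpisode, CryUnit, CycleMeasures
from cryscope.simulate import AUDIO_FS

SEED = 97531


def _flat_unit(f0=500.0, jitter=0.0, shimmer=0.0, hnr=30.0, dur=1.0, seed=SEED,
               formants=(1400.0, 3500.0, 5900.0)):
    p = CryParams(f0_mean=f0, f0_sd=0.0, f0_contour_shape="flat",
                  jitter_frac=jitter, shimmer_frac=shimmer, hnr_db=hnr,
                  formants=formants)
    return synth_cry_unit(p, dur, seed)


class TestSegmentation:
    def test_pure_silence_yields_no_episodes(self):
        assert ca.detect_voiced_regions(np.zeros(AUDIO_FS), AUDIO_FS) == []

    def test_single_continuous_unit(self):
        x = _flat_unit(dur=3.0)
        eps = ca.detect_voiced_regions(x, AUDIO_FS)
        assert len(eps) == 1
        assert len(eps[0].units) == 1
        assert eps[0].unvoiced_intervals == []

    def test_generator_boundaries_recovered(self, profiles):
        prof = default_profiles()["cry"]
        prof.cry_params.n_units = 4
        wav, truth = synth_episode(prof, SEED)
        eps = ca.detect_voiced_regions(wav, AUDIO_FS)
        units = [u for ep in eps for u in ep.units]
        assert len(units) == len(truth["units"])
        for (ts, te), u in zip(truth["units"], units):
            assert abs(u.start - ts) <= 0.05
            assert abs(u.end - te) <= 0.05


class TestTimeFeatures:
    def test_fraction_arithmetic(self):
        ep = CryEpisode(units=[CryUnit(0.0, 30.0)],
                        unvoiced_intervals=[(30.0, 50.0)])
        tf = ca.time_features(ep)
        assert tf.cryCE == 30.0 and tf.unvoicedCE == 20.0
        assert tf.cryCE_pct == pytest.approx(0.6)
        assert tf.cryCE_pct + tf.unvoicedCE_pct == pytest.approx(1.0, abs=1e-9)

    def test_zero_gaps(self):
        tf = ca.time_features(CryEpisode([CryUnit(0.0, 5.0)], []))
        assert tf.unvoicedCE == 0.0 and tf.cryCE_pct == 1.0

    def test_generator_truth_exact(self, profiles):
        prof = default_profiles()["distress"]
        prof.cry_params.n_units = 4
        rng = np.random.default_rng(3)
        for _ in range(5):
            _, truth = synth_episode(prof, rng)
            ep = CryEpisode([CryUnit(s, e) for s, e in truth["units"]],
                            truth["gaps"])
            tf = ca.time_features(ep)
            assert tf.cryCE == pytest.approx(truth["cryCE"], abs=1e-9)
            assert tf.unvoicedCE == pytest.approx(truth["unvoicedCE"], abs=1e-9)


class TestF0:
    def test_sawtooth_440(self):
        t = np.arange(int(1.0 * AUDIO_FS)) / AUDIO_FS
        x = sps.sawtooth(2 * np.pi * 440.0 * t)
        c = ca.f0_contour(x, AUDIO_FS)
        assert abs(np.median(c.f0[c.voiced]) - 440.0) < 1.0

    def test_white_noise_mostly_unvoiced(self):
        x = np.random.default_rng(SEED).standard_normal(AUDIO_FS)
        c = ca.f0_contour(x, AUDIO_FS)
        assert c.voiced.mean() <= 0.10

    def test_sweep_endpoints(self):
        """Linear 400->800 Hz pulse-train sweep: contour tracks the ends."""
        fs = AUDIO_FS
        dur = 2.0
        times, t = [], 1 / 400.0
        while t < dur:
            times.append(t)
            f_inst = 400.0 + 400.0 * t / dur
            t += 1.0 / f_inst
        x = np.zeros(int(dur * fs))
        idx = np.minimum((np.array(times) * fs).astype(int), len(x) - 1)
        x[idx] = 1.0
        c = ca.f0_contour(x, fs)
        f0 = c.f0[c.voiced]
        tt = c.times[c.voiced]
        f_lo = f0[tt < 0.2].mean()
        f_hi = f0[tt > dur - 0.2].mean()
        true_lo = 400.0 + 400.0 * 0.1 / dur
        true_hi = 400.0 + 400.0 * (dur - 0.1) / dur
        assert abs(f_lo - true_lo) / true_lo < 0.02
        assert abs(f_hi - true_hi) / true_hi < 0.02

    def test_statistics_thresholds(self):
        from cryscope.cry_acoustics import F0Contour
        f0 = np.array([500.0] * 8 + [850.0] * 2)
        c = F0Contour(np.arange(10.0), f0, np.ones(10, bool))
        stats = ca.f0_statistics(c)
        assert stats["high_pitch_pct"] == pytest.approx(0.2)
        assert stats["hyperphonation_pct"] == 0.0
        assert stats["f0_sd"] > 0

    def test_constant_contour(self):
        from cryscope.cry_acoustics import F0Contour
        c = F0Contour(np.arange(5.0), np.full(5, 500.0), np.ones(5, bool))
        stats = ca.f0_statistics(c)
        assert stats["f0_sd"] == 0.0
        assert stats["f0_min"] == stats["f0_mean"] == stats["f0_max"] == 500.0


class TestVoiceQualityFormulas:
    def test_jitter_hand_example(self):
        # mean |dT| = 0.2, mean T = 2.0667 -> 0.09677
        assert ca.jitter_local([2.0, 2.2, 2.0]) == pytest.approx(0.0968, abs=2e-4)

    def test_jitter_constant_periods(self):
        assert ca.jitter_local([2.0, 2.0, 2.0]) == 0.0

    def test_too_few_cycles_undefined(self):
        assert np.isnan(ca.jitter_local([2.0]))
        assert np.isnan(ca.shimmer_local([1.0]))

    def test_shimmer_formula(self):
        assert ca.shimmer_local([1.0, 1.2, 1.0]) == pytest.approx(
            (0.2 + 0.2) / 2 / np.mean([1.0, 1.2, 1.0]))

    def test_hnr_closed_form(self):
        m = CycleMeasures(np.array([0.002]), np.array([1.0, 1.0]),
                          np.array([0.5, 0.5]))
        assert ca.hnr(np.zeros(10), AUDIO_FS, measures=m) == pytest.approx(0.0, abs=1e-9)

    def test_hnr_noiseless_pulse_train(self):
        x = _flat_unit(hnr=40.0)
        assert ca.hnr(x, AUDIO_FS) >= 30.0


class TestRoundTrip:
    @pytest.mark.parametrize("f0,jitter,hnr", [
        (350.0, 0.0, 25.0), (500.0, 0.01, 12.0), (700.0, 0.03, 5.0),
    ])
    def test_spot_recovery(self, f0, jitter, hnr):
        x = _flat_unit(f0=f0, jitter=jitter, shimmer=0.05, hnr=hnr, dur=1.2)
        fv = ca.analyze_unit(x, AUDIO_FS)
        assert abs(fv.f0_mean - f0) / f0 <= 0.01
        assert abs(fv.jitter_local - jitter) <= max(0.005, 0.25 * jitter)
        assert abs(fv.hnr - hnr) <= 2.0
        for est, true in zip((fv.f1, fv.f2, fv.f3), (1400.0, 3500.0, 5900.0)):
            assert abs(est - true) / true <= 0.05

    def test_synthesis_jitter_tracked(self):
        rng = np.random.default_rng(SEED)
        ests = []
        for _ in range(10):
            x = _flat_unit(f0=480.0, jitter=0.02, shimmer=0.1, hnr=12.0,
                           seed=rng, dur=1.0)
            ests.append(ca.analyze_unit(x, AUDIO_FS).jitter_local)
        assert 0.015 <= np.mean(ests) <= 0.025

    def test_jitter_monotone_in_synthesis(self):
        from scipy.stats import spearmanr
        levels = [0.0, 0.01, 0.02, 0.04]
        means = []
        for j in levels:
            rng = np.random.default_rng(SEED + int(j * 1000))
            vals = [ca.analyze_unit(
                _flat_unit(jitter=j, shimmer=0.05, hnr=15.0, seed=rng, dur=0.8),
                AUDIO_FS).jitter_local for _ in range(4)]
            means.append(np.mean(vals))
        rho, _ = spearmanr(levels, means)
        assert rho == 1.0

    def test_hnr_strictly_decreasing_with_noise(self):
        vals = []
        for h in (25.0, 15.0, 5.0):
            vals.append(ca.hnr(_flat_unit(hnr=h, dur=1.0), AUDIO_FS))
        assert vals[0] > vals[1] > vals[2]

    def test_gain_invariance(self):
        x = _flat_unit(jitter=0.01, shimmer=0.08, hnr=15.0, dur=1.0)
        a = ca.analyze_unit(x, AUDIO_FS)
        b = ca.analyze_unit(0.5 * x, AUDIO_FS)
        for attr in ("f0_mean", "jitter_local", "shimmer_local", "hnr",
                     "f1", "f2", "f3"):
            va, vb = getattr(a, attr), getattr(b, attr)
            assert abs(va - vb) <= 1e-6 * max(1.0, abs(va))


class TestFormants:
    def test_table_distress_means_recovered(self):
        x = _flat_unit(f0=412.6, jitter=0.022, shimmer=0.14, hnr=6.66,
                       formants=(1630.672, 3739.816, 6094.533), dur=1.2)
        f = ca.formants(x, AUDIO_FS)
        for est, true in zip(f, (1630.672, 3739.816, 6094.533)):
            assert abs(est - true) / true < 0.05

    def test_white_noise_missing(self):
        x = np.random.default_rng(SEED).standard_normal(AUDIO_FS)
        assert all(np.isnan(v) for v in ca.formants(x, AUDIO_FS))

    def test_all_unvoiced_unit_invalid(self):
        fv = ca.analyze_unit(
            np.random.default_rng(SEED).standard_normal(AUDIO_FS // 2), AUDIO_FS)
        assert not fv.valid
        assert np.isnan(fv.f0_mean)


class TestMfccSpectrogram:
    def test_deterministic(self):
        x = _flat_unit(dur=0.8)
        np.testing.assert_array_equal(ca.mfcc(x, AUDIO_FS), ca.mfcc(x, AUDIO_FS))
        np.testing.assert_array_equal(ca.spectrogram(x, AUDIO_FS),
                                      ca.spectrogram(x, AUDIO_FS))

    def test_summary_dimension(self):
        assert ca.mfcc(_flat_unit(dur=0.6), AUDIO_FS).shape == (26,)

    def test_distinct_pitches_distinct_summaries(self):
        a = ca.mfcc(_flat_unit(f0=400.0, dur=0.8), AUDIO_FS)
        b = ca.mfcc(_flat_unit(f0=800.0, dur=0.8), AUDIO_FS)
        assert np.linalg.norm(a - b) > 0

    def test_gain_changes_only_zeroth_coefficient(self):
        x = _flat_unit(dur=0.8)
        a = ca.mfcc(x, AUDIO_FS)
        b = ca.mfcc(2.0 * x, AUDIO_FS)
        assert abs(a[0] - b[0]) > 1e-3          # energy coefficient moves
        assert np.abs(a[1:13] - b[1:13]).max() < 1e-6

    def test_spectrogram_fixed_canvas(self):
        short = ca.spectrogram(_flat_unit(dur=0.4), AUDIO_FS)
        long = ca.spectrogram(_flat_unit(dur=2.5), AUDIO_FS)
        assert short.shape == long.shape == (64, 59)
        assert short.dtype == np.float32
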