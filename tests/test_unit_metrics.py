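"""Waveform features and classification, rate statistics, STAs."""

import warnings

import numpy as np
import pytest

import optovis as ov
from optovis import unit_metrics as um

FS = 30000.0
DT_MS = 1000.0 / FS


class TestWaveformFeatures:
    def test_symmetric_peak_equals_trough(self):
        # triangle trough to -1 then back up to +1
        n = int(1.0 / DT_MS)
        w = np.concatenate([np.linspace(0, -1, n), np.linspace(-1, 1, 2 * n)])
        f = um.waveform_features(w, FS)
        assert f.peak_trough_height == pytest.approx(1.0, abs=0.01)

    def test_linear_ramp_slope_exact(self):
        n = int(2.0 / DT_MS)
        s = 0.4  # normalized amplitude per ms
        ramp = -1 + s * DT_MS * np.arange(n)
        w = np.concatenate([np.zeros(5), [-1.0], ramp[1:]])
        f = um.waveform_features(w, FS)
        assert f.post_trough_slope == pytest.approx(s, rel=1e-6)

    def test_trough_at_last_sample_errors(self):
        with pytest.raises(ValueError, match="last sample"):
            um.waveform_features(np.array([0.0, -0.5, -1.0]), FS)

    def test_normalization_scale_invariant(self):
        w = ov.synth.waveform_template(0.5, 0.25, FS)
        a = um.waveform_features(w, FS)
        b = um.waveform_features(w * 137.0, FS)
        assert a.peak_trough_height == pytest.approx(b.peak_trough_height)
        assert a.post_trough_slope == pytest.approx(b.post_trough_slope)


def centroid_features(rng, n_bs=60, n_ns=25):
    """Feature triples jittered around the empirical BS/NS class centroids."""
    bs = np.stack([
        rng.normal(0.20, 0.05, n_bs),
        rng.normal(0.73, 0.10, n_bs),
        rng.normal(0.01, 0.005, n_bs),
    ], axis=1)
    ns = np.stack([
        rng.normal(0.34, 0.05, n_ns),
        rng.normal(0.32, 0.10, n_ns),
        rng.normal(-0.01, 0.005, n_ns),
    ], axis=1)
    feats = [
        um.WaveformFeatures(h, max(t, 0.05), s)
        for h, t, s in np.concatenate([bs, ns])
    ]
    truth = np.array(["BS"] * n_bs + ["NS"] * n_ns, dtype=object)
    return feats, truth


class TestClassifyNsBs:
    def test_two_units_larger_ttp_is_bs(self):
        feats = [
            um.WaveformFeatures(0.2, 0.7, 0.01),
            um.WaveformFeatures(0.3, 0.3, -0.01),
        ]
        res = um.classify_ns_bs(feats)
        assert list(res.labels) == ["BS", "NS"]

    def test_centroid_mixture_recovered(self):
        feats, truth = centroid_features(np.random.default_rng(0))
        res = um.classify_ns_bs(feats)
        assert np.mean(res.labels == truth) >= 0.95

    def test_order_invariance(self):
        feats, _ = centroid_features(np.random.default_rng(1), 20, 10)
        res = um.classify_ns_bs(feats)
        perm = np.random.default_rng(2).permutation(len(feats))
        res_p = um.classify_ns_bs([feats[i] for i in perm])
        assert np.array_equal(res_p.labels, res.labels[perm])

    def test_affine_rescaling_of_one_feature_invariant(self):
        feats, _ = centroid_features(np.random.default_rng(3), 20, 10)
        scaled = [
            um.WaveformFeatures(
                f.peak_trough_height * 10 + 3, f.trough_to_peak, f.post_trough_slope
            )
            for f in feats
        ]
        assert np.array_equal(
            um.classify_ns_bs(feats).labels, um.classify_ns_bs(scaled).labels
        )

    def test_duplicated_units_get_duplicated_labels(self):
        feats, _ = centroid_features(np.random.default_rng(4), 10, 5)
        res = um.classify_ns_bs(feats)
        res2 = um.classify_ns_bs(feats + feats)
        assert np.array_equal(res2.labels[: len(feats)], res2.labels[len(feats):])
        assert np.array_equal(res2.labels[: len(feats)], res.labels)

    def test_identical_features_rejected(self):
        feats = [um.WaveformFeatures(0.2, 0.5, 0.0)] * 4
        with pytest.raises(ValueError, match="degenerate"):
            um.classify_ns_bs(feats)


class TestRates:
    def _table(self, counts, lasers=None, states=None):
        counts = np.asarray(counts)
        n = counts.shape[0]
        return ov.TrialTable(
            counts=counts,
            unit_ids=[f"u{j}" for j in range(counts.shape[1])],
            stimulus_direction=np.zeros(n),
            laser_on=np.zeros(n, bool) if lasers is None else np.asarray(lasers),
            locomotion=np.array(
                ["still"] * n if states is None else states, dtype=object
            ),
            mean_speed=np.zeros(n),
            window_start_offset=0.5,
            window_length=1.0,
        )

    def test_condition_rate_is_mean_over_window(self):
        t = self._table([[3], [5]])
        assert um.condition_rate(t, 0) == pytest.approx(4.0)

    def test_empty_unit_rate_zero(self):
        t = self._table([[0], [0]])
        assert um.condition_rate(t, 0) == 0.0

    def test_no_matching_trials_errors(self):
        t = self._table([[1], [2]])
        with pytest.raises(ValueError, match="laser=True"):
            um.condition_rate(t, 0, laser=True)

    def test_ratio_identical_rates_is_one(self):
        t = self._table([[4], [4]], lasers=[False, True])
        assert um.laser_rate_ratio(t, 0) == pytest.approx(1.0)

    def test_ratio_silent_laser_on_is_zero(self):
        t = self._table([[4], [4], [0], [0]], lasers=[False, False, True, True])
        assert um.laser_rate_ratio(t, 0) == 0.0

    def test_ratio_zero_off_rate_flagged_nan(self):
        t = self._table([[0], [0], [3], [3]], lasers=[False, False, True, True])
        with pytest.warns(UserWarning, match="undefined"):
            assert np.isnan(um.laser_rate_ratio(t, 0))


class TestEvokedBaselineRatio:
    def test_exact_arithmetic(self, make_session):
        # 2 trials at 0 deg: evoked 10 Hz at optimal, baseline 5 Hz
        stims = [(2.0, 2.0, 0.0), (8.0, 2.0, 0.0)]
        spikes = []
        for onset in (2.0, 8.0):
            spikes += [onset - 0.5 + 0.1 * k for k in range(5)]      # baseline, 0.5 s pre
            spikes += [onset + 0.5 + 0.05 * k for k in range(10)]    # evoked window
        sess = make_session([sorted(spikes)], stims)
        r = um.evoked_baseline_ratio(
            sess.units[0], sess.stimulus_events, pre_window=0.5
        )
        # evoked 10 spikes / 1 s = 10 Hz; baseline 5 spikes / 0.5 s = 10 Hz
        assert r == pytest.approx(1.0, abs=1e-9)

    def test_stimulus_independent_unit_near_unity(self, make_session):
        rng = np.random.default_rng(0)
        duration = 700.0
        spikes = np.sort(rng.uniform(0, duration, int(duration * 20)))
        stims = [(5.0 + 4.0 * i, 2.0, float(45 * (i % 8))) for i in range(160)]
        sess = make_session([spikes], stims, duration=duration)
        r = um.evoked_baseline_ratio(sess.units[0], sess.stimulus_events)
        assert r == pytest.approx(1.0, abs=0.2)

    def test_tuned_generator_unit_above_unity(self, small_session):
        sess, truth = small_session
        r = um.evoked_baseline_ratio(sess.units[0], sess.stimulus_events)
        assert r > 1.0


class TestCoefficientOfVariation:
    def test_constant_rates(self):
        assert um.coefficient_of_variation([4.0, 4.0, 4.0]) == 0.0

    def test_two_point_example(self):
        assert um.coefficient_of_variation([1.0, 3.0]) == pytest.approx(
            np.sqrt(2) / 2
        )

    def test_scale_invariance(self):
        rng = np.random.default_rng(0)
        r = rng.uniform(1, 10, 50)
        assert um.coefficient_of_variation(r * 7.3) == pytest.approx(
            um.coefficient_of_variation(r)
        )

    def test_poisson_limit(self):
        rng = np.random.default_rng(1)
        lam = 20.0
        counts = rng.poisson(lam, 4000)
        assert um.coefficient_of_variation(counts.astype(float)) == pytest.approx(
            1 / np.sqrt(lam), rel=0.1
        )

    def test_zero_mean_flagged(self):
        with pytest.warns(UserWarning, match="undefined"):
            assert np.isnan(um.coefficient_of_variation([0.0, 0.0]))


class TestSta:
    def test_frame_locked_spikes_recover_frame(self):
        rng = np.random.default_rng(0)
        movie = rng.standard_normal((100, 5, 5))
        frame_rate = 30.0
        spikes = (17 + np.zeros(40)) / frame_rate + 0.01
        sta, counts = um.spike_triggered_average(spikes, movie, frame_rate)
        assert counts[0] == 40
        assert np.allclose(sta[0], movie[17])

    def test_no_spikes_errors(self):
        movie = np.zeros((10, 3, 3))
        with pytest.raises(ValueError, match="no spikes"):
            um.spike_triggered_average(np.array([99.0]), movie, 30.0)

    def test_time_reversal_symmetry(self):
        rng = np.random.default_rng(1)
        movie = rng.standard_normal((200, 4, 4))
        fr = 30.0
        frames = rng.integers(0, 200, 60)
        spikes = np.sort((frames + 0.5) / fr)
        sta, _ = um.spike_triggered_average(spikes, movie, fr)
        T = movie.shape[0] / fr
        sta_rev, _ = um.spike_triggered_average(
            np.sort(T - spikes), movie[::-1], fr
        )
        assert np.allclose(sta, sta_rev)


class TestSuMu:
    def test_flat_sta_scores_low(self):
        score = um.sta_snr_score(np.zeros((1, 5, 5)), pixel_variance=1.0, n_spikes=100)
        assert score == 0.0
        assert um.classify_su_mu(np.array([score]))[0] == "MU"

    def test_strong_sta_scores_high(self):
        sta = np.zeros((1, 5, 5))
        sta[0, 2, 2] = 1.0
        score = um.sta_snr_score(sta, pixel_variance=1.0, n_spikes=400)
        assert score == pytest.approx(20.0)
        assert um.classify_su_mu(np.array([score]))[0] == "SU"

    def test_threshold_monotone(self):
        scores = np.array([0.0, 3.0, 8.0, 30.0])
        n_su = [
            np.sum(um.classify_su_mu(scores, threshold=t) == "SU")
            for t in (0.0, 5.0, 10.0, np.inf)
        ]
        assert n_su == sorted(n_su, reverse=True)
        assert n_su[-1] == 0
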