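import numpy as np
import pandas as pd
import pytest

import boldmvpa as bm
from boldmvpa.glm import HRFEstimate


class TestDeconvolution:
    def test_noiseless_kernel_recovery(self, noiseless_session):
        s = noiseless_session
        est = bm.deconvolve_hrf(s["runs"], s["events"], window_seconds=31)
        pooled = bm.pool_and_normalize_hrf(est)
        np.testing.assert_allclose(pooled.samples, s["hrf"], atol=1e-8)

    def test_per_condition_scaling_recovered(self, noiseless_session):
        # each per-speed kernel is the true kernel times that speed's
        # ROI-mean amplitude
        s = noiseless_session
        est = bm.deconvolve_hrf(s["runs"], s["events"], window_seconds=31)
        truth = s["truth"]
        for speed, hrf_c in est.items():
            sel = (truth.labels["speed"] == speed).to_numpy()
            amp = truth.amplitudes_true[sel].mean()
            np.testing.assert_allclose(hrf_c.samples, amp * s["hrf"],
                                       atol=1e-8)

    def test_all_zero_series_gives_zero_kernel(self, noiseless_session):
        s = noiseless_session
        zero_runs = [ts.with_data(np.zeros_like(ts.data)) for ts in s["runs"]]
        est = bm.deconvolve_hrf(zero_runs, s["events"], window_seconds=20)
        for hrf_c in est.values():
            assert np.abs(hrf_c.samples).max() < 1e-10

    def test_overlapping_trials_still_exact(self):
        # every ITI shorter than the kernel window: responses overlap heavily,
        # yet the full-rank FIR design still recovers the kernel exactly
        spec = bm.DesignSpec(speeds=(8.0,), trials_per_speed=30, n_runs=2,
                             iti_min_seconds=2, iti_max_seconds=6,
                             iti_mean_seconds=4)
        events = bm.build_design(spec, seed=77)
        pop = bm.make_population(1, seed=0, noise_sd=0.0, drift_order=0)
        h = bm.canonical_hrf()
        runs, truth = bm.simulate_runs(events, pop, h, spec)
        assert events.groupby("run")["onset"].diff().dropna().max() < 31
        est = bm.deconvolve_hrf(runs, events, window_seconds=31)
        amp = truth.amplitudes_true.mean()
        np.testing.assert_allclose(est[8.0].samples, amp * h, atol=1e-8)


class TestPooling:
    def test_output_sums_to_one(self):
        k = np.array([0.0, 2.0, 1.0, 0.5])
        pooled = bm.pool_and_normalize_hrf(
            [HRFEstimate(k, 1.0, "a"), HRFEstimate(3 * k, 1.0, "b")])
        assert pooled.samples.sum() == pytest.approx(1.0, abs=1e-12)
        np.testing.assert_allclose(pooled.samples, k / k.sum())

    def test_identical_inputs_idempotent(self):
        k = np.array([0.0, 1.0, 3.0])
        pooled = bm.pool_and_normalize_hrf([HRFEstimate(k, 1.0)] * 3)
        np.testing.assert_allclose(pooled.samples, k / k.sum())

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            bm.pool_and_normalize_hrf([])

    def test_mismatched_windows_rejected(self):
        with pytest.raises(ValueError):
            bm.pool_and_normalize_hrf([HRFEstimate(np.ones(3), 1.0),
                                       HRFEstimate(np.ones(4), 1.0)])


class TestTrialDesignMatrix:
    @pytest.fixture()
    def unit_hrf(self):
        k = bm.canonical_hrf()
        return HRFEstimate(k, 1.0, "pooled", unit_area=True)

    def test_one_column_per_trial(self, noiseless_session, unit_hrf):
        ev = noiseless_session["events"]
        X = bm.trial_design_matrix(ev, unit_hrf, 224, 2.0)
        assert X.shape == (6 * 224, 240)

    def test_single_trial_column_equals_kernel(self, unit_hrf):
        ev = pd.DataFrame({"onset": [0.0], "duration": 3.0, "speed": 8.0,
                           "luminance": 30.0, "run": 0})
        X = bm.trial_design_matrix(ev, unit_hrf, 100, 1.0)
        np.testing.assert_allclose(X[:len(unit_hrf.samples), 0],
                                   unit_hrf.samples)

    def test_shift_by_one_tr_shifts_column(self, unit_hrf):
        base = {"duration": 3.0, "speed": 8.0, "luminance": 30.0, "run": 0}
        ev_a = pd.DataFrame([{"onset": 10.0, **base}])
        ev_b = pd.DataFrame([{"onset": 12.0, **base}])
        Xa = bm.trial_design_matrix(ev_a, unit_hrf, 224, 2.0)
        Xb = bm.trial_design_matrix(ev_b, unit_hrf, 224, 2.0)
        np.testing.assert_allclose(Xb[6:, 0], Xa[5:-1, 0])

    def test_onset_beyond_run_rejected(self, unit_hrf):
        ev = pd.DataFrame({"onset": [500.0], "duration": 3.0, "speed": 8.0,
                           "luminance": 30.0, "run": 0})
        with pytest.raises(ValueError, match="beyond run end"):
            bm.trial_design_matrix(ev, unit_hrf, 224, 2.0)

    def test_non_unit_area_rejected(self):
        with pytest.raises(ValueError, match="unit-area"):
            bm.trial_design_matrix(pd.DataFrame(), HRFEstimate(np.ones(3), 1.0),
                                   224, 2.0)


class TestFitTrialAmplitudes:
    def test_noiseless_exact_recovery(self, noiseless_session):
        s = noiseless_session
        hrf = HRFEstimate(s["hrf"], 1.0, "pooled", unit_area=True)
        amps = bm.fit_trial_amplitudes(s["runs"], s["events"], hrf)
        np.testing.assert_allclose(amps.amplitudes,
                                   s["truth"].amplitudes_true, atol=1e-8)
        assert amps.r_squared.min() > 1 - 1e-9
        assert (amps.mean_sign > 0).all()

    def test_matrix_is_m_by_n(self, noisy_session):
        amps = noisy_session["amps"]
        assert amps.amplitudes.shape == (240, 120)
        assert (amps.r_squared >= 0).all() and (amps.r_squared <= 1).all()

    def test_pure_noise_voxels_have_low_r_squared(self, exp1_spec):
        events = bm.build_design(exp1_spec, seed=11)
        pop = bm.make_population(40, seed=12, gain=0.0, noise_sd=1.0,
                                 drift_order=0)
        runs, _ = bm.simulate_runs(events, pop, bm.canonical_hrf(), exp1_spec,
                                   seed=13)
        hrf = HRFEstimate(bm.canonical_hrf(), 1.0, "pooled", unit_area=True)
        amps = bm.fit_trial_amplitudes(runs, events, hrf)
        # 240 regressors on 1344 samples: null R^2 concentrates near m/T
        assert (amps.r_squared < 0.25).mean() > 0.9

    def test_r_squared_decreases_with_noise(self, exp1_spec):
        events = bm.build_design(exp1_spec, seed=21)
        hrf = HRFEstimate(bm.canonical_hrf(), 1.0, "pooled", unit_area=True)
        r2 = []
        for noise in (0.5, 1.0, 2.0):
            pop = bm.make_population(30, seed=22, noise_sd=noise,
                                     drift_order=0)
            runs, _ = bm.simulate_runs(events, pop, bm.canonical_hrf(),
                                       exp1_spec, seed=23)
            amps = bm.fit_trial_amplitudes(runs, events, hrf)
            r2.append(amps.r_squared.mean())
        assert r2[0] > r2[1] > r2[2]


class TestConditionStats:
    def _amps(self, values, speeds, lums=None, runs=None):
        m = len(values)
        meta = pd.DataFrame({"speed": speeds,
                             "luminance": lums or [30.0] * m,
                             "run": runs or [0] * m})
        return bm.TrialAmplitudeMatrix(
            amplitudes=np.asarray(values, float).reshape(-1, 1),
            trial_meta=meta, r_squared=np.array([1.0]),
            mean_sign=np.array([1.0]))

    def test_hand_computed_t(self):
        stats = bm.condition_stats(self._amps([1.0, 2.0, 3.0], [8.0] * 3))
        assert stats.mean[0, 0, 0] == pytest.approx(2.0)
        assert stats.sd[0, 0, 0] == pytest.approx(1.0)
        assert stats.t[0, 0, 0] == pytest.approx(2.0 / (1.0 / np.sqrt(3)))
        assert stats.df[0, 0, 0] == 2

    def test_session_cell_counts_and_df(self, noisy_session):
        # 10 trials per speed per run x 3 runs per luminance level
        stats = bm.condition_stats(noisy_session["amps"])
        assert (stats.count[stats.count > 0] == 30).all()
        assert (stats.df == np.maximum(stats.count - 1, 0)).all()

    def test_ten_trials_give_df_nine(self):
        amps = self._amps(list(range(10)), [8.0] * 10)
        stats = bm.condition_stats(amps)
        assert stats.df[0, 0, 0] == 9

    def test_all_zero_amplitudes_give_zero_t(self):
        stats = bm.condition_stats(self._amps([0.0] * 4, [8.0] * 4))
        assert stats.t[0, 0, 0] == 0.0

    def test_zero_variance_gives_signed_infinity(self):
        with pytest.warns(UserWarning, match="zero-variance"):
            stats = bm.condition_stats(self._amps([2.0, 2.0], [8.0] * 2))
        assert stats.t[0, 0, 0] == np.inf


class TestMeanTuning:
    def test_band_pass_shape_with_generator_defaults(self, noisy_session):
        curve = bm.mean_tuning(noisy_session["amps"])
        by_speed = curve.groupby("speed")["mean"].mean()
        assert by_speed[4.0] > by_speed[2.0]
        assert by_speed[8.0] > by_speed[13.3]
        assert by_speed.idxmax() in (4.0, 8.0)

    def test_flat_for_identical_amplitudes(self):
        meta = pd.DataFrame({"speed": [2.0, 4.0] * 4, "luminance": 30.0,
                             "run": 0})
        amps = bm.TrialAmplitudeMatrix(
            amplitudes=np.full((8, 3), 5.0), trial_meta=meta,
            r_squared=np.ones(3), mean_sign=np.ones(3))
        curve = bm.mean_tuning(amps)
        assert curve["mean"].nunique() == 1
        assert (curve["sem"] == 0).all()


def test_amplitude_h5_round_trip(tmp_path, noisy_session):
    amps = noisy_session["amps"]
    path = tmp_path / "amps.h5"
    bm.save_amplitudes(amps, path)
    back = bm.load_amplitudes(path)
    np.testing.assert_array_equal(back.amplitudes, amps.amplitudes)
    pd.testing.assert_frame_equal(
        back.trial_meta, amps.trial_meta.astype({"run": int}),
        check_dtype=False)
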