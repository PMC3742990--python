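import numpy as np
import pandas as pd
import pytest
from sklearn.base import clone

import boldmvpa as bm
from boldmvpa.decoder import (DecoderConfig, LarsLassoDecoder, _gram_loro_predict,
                              _loro_predict, _pattern_matrix, _precompute_folds)


def amps_from(X, speeds, runs, lums=None):
    meta = pd.DataFrame({"speed": speeds,
                         "luminance": lums if lums is not None
                         else [30.0] * len(speeds),
                         "run": runs})
    return bm.TrialAmplitudeMatrix(amplitudes=np.asarray(X, float),
                                   trial_meta=meta,
                                   r_squared=np.ones(X.shape[1]),
                                   mean_sign=np.ones(X.shape[1]))


def synthetic_amps(seed=0, m_per_run=20, n_runs=4, n_vox=30, informative=True):
    rng = np.random.default_rng(seed)
    speeds = np.tile(np.repeat([2.0, 4.0, 8.0, 13.3], m_per_run // 4), n_runs)
    runs = np.repeat(np.arange(n_runs), m_per_run)
    X = rng.normal(size=(len(speeds), n_vox))
    if informative:
        X[:, 0] = speeds
    return amps_from(X, speeds, runs)


class TestEstimator:
    def test_sklearn_protocol(self):
        est = LarsLassoDecoder(max_active=7)
        assert est.get_params() == {"max_active": 7, "standardize": True}
        est2 = clone(est).set_params(max_active=3)
        assert est2.max_active == 3

    def test_intercept_only_when_no_active_allowed(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(20, 5))
        y = rng.normal(size=20)
        model = LarsLassoDecoder(max_active=0).fit(X, y)
        np.testing.assert_allclose(model.predict(rng.normal(size=(4, 5))),
                                   np.full(4, y.mean()))

    def test_perfectly_informative_voxel_enters_first(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(60, 20))
        y = np.tile([2.0, 4.0, 8.0, 13.3], 15)
        X[:, 11] = y
        model = LarsLassoDecoder(max_active=5).fit(X, y)
        assert model.active_[0] == 11

    def test_active_set_bounded(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(100, 80))
        y = X[:, :10] @ rng.normal(size=10)
        model = LarsLassoDecoder(max_active=25).fit(X, y)
        assert np.count_nonzero(model.coef_) <= 25

    def test_infeasible_max_active_clipped_with_warning(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(10, 4))
        y = rng.normal(size=10)
        with pytest.warns(UserWarning, match="clipped"):
            LarsLassoDecoder(max_active=50).fit(X, y)

    def test_prediction_is_affine(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(40, 10))
        y = X[:, 0] * 2 + rng.normal(size=40)
        model = LarsLassoDecoder(max_active=5).fit(X, y)
        x = rng.normal(size=(3, 10))
        lhs = model.predict(2.0 * x) - model.intercept_
        rhs = 2.0 * (model.predict(x) - model.intercept_)
        np.testing.assert_allclose(lhs, rhs, atol=1e-10)
        assert model.predict(np.zeros((1, 10)))[0] == \
            pytest.approx(model.intercept_)

    def test_constant_labels_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            LarsLassoDecoder().fit(np.eye(5), np.ones(5))


class TestLeaveOneRunOut:
    def test_perfect_linear_code_decoded_exactly(self):
        amps = synthetic_amps(seed=5, informative=True)
        # keep only the informative voxel: noiseless perfect code
        amps.amplitudes = amps.amplitudes[:, [0]]
        amps.r_squared = amps.r_squared[[0]]
        amps.mean_sign = amps.mean_sign[[0]]
        cfg = DecoderConfig(max_active=1, normalization="none")
        res = bm.leave_one_run_out(amps, "speed", cfg)
        assert res.pearson_r == pytest.approx(1.0, abs=1e-8)
        np.testing.assert_allclose(res.predicted, res.actual, atol=1e-8)

    def test_uninformative_patterns_near_chance(self):
        rs = [abs(bm.leave_one_run_out(
            synthetic_amps(seed=s, n_vox=40, informative=False),
            "speed", DecoderConfig(max_active=10)).pearson_r)
            for s in (10, 11, 12)]
        assert np.median(rs) < 0.2

    def test_every_trial_predicted_once(self, noisy_session):
        res = bm.leave_one_run_out(noisy_session["amps"])
        assert len(res.predicted) == 240
        assert np.isfinite(res.predicted).all()
        assert -1.0 <= res.pearson_r <= 1.0

    def test_needs_two_runs(self):
        amps = synthetic_amps(n_runs=1)
        with pytest.raises(ValueError, match="two runs"):
            bm.leave_one_run_out(amps)

    def test_unit_norm_contract(self, noisy_session):
        X = _pattern_matrix(noisy_session["amps"], DecoderConfig())
        np.testing.assert_allclose(np.linalg.norm(X, axis=1), 1.0, atol=1e-12)


class TestPermutationChance:
    def test_deterministic_given_seed(self):
        amps = synthetic_amps(seed=20)
        cfg = DecoderConfig(max_active=5, n_permutations=10, seed=7)
        a = bm.permutation_chance(amps, "speed", cfg)
        b = bm.permutation_chance(amps, "speed", cfg)
        np.testing.assert_array_equal(a.predicted, b.predicted)
        np.testing.assert_array_equal(a.extras["permutation_r"],
                                      b.extras["permutation_r"])

    def test_gram_fast_path_matches_estimator_route(self):
        amps = synthetic_amps(seed=21)
        cfg = DecoderConfig(max_active=5)
        X = _pattern_matrix(amps, cfg)
        y = amps.trial_meta["speed"].to_numpy(float)
        runs = amps.trial_meta["run"].to_numpy()
        rng = np.random.default_rng(0)
        y_perm = y[rng.permutation(len(y))]
        slow = _loro_predict(X, y_perm, runs, cfg)
        fast = _gram_loro_predict(_precompute_folds(X, runs, cfg), y_perm, runs)
        np.testing.assert_allclose(fast, slow, atol=1e-10)

    def test_chance_centered_for_uninformative_patterns(self):
        amps = synthetic_amps(seed=22, n_vox=40, informative=False)
        cfg = DecoderConfig(max_active=10, n_permutations=60, seed=3)
        res = bm.permutation_chance(amps, "speed", cfg)
        r = res.extras["permutation_r"]
        m = len(res.actual)
        assert np.abs(r).mean() < 2 / np.sqrt(m)

    def test_chance_centered_for_decodable_patterns(self, noisy_session):
        cfg = DecoderConfig(max_active=25, n_permutations=60, seed=4)
        res = bm.permutation_chance(noisy_session["amps"], "speed", cfg)
        r = res.extras["permutation_r"]
        assert abs(r.mean()) < 3 * r.std() / np.sqrt(len(r))


class TestUnivariateControl:
    def test_single_voxel_equals_multivariate(self):
        amps = synthetic_amps(seed=30, n_vox=1, informative=True)
        cfg = DecoderConfig(max_active=1, normalization="none")
        uni = bm.univariate_control(amps, "speed", cfg)
        multi = bm.leave_one_run_out(amps, "speed", cfg)
        np.testing.assert_allclose(uni.predicted, multi.predicted, atol=1e-10)


class TestCrossCondition:
    def test_same_condition_equals_within_on_subset(self, exp2_amps):
        cfg = DecoderConfig(max_active=10)
        hi = 30.0
        cross = bm.cross_condition(exp2_amps, "speed", hi, hi, cfg)
        sel = (exp2_amps.trial_meta["luminance"] == hi).to_numpy()
        sub = bm.TrialAmplitudeMatrix(
            amplitudes=exp2_amps.amplitudes[sel],
            trial_meta=exp2_amps.trial_meta[sel].reset_index(drop=True),
            r_squared=exp2_amps.r_squared, mean_sign=exp2_amps.mean_sign)
        within = bm.leave_one_run_out(sub, "speed", cfg)
        np.testing.assert_allclose(np.sort(cross.predicted),
                                   np.sort(within.predicted), atol=1e-10)
        assert cross.regime == "train_high_test_high"

    def test_absent_condition_rejected(self, exp2_amps):
        with pytest.raises(ValueError, match="no runs"):
            bm.cross_condition(exp2_amps, "speed", 99.0, 30.0)

    def test_luminance_invariant_code_generalizes(self):
        # same speed->pattern mapping in both conditions: across-luminance
        # performance matches within-luminance performance
        rng = np.random.default_rng(40)
        speeds = np.tile(np.repeat([3.0, 6.0, 10.0], 10), 6)
        runs = np.repeat(np.arange(6), 30)
        lums = np.where(runs < 3, 30.0, 1.5)
        W = rng.normal(size=(1, 25))
        X = speeds[:, None] @ W + rng.normal(size=(180, 25)) * 2.0
        amps = amps_from(X, speeds, runs, lums)
        cfg = DecoderConfig(max_active=10)
        hh = bm.cross_condition(amps, "speed", 30.0, 30.0, cfg).pearson_r
        lh = bm.cross_condition(amps, "speed", 1.5, 30.0, cfg).pearson_r
        assert lh > 0.8 * hh


    def test_luminance_dependent_code_degrades_transfer(self):
        # different speed->pattern mapping per condition: across-luminance
        # prediction falls below within-luminance prediction
        rng = np.random.default_rng(41)
        speeds = np.tile(np.repeat([3.0, 6.0, 10.0], 10), 6)
        runs = np.repeat(np.arange(6), 30)
        lums = np.where(runs < 3, 30.0, 1.5)
        Wh, Wl = rng.normal(size=(2, 1, 25))
        X = np.where((lums == 30.0)[:, None],
                     speeds[:, None] @ Wh, speeds[:, None] @ Wl)
        X = X + rng.normal(size=X.shape) * 1.0
        amps = amps_from(X, speeds, runs, lums)
        # a rank-1 amplitude code is erased by per-trial unit-norm scaling,
        # so decode the raw patterns here
        cfg = DecoderConfig(max_active=10, normalization="none")
        hh = bm.cross_condition(amps, "speed", 30.0, 30.0, cfg).pearson_r
        lh = bm.cross_condition(amps, "speed", 1.5, 30.0, cfg).pearson_r
        assert lh < hh - 0.2

    def test_decoding_improves_with_pattern_signal(self):
        from conftest import simulate_session_amps
        rs = []
        for gain in (2.0, 15.0):
            amps, _ = simulate_session_amps(seed=909, n_voxels=60, gain=gain)
            rs.append(bm.leave_one_run_out(amps, "speed").pearson_r)
        assert rs[1] > rs[0]


class TestDecodeBinary:
    def test_additive_pattern_separates_classes(self, exp2_amps):
        res = bm.decode_binary(exp2_amps)
        means = res.mean_predicted_per_label
        assert means[1.0] - means[0.0] > 0.3
        assert res.extras["accuracy"] > 0.8

    def test_constant_labels_rejected(self):
        amps = synthetic_amps(seed=50)
        with pytest.raises(ValueError, match="two levels"):
            bm.decode_binary(amps, "luminance")
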