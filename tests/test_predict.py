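"""Feature windows, ridge/end-to-end scoring, epoch EV and derived flags."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from movenc import predict, preprocess, synth
from movenc.predict import End2EndNet, PredictionResult


class TestBuildFeatures:
    def test_embedding_window_is_80d(self):
        series = np.random.default_rng(0).normal(size=(100, 16))
        X = predict.build_features(series, 0.0034, np.array([0.1, 0.2]))
        assert X.shape == (2, 80)

    def test_marker_window_is_15d(self, small_session):
        mk = predict.marker_features(small_session.markers)
        assert mk.shape[1] == 3
        X = predict.build_features(mk, 0.0034, np.array([0.1]))
        assert X.shape == (1, 15)

    def test_tau_shift_equals_time_shift(self):
        series = np.random.default_rng(1).normal(size=(200, 4))
        t = np.array([0.2, 0.3])
        shifted = predict.build_features(series, 0.0034, t, tau=0.0068)
        direct = predict.build_features(series, 0.0034, t + 0.0068)
        assert np.allclose(shifted, direct)

    def test_edge_replication(self):
        series = np.arange(10, dtype=float)[:, None]
        X = predict.build_features(series, 1.0, np.array([0.0]))
        assert np.allclose(X[0], [0, 0, 0, 1, 2])

    def test_window_ordering(self):
        series = np.arange(50, dtype=float)[:, None]
        X = predict.build_features(series, 1.0, np.array([10.0]))
        assert np.allclose(X[0], [8, 9, 10, 11, 12])


def _toy_regression(n_trials=60, p=6, n_t=4, noise=0.0, seed=0):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n_t, n_trials, p))
    W = rng.normal(size=(p, 3))
    Y = np.einsum("tnp,pm->mnt", X, W)
    Y += noise * rng.normal(size=Y.shape)
    folds = np.arange(n_trials) % 5
    return X, Y, folds


class TestRidgePredict:
    def test_noiseless_linear_system_r2_one(self):
        X, Y, folds = _toy_regression(noise=0.0)
        res = predict.ridge_predict(X, Y, folds, np.arange(4) * 0.0034)
        assert np.all(res.r2 > 0.99)

    def test_unrelated_targets_rectified_ev_near_zero(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(3, 80, 8))
        Y = rng.normal(size=(2, 80, 3))
        folds = np.arange(80) % 5
        res = predict.ridge_predict(X, Y, folds, np.arange(3) * 0.0034)
        assert np.all(res.rectified() < 0.05)

    def test_zero_variance_target_flagged(self):
        X, Y, folds = _toy_regression()
        Y[1] = 5.0
        res = predict.ridge_predict(X, Y, folds, np.arange(4) * 0.0034)
        assert res.zero_variance[1].all()
        assert np.all(res.r2[:, 1, :] == 0.0)

    def test_held_out_predictions_cover_every_trial(self):
        X, Y, folds = _toy_regression(noise=0.5)
        res = predict.ridge_predict(X, Y, folds, np.arange(4) * 0.0034,
                                    store_predictions=True)
        assert np.isfinite(res.predictions).all()

    def test_shuffled_rates_have_no_ev(self):
        # cross-validation sanity: destroying the trial correspondence
        # drives epoch EV to ~0
        rng = np.random.default_rng(2)
        X, Y, folds = _toy_regression(n_trials=100, noise=0.5, seed=3)
        Ys = Y[:, rng.permutation(100), :]
        res = predict.ridge_predict(X, Ys, folds, np.arange(4) * 0.0034)
        assert np.all(res.rectified().mean(axis=1) < 0.02)


class TestEnd2EndArchitecture:
    def test_pre_output_length_160(self):
        net = End2EndNet(n_neurons=7, seed=0)
        assert net.PRE_OUTPUT == 160
        assert net.trunk_dim((120, 112)) * 5 == 160

    def test_small_frames_preserve_pre_output(self):
        net = End2EndNet(n_neurons=3, seed=0, frame_size=(16, 16))
        assert net.trunk_dim((16, 16)) * 5 == 160
        windows = np.random.default_rng(0).random((4, 5, 16, 16)).astype(np.float32)
        net.set_train(False)
        out = net.forward(windows)
        assert out.shape == (4, 3)

    def test_constant_rates_scored_zero(self):
        rng = np.random.default_rng(3)
        frames = rng.random((400, 8, 8)).astype(np.float32)
        rates = np.full((2, 20, 3), 4.0)
        abs_times = (np.arange(20)[:, None] * 0.05 + np.array([0.01, 0.02, 0.03]))
        folds = (np.arange(20) % 2)
        cfg = predict.End2EndConfig(steps=4, batch_size=8, eval_every=4)
        res = predict.end2end_predict(frames, 0.0034, rates, abs_times, folds,
                                      np.array([0.01, 0.02, 0.03]), cfg)
        assert np.all(res.r2 == 0.0)


def _result(r2, timepoints):
    return PredictionResult(r2=r2, timepoints=timepoints, folds=np.zeros(1),
                            method="test", eval_fold_ids=np.arange(r2.shape[0]))


def _trial_table(pre=0.3, samp=0.45, delay=0.6, resp=0.75):
    return pd.DataFrame({
        "trial_id": [0], "start_time": [0.0], "sample_on": [pre],
        "sample_off": [pre + samp], "go_cue": [pre + samp + delay],
        "response_off": [pre + samp + delay + resp],
        "lick_direction": ["left"], "correct": [True],
        "photoinhibition": [False], "free_water": [False],
        "early_lick": [False], "ignored": [False],
    })


class TestEpochAverage:
    def test_all_negative_rectifies_to_zero(self):
        tp = np.arange(0.16, 0.6, 0.0136)
        r2 = np.full((3, 2, len(tp)), -0.2)
        ev = predict.epoch_average(_result(r2, tp), _trial_table(), "response")
        assert np.all(ev == 0.0)

    def test_constant_half_passes_through(self):
        tp = np.arange(0.16, 0.6, 0.0136)
        r2 = np.full((3, 2, len(tp)), 0.5)
        ev = predict.epoch_average(_result(r2, tp), _trial_table(), "response")
        assert np.allclose(ev, 0.5)

    def test_edges_excluded(self):
        tp = np.array([0.05, 0.3, 0.7])  # first and last fall in the 150 ms edges
        r2 = np.zeros((1, 1, 3))
        r2[:, :, [0, 2]] = 1.0
        r2[:, :, 1] = 0.25
        ev = predict.epoch_average(_result(r2, tp), _trial_table(), "response")
        assert np.allclose(ev, 0.25)

    def test_short_epoch_rejected(self):
        tp = np.array([0.1])
        with pytest.raises(ValueError, match="shorter"):
            predict.epoch_average(_result(np.zeros((1, 1, 1)), tp),
                                  _trial_table(resp=0.25), "response")

    def test_low_ev_mask(self):
        assert list(predict.low_ev_mask(np.array([0.005, 0.02, 0.0]))) == \
            [True, False, True]


class TestReliableUnpredicted:
    def test_planted_cue_neurons_flagged_movement_neurons_not(self):
        # cue-driven neurons: reliable sample-epoch burst, no video relation;
        # high-SNR movement neurons: predictable, so not flagged
        rng = np.random.default_rng(11)
        specs = synth.population(6, "cue_driven", rng, coupling_gain=12.0,
                                 baseline_rate=0.3)
        specs += synth.population(6, "movement_linear", rng, coupling_gain=6.0,
                                  baseline_rate=10.0)
        cfg = synth.desk_config(n_trials=120, seed=41, neuron_specs=tuple(specs))
        b = synth.simulate_session(cfg, render=False)
        rm = preprocess.bin_spikes(b.spike_times, b.trials)
        folds = preprocess.make_folds(b.trials, 5, seed=0)
        tp_idx, abs_times = predict.eval_times(rm, b.trials, epoch="response", step=6)
        mk = predict.marker_features(b.markers)
        X = np.stack([predict.build_features(mk, cfg.frame_period, abs_times[:, i])
                      for i in range(abs_times.shape[1])])
        res = predict.ridge_predict(X, rm.rates[:, :, tp_idx], folds,
                                    rm.timepoints[tp_idx])
        ev = predict.epoch_average(res, b.trials, "response")
        flags = predict.flag_reliable_unpredicted(ev, rm)
        assert flags[:6].mean() >= 0.5       # most cue neurons flagged
        assert not flags[6:].any()           # movement neurons never flagged

    def test_silent_neurons_not_flagged(self):
        rm = preprocess.RateMatrix(rates=np.zeros((1, 5, 20)),
                                   timepoints=np.arange(20) * 0.0034,
                                   bin_width=0.04, stride=0.0034)
        flags = predict.flag_reliable_unpredicted(np.array([0.0]), rm)
        assert not flags[0]


class TestRegionSummary:
    def test_identical_groups_not_significant(self):
        rng = np.random.default_rng(0)
        v = rng.normal(0.2, 0.05, 200)
        regions = np.repeat(["a", "b"], 100)
        _, tests = predict.region_summary(v, regions)
        assert not tests["significant"].iloc[0]

    def test_planted_offset_detected(self):
        rng = np.random.default_rng(6)
        v = np.concatenate([rng.normal(0.05, 0.03, 200), rng.normal(0.15, 0.03, 200)])
        regions = np.repeat(["a", "b"], 200)
        summary, tests = predict.region_summary(v, regions)
        assert tests["significant"].iloc[0]
        # agreement with a direct rank-sum computation
        direct = stats.mannwhitneyu(v[:200], v[200:], alternative="two-sided").pvalue
        assert np.isclose(tests["p_raw"].iloc[0], direct)

    def test_small_groups_omitted(self):
        v = np.concatenate([np.zeros(150), np.ones(50)])
        regions = np.repeat(["big", "small"], [150, 50])
        summary, _ = predict.region_summary(v, regions, min_neurons=100)
        assert list(summary["region"]) == ["big"]
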