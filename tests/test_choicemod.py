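"""Choice decoding, contingency splits, modulation labels, clustering score."""

import numpy as np
import pandas as pd
import pytest

from movenc import choicemod, preprocess, synth
from movenc.choicemod import ChoiceDecodeResult


def _trials(n, right_frac=0.5, seed=0):
    rng = np.random.default_rng(seed)
    right = rng.random(n) < right_frac
    go = 1.35 + 2.2 * np.arange(n)
    return pd.DataFrame({
        "trial_id": np.arange(n), "start_time": go - 1.35,
        "sample_on": go - 1.05, "sample_off": go - 0.6, "go_cue": go,
        "response_off": go + 0.75,
        "lick_direction": np.where(right, "right", "left"), "correct": True,
        "photoinhibition": False, "free_water": False, "early_lick": False,
        "ignored": False,
    })


class TestDecodeChoice:
    def test_uninformative_features_chance_auc(self):
        rng = np.random.default_rng(0)
        trials = _trials(120)
        feats = rng.normal(size=(120, 6))
        res = choicemod.decode_choice(feats, trials, seed=1)
        assert abs(res.auc - 0.5) < 0.15

    def test_separable_features_saturate(self):
        rng = np.random.default_rng(1)
        trials = _trials(100)
        y = (trials["lick_direction"] == "right").to_numpy().astype(float)
        feats = y[:, None] + 0.05 * rng.normal(size=(100, 3))
        res = choicemod.decode_choice(feats, trials, seed=1)
        assert res.auc > 0.95

    def test_single_class_rejected(self):
        trials = _trials(40, right_frac=1.0)
        with pytest.raises(ValueError):
            choicemod.decode_choice(np.zeros((40, 2)), trials)

    def test_each_trial_predicted_once(self):
        rng = np.random.default_rng(2)
        trials = _trials(80)
        res = choicemod.decode_choice(rng.normal(size=(80, 4)), trials, seed=0)
        assert np.isfinite(res.scores).all()
        assert len(res.predicted_right) == 80


class TestTimecourse:
    def test_choice_auc_rises_from_chance_to_saturation(self):
        # before the sample epoch there is no trial information; the planted
        # delay bias makes choice decodable; overt licking saturates it
        from movenc import predict, synth

        cfg = synth.desk_config(n_trials=120, seed=51, choice_bias=0.9,
                                move_consistency=1.0, error_rate=0.0)
        lat, trials, aux = synth.simulate_latents(cfg)
        markers = synth.emit_markers(lat, cfg, aux["tongue_visible"])
        series = predict.marker_features(markers, parts=("jaw",), mode="xy")
        res = choicemod.decode_choice_from_video(
            series, cfg.frame_period, trials, timecourse=True, timecourse_step=40,
            seed=0)
        tc = res.timecourse
        bounds = preprocess.epoch_bounds(trials)
        pre = tc[tc["time"] < bounds["sample"][0]]["auc"]
        delay = tc[(tc["time"] >= bounds["delay"][0]) & (tc["time"] < 0)]["auc"]
        resp = tc[tc["time"] >= 0.2]["auc"]
        assert abs(pre.mean() - 0.5) < 0.15
        assert delay.mean() > 0.7
        assert resp.mean() > 0.9


class TestContingencySplit:
    def _decode(self, predicted_right):
        n = len(predicted_right)
        return ChoiceDecodeResult(predictor="test", auc=1.0,
                                  scores=np.where(predicted_right, 1.0, -1.0),
                                  predicted_right=np.asarray(predicted_right),
                                  folds=np.zeros(n, int))

    def test_perfect_decoder_invalidates_session(self):
        trials = _trials(100)
        right = (trials["lick_direction"] == "right").to_numpy()
        split = choicemod.split_contingencies(self._decode(right), trials)
        assert split.counts["L-vR"] == 0 and split.counts["R-vL"] == 0
        assert not split.valid

    def test_nineteen_trials_in_group_excluded(self):
        trials = _trials(200, seed=3)
        right = (trials["lick_direction"] == "right").to_numpy()
        pred = right.copy()
        flip = np.flatnonzero(right)[:19]
        pred[flip] = False  # exactly 19 R-vL trials
        split = choicemod.split_contingencies(self._decode(pred), trials)
        assert split.counts["R-vL"] == 19
        assert not split.valid

    def test_consistency_sets_group_proportions(self):
        rng = np.random.default_rng(4)
        trials = _trials(400, seed=5)
        right = (trials["lick_direction"] == "right").to_numpy()
        agree = rng.random(400) < 0.7
        pred = np.where(agree, right, ~right)
        split = choicemod.split_contingencies(self._decode(pred), trials)
        match = split.counts["L-vL"] + split.counts["R-vR"]
        sd = np.sqrt(400 * 0.7 * 0.3)
        assert abs(match - 280) < 4 * sd
        assert split.valid


@pytest.fixture(scope="module")
def dissociation():
    from movenc import pipeline
    cfg = pipeline.dissociation_session(seed=21, n_choice=10, n_movement=10,
                                        n_untuned=4, n_trials=220)
    return pipeline.run_dissociation(cfg), cfg


class TestClassifyModulation:
    def test_planted_labels_recovered(self, dissociation):
        res, cfg = dissociation
        mod, tuning = res.modulation, res.tuning
        choice = tuning == "choice_only"
        movement = tuning == "movement_linear"
        untuned = tuning == "untuned"
        assert mod.choice_modulated[choice].mean() >= 0.8
        assert mod.movement_modulated[movement].mean() >= 0.8
        # cross-contamination stays low
        assert mod.movement_modulated[choice].mean() <= 0.2
        assert mod.choice_modulated[movement].mean() <= 0.2
        assert (mod.labels()[untuned] == "neither").mean() >= 0.75

    def test_untuned_aucs_near_chance(self, dissociation):
        res, _ = dissociation
        untuned = res.tuning == "untuned"
        assert np.nanmax(np.abs(res.modulation.choice_auc[untuned] - 0.5)) < 0.2

    def test_invalid_split_rejected(self):
        split = choicemod.ContingencySplit(group=np.array(["L-vL"] * 10),
                                           counts={g: 0 for g in
                                                   choicemod.CONTINGENCIES},
                                           valid=False)
        with pytest.raises(ValueError):
            choicemod.classify_modulation(np.zeros((1, 10)), split, _trials(10))


class TestResidualDecode:
    def test_zero_residual_gives_half(self):
        trials = _trials(60, seed=6)
        rates = np.full((2, 60), 7.0)
        auc, flag = choicemod.residual_choice_decode(rates, rates.copy(), trials)
        assert np.allclose(auc, 0.5)
        assert not flag.any()

    def test_missing_predictions_rejected(self):
        trials = _trials(20, seed=7)
        rates = np.ones((1, 20))
        preds = rates.copy()
        preds[0, 3] = np.nan
        with pytest.raises(ValueError, match="missing"):
            choicemod.residual_choice_decode(rates, preds, trials)

    def test_choice_signal_survives_residualization(self):
        rng = np.random.default_rng(8)
        trials = _trials(120, seed=8)
        y = (trials["lick_direction"] == "right").to_numpy().astype(float)
        rates = (8.0 + 4.0 * y + rng.normal(0, 1.0, 120))[None, :]
        preds = np.full_like(rates, rates.mean())  # prediction carries no choice
        auc, flag = choicemod.residual_choice_decode(rates, preds, trials, seed=0)
        assert auc[0] > 0.8 and flag[0]


class TestSessionCorrelation:
    def test_planted_coupling_detected(self):
        rng = np.random.default_rng(9)
        perf = rng.uniform(0.7, 0.95, 50)
        auc = 0.3 + 0.5 * perf + rng.normal(0, 0.03, 50)
        r, p = choicemod.session_behavior_correlation(auc, perf)
        assert r > 0.5 and p < 0.001

    def test_independent_draws_near_zero(self):
        rng = np.random.default_rng(10)
        r, p = choicemod.session_behavior_correlation(rng.random(80), rng.random(80))
        assert abs(r) < 0.25

    def test_degenerate_input_reported_as_nan(self):
        r, p = choicemod.session_behavior_correlation(np.full(12, 0.7),
                                                      np.linspace(0.6, 0.9, 12))
        assert np.isnan(r) and np.isnan(p)


class TestClusteringScore:
    def test_matches_direct_dispersion_ratio(self):
        # brute-force Calinski-Harabasz on 6 points in 2 planted clusters
        X = np.array([[0.0, 0.1], [0.1, 0.0], [0.05, 0.05],
                      [1.0, 1.1], [1.1, 1.0], [1.05, 1.05]])
        labels = np.array([0, 0, 0, 1, 1, 1])
        res = choicemod.clustering_score(X, labels, n_shuffles=10, seed=0)
        grand = X.mean(axis=0)
        ssb = sum(3 * np.sum((X[labels == g].mean(axis=0) - grand) ** 2)
                  for g in (0, 1))
        ssw = sum(np.sum((X[labels == g] - X[labels == g].mean(axis=0)) ** 2)
                  for g in (0, 1))
        expected = (ssb / 1) / (ssw / 4)
        assert np.isclose(res.score, expected, atol=1e-10)

    def test_tight_clusters_significant(self):
        rng = np.random.default_rng(11)
        X = np.concatenate([rng.normal(0, 0.01, (10, 2)),
                            rng.normal(5, 0.01, (10, 2))])
        labels = np.repeat([0, 1], 10)
        res = choicemod.clustering_score(X, labels, n_shuffles=500, seed=0)
        assert res.p_value < 0.005
        assert res.score > res.null_mean + 10 * res.null_sd

    def test_zero_within_spread_capped_and_significant(self):
        X = np.repeat([[0.0, 0.0], [1.0, 1.0]], 12, axis=0)
        res = choicemod.clustering_score(X, np.repeat([0, 1], 12), n_shuffles=1000,
                                         seed=0)
        assert res.score == 1e6
        assert res.p_value < 0.001

    def test_single_cluster_rejected(self):
        with pytest.raises(ValueError):
            choicemod.clustering_score(np.zeros((4, 2)), np.zeros(4))

    def test_marker_session_filter(self):
        df = pd.DataFrame({
            "animal": ["m1", "m1", "m2", "m2", "m3"],
            "jaw_auc": [0.7, 0.8, 0.5, 0.9, 0.95],
            "nose_auc": [0.5, 0.5, 0.5, 0.5, 0.5],
        })
        out = choicemod.filter_marker_sessions(df)
        assert set(out["animal"]) == {"m1"}  # m2 has one passing session, m3 one
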