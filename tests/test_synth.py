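"""Generator checks: determinism, conservation and planted-effect recovery
by direct (pipeline-free) oracles."""

import numpy as np
import pytest
from scipy import stats

from movenc import synth
from movenc.synth import BODY_PARTS, NeuronSpec, SimConfig


def _latent_only_config(**kw):
    return synth.desk_config(**kw)


class TestConfigValidation:
    def test_rejects_bad_durations(self):
        with pytest.raises(ValueError):
            SimConfig(epoch_durations=(0.0, 1.0, 1.0, 1.0))

    def test_rejects_bad_rates(self):
        with pytest.raises(ValueError):
            SimConfig(error_rate=0.6)
        with pytest.raises(ValueError):
            NeuronSpec(baseline_rate=-1.0)
        with pytest.raises(ValueError):
            NeuronSpec(tuning_type="nope")

    def test_epoch_boundaries_on_frame_grid(self):
        cfg = SimConfig(epoch_durations=(0.5, 1.15, 1.2, 1.5))
        for d in cfg.epoch_durations:
            assert abs(round(d / cfg.frame_period) * cfg.frame_period - d) < 1e-12

    def test_default_frame_geometry(self):
        cfg = SimConfig()
        assert cfg.frame_size == (120, 112)
        assert cfg.frame_period == 0.0034
        assert np.isclose(cfg.epoch_durations[2], 1.2, atol=cfg.frame_period)


class TestDeterminismAndConservation:
    def test_identical_config_bit_identical_outputs(self):
        cfg = _latent_only_config(n_trials=6, seed=123,
                                  neuron_specs=tuple(synth.population(2, "movement_linear")))
        a = synth.simulate_session(cfg)
        b = synth.simulate_session(cfg)
        assert np.array_equal(a.latents, b.latents)
        assert np.array_equal(a.frames, b.frames)
        assert a.markers.equals(b.markers)
        for sa, sb in zip(a.spike_times, b.spike_times):
            assert np.array_equal(sa, sb)

    def test_frame_count_matches_duration(self):
        cfg = _latent_only_config(n_trials=11, seed=1)
        lat, trials, aux = synth.simulate_latents(cfg)
        expected = int(round(cfg.n_trials * cfg.trial_period / cfg.frame_period))
        assert lat.shape == (expected, len(BODY_PARTS), 2)
        markers = synth.emit_markers(lat, cfg, aux["tongue_visible"])
        assert len(markers) == expected


class TestLatents:
    def test_no_bias_means_no_choice_separation(self):
        cfg = _latent_only_config(n_trials=200, seed=5, choice_bias=0.0)
        lat, trials, aux = synth.simulate_latents(cfg)
        jx = lat[:, BODY_PARTS.index("jaw"), 0]
        delay_mean = _epoch_mean_per_trial(jx, aux["in_delay"], aux["trial_index_of_frame"],
                                           cfg.n_trials)
        right = aux["choice"] > 0
        _, p = stats.ttest_ind(delay_mean[right], delay_mean[~right])
        assert p > 0.01

    def test_zero_lick_amplitude_response_is_flat(self):
        cfg = _latent_only_config(n_trials=40, seed=6, lick_amplitude=0.0)
        lat, trials, aux = synth.simulate_latents(cfg)
        jy = lat[:, BODY_PARTS.index("jaw"), 1]
        resp_sd = jy[aux["in_response"]].std()
        base_sd = jy[~aux["in_response"]].std()
        assert resp_sd < 1.5 * base_sd  # only the OU wander remains

    def test_planted_bias_recovered_by_averaging(self):
        # sample-mean oracle: separation of delay-epoch means across the two
        # movement directions equals twice the planted bias
        bias = 3 * 0.3
        cfg = _latent_only_config(n_trials=200, seed=8, choice_bias=bias,
                                  move_consistency=1.0, marker_noise_sd=0.3,
                                  error_rate=0.0)
        lat, trials, aux = synth.simulate_latents(cfg)
        jx = lat[:, BODY_PARTS.index("jaw"), 0]
        delay_mean = _epoch_mean_per_trial(jx, aux["in_delay"], aux["trial_index_of_frame"],
                                           cfg.n_trials)
        right = aux["move_dir"] > 0
        separation = delay_mean[right].mean() - delay_mean[~right].mean()
        assert abs(separation - 2 * bias) < 0.1 * (2 * bias)


def _epoch_mean_per_trial(x, mask, trial_idx, n_trials):
    out = np.empty(n_trials)
    for t in range(n_trials):
        out[t] = x[mask & (trial_idx == t)].mean()
    return out


class TestRendering:
    def test_identical_latents_identical_frames(self):
        cfg = _latent_only_config(n_trials=2, seed=3, pixel_noise_sd=0.0)
        lat = np.tile(np.array([[8.0, 8.0], [4.0, 4.0], [8.0, 12.0], [3.0, 12.0]]),
                      (2, 1, 1))
        frames, info = synth.render_frames(lat, cfg)
        assert np.array_equal(frames[0], frames[1])
        assert info["n_clipped"] == 0

    def test_blob_shift_moves_image_centroid(self):
        # centroid oracle: with no background or noise, shifting every blob
        # center by k pixels shifts the intensity centroid by k pixels
        cfg = _latent_only_config(n_trials=2, seed=3, pixel_noise_sd=0.0,
                                  background_amplitude=0.0, blob_sigma=1.2)
        base = np.array([[7.0, 7.0], [5.0, 5.0], [7.0, 9.0], [5.0, 9.0]])
        k = 2.0
        frames, _ = synth.render_frames(np.stack([base, base + k]), cfg,
                                        tongue_visible=np.array([True, True]))
        yy, xx = np.mgrid[0:16, 0:16]

        def centroid(f):
            return np.array([(f * xx).sum(), (f * yy).sum()]) / f.sum()

        shift = centroid(frames[1]) - centroid(frames[0])
        assert np.allclose(shift, [k, k], atol=0.1)

    def test_default_frame_dimensions(self):
        cfg = SimConfig()
        lat = np.tile(np.array([[56.0, 78.0], [56.0, 30.0], [56.0, 102.0], [25.0, 96.0]]),
                      (2, 1, 1))
        frames, _ = synth.render_frames(lat, cfg)
        assert frames.shape[1:] == (120, 112)

    def test_out_of_frame_latents_clipped_and_counted(self):
        cfg = _latent_only_config(n_trials=2, seed=3)
        lat = np.tile(np.array([[99.0, 8.0], [4.0, 4.0], [8.0, 12.0], [3.0, 12.0]]),
                      (2, 1, 1))
        _, info = synth.render_frames(lat, cfg)
        assert info["n_clipped"] == 2


class TestMarkers:
    def test_noiseless_markers_equal_latents(self):
        cfg = _latent_only_config(n_trials=10, seed=4, marker_noise_sd=0.0,
                                  outlier_rate=0.0)
        lat, trials, aux = synth.simulate_latents(cfg)
        mk = synth.emit_markers(lat, cfg, aux["tongue_visible"])
        for part in ("jaw", "nose", "paw"):
            p = BODY_PARTS.index(part)
            assert np.allclose(mk[(part, "x")], lat[:, p, 0])
            assert np.allclose(mk[(part, "y")], lat[:, p, 1])
        vis = aux["tongue_visible"]
        t = BODY_PARTS.index("tongue")
        assert np.allclose(mk[("tongue", "x")][vis], lat[vis, t, 0])

    def test_outlier_count_matches_rate(self):
        cfg = _latent_only_config(n_trials=40, seed=9, marker_noise_sd=0.0,
                                  outlier_rate=0.01)
        lat, trials, aux = synth.simulate_latents(cfg)
        mk = synth.emit_markers(lat, cfg, aux["tongue_visible"])
        n = len(mk)
        jaw = mk["jaw"][["x", "y"]].to_numpy()
        planted = np.abs(jaw - lat[:, BODY_PARTS.index("jaw"), :]).max(axis=1) > 1e-9
        expect = n * 0.01
        sd = np.sqrt(n * 0.01 * 0.99)
        assert abs(planted.sum() - expect) < 4 * sd

    def test_occluded_tongue_flagged_outside_response(self):
        cfg = _latent_only_config(n_trials=10, seed=4)
        lat, trials, aux = synth.simulate_latents(cfg)
        mk = synth.emit_markers(lat, cfg, aux["tongue_visible"])
        lik = mk[("tongue", "likelihood")].to_numpy()
        assert (lik[~aux["tongue_visible"]] < 0.5).all()
        assert (lik[aux["tongue_visible"]] > 0.5).all()
        assert (~aux["tongue_visible"][~aux["in_response"]]).all()


class TestSpikes:
    def test_untuned_rate_matches_baseline(self):
        cfg = _latent_only_config(
            n_trials=140, seed=12,
            neuron_specs=(NeuronSpec(tuning_type="untuned", baseline_rate=10.0),),
        )
        b = synth.simulate_session(cfg, render=False)
        duration = cfg.n_trials * cfg.trial_period
        rate = len(b.spike_times[0]) / duration
        sd = np.sqrt(10.0 / duration)
        assert abs(rate - 10.0) < 4 * sd

    def test_planted_lag_peaks_cross_correlation(self):
        # cross-correlation oracle on the noiseless rate vs the latent
        lag = 0.0204
        cfg = _latent_only_config(
            n_trials=30, seed=13,
            neuron_specs=(NeuronSpec(tuning_type="movement_linear", coupling_gain=4.0,
                                     baseline_rate=20.0, true_lag=lag),),
        )
        b = synth.simulate_session(cfg, render=False)
        rate = b.truth.rates[0].astype(float)
        jy = b.latents[:, BODY_PARTS.index("jaw"), 1]
        shifts = np.arange(-12, 13)
        corr = [np.corrcoef(rate[12:-12], np.roll(jy, -s)[12:-12])[0, 1] for s in shifts]
        best = shifts[int(np.argmax(corr))]
        assert best == round(lag / cfg.frame_period)

    def test_choice_weight_sets_delay_rate_difference(self):
        cfg = _latent_only_config(
            n_trials=60, seed=14, error_rate=0.0,
            neuron_specs=(NeuronSpec(tuning_type="choice_only", choice_weight=5.0,
                                     baseline_rate=8.0),),
        )
        lat, trials, aux = synth.simulate_latents(cfg)
        aux["correct"] = trials["correct"].to_numpy()
        spikes, truth = synth.emit_spikes(lat, cfg.neuron_specs, cfg, aux)
        rate = truth.rates[0]
        right = aux["choice"][aux["trial_index_of_frame"]] > 0
        delay = aux["in_delay"]
        diff = rate[delay & right].mean() - rate[delay & ~right].mean()
        assert np.isclose(diff, 5.0, atol=1e-6)

    def test_ols_recovers_coupling_gain(self):
        # planted-effect recoverability: OLS of per-frame spike counts on the
        # lagged latent recovers the gain within 10% (high baseline avoids
        # rectification)
        lag = -0.0136
        cfg = _latent_only_config(
            n_trials=150, seed=15,
            neuron_specs=(NeuronSpec(tuning_type="movement_linear", coupling_gain=4.0,
                                     baseline_rate=25.0, true_lag=lag),),
        )
        b = synth.simulate_session(cfg, render=False)
        edges = np.arange(len(b.latents) + 1) * cfg.frame_period
        counts, _ = np.histogram(b.spike_times[0], bins=edges)
        y = counts / cfg.frame_period
        s = b.latents[:, BODY_PARTS.index("jaw"), 1] - cfg.base_positions()["jaw"][1]
        shift = round(lag / cfg.frame_period)
        s_lag = np.roll(s, -shift)
        sl = slice(10, -10)
        slope = np.polyfit(s_lag[sl], y[sl], 1)[0]
        assert abs(slope - 4.0) < 0.4
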