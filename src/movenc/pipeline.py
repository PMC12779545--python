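"""Session-level workflows composing the analysis stages.

These functions wire the synthetic generator, preprocessing, embedding,
prediction, offset and choice analyses into the study designs the package
is validated on: the three-method expressiveness comparison, the planted-
lag offset recovery, the peak-validity filter characterization, and the
four-contingency choice/movement dissociation. The examples/ scripts and
the acceptance machinery call these rather than re-assembling the stages.

Problem sizes follow the desk-scale profile of
:func:`movenc.synth.desk_config` (16 x 16 frames, shortened epochs).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import choicemod, embed, offsets, predict, preprocess, synth


def encode_needed_frames(frames: np.ndarray, model, needed: np.ndarray,
                         ) -> np.ndarray:
    """Embedding series with only the ``needed`` frame indices encoded.

    Avoids encoding every frame of a long session when the analysis touches
    a known subset; unused rows are zero.
    """
    needed = np.unique(needed)
    series = np.zeros((len(frames), model.embed_dim), dtype=np.float32)
    series[needed] = embed.encode(frames[needed], model)
    return series


def window_frame_indices(abs_times: np.ndarray, frame_period: float, n_frames: int,
                         tau_pad: float = 0.0) -> np.ndarray:
    """All frame indices touched by 5-frame windows at the given times
    (optionally padded by +-tau_pad for offset scans)."""
    pad = int(np.ceil(tau_pad / frame_period))
    center = np.rint(abs_times / frame_period).astype(int).ravel()
    offs = np.arange(-(2 + pad), 3 + pad)
    return np.clip(center[:, None] + offs, 0, n_frames - 1).ravel()


# ---------------------------------------------------------------------------
# expressiveness comparison (marker vs embedding vs end-to-end)
# ---------------------------------------------------------------------------

@dataclass
class ExpressivenessResult:
    ev_marker: np.ndarray
    ev_embedding: np.ndarray
    ev_end2end: np.ndarray
    nonlinear: np.ndarray               # mask of nonlinearly tuned neurons
    linear: np.ndarray

    def mean_evs(self, mask: np.ndarray) -> tuple[float, float, float]:
        return (float(self.ev_marker[mask].mean()),
                float(self.ev_embedding[mask].mean()),
                float(self.ev_end2end[mask].mean()))


def expressiveness_session(seed: int, n_trials: int = 200, n_linear: int = 30,
                           n_nonlinear: int = 30) -> synth.SimConfig:
    """Study conditions for the model-expressiveness comparison.

    Half the population is linearly coupled to jaw height; the other half
    responds to the squared jaw excursion, which a linear readout of marker
    positions cannot represent but pixels (and a nonlinear code) can.
    """
    rng = np.random.default_rng(seed)
    specs = synth.population(n_linear, "movement_linear", rng, coupling_gain=6.0,
                             baseline_rate=10.0)
    specs += synth.population(n_nonlinear, "movement_nonlinear", rng,
                              coupling_gain=8.0, baseline_rate=5.0,
                              nonlinearity="square")
    return synth.desk_config(n_trials=n_trials, seed=seed, neuron_specs=tuple(specs))


def run_expressiveness_comparison(seed: int, n_trials: int = 200,
                                  ae_epochs: int = 25, ae_frames: int = 3000,
                                  e2e_steps: int = 250, test_size: int = 64,
                                  eval_step: int = 4) -> ExpressivenessResult:
    """Three-method comparison on one synthetic session.

    Follows the method-comparison design: a single held-out test split
    balanced on direction x correctness, response-epoch epoch-averaged EV,
    identical splits across methods.
    """
    cfg = expressiveness_session(seed, n_trials=n_trials)
    bundle = synth.simulate_session(cfg)
    trials = preprocess.select_trials(bundle.trials, "encoding")
    rm = preprocess.bin_spikes(bundle.spike_times, trials)
    test = preprocess.make_split(trials, test_size=test_size, seed=seed)
    folds = test.astype(int)
    tp_idx, abs_times = predict.eval_times(rm, trials, epoch="response", step=eval_step)
    rates = rm.rates[:, :, tp_idx]
    timepoints = rm.timepoints[tp_idx]

    # marker ridge
    mk = predict.marker_features(bundle.markers)
    X = np.stack([predict.build_features(mk, cfg.frame_period, abs_times[:, i])
                  for i in range(abs_times.shape[1])])
    res_marker = predict.ridge_predict(X, rates, folds, timepoints,
                                       eval_fold_ids=np.array([1]), method="marker")

    # embedding ridge
    model, _ = embed.train_autoencoder(bundle.frames[::8][:ae_frames],
                                       epochs=ae_epochs, lr=5e-3, seed=seed)
    needed = window_frame_indices(abs_times, cfg.frame_period, len(bundle.frames))
    series = encode_needed_frames(bundle.frames, model, needed)
    Xe = np.stack([predict.build_features(series, cfg.frame_period, abs_times[:, i])
                   for i in range(abs_times.shape[1])])
    res_embed = predict.ridge_predict(Xe, rates, folds, timepoints,
                                      eval_fold_ids=np.array([1]), method="embedding")

    # end-to-end CNN
    e2e_cfg = predict.End2EndConfig(steps=e2e_steps, seed=seed)
    res_e2e = predict.end2end_predict(bundle.frames, cfg.frame_period, rates,
                                      abs_times, folds, timepoints, e2e_cfg,
                                      eval_fold_ids=np.array([1]))

    tuning = np.array([s.tuning_type for s in cfg.neuron_specs])
    return ExpressivenessResult(
        ev_marker=predict.epoch_average(res_marker, trials, "response"),
        ev_embedding=predict.epoch_average(res_embed, trials, "response"),
        ev_end2end=predict.epoch_average(res_e2e, trials, "response"),
        nonlinear=tuning == "movement_nonlinear",
        linear=tuning == "movement_linear",
    )


# ---------------------------------------------------------------------------
# temporal-offset studies
# ---------------------------------------------------------------------------

def lag_session(seed: int, lags_ms: tuple[float, ...] = (-34.0, -17.0, 0.0, 17.0, 34.0),
                n_neurons: int = 100, n_trials: int = 200,
                tuning_type: str = "movement_linear") -> synth.SimConfig:
    """Population with planted per-neuron lags cycling through ``lags_ms``."""
    rng = np.random.default_rng(seed)
    specs = []
    for i in range(n_neurons):
        xyz = tuple(rng.uniform(0.0, 2000.0, 3))
        specs.append(synth.NeuronSpec(tuning_type=tuning_type, coupling_gain=6.0,
                                      baseline_rate=10.0,
                                      true_lag=lags_ms[i % len(lags_ms)] / 1000.0,
                                      ccf_xyz=xyz))
    return synth.desk_config(n_trials=n_trials, seed=seed, neuron_specs=tuple(specs),
                             store_truth_rates=False)


def run_offset_scan(config: synth.SimConfig, use_embedding: bool = True,
                    ae_epochs: int = 20, ae_frames: int = 2500, eval_step: int = 4,
                    k_folds: int = 5, seed: int | None = None,
                    ) -> tuple[offsets.OffsetProfiles, synth.SessionBundle]:
    """Offset scan over a synthetic session, embedding- or marker-based."""
    seed = config.seed if seed is None else seed
    bundle = synth.simulate_session(config, render=use_embedding)
    trials = preprocess.select_trials(bundle.trials, "encoding")
    rm = preprocess.bin_spikes(bundle.spike_times, trials)
    folds = preprocess.make_folds(trials, k_folds, seed=seed)
    tp_idx, abs_times = predict.eval_times(rm, trials, epoch="response", step=eval_step)
    if use_embedding:
        model, _ = embed.train_autoencoder(bundle.frames[::8][:ae_frames],
                                           epochs=ae_epochs, lr=5e-3, seed=seed)
        needed = window_frame_indices(abs_times, config.frame_period,
                                      len(bundle.frames), tau_pad=offsets.TAU_MAX)
        series = encode_needed_frames(bundle.frames, model, needed)
    else:
        series = predict.marker_features(bundle.markers)
    profiles = offsets.offset_scan(series, config.frame_period,
                                   rm.rates[:, :, tp_idx], abs_times, folds,
                                   rm.timepoints[tp_idx], trials, seed=seed)
    return offsets.offset_significance(profiles), bundle


# ---------------------------------------------------------------------------
# choice / uninstructed-movement dissociation
# ---------------------------------------------------------------------------

@dataclass
class DissociationResult:
    modulation: choicemod.ModulationResult
    split: choicemod.ContingencySplit
    decode: choicemod.ChoiceDecodeResult
    tuning: np.ndarray
    residual_auc: np.ndarray | None = None


def dissociation_session(seed: int, n_choice: int = 40, n_movement: int = 40,
                         n_untuned: int = 10, n_trials: int = 260,
                         choice_weight: float = 5.0, movement_gain: float = 3.0,
                         choice_bias: float = 0.9, move_consistency: float = 0.7,
                         ) -> synth.SimConfig:
    """Study conditions for the four-contingency dissociation.

    Choice-only neurons carry an additive delay-epoch rate offset by choice;
    movement neurons couple to the laterally biased jaw position (the
    uninstructed movement); the bias direction matches the choice on a
    ``move_consistency`` fraction of trials so that mismatch trials exist.
    """
    rng = np.random.default_rng(seed)
    specs = synth.population(n_choice, "choice_only", rng, choice_weight=choice_weight,
                             baseline_rate=8.0)
    specs += synth.population(n_movement, "movement_linear", rng,
                              coupling_gain=movement_gain, coupling_axis=0,
                              baseline_rate=8.0)
    specs += synth.population(n_untuned, "untuned", rng, baseline_rate=8.0)
    return synth.desk_config(n_trials=n_trials, seed=seed, neuron_specs=tuple(specs),
                             choice_bias=choice_bias, move_consistency=move_consistency,
                             error_rate=0.05)


def run_dissociation(config: synth.SimConfig, compute_residual: bool = False,
                     ae_epochs: int = 20, ae_frames: int = 2500, seed: int | None = None,
                     ) -> DissociationResult:
    """Video choice decode -> contingency split -> per-neuron modulation AUCs.

    The video decoder uses the jaw marker (where the synthetic bias lives);
    the optional residual analysis additionally trains the autoencoder and
    subtracts held-out embedding-ridge rate predictions before re-decoding
    choice.
    """
    seed = config.seed if seed is None else seed
    bundle = synth.simulate_session(config, render=compute_residual)
    correct = preprocess.select_trials(bundle.trials, mode="choice")
    decode = choicemod.decode_choice_from_marker(bundle.markers, "jaw",
                                                 config.frame_period, correct,
                                                 seed=seed)
    split = choicemod.split_contingencies(decode, correct)
    rm = preprocess.bin_spikes(bundle.spike_times, correct)
    bounds = preprocess.epoch_bounds(correct)
    dmask = (rm.timepoints >= bounds["delay"][0]) & (rm.timepoints < bounds["delay"][1])
    delay_rates = rm.rates[:, :, dmask].mean(axis=2)
    modulation = choicemod.classify_modulation(delay_rates, split, correct, seed=seed)
    tuning = np.array([s.tuning_type for s in config.neuron_specs])

    residual_auc = None
    if compute_residual:
        model, _ = embed.train_autoencoder(bundle.frames[::8][:ae_frames],
                                           epochs=ae_epochs, lr=5e-3, seed=seed)
        tp_idx, abs_times = predict.eval_times(rm, correct, epoch="delay", step=4,
                                               edge=0.0)
        needed = window_frame_indices(abs_times, config.frame_period,
                                      len(bundle.frames))
        series = encode_needed_frames(bundle.frames, model, needed)
        X = np.stack([predict.build_features(series, config.frame_period,
                                             abs_times[:, i])
                      for i in range(abs_times.shape[1])])
        folds = preprocess.make_folds(correct, 5, seed=seed)
        res = predict.ridge_predict(X, rm.rates[:, :, tp_idx], folds,
                                    rm.timepoints[tp_idx], store_predictions=True,
                                    method="embedding")
        delay_pred = res.predictions.mean(axis=2)
        residual_auc, _ = choicemod.residual_choice_decode(
            rm.rates[:, :, tp_idx].mean(axis=2), delay_pred, correct, seed=seed)
    return DissociationResult(modulation=modulation, split=split, decode=decode,
                              tuning=tuning, residual_auc=residual_auc)
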