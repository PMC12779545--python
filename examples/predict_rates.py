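"""Predict firing rates from tracked markers with per-timepoint ridge.

Bins spikes on the go-cue-aligned 40 ms / 3.4 ms grid, builds 5-frame
marker feature windows and reports cross-validated, epoch-averaged
explained variance (EV) per neuron.
"""

import numpy as np

from movenc import predict, preprocess, synth

rng = np.random.default_rng(0)
specs = synth.population(6, "movement_linear", rng, coupling_gain=6.0,
                         baseline_rate=10.0)
specs += synth.population(2, "untuned", rng, baseline_rate=8.0)
config = synth.desk_config(n_trials=120, seed=2, neuron_specs=tuple(specs))
bundle = synth.simulate_session(config, render=False)

trials = preprocess.select_trials(bundle.trials, "encoding")
rates = preprocess.bin_spikes(bundle.spike_times, trials)
folds = preprocess.make_folds(trials, k=5, seed=0)

tp_idx, abs_times = predict.eval_times(rates, trials, epoch="response", step=4)
markers = predict.marker_features(bundle.markers)  # 3 markers -> 15-d windows
X = np.stack([predict.build_features(markers, config.frame_period, abs_times[:, i])
              for i in range(abs_times.shape[1])])
result = predict.ridge_predict(X, rates.rates[:, :, tp_idx], folds,
                               rates.timepoints[tp_idx], method="marker")
ev = predict.epoch_average(result, trials, "response")

for i, spec in enumerate(specs):
    print(f"neuron {i:2d} ({spec.tuning_type:15s}) response-epoch EV = {ev[i]:.3f}")
print("\nEV is the held-out R^2 across trials, rectified at 0 and averaged")
print("over response-epoch timepoints: movement-coupled neurons score well")
print("above the untuned ones, which sit at the (near-zero) noise floor.")
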