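"""Predicting per-timepoint neural activity from video.

Three predictors of increasing expressiveness map behavior onto binned
firing rates:

* **marker** — ridge regression on tracked body-part positions,
* **embedding** — ridge regression on the 16-d autoencoder code,
* **end2end** — a convolutional network reading the frames directly.

For a target timepoint t the ridge predictors use the features of the five
frames at t - 6.8, t - 3.4, t, t + 3.4 and t + 6.8 ms concatenated into one
vector (80-d for the embedding, 15-d for three scalar markers). A separate
regression is fit per timepoint; performance is the cross-validated
coefficient of determination across held-out trials, rectified at zero and
averaged within an epoch (excluding 150 ms at each epoch edge).

The end-to-end network passes each of the five frames through a trunk of
three residual convolution blocks (16/32/32 channels, batch-normalized,
kernel-4 max pool after each block), concatenates the five 32-d outputs into
a 160-d vector and reads out all neurons with one linear layer.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from . import nn
from .linmod import LAMBDA_GRID, RidgePath, ridge_cv_lambda
from .preprocess import RateMatrix, epoch_bounds

WINDOW_OFFSETS = np.array([-2, -1, 0, 1, 2])  # frames; +-6.8 ms at 3.4 ms/frame
EDGE_EXCLUSION = 0.150  # s removed from each epoch edge before averaging


# ---------------------------------------------------------------------------
# features
# ---------------------------------------------------------------------------

def build_features(series: np.ndarray, frame_period: float, times: np.ndarray,
                   tau: float = 0.0) -> np.ndarray:
    """Five-frame feature windows for the given absolute times.

    ``series`` is (n_frames, d) per-frame features; the window for time t is
    the frames nearest t + tau - 6.8 ms ... t + tau + 6.8 ms concatenated in
    temporal order, giving shape ``times.shape + (5 d,)``. Windows reaching
    past the session bounds replicate the terminal frame.
    """
    series = np.asarray(series)
    if series.ndim == 1:
        series = series[:, None]
    if series.ndim != 2:
        raise ValueError("series must be (n_frames, d)")
    times = np.asarray(times, dtype=float)
    center = np.rint((times + tau) / frame_period).astype(int)
    idx = center[..., None] + WINDOW_OFFSETS
    idx = np.clip(idx, 0, len(series) - 1)
    feats = series[idx]  # times.shape + (5, d)
    return feats.reshape(times.shape + (5 * series.shape[1],))


def marker_features(markers: pd.DataFrame,
                    parts: tuple[str, ...] = ("jaw", "nose", "tongue"),
                    mode: str = "scalar", scalar_coord: str = "y") -> np.ndarray:
    """Per-frame marker feature matrix.

    ``scalar`` mode takes one coordinate per marker (height by default), so
    the 5-frame windows are 15-d (3 markers x 5 timepoints); ``xy`` keeps
    both coordinates (30-d windows).
    """
    if mode == "scalar":
        cols = [(p, scalar_coord) for p in parts]
    elif mode == "xy":
        cols = [(p, c) for p in parts for c in ("x", "y")]
    else:
        raise ValueError("mode must be 'scalar' or 'xy'")
    return markers[cols].to_numpy(dtype=np.float64)


def eval_times(rate_matrix: RateMatrix, trials: pd.DataFrame, epoch: str | None = None,
               step: int = 4, edge: float = EDGE_EXCLUSION,
               ) -> tuple[np.ndarray, np.ndarray]:
    """Evaluation grid: (timepoint indices, absolute times (n_trials, n_t)).

    Timepoints are subsampled every ``step`` strides; if ``epoch`` is given,
    only timepoints inside that epoch (with ``edge`` seconds trimmed at both
    ends) are kept.
    """
    tp = rate_matrix.timepoints
    keep = np.zeros(len(tp), dtype=bool)
    keep[::step] = True
    if epoch is not None:
        t0, t1 = epoch_bounds(trials)[epoch]
        if (t1 - t0) <= 2 * edge:
            raise ValueError(f"epoch {epoch!r} shorter than {2 * edge:.3f}s")
        keep &= (tp >= t0 + edge) & (tp < t1 - edge)
    idx = np.flatnonzero(keep)
    go = trials["go_cue"].to_numpy()
    abs_times = go[:, None] + tp[idx][None, :]
    return idx, abs_times


# ---------------------------------------------------------------------------
# scoring container
# ---------------------------------------------------------------------------

@dataclass
class PredictionResult:
    """Cross-validated per-timepoint R^2 (folds x neurons x timepoints)."""

    r2: np.ndarray
    timepoints: np.ndarray              # s relative to go cue
    folds: np.ndarray                   # fold id per trial
    method: str
    eval_fold_ids: np.ndarray
    lambdas: np.ndarray | None = None   # (folds, neurons) chosen regularization
    predictions: np.ndarray | None = None  # held-out (neurons, trials, timepoints)
    zero_variance: np.ndarray | None = None

    def rectified(self) -> np.ndarray:
        """Fold-mean rectified R^2 per neuron and timepoint."""
        return np.maximum(self.r2, 0.0).mean(axis=0)


def _score_fold(Y_test: np.ndarray, pred: np.ndarray, y_train_mean: np.ndarray,
                ) -> tuple[np.ndarray, np.ndarray]:
    """Per-neuron R^2 across held-out trials at one timepoint.

    The total sum of squares is taken around the training-set mean so that
    no test-set statistic leaks into the score; zero-variance targets are
    recorded as 0 and flagged.
    """
    sse = ((Y_test - pred) ** 2).sum(axis=0)
    sst = ((Y_test - y_train_mean) ** 2).sum(axis=0)
    zero = sst <= 0
    with np.errstate(divide="ignore", invalid="ignore"):
        r2 = 1.0 - sse / sst
    r2[zero] = 0.0
    return r2, zero


# ---------------------------------------------------------------------------
# ridge predictor
# ---------------------------------------------------------------------------

def ridge_predict(X_by_time: np.ndarray, rates: np.ndarray, folds: np.ndarray,
                  timepoints: np.ndarray, lam_grid: np.ndarray = LAMBDA_GRID,
                  fixed_lams: np.ndarray | None = None, inner_k: int = 5, seed: int = 0,
                  eval_fold_ids: np.ndarray | None = None, method: str = "ridge",
                  store_predictions: bool = False) -> PredictionResult:
    """Per-timepoint ridge prediction with nested cross-validation.

    ``X_by_time`` is (n_timepoints, n_trials, p) and ``rates`` is
    (n_neurons, n_trials, n_timepoints). For every timepoint and outer fold,
    the regularization is chosen per neuron by ``inner_k``-fold CV on the
    training trials only (unless ``fixed_lams`` (folds x neurons) is given),
    and held-out trials are scored by R^2 around the training-set mean.
    """
    n_t, n_trials, _ = X_by_time.shape
    n_neurons = rates.shape[0]
    folds = np.asarray(folds)
    fold_ids = np.unique(folds) if eval_fold_ids is None else np.asarray(eval_fold_ids)
    if eval_fold_ids is None and len(fold_ids) < 2:
        raise ValueError("need at least 2 folds")

    r2 = np.empty((len(fold_ids), n_neurons, n_t))
    zero = np.zeros((n_neurons, n_t), dtype=bool)
    lam_used = np.empty((len(fold_ids), n_neurons))
    preds = np.full((n_neurons, n_trials, n_t), np.nan) if store_predictions else None

    for fi, f in enumerate(fold_ids):
        test = folds == f
        train = ~test
        for ti in range(n_t):
            X = X_by_time[ti]
            Y = rates[:, :, ti].T  # (trials, neurons)
            if fixed_lams is not None:
                lams = np.atleast_1d(fixed_lams[fi])
            else:
                lams = np.atleast_1d(
                    ridge_cv_lambda(X[train], Y[train], lam_grid, k=inner_k,
                                    seed=seed + 31 * ti + int(f))
                )
            path = RidgePath(X[train], Y[train])
            W, b = path.coef_per_target(lams)
            pred = X[test] @ W + b
            r2[fi, :, ti], z = _score_fold(Y[test], pred, Y[train].mean(axis=0))
            zero[:, ti] |= z
            if ti == 0:
                lam_used[fi] = lams
            if preds is not None:
                preds[:, test, ti] = pred.T
    return PredictionResult(r2=r2, timepoints=timepoints, folds=folds, method=method,
                            eval_fold_ids=fold_ids, lambdas=lam_used,
                            predictions=preds, zero_variance=zero)


# ---------------------------------------------------------------------------
# end-to-end CNN predictor
# ---------------------------------------------------------------------------

def _bn_conv(in_ch: int, out_ch: int, kernel: int, rng) -> list[nn.Layer]:
    return [nn.Conv2d(in_ch, out_ch, kernel, rng), nn.BatchNorm2d(out_ch), nn.ReLU()]


def _e2e_block(in_ch: int, out_ch: int, rng, pool: int = 4) -> list[nn.Layer]:
    body: list[nn.Layer] = []
    body += _bn_conv(in_ch, out_ch, 1, rng)
    for _ in range(3):
        body += _bn_conv(out_ch, out_ch, 3, rng)
    skip = nn.Conv2d(in_ch, out_ch, 1, rng) if in_ch != out_ch else None
    return [nn.Residual(nn.Sequential(*body), skip), nn.MaxPool2d(pool), nn.ReLU()]


def _e2e_pools(frame_size: tuple[int, int]) -> tuple[int, int, int]:
    """Per-block pool kernels: 4 at the reference geometry, 2 on small maps.

    The trunk always ends at 1 x 1 spatially (32 features per frame), so the
    concatenated 5-frame pre-output length is 160 for any frame size; small
    frames just keep spatial detail deeper into the stack.
    """
    d = min(frame_size)
    pools = []
    for _ in range(3):
        k = 4 if d >= 7 else 2
        pools.append(k)
        d = max(d // k, 1)
    return tuple(pools)


class End2EndNet:
    """Frames-in, all-neurons-out regression network.

    Each frame of the 5-frame window passes through the convolutional trunk
    (three residual blocks; 16, 32, 32 output channels; batch normalization
    with epsilon 1e-5 and momentum 0.1; kernel-4 stride-4 max pool after each
    block) yielding 32 features; the five outputs are concatenated into the
    160-d pre-output vector feeding one linear layer sized to the session's
    neuron count.
    """

    PRE_OUTPUT = 160

    def __init__(self, n_neurons: int, seed: int = 0,
                 frame_size: tuple[int, int] = (120, 112)):
        rng = np.random.default_rng(seed)
        p1, p2, p3 = _e2e_pools(frame_size)
        self.trunk = nn.Sequential(
            *_e2e_block(1, 16, rng, p1), *_e2e_block(16, 32, rng, p2),
            *_e2e_block(32, 32, rng, p3),
            nn.Flatten(),
        )
        self.head = nn.Linear(self.PRE_OUTPUT, n_neurons, rng)
        self.n_neurons = n_neurons

    def params(self):
        return self.trunk.params() + self.head.params()

    def set_train(self, mode: bool):
        self.trunk.set_train(mode)
        self.head.set_train(mode)

    def trunk_dim(self, frame_size: tuple[int, int]) -> int:
        """Flattened trunk output length for a single frame of this size."""
        h, w = frame_size
        self.trunk.set_train(False)
        return int(self.trunk.forward(np.zeros((1, 1, h, w), np.float32)).shape[1])

    def forward(self, windows: np.ndarray) -> np.ndarray:
        """(N, 5, H, W) frame windows -> (N, n_neurons) predicted rates."""
        n, k, h, w = windows.shape
        feats = self.trunk.forward(windows.reshape(n * k, 1, h, w))
        self._shape = (n, k * feats.shape[1])
        return self.head.forward(feats.reshape(self._shape))

    def backward(self, grad: np.ndarray) -> None:
        g = self.head.backward(grad)
        n, d = self._shape
        self.trunk.backward(g.reshape(n * 5, d // 5))


@dataclass
class End2EndConfig:
    steps: int = 200
    batch_size: int = 24
    lr: float = 2e-3
    val_fraction: float = 0.15
    eval_every: int = 25
    seed: int = 0


def end2end_predict(frames: np.ndarray, frame_period: float, rates: np.ndarray,
                    abs_times: np.ndarray, folds: np.ndarray, timepoints: np.ndarray,
                    config: End2EndConfig | None = None,
                    eval_fold_ids: np.ndarray | None = None) -> PredictionResult:
    """Train the end-to-end network per fold and score like the ridge path.

    ``abs_times`` is (n_trials, n_timepoints) absolute times of the targets;
    the network is trained on (trial, timepoint) samples from the training
    trials (an inner validation split of training trials selects the best
    checkpoint) and scored on held-out trials with the same R^2 convention.
    """
    cfg = config or End2EndConfig()
    frames = np.asarray(frames, dtype=np.float32)
    n_neurons, n_trials, n_t = rates.shape
    folds = np.asarray(folds)
    fold_ids = np.unique(folds) if eval_fold_ids is None else np.asarray(eval_fold_ids)
    center = np.rint(abs_times / frame_period).astype(int)
    win_idx = np.clip(center[..., None] + WINDOW_OFFSETS, 0, len(frames) - 1)

    r2 = np.empty((len(fold_ids), n_neurons, n_t))
    rng_master = np.random.default_rng(cfg.seed)
    for fi, f in enumerate(fold_ids):
        test = folds == f
        train_trials = np.flatnonzero(~test)
        rng = np.random.default_rng(int(rng_master.integers(2**31)))
        n_val = max(int(round(cfg.val_fraction * len(train_trials))), 1)
        perm = rng.permutation(train_trials)
        val_trials, fit_trials = perm[:n_val], perm[n_val:]

        # normalize targets for stable optimization; undone at prediction
        y_mean = rates[:, ~test, :].mean(axis=(1, 2))
        y_sd = np.maximum(rates[:, ~test, :].std(axis=(1, 2)), 1e-3)

        net = End2EndNet(n_neurons, seed=int(rng.integers(2**31)),
                         frame_size=frames.shape[1:])
        opt = nn.Adam(net.params(), lr=cfg.lr)
        pairs = np.stack(np.meshgrid(fit_trials, np.arange(n_t), indexing="ij"),
                         axis=-1).reshape(-1, 2)
        best: tuple[float, list | None] = (np.inf, None)
        net.set_train(True)
        for step in range(cfg.steps):
            take = pairs[rng.integers(len(pairs), size=cfg.batch_size)]
            windows = frames[win_idx[take[:, 0], take[:, 1]]]
            target = (rates[:, take[:, 0], take[:, 1]].T - y_mean) / y_sd
            opt.zero_grad()
            pred = net.forward(windows)
            loss, grad = nn.mse_loss(pred, target)
            if not np.isfinite(loss):
                raise RuntimeError(f"end-to-end training diverged at step {step}")
            net.backward(grad)
            opt.step()
            if (step + 1) % cfg.eval_every == 0 or step == cfg.steps - 1:
                val_loss = _e2e_eval_loss(net, frames, win_idx, rates, val_trials,
                                          y_mean, y_sd, rng)
                if val_loss < best[0]:
                    best = (val_loss, [p.v.copy() for p in net.params()])
                net.set_train(True)
        if best[1] is not None:
            for p, v in zip(net.params(), best[1]):
                p.v[...] = v

        net.set_train(False)
        pred_test = _e2e_forward_all(net, frames, win_idx, np.flatnonzero(test))
        pred_test = pred_test * y_sd[None, None, :] + y_mean[None, None, :]
        for ti in range(n_t):
            Y = rates[:, :, ti].T
            r2[fi, :, ti], _ = _score_fold(Y[test], pred_test[:, ti, :],
                                           Y[~test].mean(axis=0))
    return PredictionResult(r2=r2, timepoints=timepoints, folds=folds,
                            method="end2end", eval_fold_ids=fold_ids)


def _e2e_eval_loss(net, frames, win_idx, rates, trials_idx, y_mean, y_sd, rng,
                   max_samples: int = 256) -> float:
    net.set_train(False)
    n_t = win_idx.shape[1]
    pairs = np.stack(np.meshgrid(trials_idx, np.arange(n_t), indexing="ij"),
                     axis=-1).reshape(-1, 2)
    if len(pairs) > max_samples:
        pairs = pairs[rng.choice(len(pairs), max_samples, replace=False)]
    pred = net.forward(frames[win_idx[pairs[:, 0], pairs[:, 1]]])
    target = (rates[:, pairs[:, 0], pairs[:, 1]].T - y_mean) / y_sd
    return float(np.mean((pred - target) ** 2))


def _e2e_forward_all(net, frames, win_idx, trials_idx, batch: int = 64) -> np.ndarray:
    """Predictions (n_sel_trials, n_t, n_neurons) in normalized units."""
    n_t = win_idx.shape[1]
    pairs = np.stack(np.meshgrid(trials_idx, np.arange(n_t), indexing="ij"),
                     axis=-1).reshape(-1, 2)
    out = np.empty((len(pairs), net.n_neurons), dtype=np.float64)
    for s in range(0, len(pairs), batch):
        chunk = pairs[s:s + batch]
        out[s:s + batch] = net.forward(frames[win_idx[chunk[:, 0], chunk[:, 1]]])
    return out.reshape(len(trials_idx), n_t, net.n_neurons)


# ---------------------------------------------------------------------------
# epoch-averaged explained variance and derived flags
# ---------------------------------------------------------------------------

def epoch_average(result: PredictionResult, trials: pd.DataFrame, epoch: str,
                  edge: float = EDGE_EXCLUSION) -> np.ndarray:
    """Per-neuron epoch-averaged EV: rectify, average folds, average timepoints.

    Negative per-fold R^2 values are set to zero before averaging; the first
    and last ``edge`` seconds of the epoch are excluded.
    """
    t0, t1 = epoch_bounds(trials)[epoch]
    if (t1 - t0) <= 2 * edge:
        raise ValueError(f"epoch {epoch!r} shorter than {2 * edge:.3f}s")
    keep = (result.timepoints >= t0 + edge) & (result.timepoints < t1 - edge)
    if not keep.any():
        raise ValueError(f"no evaluated timepoints inside epoch {epoch!r}")
    return result.rectified()[:, keep].mean(axis=1)


def low_ev_mask(ev: np.ndarray, threshold: float = 0.01) -> np.ndarray:
    """Neurons whose EV is too low to enter downstream population averages."""
    return np.asarray(ev) < threshold


def flag_reliable_unpredicted(response_ev: np.ndarray, rate_matrix: RateMatrix,
                              ev_thresh: float = 0.1, corr_thresh: float = 0.4,
                              var_thresh: float = 100.0) -> np.ndarray:
    """Reliable firing patterns that video nonetheless fails to predict.

    Flags neurons with response-epoch embedding EV below ``ev_thresh`` whose
    single-trial rate traces correlate with the trial-averaged pattern above
    ``corr_thresh`` and whose mean instantaneous across-trial rate variance
    is below ``var_thresh`` (s^-2). Neurons with undefined correlation (for
    example silent ones) are never flagged.
    """
    rates = rate_matrix.rates
    n_neurons = rates.shape[0]
    psth = rates.mean(axis=1)
    mean_corr = np.full(n_neurons, np.nan)
    for i in range(n_neurons):
        p = psth[i] - psth[i].mean()
        denom_p = np.sqrt((p**2).sum())
        if denom_p == 0:
            continue
        x = rates[i] - rates[i].mean(axis=1, keepdims=True)
        denom_x = np.sqrt((x**2).sum(axis=1))
        ok = denom_x > 0
        if not ok.any():
            continue
        mean_corr[i] = np.mean((x[ok] @ p) / (denom_x[ok] * denom_p))
    trial_var = rates.var(axis=1).mean(axis=1)
    with np.errstate(invalid="ignore"):
        return ((np.asarray(response_ev) < ev_thresh)
                & (mean_corr > corr_thresh)
                & (trial_var < var_thresh))


def region_summary(values: np.ndarray, regions: np.ndarray, min_neurons: int = 0,
                   alpha: float = 0.05) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Group means +- SEM with pairwise rank-sum tests (Bonferroni corrected).

    Groups smaller than ``min_neurons`` are omitted. Returns (summary table,
    pairwise test table with corrected p-values and significance flags).
    """
    values = np.asarray(values, dtype=float)
    regions = np.asarray(regions)
    rows, groups = [], {}
    for r in pd.unique(regions):
        v = values[regions == r]
        if len(v) < max(min_neurons, 1):
            continue
        groups[r] = v
        rows.append({"region": r, "n": len(v), "mean": v.mean(),
                     "sem": v.std(ddof=1) / np.sqrt(len(v)) if len(v) > 1 else np.nan})
    summary = pd.DataFrame(rows)
    names = list(groups)
    pairs = [(a, b) for i, a in enumerate(names) for b in names[i + 1:]]
    tests = []
    for a, b in pairs:
        stat, p = stats.mannwhitneyu(groups[a], groups[b], alternative="two-sided")
        tests.append({"a": a, "b": b, "U": float(stat), "p_raw": float(p)})
    tests = pd.DataFrame(tests)
    if len(tests):
        tests["p_corrected"] = np.minimum(tests["p_raw"] * len(tests), 1.0)
        tests["significant"] = tests["p_corrected"] < alpha
    return summary, tests
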