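"""Temporal-offset analysis: does activity lead or follow movement?

The video feature window is shifted by an offset tau (multiples of 6.8 ms,
two frames) relative to the predicted activity timepoint and the embedding
ridge prediction is repeated for every shift in -102 ... +102 ms (31
values). tau > 0 means a window from the *future* predicts current
activity — the activity leads the movement (motor-like); tau < 0 means
activity follows movement (sensory-like, e.g. reafferent).

Each neuron's profile EV(tau) yields a best offset tau* (argmax of the
fold-mean epoch-averaged EV; ties resolved toward zero). Flat profiles are
discarded by a peak-validity rule (max >= 1.2 x mean over the 31 shifts,
and a minimum EV at the peak), and the per-fold best offsets support a
t-test of tau* against zero with Benjamini-Hochberg FDR control across
neurons.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .linmod import LAMBDA_GRID, RidgePath, ridge_cv_lambda
from .predict import build_features, epoch_bounds, ridge_predict
from .spatial import voxel_map  # noqa: F401  (re-exported for map building)

TAU_MAX = 0.102
TAU_STEP = 0.0068


def default_tau_grid() -> np.ndarray:
    """-102 ... +102 ms in 6.8 ms steps (31 offsets)."""
    k = int(round(TAU_MAX / TAU_STEP))
    return np.arange(-k, k + 1) * TAU_STEP


@dataclass
class OffsetProfiles:
    """Offset-scan results for a batch of neurons."""

    taus: np.ndarray                  # (n_tau,)
    ev: np.ndarray                    # (n_folds, n_tau, n_neurons) epoch EV per fold
    best_tau: np.ndarray              # (n_neurons,) argmax of fold-mean EV
    peak_valid: np.ndarray            # (n_neurons,) bool
    fold_best_tau: np.ndarray         # (n_folds, n_neurons)
    fold_peak_valid: np.ndarray       # (n_folds, n_neurons) bool
    p_value: np.ndarray | None = None
    significant: np.ndarray | None = None

    @property
    def fold_mean_ev(self) -> np.ndarray:
        return self.ev.mean(axis=0)   # (n_tau, n_neurons)


def _argmax_prefer_zero(ev_tau: np.ndarray, taus: np.ndarray) -> np.ndarray:
    """Argmax over tau; exact ties go to the smallest |tau|, negative first."""
    order = np.lexsort((taus > 0, np.abs(taus)))  # tau indices, preferred first
    ev_ord = ev_tau[order]                        # (n_tau, ...)
    best_ord = np.argmax(ev_ord == ev_ord.max(axis=0, keepdims=True), axis=0)
    return taus[order][best_ord]


def _epoch_ev_per_fold(r2: np.ndarray, timepoints: np.ndarray, window: tuple[float, float],
                       edge: float) -> np.ndarray:
    t0, t1 = window
    keep = (timepoints >= t0 + edge) & (timepoints < t1 - edge)
    if not keep.any():
        raise ValueError("epoch too short after edge exclusion")
    return np.maximum(r2[:, :, keep], 0.0).mean(axis=2)  # (n_folds, n_neurons)


def offset_scan(series: np.ndarray, frame_period: float, rates: np.ndarray,
                abs_times: np.ndarray, folds: np.ndarray, timepoints: np.ndarray,
                trials: pd.DataFrame | None = None, epoch: str = "response",
                taus: np.ndarray | None = None, lam_grid: np.ndarray = LAMBDA_GRID,
                min_peak_ev: float = 0.01, peak_ratio: float = 1.2,
                inner_k: int = 5, seed: int = 0, edge: float = 0.150,
                window: tuple[float, float] | None = None) -> OffsetProfiles:
    """Scan temporal offsets for every neuron.

    ``series`` is the per-frame feature time series (embedding by default
    usage), ``rates`` is (n_neurons, n_trials, n_timepoints) on the
    evaluation grid with absolute target times ``abs_times``. For each tau
    the feature windows are shifted and the per-timepoint ridge prediction
    repeated; EV(tau) is the rectified epoch average per fold.

    The ridge penalty is selected per (neuron, fold) by inner CV at tau = 0
    on a subsample of timepoints and reused across the scan.
    """
    taus = default_tau_grid() if taus is None else np.asarray(taus)
    folds = np.asarray(folds)
    fold_ids = np.unique(folds)
    n_neurons = rates.shape[0]
    n_t = abs_times.shape[1]
    if window is None:
        if trials is None:
            raise ValueError("provide either trials (+ epoch) or an explicit window")
        window = epoch_bounds(trials)[epoch]

    # penalty per (fold, neuron), chosen once at tau = 0
    probe = np.linspace(0, n_t - 1, min(3, n_t)).astype(int)
    fixed_lams = np.empty((len(fold_ids), n_neurons))
    for fi, f in enumerate(fold_ids):
        train = folds != f
        sse = np.zeros((len(lam_grid), n_neurons))
        for ti in probe:
            X = build_features(series, frame_period, abs_times[:, ti])
            Y = rates[:, :, ti].T
            sse += _inner_sse(X[train], Y[train], lam_grid, inner_k,
                              seed + 977 * fi + int(ti))
        fixed_lams[fi] = lam_grid[np.argmin(sse, axis=0)]

    ev = np.empty((len(fold_ids), len(taus), n_neurons))
    for k, tau in enumerate(taus):
        X_by_time = np.stack([
            build_features(series, frame_period, abs_times[:, ti], tau=tau)
            for ti in range(n_t)
        ])
        res = ridge_predict(X_by_time, rates, folds, timepoints,
                            fixed_lams=fixed_lams, method=f"tau={tau:+.4f}")
        ev[:, k, :] = _epoch_ev_per_fold(res.r2, timepoints, window, edge)

    mean_ev = ev.mean(axis=0)                              # (n_tau, n_neurons)
    best_tau = _argmax_prefer_zero(mean_ev, taus)
    peak_valid = (mean_ev.max(axis=0) >= peak_ratio * mean_ev.mean(axis=0)) \
        & (mean_ev.max(axis=0) >= min_peak_ev)
    fold_best = np.empty((len(fold_ids), n_neurons))
    fold_valid = np.empty((len(fold_ids), n_neurons), dtype=bool)
    for fi in range(len(fold_ids)):
        fold_best[fi] = _argmax_prefer_zero(ev[fi], taus)
        fold_valid[fi] = (ev[fi].max(axis=0) >= peak_ratio * ev[fi].mean(axis=0)) \
            & (ev[fi].max(axis=0) >= min_peak_ev)
    return OffsetProfiles(taus=taus, ev=ev, best_tau=best_tau, peak_valid=peak_valid,
                          fold_best_tau=fold_best, fold_peak_valid=fold_valid)


def _inner_sse(X: np.ndarray, Y: np.ndarray, lam_grid: np.ndarray, k: int,
               seed: int) -> np.ndarray:
    """Inner-CV squared error per (lambda, neuron) — shared with ridge_cv_lambda
    logic but accumulating the raw SSE matrix."""
    rng = np.random.default_rng(seed)
    n = len(X)
    parts = np.array_split(rng.permutation(n), k)
    sse = np.zeros((len(lam_grid), Y.shape[1]))
    for test in parts:
        mask = np.ones(n, dtype=bool)
        mask[test] = False
        path = RidgePath(X[mask], Y[mask])
        for j, lam in enumerate(lam_grid):
            W, b = path.coef(lam)
            sse[j] += ((Y[test] - (X[test] @ W + b)) ** 2).sum(axis=0)
    return sse


def offset_significance(profiles: OffsetProfiles, q: float = 0.05,
                        min_valid_folds: int = 2) -> OffsetProfiles:
    """Per-neuron t-test of fold-wise best offsets against zero + BH control.

    Only folds with a valid peak enter the test; neurons with fewer than
    ``min_valid_folds`` such folds (or an invalid overall peak) are excluded
    (p = NaN). Significance is established across the tested set by
    Benjamini-Hochberg FDR at rate ``q``.
    """
    n_neurons = profiles.fold_best_tau.shape[1]
    p = np.full(n_neurons, np.nan)
    for i in range(n_neurons):
        if not profiles.peak_valid[i]:
            continue
        offs = profiles.fold_best_tau[profiles.fold_peak_valid[:, i], i]
        if len(offs) < min_valid_folds:
            continue
        if np.allclose(offs.std(), 0.0):
            p[i] = 1.0 if np.allclose(offs.mean(), 0.0) else 0.0
        else:
            p[i] = stats.ttest_1samp(offs, 0.0).pvalue
    significant = np.zeros(n_neurons, dtype=bool)
    tested = np.isfinite(p)
    if tested.any():
        significant[tested] = multipletests(p[tested], alpha=q, method="fdr_bh")[0]
    profiles.p_value = p
    profiles.significant = significant
    return profiles


def offset_maps(profiles: OffsetProfiles, ccf_xyz: np.ndarray, voxel_size: float,
                plane: tuple[int, int] = (0, 1), median_filter: int = 3,
                ) -> dict[str, pd.DataFrame]:
    """Voxel maps of best offsets: per-voxel mean tau* and sign fractions."""
    valid = profiles.peak_valid
    xyz = np.asarray(ccf_xyz)[valid]
    tau = profiles.best_tau[valid]
    return {
        "mean_tau": voxel_map(tau, xyz, voxel_size, "mean", plane, median_filter),
        "fraction_positive": voxel_map(tau, xyz, voxel_size, "fraction_positive",
                                       plane, median_filter),
        "fraction_negative": voxel_map(tau, xyz, voxel_size, "fraction_negative",
                                       plane, median_filter),
    }


def region_offset_summary(profiles: OffsetProfiles, regions: np.ndarray) -> pd.DataFrame:
    """Per-region mean +- SEM of best offsets (valid-peak neurons only)."""
    valid = profiles.peak_valid
    df = pd.DataFrame({"region": np.asarray(regions)[valid],
                       "tau": profiles.best_tau[valid]})
    out = df.groupby("region")["tau"].agg(["count", "mean", "sem"]).reset_index()
    return out.rename(columns={"count": "n"})


def axis_correlation(profiles: OffsetProfiles, axis_values: np.ndarray,
                     ) -> tuple[float, float]:
    """Spearman rank correlation of tau* with an anatomical axis (e.g. depth)."""
    valid = profiles.peak_valid
    rho, p = stats.spearmanr(np.asarray(axis_values)[valid], profiles.best_tau[valid])
    return float(rho), float(p)
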