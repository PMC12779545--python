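"""Single-trial choice decoding from video and choice/movement dissociation.

If uninstructed movements during the sample and delay epochs are biased
toward the upcoming choice, the choice becomes decodable from video before
the animal licks. The module decodes lick direction from video features
with L2 logistic regression (stratified 20-fold CV), then uses trials where
the video-predicted choice (vL/vR) and the actual choice (L/R) disagree to
dissociate neurons modulated by choice from neurons modulated by the
movements themselves:

* choice AUC — decode L vs R from a neuron's delay-epoch mean rate while
  holding the video-prediction group fixed (average of the vL and vR
  conditions);
* movement AUC — decode vL vs vR while holding choice fixed (average of
  the L and R conditions).

A neuron is labeled choice- (movement-) modulated when the corresponding
held-out AUC exceeds 0.65. A residual variant first subtracts the
embedding-based rate prediction and decodes choice from what remains.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import calinski_harabasz_score

from .linmod import LAMBDA_GRID, auc_score, fit_logistic, logistic_cv_lambda
from .predict import build_features, epoch_bounds

CONTINGENCIES = ("L-vL", "L-vR", "R-vR", "R-vL")
AUC_THRESHOLD = 0.65
MIN_GROUP_TRIALS = 20


def _stratified_folds(labels: np.ndarray, k: int, seed: int) -> np.ndarray:
    rng = np.random.default_rng(seed)
    folds = np.empty(len(labels), dtype=int)
    start = 0
    for val in np.unique(labels):
        idx = rng.permutation(np.flatnonzero(labels == val))
        folds[idx] = (np.arange(len(idx)) + start) % k
        start += len(idx)
    return folds


def _cv_scores(X: np.ndarray, y: np.ndarray, folds: np.ndarray,
               lam_grid: np.ndarray, inner: int | str, seed: int) -> np.ndarray:
    """Held-out decision scores for every trial (linear logistic, nested CV).

    When the grid has a single value the inner search is skipped — for
    monotone (one-dimensional) features the held-out ranking, hence the
    AUC, does not depend on the penalty.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    scores = np.full(len(y), np.nan)
    for f in np.unique(folds):
        test = folds == f
        train = ~test
        if len(np.unique(y[train])) < 2:
            continue
        lam = (float(lam_grid[0]) if len(lam_grid) == 1 else
               logistic_cv_lambda(X[train], y[train], lam_grid, inner=inner,
                                  seed=seed + int(f)))
        w, b = fit_logistic(X[train], y[train], lam)
        scores[test] = X[test] @ w + b
    return scores


@dataclass
class ChoiceDecodeResult:
    """Held-out choice decoding from one predictor."""

    predictor: str
    auc: float                          # delay-epoch (or supplied-feature) AUC
    scores: np.ndarray                  # held-out decision score per trial
    predicted_right: np.ndarray         # vR flag per trial
    folds: np.ndarray
    timecourse: pd.DataFrame | None = None  # per-timepoint AUC, if computed


def epoch_mean_features(series: np.ndarray, frame_period: float,
                        trials: pd.DataFrame, epoch: str = "delay") -> np.ndarray:
    """Per-trial mean of a per-frame feature series within an epoch."""
    series = np.asarray(series)
    if series.ndim == 1:
        series = series[:, None]
    b = epoch_bounds(trials)[epoch]
    go = trials["go_cue"].to_numpy()
    out = np.empty((len(trials), series.shape[1]))
    for i, g in enumerate(go):
        i0 = int(np.rint((g + b[0]) / frame_period))
        i1 = int(np.rint((g + b[1]) / frame_period))
        out[i] = series[max(i0, 0):min(i1, len(series))].mean(axis=0)
    return out


def decode_choice(features: np.ndarray, trials: pd.DataFrame, n_folds: int = 20,
                  lam_grid: np.ndarray = LAMBDA_GRID, inner: int | str = 5,
                  seed: int = 0, predictor: str = "embedding") -> ChoiceDecodeResult:
    """Decode lick direction from per-trial features (correct trials only).

    Stratified ``n_folds``-fold CV; the logistic L2 penalty is chosen by
    nested CV within each training set. Every trial receives exactly one
    held-out score; the AUC is computed over the pooled held-out scores.
    """
    y = (trials["lick_direction"].to_numpy() == "right").astype(float)
    if len(np.unique(y)) < 2:
        raise ValueError("both lick directions must be present")
    folds = _stratified_folds(y, n_folds, seed)
    scores = _cv_scores(features, y, folds, lam_grid, inner, seed)
    return ChoiceDecodeResult(
        predictor=predictor,
        auc=auc_score(y, scores),
        scores=scores,
        predicted_right=scores > 0,
        folds=folds,
    )


def decode_choice_from_video(series: np.ndarray, frame_period: float,
                             trials: pd.DataFrame, n_folds: int = 20,
                             lam_grid: np.ndarray = LAMBDA_GRID, inner: int | str = 5,
                             seed: int = 0, timecourse_step: int = 8,
                             timecourse: bool = False, predictor: str = "embedding",
                             ) -> ChoiceDecodeResult:
    """Choice decoding from a per-frame feature series (embedding or markers).

    The per-trial prediction (vL/vR) uses the delay-epoch feature mean.
    Optionally also computes a per-timepoint AUC time course from 5-frame
    feature windows on a subsampled grid across the whole trial.
    """
    feats = epoch_mean_features(series, frame_period, trials, "delay")
    result = decode_choice(feats, trials, n_folds, lam_grid, inner, seed, predictor)
    if timecourse:
        y = (trials["lick_direction"].to_numpy() == "right").astype(float)
        bounds = epoch_bounds(trials)
        tp = np.arange(bounds["presample"][0], bounds["response"][1],
                       timecourse_step * frame_period)
        go = trials["go_cue"].to_numpy()
        rows = []
        for t in tp:
            X = build_features(series, frame_period, go + t)
            sc = _cv_scores(X, y, result.folds, lam_grid[:: max(len(lam_grid) // 4, 1)],
                            3, seed + 1)
            rows.append({"time": t, "auc": auc_score(y, sc)})
        result.timecourse = pd.DataFrame(rows)
    return result


def decode_choice_from_marker(markers: pd.DataFrame, part: str, frame_period: float,
                              trials: pd.DataFrame, n_folds: int = 20,
                              lam_grid: np.ndarray = LAMBDA_GRID, inner: int | str = 5,
                              seed: int = 0) -> ChoiceDecodeResult:
    """Choice decoding from a single marker's (x, y) trace."""
    series = markers[[(part, "x"), (part, "y")]].to_numpy(dtype=float)
    return decode_choice_from_video(series, frame_period, trials, n_folds, lam_grid,
                                    inner, seed, predictor=f"{part}-marker")


# ---------------------------------------------------------------------------
# contingency split and modulation classification
# ---------------------------------------------------------------------------

@dataclass
class ContingencySplit:
    group: np.ndarray                   # per-trial label from CONTINGENCIES
    counts: dict[str, int]
    valid: bool
    min_group: int = MIN_GROUP_TRIALS


def split_contingencies(decode: ChoiceDecodeResult, trials: pd.DataFrame,
                        min_group: int = MIN_GROUP_TRIALS) -> ContingencySplit:
    """Cross-classify correct trials by choice (L/R) and video prediction (vL/vR)."""
    actual_right = trials["lick_direction"].to_numpy() == "right"
    group = np.where(actual_right,
                     np.where(decode.predicted_right, "R-vR", "R-vL"),
                     np.where(decode.predicted_right, "L-vR", "L-vL"))
    counts = {g: int((group == g).sum()) for g in CONTINGENCIES}
    valid = all(c >= min_group for c in counts.values())
    return ContingencySplit(group=group, counts=counts, valid=valid,
                            min_group=min_group)


@dataclass
class ModulationResult:
    choice_auc: np.ndarray
    movement_auc: np.ndarray
    choice_modulated: np.ndarray
    movement_modulated: np.ndarray
    threshold: float
    residual_auc: np.ndarray | None = None
    residual_choice_modulated: np.ndarray | None = None
    skipped_conditions: list[str] = field(default_factory=list)

    def labels(self) -> np.ndarray:
        out = np.full(len(self.choice_auc), "neither", dtype=object)
        out[self.choice_modulated & ~self.movement_modulated] = "choice"
        out[~self.choice_modulated & self.movement_modulated] = "movement"
        out[self.choice_modulated & self.movement_modulated] = "both"
        return out


def _conditioned_auc(x: np.ndarray, y: np.ndarray, cond: np.ndarray,
                     outer_k: int, lam_grid, inner, seed: int,
                     min_cell: int) -> tuple[float, bool]:
    """Fold-averaged held-out AUC of a 1-D decoder within one condition cell."""
    sel = np.flatnonzero(cond)
    ys = y[sel]
    if min((ys == 0).sum(), (ys == 1).sum()) < min_cell:
        return np.nan, True
    folds = _stratified_folds(ys, min(outer_k, int(np.bincount(ys.astype(int)).min())),
                              seed)
    scores = _cv_scores(x[sel], ys, folds, lam_grid, inner, seed)
    aucs = []
    for f in np.unique(folds):
        m = folds == f
        if len(np.unique(ys[m])) == 2 and np.isfinite(scores[m]).all():
            aucs.append(auc_score(ys[m], scores[m]))
    return (float(np.mean(aucs)) if aucs else np.nan), False


def classify_modulation(delay_rates: np.ndarray, split: ContingencySplit,
                        trials: pd.DataFrame, threshold: float = AUC_THRESHOLD,
                        outer_k: int = 5, lam_grid: np.ndarray = np.array([1.0]),
                        inner: int | str = "loo", min_cell: int = 10, seed: int = 0,
                        ) -> ModulationResult:
    """Choice vs uninstructed-movement modulation for every neuron.

    ``delay_rates`` is (n_neurons, n_trials) delay-epoch mean rates over the
    correct trials of ``split``. For each neuron, choice AUC is the average
    of decoding L vs R within vL and within vR trials; movement AUC is the
    average of decoding vL vs vR within L and within R trials. Decoders are
    L2 logistic regressions on the single-neuron rate with held-out AUC
    averaged over stratified folds. The default single-value penalty grid
    skips the nested search (the AUC of a one-dimensional decoder is
    invariant to the penalty); passing a grid enables nested ``inner`` CV.
    Conditions with fewer than ``min_cell`` trials per class are skipped.
    """
    if not split.valid:
        raise ValueError(f"session invalid: contingency counts {split.counts} "
                         f"(need >= {split.min_group} per group)")
    choice_r = (trials["lick_direction"].to_numpy() == "right").astype(float)
    video_r = np.isin(split.group, ("L-vR", "R-vR")).astype(float)
    n_neurons = delay_rates.shape[0]
    choice_auc = np.full(n_neurons, np.nan)
    movement_auc = np.full(n_neurons, np.nan)
    skipped: set[str] = set()
    for i in range(n_neurons):
        x = delay_rates[i]
        vals = []
        for v, name in ((0.0, "vL"), (1.0, "vR")):
            a, skip = _conditioned_auc(x, choice_r, video_r == v, outer_k, lam_grid,
                                       inner, seed + i, min_cell)
            if skip:
                skipped.add(f"choice|{name}")
            elif np.isfinite(a):
                vals.append(a)
        if vals:
            choice_auc[i] = np.mean(vals)
        vals = []
        for c, name in ((0.0, "L"), (1.0, "R")):
            a, skip = _conditioned_auc(x, video_r, choice_r == c, outer_k, lam_grid,
                                       inner, seed + 7919 + i, min_cell)
            if skip:
                skipped.add(f"movement|{name}")
            elif np.isfinite(a):
                vals.append(a)
        if vals:
            movement_auc[i] = np.mean(vals)
    with np.errstate(invalid="ignore"):
        return ModulationResult(
            choice_auc=choice_auc,
            movement_auc=movement_auc,
            choice_modulated=choice_auc > threshold,
            movement_modulated=movement_auc > threshold,
            threshold=threshold,
            skipped_conditions=sorted(skipped),
        )


def residual_choice_decode(delay_rates: np.ndarray, delay_predictions: np.ndarray,
                           trials: pd.DataFrame, n_folds: int = 5,
                           threshold: float = AUC_THRESHOLD,
                           lam_grid: np.ndarray = np.array([1.0]),
                           inner: int | str = 5, seed: int = 0,
                           ) -> tuple[np.ndarray, np.ndarray]:
    """Choice AUC from movement-subtracted residual activity, per neuron.

    ``delay_predictions`` are the held-out embedding-based rate predictions
    (same shape as ``delay_rates``); the residual rate - prediction is the
    activity the video model cannot account for. Returns (AUC per neuron,
    choice-modulated flag at ``threshold``).
    """
    if delay_predictions.shape != delay_rates.shape:
        raise ValueError("predictions must match rates shape")
    if not np.isfinite(delay_predictions).all():
        raise ValueError("missing predictions for some trials")
    residual = delay_rates - delay_predictions
    y = (trials["lick_direction"].to_numpy() == "right").astype(float)
    n_neurons = residual.shape[0]
    auc = np.full(n_neurons, np.nan)
    for i in range(n_neurons):
        folds = _stratified_folds(y, n_folds, seed + i)
        scores = _cv_scores(residual[i], y, folds, lam_grid, inner, seed + i)
        aucs = []
        for f in np.unique(folds):
            m = folds == f
            if len(np.unique(y[m])) == 2:
                aucs.append(auc_score(y[m], scores[m]))
        if np.allclose(residual[i].std(), 0.0):
            auc[i] = 0.5  # constant residual carries no information
        elif aucs:
            auc[i] = float(np.mean(aucs))
    with np.errstate(invalid="ignore"):
        return auc, auc > threshold


# ---------------------------------------------------------------------------
# across-session analyses
# ---------------------------------------------------------------------------

def session_behavior_correlation(session_auc: np.ndarray, fraction_correct: np.ndarray,
                                 ) -> tuple[float, float]:
    """Correlation between video choice-predictability and task performance."""
    session_auc = np.asarray(session_auc, dtype=float)
    fraction_correct = np.asarray(fraction_correct, dtype=float)
    if session_auc.std() == 0 or fraction_correct.std() == 0:
        return np.nan, np.nan
    r, p = stats.pearsonr(session_auc, fraction_correct)
    return float(r), float(p)


@dataclass
class ClusteringResult:
    score: float
    p_value: float
    null_mean: float
    null_sd: float
    null: np.ndarray


def clustering_score(features: np.ndarray, labels: np.ndarray, n_shuffles: int = 1000,
                     seed: int = 0, cap: float = 1e6) -> ClusteringResult:
    """Calinski-Harabasz score of animal clustering with a label-shuffle null.

    The score is the between- to within-cluster dispersion ratio of session
    features grouped by animal; the null randomly reassigns animal labels.
    Degenerate (zero within-cluster spread) scores are capped at ``cap``.
    p is the (+1-corrected) fraction of null scores >= the observed one.
    """
    features = np.asarray(features, dtype=float)
    if features.ndim == 1:
        features = features[:, None]
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("need at least two clusters (animals)")

    def ch(lab):
        ssw = sum(float(((features[lab == g] - features[lab == g].mean(axis=0)) ** 2).sum())
                  for g in np.unique(lab))
        if ssw == 0.0:  # perfectly tight clusters: dispersion ratio diverges
            return cap
        with np.errstate(divide="ignore"):
            s = calinski_harabasz_score(features, lab)
        return float(min(s, cap)) if np.isfinite(s) else cap

    observed = ch(labels)
    rng = np.random.default_rng(seed)
    null = np.array([ch(rng.permutation(labels)) for _ in range(n_shuffles)])
    p = (float((null >= observed).sum()) + 1.0) / (n_shuffles + 1.0)
    return ClusteringResult(score=observed, p_value=p, null_mean=float(null.mean()),
                            null_sd=float(null.std()), null=null)


def filter_marker_sessions(session_table: pd.DataFrame, auc_threshold: float = 0.65,
                           min_sessions: int = 2) -> pd.DataFrame:
    """Marker-variant session filter for the clustering analysis.

    Keeps sessions where either the jaw or the nose marker decodes choice at
    AUC >= ``auc_threshold``, then keeps only animals with at least
    ``min_sessions`` such sessions. Expects columns 'animal', 'jaw_auc',
    'nose_auc'.
    """
    ok = session_table[(session_table["jaw_auc"] >= auc_threshold)
                       | (session_table["nose_auc"] >= auc_threshold)]
    counts = ok["animal"].value_counts()
    keep = counts[counts >= min_sessions].index
    return ok[ok["animal"].isin(keep)]
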