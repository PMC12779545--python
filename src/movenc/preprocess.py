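"""Analysis-ready structures: binned rates, cleaned markers, trial/neuron sets.

Spikes are binned into firing rates with a 40 ms window sliding at the 3.4 ms
frame stride, on a grid anchored at each trial's go cue (t = 0 at the go cue,
negative times before it). Marker traces are cleaned by a five-sigma velocity
outlier rule with linear imputation, and trials/neurons are filtered the way
the downstream encoding and choice analyses expect.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._util import mad_sd

EXCLUSION_FLAGS = ("photoinhibition", "free_water", "early_lick", "ignored")


@dataclass
class RateMatrix:
    """Binned firing rates, neurons x trials x timepoints (spikes/s).

    ``timepoints`` are bin centers relative to the go cue; each rate is the
    spike count in the half-open window [t - w/2, t + w/2) divided by w.
    """

    rates: np.ndarray
    timepoints: np.ndarray
    bin_width: float
    stride: float

    @property
    def n_neurons(self) -> int:
        return self.rates.shape[0]

    @property
    def n_trials(self) -> int:
        return self.rates.shape[1]

    def mean_rates(self) -> np.ndarray:
        """Session-mean rate per neuron (spikes/s)."""
        return self.rates.mean(axis=(1, 2))


def epoch_bounds(trials: pd.DataFrame) -> dict[str, tuple[float, float]]:
    """Epoch windows relative to the go cue, shared across trials."""
    pre = trials["sample_on"] - trials["start_time"]
    samp = trials["sample_off"] - trials["sample_on"]
    delay = trials["go_cue"] - trials["sample_off"]
    resp = trials["response_off"] - trials["go_cue"]
    for name, d in (("pre", pre), ("sample", samp), ("delay", delay), ("response", resp)):
        if np.ptp(d.to_numpy()) > 1e-6:
            raise ValueError(f"{name} epoch duration varies across trials")
    pre, samp, delay, resp = (float(x.iloc[0]) for x in (pre, samp, delay, resp))
    return {
        "presample": (-(pre + samp + delay), -(samp + delay)),
        "sample": (-(samp + delay), -delay),
        "delay": (-delay, 0.0),
        "response": (0.0, resp),
    }


def bin_spikes(spike_times: list[np.ndarray], trials: pd.DataFrame,
               bin_width: float = 0.040, stride: float = 0.0034) -> RateMatrix:
    """Bin spikes into firing rates on the go-cue-anchored sliding-window grid."""
    if bin_width < stride:
        raise ValueError("bin_width must be at least the stride")
    for i, st in enumerate(spike_times):
        if np.any(np.diff(st) < 0):
            raise ValueError(f"spike train {i} is not sorted")

    bounds = epoch_bounds(trials)
    t0 = bounds["presample"][0]
    t1 = bounds["response"][1]
    k = np.arange(int(np.ceil(t0 / stride)), int(np.floor(t1 / stride)) + 1)
    timepoints = k * stride

    go = trials["go_cue"].to_numpy()
    centers = go[:, None] + timepoints[None, :]          # (n_trials, n_t)
    lo = (centers - bin_width / 2).ravel()
    hi = (centers + bin_width / 2).ravel()

    n_trials, n_t = centers.shape
    rates = np.empty((len(spike_times), n_trials, n_t), dtype=np.float32)
    for i, st in enumerate(spike_times):
        counts = np.searchsorted(st, hi, side="left") - np.searchsorted(st, lo, side="left")
        rates[i] = (counts / bin_width).reshape(n_trials, n_t)
    return RateMatrix(rates=rates, timepoints=timepoints, bin_width=bin_width, stride=stride)


def clean_markers(markers: pd.DataFrame, sigma_thresh: float = 5.0,
                  occlusion_likelihood: float = 0.5) -> tuple[pd.DataFrame, dict]:
    """Impute velocity outliers and occluded-tongue frames in marker traces.

    Frames whose frame-to-frame speed exceeds ``sigma_thresh`` times the
    robust (MAD-based) SD of speed are replaced by linear interpolation from
    the nearest unflagged frames. Tongue frames with likelihood below
    ``occlusion_likelihood`` are set to the tongue's mean visible position.
    """
    if len(markers) < 3:
        raise ValueError("need at least 3 frames to clean markers")
    out = markers.copy()
    parts = out.columns.get_level_values("bodypart").unique()
    info: dict[str, np.ndarray] = {}
    for part in parts:
        xy = out[part][["x", "y"]].to_numpy(dtype=float)
        occ = np.zeros(len(xy), dtype=bool)
        if part == "tongue" and "likelihood" in out[part].columns:
            occ = out[(part, "likelihood")].to_numpy() < occlusion_likelihood
            if occ.any() and not occ.all():
                xy[occ] = xy[~occ].mean(axis=0)
            info["tongue_occluded"] = occ

        vel = np.diff(xy, axis=0)
        speed = np.linalg.norm(vel, axis=1)
        # robust per-axis SDs (MAD assumes a roughly normal distribution,
        # which holds per component but not for the Rayleigh-like magnitude)
        sd = np.sqrt(mad_sd(vel[:, 0]) ** 2 + mad_sd(vel[:, 1]) ** 2)
        flagged = np.zeros(len(xy), dtype=bool)
        if sd > 0:
            flagged[1:] = speed > sigma_thresh * sd
        # occlusion-imputed frames are held fixed, and steps across an
        # occlusion boundary are real discontinuities, not tracking outliers
        flagged[1:] &= ~(occ[1:] | occ[:-1])
        flagged &= ~occ
        if flagged.all() or (~flagged).sum() < 2:
            raise ValueError(f"degenerate trace for {part!r}: all frames flagged")
        if flagged.any():
            good = np.flatnonzero(~flagged)
            bad = np.flatnonzero(flagged)
            for ax in range(2):
                xy[bad, ax] = np.interp(bad, good, xy[good, ax])
        out[(part, "x")] = xy[:, 0]
        out[(part, "y")] = xy[:, 1]
        info[f"{part}_outliers"] = flagged
    return out, info


def select_trials(trials: pd.DataFrame, mode: str = "encoding") -> pd.DataFrame:
    """Drop excluded trials; in ``choice`` mode additionally drop error trials."""
    if mode not in ("encoding", "choice"):
        raise ValueError("mode must be 'encoding' or 'choice'")
    excluded = np.zeros(len(trials), dtype=bool)
    for flag in EXCLUSION_FLAGS:
        if flag in trials:
            excluded |= trials[flag].to_numpy().astype(bool)
    keep = ~excluded
    if mode == "choice":
        keep &= trials["correct"].to_numpy().astype(bool)
    if not keep.any():
        counts = {flag: int(trials[flag].sum()) for flag in EXCLUSION_FLAGS if flag in trials}
        raise ValueError(f"no trials left after selection; exclusions: {counts}")
    return trials.loc[keep]


def filter_neurons(rate_matrix: RateMatrix, min_rate: float = 2.0) -> np.ndarray:
    """Indices of neurons whose session-mean rate is at least ``min_rate`` Hz."""
    mean = rate_matrix.mean_rates()
    keep = np.flatnonzero(mean >= min_rate)
    return keep


def make_folds(trials: pd.DataFrame, k: int = 5, seed: int = 0,
               stratify_on: tuple[str, ...] = ("lick_direction", "correct")) -> np.ndarray:
    """Stratified k-fold assignment, one fold index per trial row.

    Within each stratum (e.g. lick direction x correctness) trials are
    permuted with the given seed and dealt round-robin, so per-fold stratum
    counts differ from perfect proportionality by at most one trial. Strata
    smaller than k are merged (with a warning) before assignment.
    """
    n = len(trials)
    if n < k:
        raise ValueError(f"cannot make {k} folds from {n} trials")
    labels = pd.Series(["|".join(str(trials[c].iloc[i]) for c in stratify_on)
                        for i in range(n)], index=trials.index)
    counts = labels.value_counts()
    small = counts[counts < k].index
    if len(small) > 0:
        warnings.warn(f"merging {len(small)} strata smaller than k={k}")
        labels[labels.isin(small)] = "__merged__"

    rng = np.random.default_rng(seed)
    folds = np.empty(n, dtype=int)
    pos = labels.reset_index(drop=True)
    start = 0  # rotate fold order between strata to balance fold sizes
    for stratum in sorted(pos.unique()):
        idx = np.flatnonzero(pos.to_numpy() == stratum)
        perm = rng.permutation(idx)
        folds[perm] = (np.arange(len(perm)) + start) % k
        start += len(perm)
    return folds


def make_split(trials: pd.DataFrame, test_size: int = 64, seed: int = 0,
               stratify_on: tuple[str, ...] = ("lick_direction", "correct")) -> np.ndarray:
    """Single balanced train/test split (True = test trial).

    Used for the three-way method comparison, which holds out a fixed-size
    test set balanced on lick direction and correctness.
    """
    n = len(trials)
    if not 0 < test_size < n:
        raise ValueError("test_size must be between 0 and the number of trials")
    labels = np.array(["|".join(str(trials[c].iloc[i]) for c in stratify_on)
                       for i in range(n)])
    rng = np.random.default_rng(seed)
    test = np.zeros(n, dtype=bool)
    uniq, inv = np.unique(labels, return_inverse=True)
    # largest-remainder allocation of the test quota across strata
    sizes = np.bincount(inv)
    quota = test_size * sizes / n
    take = np.floor(quota).astype(int)
    rem = test_size - take.sum()
    order = np.argsort(-(quota - take))
    take[order[:rem]] += 1
    for g in range(len(uniq)):
        idx = np.flatnonzero(inv == g)
        test[rng.permutation(idx)[: take[g]]] = True
    return test
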