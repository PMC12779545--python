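"""Atlas-space statistics over neurons with CCF coordinates.

Neurons registered to a common coordinate framework can be pooled across
animals and binned into cubic voxels. Two shuffle-null tests ask whether a
per-neuron scalar (explained variance, AUC, best offset) is spatially
organized:

* ``uniformity_test`` — one-way F statistic over the voxel grouping against
  a null built by shuffling values across neurons with coordinates fixed;
* ``neighbor_smoothness_test`` — mean absolute difference between nearest-
  neighbor pairs (within anatomical groups) against within-group shuffles,
  detecting smooth spatial variation rather than any grouping signal.

``voxel_map`` produces the 2-D projected per-voxel statistic tables used
for display, with an optional 3x3 median filter.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


def voxelize(ccf_xyz: np.ndarray, voxel_size: float, origin: float = 0.0) -> np.ndarray:
    """Voxel id per neuron (disjoint cubes anchored at the CCF origin)."""
    xyz = np.asarray(ccf_xyz, dtype=float)
    cells = np.floor((xyz - origin) / voxel_size).astype(np.int64)
    _, ids = np.unique(cells, axis=0, return_inverse=True)
    return ids


def _f_stat(values: np.ndarray, group_onehot: np.ndarray, sizes: np.ndarray) -> np.ndarray:
    """Vectorized one-way F statistic; values may be (n,) or (shuffles, n)."""
    v = np.atleast_2d(values)
    n = v.shape[1]
    g = group_onehot.shape[1]
    sums = v @ group_onehot                      # (s, g)
    means = sums / sizes
    grand = v.mean(axis=1, keepdims=True)
    ss_between = (sizes * (means - grand) ** 2).sum(axis=1)
    ss_total = ((v - grand) ** 2).sum(axis=1)
    ss_within = ss_total - ss_between
    df_b, df_w = g - 1, n - g
    if df_b <= 0 or df_w <= 0:
        raise ValueError("need at least 2 groups and n > n_groups")
    f = (ss_between / df_b) / np.maximum(ss_within / df_w, 1e-300)
    return f if np.ndim(values) > 1 else f[0]


@dataclass
class ShuffleTestResult:
    statistic: float
    p_value: float
    null: np.ndarray
    n_groups: int


def uniformity_test(values: np.ndarray, ccf_xyz: np.ndarray, voxel_size: float,
                    n_shuffles: int = 10000, seed: int = 0) -> ShuffleTestResult:
    """Test a scalar statistic against spatial uniformity on a voxel grid.

    The observed one-way F over the voxel grouping is compared with a null
    of value shuffles across neurons (coordinates fixed); the bootstrap p is
    the (+1-corrected) fraction of null F values at least as large.
    """
    values = np.asarray(values, dtype=float)
    ids = voxelize(ccf_xyz, voxel_size)
    sizes = np.bincount(ids)
    if len(sizes) < 2:
        raise ValueError("all neurons fall in one voxel; decrease voxel_size")
    if (sizes >= 2).sum() < 2:
        raise ValueError("need at least 2 voxels with at least 2 neurons")
    onehot = np.zeros((len(values), len(sizes)))
    onehot[np.arange(len(values)), ids] = 1.0
    observed = float(_f_stat(values, onehot, sizes))
    rng = np.random.default_rng(seed)
    shuffled = rng.permuted(np.broadcast_to(values, (n_shuffles, len(values))).copy(),
                            axis=1)
    null = _f_stat(shuffled, onehot, sizes)
    p = (float((null >= observed).sum()) + 1.0) / (n_shuffles + 1.0)
    return ShuffleTestResult(statistic=observed, p_value=p, null=null,
                             n_groups=len(sizes))


def nearest_neighbor_pairs(ccf_xyz: np.ndarray, groups: np.ndarray | None = None,
                           ) -> np.ndarray:
    """Index of each neuron's nearest neighbor (within its group).

    Euclidean distance in CCF space; self-pairs excluded by index; distance
    ties broken toward the lowest neuron index. Singleton groups get -1.
    """
    xyz = np.asarray(ccf_xyz, dtype=float)
    n = len(xyz)
    groups = np.zeros(n, dtype=int) if groups is None else np.asarray(groups)
    nn_idx = np.full(n, -1, dtype=int)
    for g in np.unique(groups):
        members = np.flatnonzero(groups == g)
        if len(members) < 2:
            continue
        sub = xyz[members]
        d2 = ((sub[:, None, :] - sub[None, :, :]) ** 2).sum(-1)
        np.fill_diagonal(d2, np.inf)
        nn_idx[members] = members[np.argmin(d2, axis=1)]  # argmin takes lowest index on ties
    return nn_idx


def neighbor_smoothness_test(values: np.ndarray, ccf_xyz: np.ndarray,
                             groups: np.ndarray | None = None, n_shuffles: int = 1000,
                             seed: int = 0) -> ShuffleTestResult:
    """Test for smooth spatial variation via nearest-neighbor differences.

    The observed mean |value difference| between nearest-neighbor pairs is
    compared with a null where values are shuffled within each group
    (coordinates, hence the neighbor structure, fixed); small observed
    differences indicate smooth spatial structure. p is the (+1-corrected)
    fraction of shuffles with mean difference at most the observed one.
    """
    values = np.asarray(values, dtype=float)
    n = len(values)
    groups = np.zeros(n, dtype=int) if groups is None else np.asarray(groups)
    nn_idx = nearest_neighbor_pairs(ccf_xyz, groups)
    has_nn = nn_idx >= 0
    if not has_nn.any():
        raise ValueError("no group has >= 2 neurons")
    observed = float(np.mean(np.abs(values[has_nn] - values[nn_idx[has_nn]])))

    rng = np.random.default_rng(seed)
    shuffled = np.broadcast_to(values, (n_shuffles, n)).copy()
    for g in np.unique(groups):
        members = np.flatnonzero(groups == g)
        if len(members) >= 2:
            shuffled[:, members] = rng.permuted(shuffled[:, members], axis=1)
    null = np.mean(np.abs(shuffled[:, has_nn] - shuffled[:, nn_idx[has_nn]]), axis=1)
    p = (float((null <= observed).sum()) + 1.0) / (n_shuffles + 1.0)
    return ShuffleTestResult(statistic=observed, p_value=p, null=null,
                             n_groups=len(np.unique(groups)))


def neighbor_difference_cdf(values: np.ndarray, ccf_xyz: np.ndarray,
                            groups: np.ndarray | None = None,
                            ) -> tuple[np.ndarray, np.ndarray]:
    """Empirical CDF of |nearest-neighbor value differences| (for display)."""
    values = np.asarray(values, dtype=float)
    nn_idx = nearest_neighbor_pairs(ccf_xyz, groups)
    has_nn = nn_idx >= 0
    diffs = np.sort(np.abs(values[has_nn] - values[nn_idx[has_nn]]))
    cdf = np.arange(1, len(diffs) + 1) / len(diffs)
    return diffs, cdf


def voxel_map(values: np.ndarray, ccf_xyz: np.ndarray, voxel_size: float,
              statistic: str = "mean", plane: tuple[int, int] = (0, 1),
              median_filter: int = 3) -> pd.DataFrame:
    """Projected 2-D voxel map of a per-neuron statistic.

    Neurons are binned on the two ``plane`` axes (the third dimension spans
    the brain); the per-voxel statistic is ``mean``, ``fraction_positive``
    or ``fraction_negative``. A median filter over ``median_filter`` x
    ``median_filter`` voxel windows (ignoring empty voxels) smooths the map
    for display when the window is > 1. Returns a tidy table with voxel
    centers, occupancy, and raw + filtered statistic values.
    """
    values = np.asarray(values, dtype=float)
    xyz = np.asarray(ccf_xyz, dtype=float)[:, list(plane)]
    cells = np.floor(xyz / voxel_size).astype(int)
    cmin = cells.min(axis=0)
    cells = cells - cmin
    shape = tuple(cells.max(axis=0) + 1)
    flat = cells[:, 0] * shape[1] + cells[:, 1]
    counts = np.bincount(flat, minlength=shape[0] * shape[1]).reshape(shape)
    if statistic == "mean":
        w = values
    elif statistic == "fraction_positive":
        w = (values > 0).astype(float)
    elif statistic == "fraction_negative":
        w = (values < 0).astype(float)
    else:
        raise ValueError(f"unknown statistic {statistic!r}")
    agg = np.bincount(flat, weights=w, minlength=shape[0] * shape[1]).reshape(shape)
    grid = np.where(counts > 0, agg / np.maximum(counts, 1), np.nan)

    filtered = grid.copy()
    if median_filter and median_filter > 1:
        r = median_filter // 2
        padded = np.pad(grid, r, constant_values=np.nan)
        filtered = np.full(shape, np.nan)
        for i in range(shape[0]):
            for j in range(shape[1]):
                if counts[i, j] == 0:
                    continue
                window = padded[i:i + median_filter, j:j + median_filter]
                filtered[i, j] = np.nanmedian(window)

    ii, jj = np.nonzero(counts)
    return pd.DataFrame({
        "center_0": (ii + cmin[0] + 0.5) * voxel_size,
        "center_1": (jj + cmin[1] + 0.5) * voxel_size,
        "n_neurons": counts[ii, jj],
        "value": grid[ii, jj],
        "value_filtered": filtered[ii, jj],
    })
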