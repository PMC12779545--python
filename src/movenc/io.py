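"""Session container I/O: HDF5 bundles and DeepLabCut-style marker CSV."""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .synth import BODY_PARTS, GroundTruth, NeuronSpec, SessionBundle, SimConfig


def _config_to_json(config: SimConfig) -> str:
    d = dataclasses.asdict(config)
    d["neuron_specs"] = [dataclasses.asdict(s) for s in config.neuron_specs]
    return json.dumps(d)


def _config_from_json(payload: str) -> SimConfig:
    d = json.loads(payload)
    specs = tuple(NeuronSpec(**{**s, "ccf_xyz": tuple(s["ccf_xyz"])}) for s in d.pop("neuron_specs"))
    d["epoch_durations"] = tuple(d["epoch_durations"])
    d["frame_size"] = tuple(d["frame_size"])
    d["bias_parts"] = tuple(d["bias_parts"])
    return SimConfig(neuron_specs=specs, **d)


def save_session(path: str | Path, bundle: SessionBundle) -> None:
    """Write one session (frames, markers, spikes, trials, ground truth) to HDF5.

    The simulation config is stored as an attribute and, for convenience,
    as a JSON sidecar next to the container.
    """
    path = Path(path)
    path.with_suffix(path.suffix + ".json").write_text(_config_to_json(bundle.config))
    with h5py.File(path, "w") as f:
        f.attrs["config_json"] = _config_to_json(bundle.config)
        if bundle.frames is not None:
            f.create_dataset("frames", data=bundle.frames, compression="gzip", shuffle=True)
        f.create_dataset("latents", data=bundle.latents.astype(np.float32))
        f.create_dataset("markers", data=bundle.markers.to_numpy())
        grp = f.create_group("spikes")
        for i, st in enumerate(bundle.spike_times):
            grp.create_dataset(str(i), data=st)
        tr = f.create_group("trials")
        for col in bundle.trials.columns:
            vals = bundle.trials[col].to_numpy()
            if vals.dtype == object:
                vals = vals.astype("S")
            tr.create_dataset(col, data=vals)
        gt = f.create_group("truth")
        gt.create_dataset("tongue_visible", data=bundle.truth.tongue_visible)
        gt.create_dataset("choice", data=bundle.truth.choice)
        gt.create_dataset("correct", data=bundle.truth.correct)
        gt.create_dataset("move_dir", data=bundle.truth.move_dir)
        if bundle.truth.rates is not None:
            gt.create_dataset("rates", data=bundle.truth.rates, compression="gzip")


def load_session(path: str | Path) -> SessionBundle:
    """Read a session bundle written by :func:`save_session`."""
    with h5py.File(path, "r") as f:
        config = _config_from_json(f.attrs["config_json"])
        frames = f["frames"][()] if "frames" in f else None
        latents = f["latents"][()].astype(np.float64)
        cols = pd.MultiIndex.from_product([BODY_PARTS, ("x", "y", "likelihood")],
                                          names=["bodypart", "coord"])
        markers = pd.DataFrame(f["markers"][()], columns=cols)
        markers.index.name = "frame"
        spikes = [f["spikes"][str(i)][()] for i in range(len(f["spikes"]))]
        trials = {}
        for col, ds in f["trials"].items():
            vals = ds[()]
            if vals.dtype.kind == "S":
                vals = vals.astype(str)
            trials[col] = vals
        trials = pd.DataFrame(trials)
        order = ["trial_id", "start_time", "sample_on", "sample_off", "go_cue",
                 "response_off", "lick_direction", "correct", "photoinhibition",
                 "free_water", "early_lick", "ignored"]
        trials = trials[[c for c in order if c in trials.columns]]
        gt = f["truth"]
        truth = GroundTruth(
            latents=latents,
            tongue_visible=gt["tongue_visible"][()].astype(bool),
            choice=gt["choice"][()],
            correct=gt["correct"][()].astype(bool),
            move_dir=gt["move_dir"][()],
            neuron_specs=config.neuron_specs,
            rates=gt["rates"][()] if "rates" in gt else None,
        )
    meta = pd.DataFrame(
        {
            "unit_id": np.arange(len(config.neuron_specs)),
            "region": [s.region_label for s in config.neuron_specs],
            "ccf_x": [s.ccf_xyz[0] for s in config.neuron_specs],
            "ccf_y": [s.ccf_xyz[1] for s in config.neuron_specs],
            "ccf_z": [s.ccf_xyz[2] for s in config.neuron_specs],
            "tuning_type": [s.tuning_type for s in config.neuron_specs],
        }
    )
    return SessionBundle(config=config, trials=trials, latents=latents, frames=frames,
                         markers=markers, spike_times=spikes, neuron_meta=meta, truth=truth)


def write_dlc_csv(path: str | Path, markers: pd.DataFrame, scorer: str = "movenc") -> None:
    """Write markers in the DeepLabCut wide CSV layout (scorer/bodyparts/coords)."""
    df = markers.copy()
    df.columns = pd.MultiIndex.from_tuples(
        [(scorer, part, coord) for part, coord in df.columns],
        names=["scorer", "bodyparts", "coords"],
    )
    df.to_csv(path)


def read_dlc_csv(path: str | Path) -> pd.DataFrame:
    """Read a DeepLabCut wide CSV into the (bodypart, coord) marker layout."""
    df = pd.read_csv(path, header=[0, 1, 2], index_col=0)
    df.columns = pd.MultiIndex.from_tuples(
        [(part, coord) for _, part, coord in df.columns],
        names=["bodypart", "coord"],
    )
    df.index.name = "frame"
    return df
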