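"""Synthetic sessions for the video-to-spikes pipeline.

A session emulates a head-fixed mouse performing a delayed-response licking
task: each trial has a pre-sample baseline, a sample epoch in which an
auditory cue instructs the lick direction, a delay epoch in which the animal
must withhold licking, and a response epoch with rhythmic directional licking.

The generator produces, on a common frame grid (3.4 ms nominal frame period):

* smooth latent 2-D trajectories for jaw, nose, tongue and paw
  (Ornstein-Uhlenbeck baseline plus epoch-gated sinusoidal licking, with an
  optional choice-biased "uninstructed movement" offset in sample/delay),
* small rendered grayscale frames (isotropic Gaussian blobs at the latent
  positions on a fixed background, plus pixel noise),
* DeepLabCut-style marker tracks (latents + noise + occasional large
  outliers, with the tongue occluded outside licking bouts),
* inhomogeneous-Poisson spike trains whose rates are (possibly nonlinear)
  functions of the latents at per-neuron lags, plus choice-dependent offsets,

together with full ground truth for parameter-recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._util import substream

BODY_PARTS = ("jaw", "nose", "tongue", "paw")

TUNING_TYPES = (
    "movement_linear",
    "movement_nonlinear",
    "choice_only",
    "mixed",
    "cue_driven",
    "untuned",
)


@dataclass(frozen=True)
class NeuronSpec:
    """Generative tuning of one synthetic neuron.

    ``true_lag`` is in seconds with the motor convention: positive lag means
    the activity *leads* the movement, i.e. the rate at time t follows the
    latent at time t + true_lag.
    """

    tuning_type: str = "movement_linear"
    baseline_rate: float = 8.0          # spikes/s
    coupling_gain: float = 0.0          # spikes/s per latent unit (or cue amplitude)
    true_lag: float = 0.0               # s; positive = activity leads movement
    choice_weight: float = 0.0          # spikes/s added on lick-right trials
    coupling_part: str = "jaw"
    coupling_axis: int = 1              # 0 = horizontal, 1 = vertical (height)
    nonlinearity: str = "tanh"          # for movement_nonlinear: "tanh" | "square"
    squash_scale: float = 2.0           # latent units; scale of the nonlinearity
    ccf_xyz: tuple[float, float, float] = (0.0, 0.0, 0.0)  # micrometres
    region_label: str = "synthetic"

    def __post_init__(self):
        if self.tuning_type not in TUNING_TYPES:
            raise ValueError(f"unknown tuning_type {self.tuning_type!r}")
        if self.baseline_rate < 0:
            raise ValueError("baseline_rate must be >= 0")
        if not np.all(np.isfinite(self.ccf_xyz)):
            raise ValueError("ccf_xyz must be finite")


@dataclass(frozen=True)
class SimConfig:
    """Session-level simulation parameters.

    Defaults follow the task structure of the delayed-response paradigm:
    300 Hz video treated as a 3.4 ms frame period, a 1.2 s delay epoch and
    120 x 112 pixel frames. Epoch durations are snapped to the frame grid.
    """

    n_trials: int = 200
    # (pre_sample, sample, delay, response) in seconds
    epoch_durations: tuple[float, float, float, float] = (0.5, 1.15, 1.2, 1.5)
    inter_trial_interval: float = 0.2
    frame_period: float = 0.0034
    frame_size: tuple[int, int] = (120, 112)   # (height, width)
    neuron_specs: tuple[NeuronSpec, ...] = ()
    # latent movement model
    lick_freq: float = 7.0          # Hz, licking rhythm
    lick_amplitude: float = 3.0     # px, jaw/tongue oscillation
    choice_bias: float = 0.0        # px, uninstructed-movement offset in sample/delay
    bias_parts: tuple[str, ...] = ("jaw",)
    move_consistency: float = 0.7   # P(uninstructed movement direction == choice)
    ou_timescale: float = 0.15      # s, smoothness of the OU baseline wander
    ou_sd: float = 1.0              # px, stationary SD of the OU wander
    # rendering
    blob_sigma: float = 3.0         # px
    background_amplitude: float = 0.15
    pixel_noise_sd: float = 0.02
    # markers
    marker_noise_sd: float = 0.5    # px
    outlier_rate: float = 0.001     # per frame and body part
    # trials
    choice_balance: float = 0.5     # fraction lick-right
    error_rate: float = 0.1         # fraction incorrect trials
    seed: int = 0
    store_truth_rates: bool = True

    def __post_init__(self):
        if any(d <= 0 for d in self.epoch_durations):
            raise ValueError("epoch durations must be > 0")
        if self.frame_period <= 0:
            raise ValueError("frame_period must be > 0")
        if not 0.0 <= self.choice_balance <= 1.0:
            raise ValueError("choice_balance must be in [0, 1]")
        if not 0.0 <= self.error_rate < 0.5:
            raise ValueError("error_rate must be in [0, 0.5)")
        if self.inter_trial_interval < 0:
            raise ValueError("inter_trial_interval must be >= 0")
        # snap epoch boundaries onto the frame grid
        snapped = tuple(
            round(d / self.frame_period) * self.frame_period for d in self.epoch_durations
        )
        object.__setattr__(self, "epoch_durations", snapped)
        object.__setattr__(
            self,
            "inter_trial_interval",
            round(self.inter_trial_interval / self.frame_period) * self.frame_period,
        )

    # --- derived geometry -------------------------------------------------
    @property
    def trial_duration(self) -> float:
        return float(sum(self.epoch_durations))

    @property
    def trial_period(self) -> float:
        return self.trial_duration + self.inter_trial_interval

    @property
    def n_frames(self) -> int:
        return int(round(self.n_trials * self.trial_period / self.frame_period))

    def frame_times(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.frame_period

    def base_positions(self) -> dict[str, np.ndarray]:
        """Resting (x, y) pixel position of each body part."""
        h, w = self.frame_size
        return {
            "jaw": np.array([0.50 * w, 0.65 * h]),
            "nose": np.array([0.50 * w, 0.25 * h]),
            "tongue": np.array([0.50 * w, 0.85 * h]),
            "paw": np.array([0.22 * w, 0.80 * h]),
        }


@dataclass
class GroundTruth:
    """Everything the generator knows and the pipeline must recover."""

    latents: np.ndarray                 # (n_frames, n_parts, 2) noiseless positions
    tongue_visible: np.ndarray          # (n_frames,) bool
    choice: np.ndarray                  # (n_trials,) +1 lick-right / -1 lick-left
    correct: np.ndarray                 # (n_trials,) bool
    move_dir: np.ndarray                # (n_trials,) direction of uninstructed bias
    neuron_specs: tuple[NeuronSpec, ...]
    rates: np.ndarray | None = None     # (n_neurons, n_frames) noiseless spikes/s


@dataclass
class SessionBundle:
    """All raw inputs of one synthetic session, plus provenance."""

    config: SimConfig
    trials: pd.DataFrame
    latents: np.ndarray
    frames: np.ndarray | None
    markers: pd.DataFrame
    spike_times: list[np.ndarray]
    neuron_meta: pd.DataFrame
    truth: GroundTruth


# ---------------------------------------------------------------------------
# latent trajectories and trial table
# ---------------------------------------------------------------------------

def _ou_process(rng: np.random.Generator, n: int, dt: float, tau: float, sd: float,
                shape: tuple[int, ...]) -> np.ndarray:
    """Stationary Ornstein-Uhlenbeck paths, exact discretization."""
    a = np.exp(-dt / tau)
    noise_sd = sd * np.sqrt(1.0 - a * a)
    x = np.empty((n,) + shape, dtype=np.float64)
    x[0] = rng.normal(0.0, sd, size=shape)
    eps = rng.normal(0.0, noise_sd, size=(n - 1,) + shape)
    for i in range(1, n):
        x[i] = a * x[i - 1] + eps[i - 1]
    return x


def simulate_latents(config: SimConfig):
    """Latent body-part trajectories plus the trial table.

    Returns ``(latents, trials, aux)`` where ``latents`` is
    (n_frames, n_parts, 2) in pixels (parts ordered as :data:`BODY_PARTS`),
    ``trials`` is the trial table with epoch boundaries on the frame grid,
    and ``aux`` carries the tongue-visibility mask and per-trial uninstructed
    movement direction.
    """
    rng = substream(config.seed, "latents")
    n = config.n_frames
    dt = config.frame_period
    t = config.frame_times()
    n_parts = len(BODY_PARTS)

    # trial table ----------------------------------------------------------
    pre, samp, delay, resp = config.epoch_durations
    starts = np.arange(config.n_trials) * config.trial_period
    instruct = np.where(rng.random(config.n_trials) < config.choice_balance, 1, -1)
    correct = rng.random(config.n_trials) >= config.error_rate
    choice = np.where(correct, instruct, -instruct)
    move_dir = np.where(
        rng.random(config.n_trials) < config.move_consistency, choice, -choice
    )
    trials = pd.DataFrame(
        {
            "trial_id": np.arange(config.n_trials),
            "start_time": starts,
            "sample_on": starts + pre,
            "sample_off": starts + pre + samp,
            "go_cue": starts + pre + samp + delay,
            "response_off": starts + pre + samp + delay + resp,
            "lick_direction": np.where(choice > 0, "right", "left"),
            "correct": correct,
            "photoinhibition": False,
            "free_water": False,
            "early_lick": False,
            "ignored": False,
        }
    )

    # smooth OU wander around the resting positions ------------------------
    base = config.base_positions()
    lat = _ou_process(rng, n, dt, config.ou_timescale, config.ou_sd, (n_parts, 2))
    for p, part in enumerate(BODY_PARTS):
        lat[:, p, :] += base[part]

    # epoch masks on the frame grid ---------------------------------------
    phase = np.mod(t, config.trial_period)
    trial_idx = np.minimum((t / config.trial_period).astype(int), config.n_trials - 1)
    in_sample = (phase >= pre) & (phase < pre + samp)
    in_delay = (phase >= pre + samp) & (phase < pre + samp + delay)
    in_response = (phase >= pre + samp + delay) & (phase < config.trial_duration)

    choice_f = choice[trial_idx].astype(float)
    move_f = move_dir[trial_idx].astype(float)

    # rhythmic licking in the response epoch -------------------------------
    lick_phase = rng.uniform(0, 2 * np.pi, config.n_trials)[trial_idx]
    amp_jitter = (1.0 + 0.15 * rng.standard_normal(config.n_trials))[trial_idx]
    osc = np.sin(2 * np.pi * config.lick_freq * (phase - (pre + samp + delay)) + lick_phase)
    amp = config.lick_amplitude * amp_jitter * in_response
    jaw_i = BODY_PARTS.index("jaw")
    tongue_i = BODY_PARTS.index("tongue")
    # vertical jaw oscillation, lateral component signed by lick direction
    lat[:, jaw_i, 1] += amp * osc
    lat[:, jaw_i, 0] += choice_f * amp * (0.6 + 0.35 * osc)
    # tongue protrudes on the positive half of the lick cycle
    protrude = np.maximum(osc, 0.0)
    lat[:, tongue_i, 1] += 1.2 * amp * protrude
    lat[:, tongue_i, 0] += choice_f * 0.8 * amp * protrude
    tongue_visible = (amp * protrude) > (0.2 * config.lick_amplitude)

    # choice-biased uninstructed movements in sample + delay ---------------
    if config.choice_bias != 0.0:
        gate = (in_sample | in_delay).astype(float)
        # smooth onset over ~100 ms so markers stay physically plausible
        ramp_frames = max(int(round(0.1 / dt)), 1)
        kernel = np.ones(ramp_frames) / ramp_frames
        gate = np.convolve(gate, kernel, mode="same")
        for part in config.bias_parts:
            p = BODY_PARTS.index(part)
            lat[:, p, 0] += config.choice_bias * move_f * gate

    aux = {
        "tongue_visible": tongue_visible,
        "move_dir": move_dir,
        "in_sample": in_sample,
        "in_delay": in_delay,
        "in_response": in_response,
        "trial_index_of_frame": trial_idx,
        "choice": choice,
    }
    return lat, trials, aux


# ---------------------------------------------------------------------------
# rendering and markers
# ---------------------------------------------------------------------------

_BLOB_AMPLITUDE = {"jaw": 0.8, "nose": 0.7, "tongue": 0.9, "paw": 0.6}


def render_frames(latents: np.ndarray, config: SimConfig,
                  tongue_visible: np.ndarray | None = None) -> tuple[np.ndarray, dict]:
    """Render grayscale frames from latent positions.

    Each frame is a deterministic function of that frame's latents — isotropic
    Gaussian blobs on a fixed smooth background — plus i.i.d. pixel noise.
    Latents outside the frame are clipped (count reported in the info dict).
    """
    h, w = config.frame_size
    n = latents.shape[0]
    rng_bg = substream(config.seed, "background")
    rng_px = substream(config.seed, "frames")

    # fixed smooth background: low-frequency random surface
    yy, xx = np.mgrid[0:h, 0:w].astype(np.float32)
    bg = np.zeros((h, w), dtype=np.float32)
    for _ in range(3):
        fx, fy = rng_bg.uniform(0.5, 2.0, 2)
        px, py = rng_bg.uniform(0, 2 * np.pi, 2)
        bg += np.sin(2 * np.pi * fx * xx / w + px).astype(np.float32) * \
              np.sin(2 * np.pi * fy * yy / h + py).astype(np.float32)
    bg = config.background_amplitude * (bg - bg.min()) / max(float(np.ptp(bg)), 1e-9)

    pos = latents.copy()
    lo = np.array([0.0, 0.0])
    hi = np.array([w - 1.0, h - 1.0])
    clipped = int(np.sum((pos < lo) | (pos > hi)))
    pos = np.clip(pos, lo, hi)

    frames = np.broadcast_to(bg, (n, h, w)).copy()
    inv2s2 = 1.0 / (2.0 * config.blob_sigma**2)
    vis = np.ones(n, dtype=bool) if tongue_visible is None else tongue_visible
    for p, part in enumerate(BODY_PARTS):
        ampl = _BLOB_AMPLITUDE[part]
        cx = pos[:, p, 0][:, None, None].astype(np.float32)
        cy = pos[:, p, 1][:, None, None].astype(np.float32)
        blob = np.exp(-((xx - cx) ** 2 + (yy - cy) ** 2) * inv2s2)
        if part == "tongue":
            blob *= vis[:, None, None]
        frames += ampl * blob
    if config.pixel_noise_sd > 0:
        frames += rng_px.normal(0.0, config.pixel_noise_sd, frames.shape).astype(np.float32)
    np.clip(frames, 0.0, None, out=frames)
    frames /= max(frames.max(), 1.0)
    return frames.astype(np.float32), {"n_clipped": clipped}


def emit_markers(latents: np.ndarray, config: SimConfig,
                 tongue_visible: np.ndarray | None = None) -> pd.DataFrame:
    """DeepLabCut-style marker table: latents + noise + occasional outliers.

    Columns are a (bodypart, {x, y, likelihood}) MultiIndex. With probability
    ``outlier_rate`` a frame's marker jumps by at least 8 sigma of the
    frame-to-frame velocity. Occluded tongue frames are placed at the resting
    mouth position with low likelihood.
    """
    rng = substream(config.seed, "markers")
    n, n_parts, _ = latents.shape
    pos = latents + rng.normal(0.0, config.marker_noise_sd, latents.shape)
    likelihood = np.full((n, n_parts), 0.99)

    if tongue_visible is not None:
        ti = BODY_PARTS.index("tongue")
        mouth = config.base_positions()["tongue"] - np.array([0.0, 2.0])
        occluded = ~tongue_visible
        pos[occluded, ti, :] = mouth + rng.normal(0.0, 0.2, (int(occluded.sum()), 2))
        likelihood[occluded, ti] = 0.05

    if config.outlier_rate > 0:
        # jump size referenced to the marker (latent + noise) velocity scale
        vel_sd = np.sqrt(np.std(np.diff(latents, axis=0), axis=0) ** 2
                         + 2.0 * config.marker_noise_sd**2)  # (n_parts, 2)
        jump = 8.0 * np.maximum(np.linalg.norm(vel_sd, axis=1), 1e-6)
        for p in range(n_parts):
            hit = rng.random(n) < config.outlier_rate
            k = int(hit.sum())
            if k:
                ang = rng.uniform(0, 2 * np.pi, k)
                step = jump[p] * rng.uniform(1.0, 2.0, k)
                pos[hit, p, 0] += step * np.cos(ang)
                pos[hit, p, 1] += step * np.sin(ang)

    cols = pd.MultiIndex.from_product([BODY_PARTS, ("x", "y", "likelihood")],
                                      names=["bodypart", "coord"])
    out = np.empty((n, n_parts * 3))
    out[:, 0::3] = pos[:, :, 0]
    out[:, 1::3] = pos[:, :, 1]
    out[:, 2::3] = likelihood
    df = pd.DataFrame(out, columns=cols)
    df.index.name = "frame"
    return df


# ---------------------------------------------------------------------------
# spikes
# ---------------------------------------------------------------------------

def _coupling_signal(latents: np.ndarray, spec: NeuronSpec, config: SimConfig) -> np.ndarray:
    p = BODY_PARTS.index(spec.coupling_part)
    base = config.base_positions()[spec.coupling_part][spec.coupling_axis]
    return latents[:, p, spec.coupling_axis] - base


def _apply_nonlinearity(s: np.ndarray, spec: NeuronSpec) -> np.ndarray:
    if spec.tuning_type == "movement_linear" or spec.nonlinearity == "identity":
        return s
    if spec.nonlinearity == "tanh":
        return spec.squash_scale * np.tanh(s / spec.squash_scale)
    if spec.nonlinearity == "square":
        return (s * s) / spec.squash_scale
    raise ValueError(f"unknown nonlinearity {spec.nonlinearity!r}")


def noiseless_rate(latents: np.ndarray, spec: NeuronSpec, config: SimConfig,
                   aux: dict) -> np.ndarray:
    """Per-frame Poisson intensity (spikes/s) for one neuron, half-wave rectified."""
    n = latents.shape[0]
    dt = config.frame_period
    rate = np.full(n, spec.baseline_rate, dtype=np.float64)

    if spec.tuning_type in ("movement_linear", "movement_nonlinear", "mixed"):
        s = _coupling_signal(latents, spec, config)
        shift = int(round(spec.true_lag / dt))
        # rate(t) = g(latent(t + true_lag)): positive lag = activity leads movement
        s = np.roll(s, -shift)
        if shift > 0:
            s[-shift:] = s[-shift - 1] if shift < n else 0.0
        elif shift < 0:
            s[:-shift] = s[-shift]
        rate += spec.coupling_gain * _apply_nonlinearity(s, spec)
    elif spec.tuning_type == "cue_driven":
        rate += spec.coupling_gain * aux["in_sample"].astype(float)

    if spec.tuning_type in ("choice_only", "mixed") and spec.choice_weight != 0.0:
        # choice signal develops from stimulus onset through the response
        trial_idx = aux["trial_index_of_frame"]
        lick_right = aux["choice"][trial_idx] > 0
        active = aux["in_sample"] | aux["in_delay"] | aux["in_response"]
        rate += spec.choice_weight * (lick_right & active)

    np.clip(rate, 0.0, None, out=rate)
    return rate


def emit_spikes(latents: np.ndarray, neuron_specs, config: SimConfig, aux: dict,
                ) -> tuple[list[np.ndarray], GroundTruth]:
    """Inhomogeneous Poisson spike trains for every neuron, plus ground truth."""
    rng = substream(config.seed, "spikes")
    dt = config.frame_period
    t = config.frame_times()
    spike_times: list[np.ndarray] = []
    rates = (
        np.empty((len(neuron_specs), latents.shape[0]), dtype=np.float32)
        if config.store_truth_rates else None
    )
    for i, spec in enumerate(neuron_specs):
        rate = noiseless_rate(latents, spec, config, aux)
        if rates is not None:
            rates[i] = rate
        counts = rng.poisson(rate * dt)
        idx = np.repeat(np.arange(latents.shape[0]), counts)
        times = t[idx] + rng.uniform(0.0, dt, idx.size)
        spike_times.append(np.sort(times))

    truth = GroundTruth(
        latents=latents,
        tongue_visible=aux["tongue_visible"],
        choice=aux["choice"],
        correct=np.asarray(aux.get("correct", np.ones_like(aux["choice"], bool))),
        move_dir=aux["move_dir"],
        neuron_specs=tuple(neuron_specs),
        rates=rates,
    )
    return spike_times, truth


# ---------------------------------------------------------------------------
# whole-session convenience
# ---------------------------------------------------------------------------

def simulate_session(config: SimConfig, render: bool = True) -> SessionBundle:
    """Generate a full session: latents, frames, markers, spikes, metadata."""
    latents, trials, aux = simulate_latents(config)
    aux["correct"] = trials["correct"].to_numpy()
    frames = None
    if render:
        frames, _ = render_frames(latents, config, aux["tongue_visible"])
    markers = emit_markers(latents, config, aux["tongue_visible"])
    spikes, truth = emit_spikes(latents, config.neuron_specs, config, aux)
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
    return SessionBundle(
        config=config,
        trials=trials,
        latents=latents,
        frames=frames,
        markers=markers,
        spike_times=spikes,
        neuron_meta=meta,
        truth=truth,
    )


def desk_config(**overrides) -> SimConfig:
    """Scaled-down session profile used throughout the test suite.

    Small frames and shortened epochs keep end-to-end runs tractable on one
    CPU while preserving the task structure (four epochs on the 3.4 ms frame
    grid, rhythmic response-epoch licking, delay-epoch choice bias).
    """
    params = dict(
        epoch_durations=(0.3, 0.45, 0.6, 0.75),
        inter_trial_interval=0.1,
        frame_size=(16, 16),
        blob_sigma=2.4,
        lick_amplitude=2.0,
        ou_sd=1.0,
        ou_timescale=0.15,
        marker_noise_sd=0.3,
        outlier_rate=0.0,
    )
    params.update(overrides)
    return SimConfig(**params)


def population(n: int, tuning_type: str, rng: np.random.Generator | None = None,
               region_label: str = "synthetic", **spec_kw) -> list[NeuronSpec]:
    """Homogeneous neuron population with random CCF coordinates (µm)."""
    rng = rng or np.random.default_rng(0)
    specs = []
    for _ in range(n):
        xyz = tuple(rng.uniform(0.0, 2000.0, 3))
        specs.append(
            NeuronSpec(tuning_type=tuning_type, ccf_xyz=xyz,
                       region_label=region_label, **spec_kw)
        )
    return specs
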