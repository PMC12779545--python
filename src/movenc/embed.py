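"""Convolutional-autoencoder embedding of behavioral video frames.

Each grayscale frame is compressed through a convolutional encoder into a
16-dimensional code and reconstructed by a single fully connected linear
decoder. The encoder is an initial 3x3 convolution (16 channels, ReLU,
2x2 max pool) followed by two residual blocks of four 3x3 convolutions
(16 then 32 channels), each block ending in a kernel-4 max pool, then two
fully connected layers (flatten -> 128 -> 16). For the reference 120x112
input the flattened convolutional output has length 288.

The time series of the 16-d code is the "embedding" predictor used by the
encoding, temporal-offset and choice-decoding analyses.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from . import nn

EMBED_DIM = 16


def _res_block(in_ch: int, out_ch: int, rng: np.random.Generator) -> nn.Residual:
    layers: list[nn.Layer] = []
    ch = in_ch
    for _ in range(4):
        layers += [nn.Conv2d(ch, out_ch, 3, rng), nn.ReLU()]
        ch = out_ch
    skip = nn.Conv2d(in_ch, out_ch, 1, rng) if in_ch != out_ch else None
    return nn.Residual(nn.Sequential(*layers), skip)


def _block_pool(dim: int) -> int:
    """Kernel of the max pool ending a residual block.

    4 at the reference geometry (120 x 112 -> 60 -> 15 -> 3, flatten 288);
    on small frames the kernel drops to 2 so the terminal grid keeps at
    least ~2 positions per side and the code retains spatial information.
    """
    return 4 if dim >= 12 else 2


class ConvAutoencoder:
    """Session-specific frame autoencoder with a linear decoder."""

    def __init__(self, frame_size: tuple[int, int], embed_dim: int = EMBED_DIM,
                 seed: int = 0):
        rng = np.random.default_rng(seed)
        self.frame_size = tuple(frame_size)
        self.embed_dim = embed_dim
        d = min(frame_size) // 2
        p1 = _block_pool(d)
        p2 = _block_pool(d // p1)
        self.conv = nn.Sequential(
            nn.Conv2d(1, 16, 3, rng), nn.ReLU(), nn.MaxPool2d(2),
            _res_block(16, 16, rng), nn.MaxPool2d(p1),
            _res_block(16, 32, rng), nn.MaxPool2d(p2),
            nn.Flatten(),
        )
        h, w = self.frame_size
        self.flat_dim = int(self.conv.forward(np.zeros((1, 1, h, w), np.float32)).shape[1])
        # mean training frame, subtracted before encoding (set during training)
        self.frame_mean = np.zeros((h, w), dtype=np.float32)
        self.head = nn.Sequential(
            nn.Linear(self.flat_dim, 128, rng), nn.ReLU(),
            nn.Linear(128, embed_dim, rng),
        )
        self.decoder = nn.Linear(embed_dim, h * w, rng)

    # ------------------------------------------------------------------
    def params(self):
        return self.conv.params() + self.head.params() + self.decoder.params()

    def set_train(self, mode: bool):
        for part in (self.conv, self.head, self.decoder):
            part.set_train(mode)

    def encode_batch(self, x: np.ndarray) -> np.ndarray:
        """(N, H, W) frames -> (N, embed_dim) codes."""
        return self.head.forward(self.conv.forward(x[:, None, :, :]))

    def forward(self, x: np.ndarray) -> np.ndarray:
        """Full autoencoder pass: frames -> reconstructed flat frames."""
        return self.decoder.forward(self.encode_batch(x))

    def backward(self, grad: np.ndarray) -> None:
        g = self.decoder.backward(grad)
        g = self.head.backward(g)
        self.conv.backward(g)


@dataclass
class TrainTrace:
    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    best_epoch: int = -1


def train_autoencoder(frames: np.ndarray, epochs: int = 15, batch_size: int = 64,
                      lr: float = 1e-3, val_fraction: float = 0.1, patience: int = 3,
                      seed: int = 0, embed_dim: int = EMBED_DIM,
                      ) -> tuple[ConvAutoencoder, TrainTrace]:
    """Train a session autoencoder by minimizing reconstruction MSE.

    Frames are normalized to [0, 1]; a held-out validation split drives early
    stopping. Deterministic for a fixed seed. Returns the model at the best
    validation epoch together with the loss trace.
    """
    frames = np.asarray(frames, dtype=np.float32)
    if frames.ndim != 3:
        raise ValueError("frames must be (n_frames, height, width)")
    if len(frames) < 1000:
        warnings.warn(f"training on only {len(frames)} frames; the embedding "
                      "is intended for >= 1000 frames")
    fmax = float(frames.max())
    if fmax > 1.0:
        frames = frames / fmax

    rng = np.random.default_rng(seed)
    n = len(frames)
    perm = rng.permutation(n)
    n_val = max(int(round(val_fraction * n)), 1)
    val_idx, train_idx = perm[:n_val], perm[n_val:]

    model = ConvAutoencoder(frames.shape[1:], embed_dim=embed_dim, seed=seed)
    model.frame_mean = frames[train_idx].mean(axis=0)
    frames = frames - model.frame_mean
    target = frames.reshape(n, -1)
    model.set_train(True)
    opt = nn.Adam(model.params(), lr=lr)
    trace = TrainTrace()
    best_val = np.inf
    best_state = None
    bad_epochs = 0

    for epoch in range(epochs):
        # step decay: drop the learning rate late in training
        opt.lr = lr * (0.3 if epoch >= int(0.6 * epochs) else 1.0) \
            * (0.3 if epoch >= int(0.85 * epochs) else 1.0)
        order = rng.permutation(train_idx)
        losses = []
        for start in range(0, len(order), batch_size):
            idx = order[start:start + batch_size]
            opt.zero_grad()
            pred = model.forward(frames[idx])
            loss, grad = nn.mse_loss(pred, target[idx])
            if not np.isfinite(loss):
                raise RuntimeError(f"autoencoder loss diverged at epoch {epoch}")
            model.backward(grad)
            opt.step()
            losses.append(loss)
        trace.train_loss.append(float(np.mean(losses)))

        model.set_train(False)
        val_pred = model.forward(frames[val_idx])
        val_loss = float(np.mean((val_pred - target[val_idx]) ** 2))
        model.set_train(True)
        trace.val_loss.append(val_loss)
        if val_loss < best_val - 1e-7:
            best_val = val_loss
            best_state = [p.v.copy() for p in model.params()]
            trace.best_epoch = epoch
            bad_epochs = 0
        else:
            bad_epochs += 1
            if bad_epochs >= patience:
                break

    if best_state is not None:
        for p, v in zip(model.params(), best_state):
            p.v[...] = v
    model.set_train(False)
    return model, trace


def encode(frames: np.ndarray, model: ConvAutoencoder, batch_size: int = 256,
           ) -> np.ndarray:
    """EmbeddingSeries: one ``embed_dim`` code per frame (pure in the frame)."""
    frames = np.asarray(frames, dtype=np.float32)
    fmax = float(frames.max())
    if fmax > 1.0:
        frames = frames / fmax
    model.set_train(False)
    out = np.empty((len(frames), model.embed_dim), dtype=np.float32)
    for start in range(0, len(frames), batch_size):
        chunk = frames[start:start + batch_size] - model.frame_mean
        out[start:start + batch_size] = model.encode_batch(chunk)
    return out
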