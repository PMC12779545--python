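"""Shared helpers: named RNG substreams and small numeric utilities."""

from __future__ import annotations

import hashlib

import numpy as np




def substream(seed: int, name: str) -> np.random.Generator:
    """Independent, reproducible RNG stream derived from a session seed.

    The same (seed, name) pair always yields the same stream, and different
    names give statistically independent streams, so e.g. markers can be
    regenerated without touching the spike stream.
    """
    digest = hashlib.sha256(name.encode()).digest()
    key = int.from_bytes(digest[:4], "little")
    return np.random.default_rng(np.random.SeedSequence(entropy=int(seed) & 0x7FFFFFFF, spawn_key=(key,)))


def mad_sd(x: np.ndarray) -> float:
    """Robust standard deviation via the median absolute deviation."""
    x = np.asarray(x, dtype=float)
    return 1.4826 * float(np.median(np.abs(x - np.median(x))))
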