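"""Shared helpers: deterministic sub-stream seeding and small validators."""

from __future__ import annotations

import zlib

import numpy as np


def stable_hash(label: object) -> int:
    """CRC32 of the string form of *label* — stable across runs and platforms."""
    return zlib.crc32(str(label).encode("utf-8"))


def substream(seed: int, *labels: object) -> np.random.Generator:
    """Derive an independent RNG stream from a base seed and a label path.

    Streams are keyed by hashed labels, so adding more transects or species
    to a simulation never perturbs the draws of existing ones.
    """
    key = [int(seed)] + [stable_hash(lab) for lab in labels]
    return np.random.default_rng(np.random.SeedSequence(key))


def check_square(d: np.ndarray) -> np.ndarray:
    d = np.asarray(d, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError(f"distance matrix must be square, got shape {d.shape}")
    if not np.allclose(d, d.T, atol=1e-10):
        raise ValueError("distance matrix must be symmetric")
    if not np.allclose(np.diag(d), 0.0, atol=1e-10):
        raise ValueError("distance matrix must have a zero diagonal")
    return d
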