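"""Shared numerics and reproducibility helpers."""

from __future__ import annotations

import logging
import zlib

import numpy as np
from scipy.special import expit, logit  # noqa: F401  (re-exported)

logger = logging.getLogger("finclock")


def stage_seed(master_seed: int, label: str) -> int:
    """Derive a stable per-stage seed (< 2**31) from a master seed and a label.

    The derivation is a CRC32 mix so the same (master, label) pair always maps
    to the same child seed, independent of execution order.
    """
    return (int(master_seed) ^ zlib.crc32(label.encode())) % (2**31 - 1)


def rng_for(master_seed: int, label: str) -> np.random.Generator:
    return np.random.default_rng(stage_seed(master_seed, label))


def as_float_array(x, name: str = "array") -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.size == 0:
        raise ValueError(f"{name} is empty")
    return arr
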