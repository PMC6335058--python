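"""Deterministic stream splitting for all randomness in the package.

Every stochastic stage derives its generator from a single master seed and a
short stage label, so stages can be re-run or re-ordered without perturbing
each other's streams.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["split_rng", "child_seed"]


def child_seed(seed: int, label: str) -> np.random.SeedSequence:
    """Seed sequence for a named stage, derived from the master seed."""
    key = zlib.crc32(label.encode("utf-8"))
    return np.random.SeedSequence(int(seed), spawn_key=(key,))


def split_rng(seed: int, label: str) -> np.random.Generator:
    """Generator for a named stage, derived from the master seed."""
    return np.random.default_rng(child_seed(seed, label))
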