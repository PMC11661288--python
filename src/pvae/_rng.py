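"""Seeded randomness helpers.

A single integer seed controls every stochastic component; per-purpose
generators are spawned deterministically from it so that adding a consumer
does not perturb the streams of existing ones.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["as_generator", "spawn"]


def as_generator(rng: int | np.random.Generator | None) -> np.random.Generator:
    """Coerce a seed into a Generator; Generator-like objects pass through."""
    if rng is None or isinstance(rng, (int, np.integer)):
        return np.random.default_rng(rng)
    return rng


def spawn(seed: int, key: str) -> np.random.Generator:
    """Derive an independent, reproducible stream named by ``key``."""
    h = zlib.crc32(key.encode("utf-8")) % (2 ** 31)  # stable across processes
    ss = np.random.SeedSequence([int(seed), int(h)])
    return np.random.default_rng(ss)
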