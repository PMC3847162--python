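"""Seeded sub-stream derivation.

Every stochastic stage draws from a named child of a single global seed, so
that stages are reproducible independently of each other and of call order.
"""

from __future__ import annotations

import zlib

import numpy as np


def substream(seed: int, name: str) -> np.random.Generator:
    """Return a Generator for the named sub-stream of ``seed``.

    The sub-stream key is a CRC32 of ``name``, so the mapping is stable
    across sessions and platforms.
    """
    key = zlib.crc32(name.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(key,)))


def substream_seed(seed: int, name: str) -> int:
    """A plain integer seed (< 2**31) derived from the named sub-stream."""
    key = zlib.crc32(name.encode("utf-8"))
    state = np.random.SeedSequence(seed, spawn_key=(key,)).generate_state(1)[0]
    return int(state % (2**31))
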