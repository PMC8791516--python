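"""Seed-substream helpers: one top-level seed, named independent streams."""

from __future__ import annotations

import zlib

import numpy as np


def substream(seed: int, *names) -> np.random.Generator:
    """Independent generator for a named substream of a top-level seed.

    Stream identity is a stable hash of the names, so adding a new stream
    never perturbs existing ones.
    """
    keys = [zlib.crc32(str(n).encode()) for n in names]
    return np.random.default_rng(np.random.SeedSequence([int(seed) % (2**31), *keys]))


def subseed(seed: int, *names) -> int:
    """A derived integer seed (< 2**31) for APIs that take plain seeds."""
    return int(substream(seed, *names).integers(0, 2**31))
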