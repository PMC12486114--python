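"""Seed-substream derivation.

Every random draw in the package flows from a single master seed through
named substreams, so that stages can be re-run independently and the whole
pipeline is reproducible bit-for-bit.
"""

from __future__ import annotations

import zlib

import numpy as np


def child_seed(master_seed: int, *names: object) -> int:
    """Derive a deterministic 31-bit child seed from a master seed and names."""
    tag = ":".join(str(n) for n in names)
    h = zlib.crc32(tag.encode("utf-8"), int(master_seed) & 0xFFFFFFFF)
    return h & 0x7FFFFFFF


def substream(master_seed: int, *names: object) -> np.random.Generator:
    """A Generator seeded from a named substream of the master seed."""
    keys = tuple(zlib.crc32(str(n).encode("utf-8")) & 0x7FFFFFFF for n in names)
    ss = np.random.SeedSequence(entropy=int(master_seed) & 0x7FFFFFFF, spawn_key=keys)
    return np.random.default_rng(ss)
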