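"""Seed plumbing: named substreams derived from one master seed.

Each analysis stage draws its randomness from a substream identified by a
short name, so changing the permutation count in one stage never shifts the
random numbers seen by another.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["substream_seed", "substream_rng"]


def substream_seed(master_seed: int, name: str) -> int:
    """Derive a deterministic 31-bit child seed from (master_seed, name)."""
    ss = np.random.SeedSequence(entropy=int(master_seed) & 0xFFFFFFFF,
                                spawn_key=(zlib.crc32(name.encode("utf-8")),))
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


def substream_rng(master_seed: int, name: str) -> np.random.Generator:
    return np.random.default_rng(substream_seed(master_seed, name))
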