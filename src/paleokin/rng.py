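"""Seed-substream management.

One master seed is configured per run; each analysis derives an independent
NumPy generator keyed by a short name, so adding or reordering analyses never
perturbs another analysis's stream.
"""

from __future__ import annotations

import zlib

import numpy as np


def substream(seed: int, name: str) -> np.random.Generator:
    """Return a generator for analysis ``name`` derived from the master seed."""
    key = zlib.crc32(name.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence(entropy=int(seed) % (2**31), spawn_key=(key,)))
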