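"""Named RNG substreams derived from one global seed.

Each pipeline stage draws from its own stream so that rerunning a single
stage reproduces it bit-identically regardless of what other stages
consumed.
"""

from __future__ import annotations

import zlib

import numpy as np


def rng_for(seed: int, *names: str) -> np.random.Generator:
    """A generator seeded by ``seed`` and a stable hash of ``names``."""
    keys = [int(seed)] + [zlib.crc32(n.encode()) for n in names]
    return np.random.default_rng(np.random.SeedSequence(keys))
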