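"""Seed-stream derivation used by every stochastic operation.

A single master seed drives the whole pipeline.  Each operation derives its
own independent :class:`numpy.random.Generator` from the master seed plus a
string tag (hashed into a spawn key), so adding a generator call in one
stage never shifts the random stream of another.
"""

from __future__ import annotations

import zlib

import numpy as np


def derive_rng(seed: int, *tags: str | int) -> np.random.Generator:
    """Return a generator keyed by ``seed`` and a tuple of tags.

    Tags may be strings (hashed with CRC32) or plain integers (e.g. a
    patient index), so ``derive_rng(seed, "phantom", i)`` gives patient
    ``i`` a stable private stream.
    """
    key = tuple(
        zlib.crc32(t.encode()) if isinstance(t, str) else int(t) % (2**32)
        for t in tags
    )
    return np.random.default_rng(np.random.SeedSequence(int(seed) % (2**31), spawn_key=key))
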