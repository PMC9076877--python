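"""Named, independent random streams derived from a single cohort seed.

Every stochastic component draws from ``stream(seed, name)`` so that adding
a new lesion type or noise source never perturbs the draws of an existing
one, and a single integer seed reproduces an entire cohort byte-for-byte.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["stream"]


def stream(seed: int, name: str) -> np.random.Generator:
    """Return an independent Generator keyed by ``(seed, name)``.

    The stream key is a CRC32 of the name used as a spawn key, so streams
    are stable across sessions and platforms.
    """
    key = zlib.crc32(name.encode("utf-8"))
    ss = np.random.SeedSequence(entropy=int(seed), spawn_key=(key,))
    return np.random.default_rng(ss)
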