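"""Named random substreams.

One global seed is propagated to every stochastic operation through a named
substream so partial pipeline reruns reproduce exactly: the stream for, say,
genotype masking does not shift when an unrelated stage draws more numbers.
"""

from __future__ import annotations

import zlib

import numpy as np


def substream(seed: int, name: str) -> np.random.Generator:
    """Return a Generator for ``name`` deterministically derived from ``seed``."""
    key = zlib.crc32(name.encode("utf-8")) & 0x7FFFFFFF
    return np.random.default_rng(np.random.SeedSequence(int(seed), spawn_key=(key,)))


def subseed(seed: int, name: str) -> int:
    """A 31-bit integer seed for ``name`` (for samplers taking plain ints)."""
    return int(substream(seed, name).integers(0, 2**31 - 1))
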