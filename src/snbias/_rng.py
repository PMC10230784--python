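"""Named random substreams derived from one global seed.

Every stochastic stage draws from ``substream(seed, "stage-name")`` so that
stages are reproducible in isolation and independent of execution order.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["substream"]


def substream(seed: int, *names: str | int) -> np.random.Generator:
    """Return a Generator keyed by ``seed`` and a sequence of stage names."""
    words = [int(seed) & 0x7FFFFFFF]
    for name in names:
        if isinstance(name, int):
            words.append(name & 0x7FFFFFFF)
        else:
            words.append(zlib.crc32(str(name).encode()) & 0x7FFFFFFF)
    return np.random.default_rng(np.random.SeedSequence(words))
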