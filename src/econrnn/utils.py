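"""Small shared helpers."""

from __future__ import annotations

import zlib

import numpy as np


def derive_rng(seed: int, *keys) -> np.random.Generator:
    """Child generator deterministically derived from a seed and labels.

    String keys are hashed with crc32 so the same (seed, keys) pair always
    yields the same stream; all derived integers stay below 2**31.
    """
    ints = [int(seed) % (2 ** 31)]
    for k in keys:
        if isinstance(k, str):
            ints.append(zlib.crc32(k.encode()) % (2 ** 31))
        else:
            ints.append(int(k) % (2 ** 31))
    return np.random.default_rng(ints)
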