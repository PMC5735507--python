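"""Deterministic seed derivation.

One master seed drives the whole pipeline; every stage and scene draws
its own substream via :func:`derive_seed` so stages stay statistically
independent and reruns are bit-reproducible.  String keys are hashed
with CRC32 so the derivation does not depend on Python's randomized
``hash``.
"""

from __future__ import annotations

import zlib

import numpy as np


def derive_seed(master_seed: int, *keys: int | str) -> int:
    """Stable 31-bit child seed from a master seed and a key path."""
    ints = [int(master_seed) & 0x7FFFFFFF]
    for k in keys:
        if isinstance(k, str):
            ints.append(zlib.crc32(k.encode("utf-8")))
        else:
            ints.append(int(k) & 0xFFFFFFFF)
    ss = np.random.SeedSequence(ints)
    return int(ss.generate_state(1)[0] % (2**31))
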