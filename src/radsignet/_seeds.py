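"""Deterministic sub-seed derivation: all randomness flows from named seeds."""

from __future__ import annotations

import zlib

import numpy as np


def derive_seed(seed: int, name: str) -> int:
    """Stable sub-seed for a named stage/repeat, independent of call order.

    Mixes the parent seed with a CRC of the name through a SeedSequence and
    returns a value below 2**31 (safe for every consumer in the stack).
    """
    ss = np.random.SeedSequence([int(seed) & 0x7FFFFFFF, zlib.crc32(name.encode())])
    return int(ss.generate_state(1)[0] % (2**31))
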