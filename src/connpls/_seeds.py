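"""Counter-based random streams.

Every stochastic operation in the package draws from a named stream derived
from one integer master seed. Streams are independent of call order, so a
stage can be rerun in isolation and still reproduce its draws.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["stream_rng", "stream_seed"]


def stream_seed(seed: int, stream: str) -> int:
    """Derive a 31-bit child seed for a named stream from a master seed."""
    h = zlib.crc32(stream.encode("utf-8"))
    ss = np.random.SeedSequence(entropy=int(seed), spawn_key=(h,))
    return int(ss.generate_state(1, dtype=np.uint32)[0] & 0x7FFFFFFF)


def stream_rng(seed: int, stream: str) -> np.random.Generator:
    """Generator for a named stream under a master seed.

    Identical ``(seed, stream)`` pairs always yield identical draws.
    """
    h = zlib.crc32(stream.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence(entropy=int(seed), spawn_key=(h,)))
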