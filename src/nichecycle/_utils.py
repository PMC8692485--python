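"""Shared helpers: deterministic seed derivation and small numerics."""

from __future__ import annotations

import zlib

import numpy as np


def derive_seed(global_seed: int, *tokens: object) -> int:
    """Derive a child seed deterministically from a global seed and tokens.

    Uses CRC32 of the joined string representation; result fits in 31 bits
    so it is a valid seed everywhere.  Same inputs -> same seed, independent
    of execution order, which makes per-ASV / per-stage randomness
    reproducible and parallelizable by contract.
    """
    key = ":".join([str(int(global_seed))] + [str(t) for t in tokens])
    return zlib.crc32(key.encode("utf-8")) & 0x7FFFFFFF


def rng_for(global_seed: int, *tokens: object) -> np.random.Generator:
    """A numpy Generator seeded by :func:`derive_seed`."""
    return np.random.default_rng(derive_seed(global_seed, *tokens))
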