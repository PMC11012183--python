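"""Deterministic seed derivation.

Every stochastic stage derives its own :class:`numpy.random.Generator` from the
user-facing integer seed plus a stable key path (stage name, iteration index,
feature index, ...), so that adding or reordering stages never perturbs the
random stream of another stage.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["child_rng", "child_int_seed"]


def _key_to_int(key: int | str) -> int:
    if isinstance(key, (int, np.integer)):
        if key < 0:
            raise ValueError("seed keys must be non-negative")
        return int(key)
    return zlib.crc32(key.encode("utf-8"))


def child_rng(seed: int, *keys: int | str) -> np.random.Generator:
    """Generator for the stream identified by ``(seed, *keys)``."""
    spawn_key = tuple(_key_to_int(k) for k in keys)
    return np.random.default_rng(np.random.SeedSequence(entropy=int(seed), spawn_key=spawn_key))


def child_int_seed(seed: int, *keys: int | str) -> int:
    """A 31-bit integer seed for libraries that take ``random_state`` ints."""
    return int(child_rng(seed, *keys).integers(0, 2**31 - 1))
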