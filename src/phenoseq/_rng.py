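"""Deterministic, key-addressable random substreams.

All stochastic operations in this package derive their generators from an
explicit integer seed plus string keys (spheroid id, gene id, ...) so that
results are reproducible and independent of iteration order.
"""

from __future__ import annotations

import hashlib

import numpy as np

__all__ = ["substream"]


def _key_entropy(key: object) -> int:
    digest = hashlib.sha256(repr(key).encode()).digest()
    return int.from_bytes(digest[:8], "little")


def substream(seed: int, *keys: object) -> np.random.Generator:
    """Return a Generator keyed on ``(seed, *keys)``.

    The same (seed, keys) combination always yields an identical stream,
    regardless of how many other substreams were drawn before it.
    """
    entropy = [int(seed)] + [_key_entropy(k) for k in keys]
    return np.random.default_rng(np.random.SeedSequence(entropy))
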