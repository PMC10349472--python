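"""Reproducible random-number streams.

One root seed governs a whole simulated experiment. Every well (or plate,
or replicate) draws from its own child stream derived from the root seed
and a stable string key, so the noise realisation of a single well does
not depend on how many other wells exist or in which order they are
simulated.

Derivation: the key string is hashed with BLAKE2b (8-byte digest) and the
resulting integer is used as a ``spawn_key`` on ``numpy.random.SeedSequence``
initialised with the root seed.
"""

from __future__ import annotations

import hashlib

import numpy as np

__all__ = ["child_rng"]


def _key_to_int(key: str) -> int:
    digest = hashlib.blake2b(key.encode("utf-8"), digest_size=8).digest()
    return int.from_bytes(digest, "big")


def child_rng(seed: int, *keys: object) -> np.random.Generator:
    """Return an independent generator for ``seed`` and a hierarchy of keys.

    Parameters
    ----------
    seed:
        Root seed of the experiment.
    *keys:
        Arbitrary hashable labels, e.g. ``("run1", "A01")``. The same
        (seed, keys) pair always yields the same stream.
    """
    spawn_key = tuple(_key_to_int(str(k)) for k in keys)
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=spawn_key))
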