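"""Deterministic seed derivation.

All randomness in the package flows from one root seed expanded per
(context key) by a counter scheme, so any sub-result is reproducible in
isolation.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["derive_rng", "derive_seed"]


def _key_to_int(key: object) -> int:
    if isinstance(key, (int, np.integer)):
        return int(key) & 0xFFFFFFFF
    return zlib.crc32(str(key).encode("utf-8"))


def derive_seed(root_seed: int, *keys: object) -> np.random.SeedSequence:
    """A child SeedSequence for the context identified by ``keys``.

    Keys may be ints or strings; strings are hashed stably (CRC32) so the
    derivation does not depend on Python's per-process hash seed.
    """
    return np.random.SeedSequence(
        entropy=int(root_seed), spawn_key=tuple(_key_to_int(k) for k in keys)
    )


def derive_rng(root_seed: int, *keys: object) -> np.random.Generator:
    """A Generator seeded for the context identified by ``keys``."""
    return np.random.default_rng(derive_seed(root_seed, *keys))
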