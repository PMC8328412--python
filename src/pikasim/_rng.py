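"""Seed-derivation helpers.

All randomness in the package flows from one root integer seed.  Child
streams are derived with :class:`numpy.random.SeedSequence` spawn keys, so
they are reproducible and independent of the order in which they are
created.  String key components are hashed with CRC-32 to a stable uint32;
integer components are used as-is.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["child_rng", "child_seed_key"]


def child_seed_key(*key: int | str) -> tuple[int, ...]:
    """Map a mixed str/int key path to a SeedSequence spawn key."""
    words: list[int] = []
    for part in key:
        if isinstance(part, str):
            words.append(zlib.crc32(part.encode("utf-8")))
        else:
            part = int(part)
            if part < 0:
                raise ValueError("integer key components must be non-negative")
            words.append(part)
    return tuple(words)


def child_rng(seed: int, *key: int | str) -> np.random.Generator:
    """Return a Generator for the child stream named by ``key``.

    Examples
    --------
    >>> r1 = child_rng(42, "landscape")
    >>> r2 = child_rng(42, "day", 0)
    """
    ss = np.random.SeedSequence(int(seed), spawn_key=child_seed_key(*key))
    return np.random.default_rng(ss)
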