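"""Hierarchical random-number streams.

Every stochastic operation in the package takes an explicit integer seed (or
an already-constructed :class:`numpy.random.Generator`).  Experiments that
need several independent substreams derive them from one master seed plus a
tuple of string/integer keys, so that parallel or repeated runs never share
or reuse a stream by accident and no global numpy state is touched.
"""

from __future__ import annotations

import hashlib

import numpy as np

__all__ = ["substream", "as_generator", "derive_int_seed"]


def _key_words(keys: tuple) -> list[int]:
    """Hash a tuple of keys into a list of uint32 words (stable across runs)."""
    h = hashlib.blake2b("\x1f".join(map(repr, keys)).encode(), digest_size=16)
    d = h.digest()
    return [int.from_bytes(d[i : i + 4], "little") for i in range(0, 16, 4)]


def substream(master_seed: int, *keys) -> np.random.Generator:
    """Return a Generator for the named substream of ``master_seed``.

    The same (seed, keys) pair always yields the same stream; distinct key
    tuples yield statistically independent streams.
    """
    ss = np.random.SeedSequence([int(master_seed) & 0x7FFFFFFF, *_key_words(keys)])
    return np.random.default_rng(ss)


def as_generator(seed) -> np.random.Generator:
    """Accept an int seed, a Generator, or None (fresh entropy)."""
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def derive_int_seed(rng: np.random.Generator) -> int:
    """Draw a positive 31-bit integer seed (for libraries wanting an int)."""
    return int(rng.integers(1, 2**31 - 1))
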