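"""Deterministic seed derivation.

Every stochastic stage derives its RNG from a master seed plus a tuple of
string/int tokens (stage name, subject index, repetition index, ...) so that
identical configurations reproduce bit-identical outputs while distinct
stages draw from effectively independent streams.
"""

from __future__ import annotations

import hashlib

import numpy as np

__all__ = ["derive_seed", "rng_for"]


def derive_seed(master_seed: int, *tokens: object) -> int:
    """Derive a child seed (< 2**31) from a master seed and context tokens."""
    h = hashlib.sha256()
    h.update(str(int(master_seed)).encode())
    for tok in tokens:
        h.update(b"\x00" + str(tok).encode())
    return int.from_bytes(h.digest()[:4], "little") % (2**31)


def rng_for(master_seed: int, *tokens: object) -> np.random.Generator:
    """A numpy Generator seeded from :func:`derive_seed`."""
    return np.random.default_rng(derive_seed(master_seed, *tokens))
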