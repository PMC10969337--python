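"""Deterministic seed derivation.

Every stochastic component (weight init, shuffling, augmentation, dropout,
bootstrap, synthetic generation) draws from a ``numpy.random.Generator``
seeded through :func:`derive_seed`, so any stage of a run can be reproduced
in isolation from the master seed plus its tag path.
"""

from __future__ import annotations

import hashlib

__all__ = ["derive_seed"]


def derive_seed(master: int, *tags: object) -> int:
    """Derive a child seed from a master seed and a sequence of tags.

    Stable across processes and platforms (SHA-256 based, unlike ``hash()``).
    The result is a non-negative int below 2**31 so it is safe for any RNG
    seed parameter.
    """
    h = hashlib.sha256()
    h.update(str(int(master)).encode())
    for tag in tags:
        h.update(b"\x1f")
        h.update(str(tag).encode())
    return int.from_bytes(h.digest()[:4], "big") % (2**31)
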