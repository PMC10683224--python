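"""Deterministic seed derivation.

A single master seed fans out to independent per-fold / per-model streams by
hashing the master seed together with a string tag.  The derivation is stable
across platforms and Python versions (sha256, not ``hash``).
"""

from __future__ import annotations

import hashlib

import numpy as np

__all__ = ["derive_seed", "rng_for"]


def derive_seed(master: int, *tags: object) -> int:
    """Derive a child seed < 2**31 from ``master`` and a sequence of tags."""
    h = hashlib.sha256()
    h.update(str(int(master)).encode())
    for t in tags:
        h.update(b"\x1f")
        h.update(str(t).encode())
    return int.from_bytes(h.digest()[:4], "big") % (2**31)


def rng_for(master: int, *tags: object) -> np.random.Generator:
    """A numpy Generator seeded from :func:`derive_seed`."""
    return np.random.default_rng(derive_seed(master, *tags))
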