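"""Deterministic seed derivation.

Every stochastic operation in the package draws from a child generator
derived from one master seed plus a string/integer path, so that a whole
federated run is reproducible bit-for-bit from its RunConfig and the two
protocol modes consume identical random streams wherever their behaviour
is meant to coincide.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["child_seed", "child_rng"]


def _token_int(token: object) -> int:
    if isinstance(token, (int, np.integer)):
        return int(token) & 0xFFFFFFFF
    return zlib.crc32(str(token).encode("utf-8"))


def child_seed(master: int, *path: object) -> int:
    """Derive a stable 31-bit child seed from a master seed and a path."""
    ss = np.random.SeedSequence([int(master) & 0x7FFFFFFF, *(_token_int(t) for t in path)])
    return int(ss.generate_state(1, dtype=np.uint32)[0]) & 0x7FFFFFFF


def child_rng(master: int, *path: object) -> np.random.Generator:
    """A numpy Generator seeded from :func:`child_seed`."""
    return np.random.default_rng(child_seed(master, *path))
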