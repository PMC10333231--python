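"""Deterministic seed derivation.

Every stochastic operation takes an explicit seed; pipeline code derives
per-operation seeds from a single master seed by stable hashing, so adding
an operation never perturbs the random stream of another.
"""

from __future__ import annotations

import hashlib

_MOD = 2**31  # keep derived seeds in the range any RNG backend accepts


def derive_seed(master_seed: int, name: str) -> int:
    """Derive a child seed from ``(master_seed, name)`` by stable hashing.

    Uses BLAKE2b, so the mapping is identical across platforms and Python
    processes (unlike ``hash()``).
    """
    digest = hashlib.blake2b(
        f"{master_seed}:{name}".encode("utf-8"), digest_size=8
    ).digest()
    return int.from_bytes(digest, "big") % _MOD
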