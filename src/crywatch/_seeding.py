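"""Deterministic seed derivation.

A single master seed fans out to per-stage / per-fold / per-run seeds via a
stable cryptographic hash, so results are reproducible across platforms and
process invocations (unlike the built-in ``hash``, which is salted).
"""

from __future__ import annotations

import hashlib

__all__ = ["derive_seed"]


def derive_seed(master: int, *keys: object) -> int:
    """Derive a child seed from a master seed and a sequence of keys.

    Returns a non-negative integer < 2**31, suitable for numpy and
    scikit-learn random states.
    """
    token = ":".join([str(int(master))] + [str(k) for k in keys])
    digest = hashlib.sha256(token.encode("utf-8")).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)
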