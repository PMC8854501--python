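"""Deterministic seed derivation.

Every stage and patient gets its own stream derived from the master seed, so
seeds are never reused across patients and the whole pipeline is a pure
function of the master seed.
"""

from __future__ import annotations

import hashlib

__all__ = ["derive_seed"]


def derive_seed(master: int, *parts: object) -> int:
    """Hash (master seed, stage name, patient id, ...) into a 31-bit seed."""
    h = hashlib.blake2b(digest_size=8)
    h.update(str(int(master)).encode())
    for part in parts:
        h.update(b"\x00")
        h.update(str(part).encode())
    return int.from_bytes(h.digest()[:4], "big") % (2**31)
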