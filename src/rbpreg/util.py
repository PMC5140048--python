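"""Shared plumbing: deterministic seed derivation and package logging."""

from __future__ import annotations

import hashlib
import logging

logger = logging.getLogger("rbpreg")
if not logger.handlers:  # library default: quiet unless the app configures it
    logger.addHandler(logging.NullHandler())


def stable_seed(master: int, *tokens) -> int:
    """Derive a reproducible child seed from a master seed and string tokens.

    Uses SHA-256 so the derivation is stable across Python processes and
    platforms (unlike ``hash()``), and keeps the result below 2**31 so it is
    a valid seed for every RNG in the stack.
    """
    key = "|".join([str(int(master))] + [str(t) for t in tokens])
    digest = hashlib.sha256(key.encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)
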