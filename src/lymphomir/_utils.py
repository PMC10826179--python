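"""Internal helpers: reproducible per-stage seeds and small validators."""

from __future__ import annotations

import hashlib

_SEED_MOD = 2**31


def derive_seed(seed: int, *names: str) -> int:
    """Derive a child seed from a global seed and a stage name.

    Stable across processes and Python versions (SHA-256, not ``hash``),
    always below 2**31 so it is usable everywhere a 32-bit seed is expected.
    """
    payload = f"{int(seed)}:" + ":".join(names)
    digest = hashlib.sha256(payload.encode("utf-8")).digest()
    return int.from_bytes(digest[:4], "big") % _SEED_MOD


def require(cond: bool, message: str) -> None:
    if not cond:
        raise ValueError(message)
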