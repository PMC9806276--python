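"""Deterministic seed fan-out.

One global run seed derives independent per-stage sub-seeds by hashing the
stage label, so adding a stage never perturbs the random streams of the
others.  Derived seeds stay below 2**31.
"""

from __future__ import annotations

import hashlib


def derive_seed(seed: int, label: str) -> int:
    digest = hashlib.sha256(f"{seed}:{label}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2 ** 31)
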