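"""Stable derivation of per-gene / per-stage RNG substreams.

All randomness in the package flows from one master seed.  Substreams are
keyed by string labels through a cryptographic hash, so adding genes to a
dataset, or reordering them, never perturbs the stream any existing gene
sees.
"""
from __future__ import annotations

import hashlib

_MASK = 0x7FFFFFFF  # keep derived seeds below 2**31


def derive_seed(master_seed: int, *parts: object) -> int:
    """Derive a deterministic 31-bit seed from a master seed and labels."""
    key = ":".join([str(int(master_seed))] + [str(p) for p in parts])
    digest = hashlib.blake2s(key.encode("utf-8"), digest_size=8).digest()
    return int.from_bytes(digest[:4], "big") & _MASK
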