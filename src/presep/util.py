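"""Small shared helpers."""

from __future__ import annotations

import hashlib


def derive_seed(master: int, *tags) -> int:
    """Derive a reproducible sub-seed (< 2**31) from a master seed and tags.

    Stable across platforms and Python processes (SHA-256 of the rendered
    master/tag string), so independent pipeline stages (fold assignment,
    per-sweep-point forests, fixture RNG streams) get decorrelated but
    fully reproducible randomness from one master seed.
    """
    key = ":".join([str(int(master))] + [str(t) for t in tags])
    digest = hashlib.sha256(key.encode("utf-8")).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)
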