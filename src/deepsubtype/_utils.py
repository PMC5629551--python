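"""Small shared helpers: deterministic child seeds and file checksums."""

from __future__ import annotations

import hashlib
from pathlib import Path

import numpy as np


def derive_seed(base: int, *tags: int) -> int:
    """Deterministic child seed (< 2**31) from a base seed and tag ints."""
    ss = np.random.SeedSequence([int(base), *[int(t) for t in tags]])
    return int(ss.generate_state(1)[0] % (2 ** 31))


def sha256_file(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as f:
        for chunk in iter(lambda: f.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()
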