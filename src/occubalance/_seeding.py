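"""Deterministic seed derivation.

One master seed drives the whole pipeline; each component derives its own
generator from the master seed plus a stable name so components are
independently reproducible and insensitive to each other's draw counts.
"""

from __future__ import annotations

import hashlib

import numpy as np


def _name_words(*names: object) -> list[int]:
    words: list[int] = []
    for name in names:
        if isinstance(name, (int, np.integer)):
            words.append(int(name) & 0x7FFFFFFF)
        else:
            digest = hashlib.sha256(str(name).encode("utf-8")).digest()
            words.append(int.from_bytes(digest[:4], "big"))
    return words


def derive_seed(master_seed: int, *names: object) -> int:
    """A stable sub-seed (< 2**31) for ``names`` under ``master_seed``."""
    seq = np.random.SeedSequence([int(master_seed) & 0x7FFFFFFF, *_name_words(*names)])
    return int(seq.generate_state(1, dtype=np.uint32)[0]) & 0x7FFFFFFF


def derive_rng(master_seed: int, *names: object) -> np.random.Generator:
    """A generator keyed to ``names``; same inputs, same stream, always."""
    return np.random.default_rng(
        np.random.SeedSequence([int(master_seed) & 0x7FFFFFFF, *_name_words(*names)])
    )
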