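"""Seeding helpers: derive independent substreams from one root seed."""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["substream"]


def substream(root_seed: int, *keys) -> np.random.Generator:
    """Generator seeded by a stable hash of (root_seed, *keys).

    The same (seed, keys) always yields the same stream, and streams for
    different keys are statistically independent — so, e.g., per-unit
    draws do not shift when unrelated units are added.
    """
    digest = [zlib.crc32(repr(k).encode()) for k in keys]
    return np.random.default_rng(np.random.SeedSequence(
        entropy=int(root_seed), spawn_key=tuple(digest)))
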