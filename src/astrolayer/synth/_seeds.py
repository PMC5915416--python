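"""Deterministic seed splitting for the generators.

One global integer seed expands into independent per-generator streams:
the child stream for name ``s`` is ``default_rng(SeedSequence([seed,
crc32(s)]))``.  The rule is pure arithmetic, so identical (seed, name)
pairs always yield bit-identical streams.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["child_rng", "child_seed"]


def child_seed(seed: int, stream: str) -> np.random.SeedSequence:
    return np.random.SeedSequence([int(seed), zlib.crc32(stream.encode("utf-8"))])


def child_rng(seed: int, stream: str) -> np.random.Generator:
    """Independent random stream named ``stream`` under a global seed."""
    return np.random.default_rng(child_seed(seed, stream))
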