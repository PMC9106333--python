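"""Deterministic RNG substream derivation.

One integer seed governs an analysis; per-case / per-seed substreams are derived
from (seed, tag) so that adding or reordering cases never perturbs the draws of
another case.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["substream", "subseed"]


def subseed(base_seed: int, tag: str = "") -> int:
    """Derive a stable 31-bit sub-seed from a base seed and a string tag."""
    return (int(base_seed) ^ zlib.crc32(tag.encode("utf-8"))) & 0x7FFFFFFF


def substream(base_seed: int, tag: str = "") -> np.random.Generator:
    """Return an independent Generator for (base_seed, tag).

    The same pair always yields the same stream; distinct tags yield streams
    that are independent for all practical purposes (SeedSequence mixing).
    """
    ss = np.random.SeedSequence([int(base_seed) & 0x7FFFFFFF, subseed(base_seed, tag)])
    return np.random.default_rng(ss)
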