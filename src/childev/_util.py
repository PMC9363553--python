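"""Shared helpers: seeded substreams and rounding."""

from __future__ import annotations

import zlib

import numpy as np


def substream(seed: int, name: str) -> np.random.Generator:
    """Independent RNG for a named stage under one root seed.

    Mixing the stage name into the seed sequence gives stage-level
    reproducibility: rerunning one stage draws the same stream regardless
    of what other stages consumed.
    """
    return np.random.default_rng(
        np.random.SeedSequence([int(seed) & 0x7FFFFFFF, zlib.crc32(name.encode())])
    )


def round_half_up(x: float) -> int:
    """Round to nearest integer, ties away from zero toward +inf."""
    return int(np.floor(x + 0.5))
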