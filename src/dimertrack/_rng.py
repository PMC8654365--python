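"""Seed management: one root seed, independent named substreams per stage."""

from __future__ import annotations

import zlib

import numpy as np


def stage_rng(seed: int, stage: str) -> np.random.Generator:
    """Return a Generator for a named stage, independent of other stages.

    The substream is keyed by a CRC32 of the stage name, so adding a new
    stage never perturbs the streams of existing ones.
    """
    key = zlib.crc32(stage.encode("utf8")) & 0x7FFFFFFF
    return np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, key]))


def stage_seed(seed: int, stage: str) -> int:
    """Integer seed (< 2^31) for a named stage."""
    key = zlib.crc32(stage.encode("utf8")) & 0x7FFFFFFF
    return int(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, key]).generate_state(1)[0] & 0x7FFFFFFF)
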