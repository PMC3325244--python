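"""Seed plumbing shared across stages.

A single user-facing integer seed governs every stochastic stage; each stage
draws from its own child stream so that adding or reordering stages never
shifts another stage's random numbers.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["child_rng", "child_seed"]


def child_seed(seed: int, stage: str) -> np.random.SeedSequence:
    """Derive a stage-specific seed sequence from the global seed.

    The spawn key is a CRC32 of the stage name, so the mapping is stable
    across runs and independent of the order stages are initialised in.
    """
    return np.random.SeedSequence(int(seed), spawn_key=(zlib.crc32(stage.encode()),))


def child_rng(seed: int, stage: str) -> np.random.Generator:
    """A :class:`numpy.random.Generator` for one named stage."""
    return np.random.default_rng(child_seed(seed, stage))
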