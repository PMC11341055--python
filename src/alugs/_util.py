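"""Small shared helpers."""

from __future__ import annotations

import numpy as np


def round_half_up(x: float) -> int:
    """Round to nearest integer, halves away from zero (0.5 -> 1).

    Used for "top 10% of n" style counts so that 0.25 * 334 = 83.5 -> 84
    and 0.10 * 334 = 33.4 -> 33, independent of banker's rounding.
    """
    return int(np.floor(x + 0.5))


def stage_rng(seed: int, stage: int) -> np.random.Generator:
    """Deterministic per-stage generator derived from a global seed.

    Each pipeline stage draws from its own stream so stages can be re-run
    independently without perturbing one another.
    """
    return np.random.default_rng(np.random.SeedSequence(entropy=int(seed), spawn_key=(int(stage),)))
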