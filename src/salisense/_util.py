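"""Small shared helpers: seeded stream splitting and report-style rounding."""

from __future__ import annotations

import math

import numpy as np

# Named sub-streams so that adding draws to one stage never perturbs another.
STREAM_COHORT = 0
STREAM_RESPONSES = 1
STREAM_REPLICATES = 2
STREAM_PIXELS = 3
STREAM_NORMS = 4


def stream_rng(seed: int, stream: int) -> np.random.Generator:
    """Independent generator for one purpose under a single user-facing seed."""
    return np.random.default_rng(np.random.SeedSequence(entropy=int(seed), spawn_key=(stream,)))


def round_half_away(x: float, ndigits: int = 1) -> float:
    """Round half away from zero (table-reporting convention; Python's
    built-in ``round`` is banker's rounding and would give 88.8 for 88.85)."""
    factor = 10.0 ** ndigits
    return math.copysign(math.floor(abs(x) * factor + 0.5), x) / factor
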