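"""Named random-number streams.

All stochastic components draw from streams derived from one master seed,
keyed by a stable string name.  Adding a new distractor class (its own
stream) therefore never perturbs the draws of an existing one — axon
geometry is reproducible regardless of which other scene elements are
switched on.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["stream_rng", "stream_seed"]


def stream_seed(seed: int, name: str) -> np.random.SeedSequence:
    """Derive a child seed sequence from ``seed`` keyed by ``name``."""
    if not (0 <= int(seed) < 2**63):
        raise ValueError(f"seed must be a non-negative integer, got {seed!r}")
    return np.random.SeedSequence([int(seed), zlib.crc32(name.encode("utf-8"))])


def stream_rng(seed: int, name: str) -> np.random.Generator:
    """A PCG64 generator for the named stream of a master seed."""
    return np.random.default_rng(stream_seed(seed, name))
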