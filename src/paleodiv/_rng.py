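"""Seed handling.

All stochastic stages take an integer seed and derive independent streams
from it through :class:`numpy.random.SeedSequence` spawning, so a single
top-level seed reproduces every downstream draw.
"""

from __future__ import annotations

import numpy as np

__all__ = ["rng_from_seed", "spawn_seeds"]


def rng_from_seed(seed: int | np.random.Generator) -> np.random.Generator:
    """Return a Generator; pass an existing Generator through unchanged."""
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(int(seed))


def spawn_seeds(seed: int, n: int) -> list[int]:
    """Derive ``n`` independent child seeds (< 2**31) from one parent seed."""
    ss = np.random.SeedSequence(int(seed))
    return [int(child.generate_state(1, dtype=np.uint32)[0] % (2**31 - 1)) for child in ss.spawn(n)]
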