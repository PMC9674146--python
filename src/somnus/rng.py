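"""Seeded randomness management: one master seed, named child streams."""

from __future__ import annotations

import numpy as np

#: Stream names used by a standard run; modules draw only from their own
#: stream so components are reproducible in isolation.
STREAMS = ("wiring", "weights", "environment", "release", "exploration",
           "ties", "sleep", "analysis")


def spawn_streams(master_seed: int, names=STREAMS) -> dict[str, np.random.Generator]:
    """Derive independent named generators from one master seed."""
    ss = np.random.SeedSequence(master_seed)
    children = ss.spawn(len(names))
    return {name: np.random.default_rng(child)
            for name, child in zip(names, children)}


def kernel_seed(rng: np.random.Generator) -> int:
    """Draw a 31-bit seed for the compiled kernel's internal generator."""
    return int(rng.integers(0, 2**31 - 1))
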