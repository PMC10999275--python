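"""Seed-stream management.

All randomness in the package flows from a single integer run seed expanded
into named, independent component streams.  Adding a new component (a new
stream name) never perturbs the draws of existing components.
"""
from __future__ import annotations

import zlib

import numpy as np

__all__ = ["stream"]


def stream(seed: int, name: str) -> np.random.Generator:
    """Return the named child generator of a run seed.

    Parameters
    ----------
    seed
        Master run seed (non-negative integer).
    name
        Component name; the same (seed, name) pair always yields a
        generator producing the identical sequence.
    """
    if seed is None:
        raise ValueError("a seed is required for stochastic operations")
    key = zlib.crc32(name.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence([int(seed), key]))
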