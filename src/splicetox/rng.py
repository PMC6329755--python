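"""Named RNG substreams.

Every simulator derives all of its randomness from a single integer seed.
Independent parts of a simulation (baseline abundances, per-replicate
counts, noise, ...) each draw from a *named* substream so that adding a new
draw site never perturbs existing ones, and partial re-runs are
reproducible.  The substream for ``(seed, name)`` is
``default_rng(SeedSequence([seed, crc32(name)]))``.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["substream"]


def substream(seed: int, name: str) -> np.random.Generator:
    """Return the deterministic RNG substream for ``(seed, name)``."""
    seed = int(seed)
    if seed < 0:
        raise ValueError("seed must be non-negative")
    key = zlib.crc32(name.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence([seed & 0x7FFFFFFF, key]))
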