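"""Seed plumbing.

Every stochastic entry point accepts a ``seed`` that may be an int, a
:class:`numpy.random.SeedSequence`, an existing :class:`numpy.random.Generator`
or ``None``.  Substreams are derived with explicit spawn keys so that any
single (grid point, replicate) stream can be reconstructed in isolation.
"""

from __future__ import annotations

import numpy as np

__all__ = ["seed_sequence", "substream", "generator"]


def seed_sequence(seed=None) -> np.random.SeedSequence:
    """Coerce ``seed`` to a SeedSequence (Generators are not accepted here)."""
    if isinstance(seed, np.random.SeedSequence):
        return seed
    if isinstance(seed, np.random.Generator):
        raise TypeError(
            "substream derivation needs an int or SeedSequence, not a Generator"
        )
    return np.random.SeedSequence(seed)


def substream(root: np.random.SeedSequence, *key: int) -> np.random.SeedSequence:
    """Child SeedSequence addressed by an integer key path (e.g. grid i, j, rep)."""
    return np.random.SeedSequence(
        entropy=root.entropy, spawn_key=tuple(root.spawn_key) + tuple(key)
    )


def generator(seed=None) -> np.random.Generator:
    """A Generator from any accepted seed form (Generators pass through)."""
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed_sequence(seed))
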