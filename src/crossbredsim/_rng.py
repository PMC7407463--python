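"""Deterministic seed management.

All randomness in the package flows from a single master seed through
named substreams.  A substream is identified by a short label (and an
optional integer index, e.g. a replicate number), so that two runs that
share a master seed but differ only in, say, the mate-allocation strategy
draw byte-identical genomes, trait architectures and residuals.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["substream", "spawn_rng"]


def _label_key(label: str) -> int:
    return zlib.crc32(label.encode("utf-8")) & 0x7FFFFFFF


def substream(master_seed: int, label: str, index: int = 0) -> np.random.SeedSequence:
    """Return the seed sequence of a named substream of the master seed."""
    return np.random.SeedSequence(entropy=[int(master_seed), _label_key(label), int(index)])


def spawn_rng(master_seed: int, label: str, index: int = 0) -> np.random.Generator:
    """A :class:`numpy.random.Generator` for a named substream."""
    return np.random.default_rng(substream(master_seed, label, index))
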