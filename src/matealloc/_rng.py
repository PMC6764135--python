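"""Named, reproducible random substreams.

A single master seed drives the whole pipeline; each stage draws from its own
named substream so that changing the number of draws in one stage does not
shift the randomness seen by another.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["substream"]


def substream(seed: int, name: str) -> np.random.Generator:
    """Return a Generator for the substream ``name`` under ``seed``.

    The mapping is a pure function of ``(seed, name)``: the stream is stable
    across runs and independent (in the SeedSequence sense) of every other
    named stream under the same master seed.
    """
    key = zlib.crc32(name.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(key,)))
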