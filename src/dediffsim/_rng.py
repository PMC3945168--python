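"""Buffered uniform-variate streams with deterministic per-replicate seeding.

Event-driven simulations here consume one scalar uniform at a time, which is
slow through ``Generator.random()`` call-by-call.  ``UniformStream`` draws in
blocks from a PCG64 generator and hands out scalars, so results are
bit-reproducible for a given seed while the amortized cost per variate stays
small.
"""

from __future__ import annotations

import numpy as np

_BLOCK = 1 << 14


class UniformStream:
    """Stream of U(0,1) scalars backed by a block-buffered numpy Generator."""

    __slots__ = ("_rng", "_buf", "_i")

    def __init__(self, seed) -> None:
        # seed may be an int or a numpy SeedSequence
        self._rng = np.random.Generator(np.random.PCG64(seed))
        # plain-float list: scalar access is faster than numpy item lookup
        self._buf = self._rng.random(_BLOCK).tolist()
        self._i = 0

    def next(self) -> float:
        i = self._i
        if i >= _BLOCK:
            self._buf = self._rng.random(_BLOCK).tolist()
            i = 0
        self._i = i + 1
        return self._buf[i]

    def take(self, n: int) -> np.ndarray:
        """Draw ``n`` uniforms at once (advances the same stream)."""
        out = np.empty(n)
        for j in range(n):
            out[j] = self.next()
        return out


def replicate_seed(base_seed: int, replicate: int) -> np.random.SeedSequence:
    """Deterministic independent seed for one replicate of an experiment."""
    return np.random.SeedSequence(entropy=int(base_seed), spawn_key=(int(replicate),))


def replicate_stream(base_seed: int, replicate: int) -> UniformStream:
    return UniformStream(replicate_seed(base_seed, replicate))
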