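"""Counter-based random streams for the screening engine.

The natural-history draws are produced in bulk by a seeded
``numpy.random.Generator``.  Screening, in contrast, consumes an unbounded,
person-specific sequence of uniforms whose length depends on the person's
history (tests taken, lesions resected, re-onsets).  To keep the paired
arms perfectly coupled and the engine embarrassingly order-independent we
use a stateless SplitMix64 stream per person: draw ``i`` for person ``p``
is a pure function of ``(seed, p, i)``.

Both the pure-Python reference walk and the compiled production engine
implement exactly this protocol, which is what makes their event-by-event
agreement testable bit-for-bit.
"""

from __future__ import annotations

import numpy as np
from numba import njit

_MASK = (1 << 64) - 1
_GAMMA = 0x9E3779B97F4A7C15
_INV_2_53 = 1.0 / 9007199254740992.0  # 2**-53


def mix64(z: int) -> int:
    """SplitMix64 output function (Stafford variant 13) on a 64-bit word."""
    z = (z + _GAMMA) & _MASK
    z = ((z ^ (z >> 30)) * 0xBF58476D1CE4E5B9) & _MASK
    z = ((z ^ (z >> 27)) * 0x94D049BB133111EB) & _MASK
    return z ^ (z >> 31)


def stream_key(seed: int, person: int) -> int:
    """Derive the per-person stream key from the scenario seed."""
    return mix64(mix64(seed & _MASK) ^ mix64(person & _MASK))


def u01(key: int, counter: int) -> float:
    """Uniform in [0, 1) for draw ``counter`` of stream ``key``."""
    h = mix64((key + counter * _GAMMA) & _MASK)
    return (h >> 11) * _INV_2_53


class CounterStream:
    """Sequential view over a person's counter-based stream (reference walk)."""

    def __init__(self, seed: int, person: int):
        self._key = stream_key(seed, person)
        self._ctr = 0

    def next(self) -> float:
        u = u01(self._key, self._ctr)
        self._ctr += 1
        return u


# --- numba twins (uint64 arithmetic wraps, matching the masked Python ints) ---

_GAMMA_U = np.uint64(_GAMMA)
_M1_U = np.uint64(0xBF58476D1CE4E5B9)
_M2_U = np.uint64(0x94D049BB133111EB)


@njit(cache=True, inline="always")
def mix64_nb(z):
    z = z + _GAMMA_U
    z = (z ^ (z >> np.uint64(30))) * _M1_U
    z = (z ^ (z >> np.uint64(27))) * _M2_U
    return z ^ (z >> np.uint64(31))


@njit(cache=True, inline="always")
def stream_key_nb(seed, person):
    return mix64_nb(mix64_nb(seed) ^ mix64_nb(person))


@njit(cache=True, inline="always")
def u01_nb(key, counter):
    h = mix64_nb(key + counter * _GAMMA_U)
    return (h >> np.uint64(11)) * _INV_2_53
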