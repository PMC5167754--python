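"""Counter-based random streams.

Every stochastic decision in the simulator is a pure function of
``(seed, unit, time, purpose)`` hashed through a splitmix64 finalizer.
There is no sequential generator state: the same configuration and seed
produce bit-identical results regardless of iteration order, engine
(pure-Python reference vs. compiled kernel), or chunking of the run.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = [
    "uniform",
    "uniform_int",
    "SALT_DYNAMICS",
    "SALT_CHANNEL_ORDER",
    "SALT_INIT_V",
    "SALT_SIGNATURE",
    "SALT_STIMULUS",
]

# Stream purposes.  Distinct salts keep the per-(unit, time) streams
# independent of each other.
SALT_DYNAMICS = 1  # subthreshold / intra-burst Bernoulli(p) increments
SALT_CHANNEL_ORDER = 2  # random channel-processing permutation
SALT_INIT_V = 3  # initial membrane potentials
SALT_SIGNATURE = 4  # random signature ISIs
SALT_STIMULUS = 5  # stimulated-cell placement

_INV_2_53 = 1.0 / (1 << 53)


@njit("uint64(uint64)", cache=True)
def _splitmix64(z):
    z = z + np.uint64(0x9E3779B97F4A7C15)
    z = (z ^ (z >> np.uint64(30))) * np.uint64(0xBF58476D1CE4E5B9)
    z = (z ^ (z >> np.uint64(27))) * np.uint64(0x94D049BB133111EB)
    return z ^ (z >> np.uint64(31))


@njit("uint64(uint64, uint64, uint64, uint64)", cache=True)
def _hash4(seed, unit, time, salt):
    h = _splitmix64(salt)
    h = _splitmix64(h ^ time)
    h = _splitmix64(h ^ unit)
    h = _splitmix64(h ^ seed)
    return h


@njit("float64(uint64, uint64, uint64, uint64)", cache=True)
def _uniform(seed, unit, time, salt):
    return (_hash4(seed, unit, time, salt) >> np.uint64(11)) * _INV_2_53


def uniform(seed: int, unit: int, time: int, salt: int) -> float:
    """Uniform draw in [0, 1) for stream (seed, unit, time, salt)."""
    return _uniform(
        np.uint64(seed), np.uint64(unit), np.uint64(time), np.uint64(salt)
    )


def uniform_int(seed: int, unit: int, time: int, salt: int, n: int) -> int:
    """Uniform integer in [0, n) for stream (seed, unit, time, salt)."""
    return int(uniform(seed, unit, time, salt) * n)
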