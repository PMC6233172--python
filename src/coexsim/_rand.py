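"""Counter-based uniform/normal draws keyed on (seed, tag, step, entity ids).

The simulation needs randomness that is addressable per (time step, locality,
species) rather than sequential: paired scenario runs must see identical
climate, adaptation and extinction-hazard draws for every population they
share, even after their communities diverge.  A splitmix64-style avalanche
hash gives high-quality 64-bit streams for that purpose.
"""

from __future__ import annotations

import numpy as np
from scipy.special import ndtri

_U = np.uint64
_M1 = _U(0xBF58476D1CE4E5B9)
_M2 = _U(0x94D049BB133111EB)
_GOLDEN = _U(0x9E3779B97F4A7C15)

# stream tags (arbitrary distinct constants)
TAG_TEMP = 0x01
TAG_ADAPT_SEL = 0x02
TAG_ADAPT_SHIFT = 0x03
TAG_HAZARD = 0x04


def _mix(x: np.ndarray) -> np.ndarray:
    # splitmix64 finalizer (Steele, Lea & Flood), vectorized on uint64
    x = (x ^ (x >> _U(30))) * _M1
    x = (x ^ (x >> _U(27))) * _M2
    return x ^ (x >> _U(31))


def key_from(*parts: int) -> np.uint64:
    """Fold integer parts (seed, tag, step, locality id, ...) into a 64-bit key."""
    with np.errstate(over="ignore"):
        k = _U(0)
        for p in parts:
            k = _mix((k + _U(int(p) & 0xFFFFFFFFFFFFFFFF)) * _GOLDEN)
    return k


def uniforms(key: np.uint64, ids) -> np.ndarray:
    """Uniform(0,1) draws, one per entity id, deterministic in (key, id)."""
    ids = np.asarray(ids, dtype=np.uint64)
    with np.errstate(over="ignore"):
        h = _mix((ids + _U(1)) * _GOLDEN ^ key)
    u = (h >> _U(11)).astype(np.float64) * 2.0**-53
    # keep strictly inside (0,1) so ndtri stays finite
    return np.clip(u, 1e-16, 1.0 - 1e-16)


def normals(key: np.uint64, ids, mean: float = 0.0, sd: float = 1.0) -> np.ndarray:
    """Gaussian draws per entity id via the inverse normal CDF."""
    return mean + sd * ndtri(uniforms(key, ids))
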