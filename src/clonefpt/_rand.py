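"""Counter-free xorshift128+ bit stream for the numba kernels.

The walk and lattice kernels need a uniform stream whose state is a plain
uint64 array, so it can be passed into and out of njit functions and split
deterministically across replicates.  State is seeded via splitmix64.
"""

from __future__ import annotations

import numba as nb
import numpy as np

_MASK = 0xFFFFFFFFFFFFFFFF


def seed_state(seed: int) -> np.ndarray:
    """Expand an integer seed into a non-zero xorshift128+ state."""
    x = int(seed) & _MASK
    out = np.empty(2, dtype=np.uint64)
    for i in range(2):
        x = (x + 0x9E3779B97F4A7C15) & _MASK
        z = x
        z = ((z ^ (z >> 30)) * 0xBF58476D1CE4E5B9) & _MASK
        z = ((z ^ (z >> 27)) * 0x94D049BB133111EB) & _MASK
        out[i] = np.uint64(z ^ (z >> 31))
    if out[0] == 0 and out[1] == 0:
        out[0] = np.uint64(0x9E3779B97F4A7C15)
    return out


@nb.njit(inline="always", cache=True)
def next_u64(state):
    s1 = state[0]
    s0 = state[1]
    state[0] = s0
    s1 ^= s1 << np.uint64(23)
    s1 = s1 ^ s0 ^ (s1 >> np.uint64(17)) ^ (s0 >> np.uint64(26))
    state[1] = s1
    return s1 + s0


@nb.njit(inline="always", cache=True)
def rand_f64(state):
    """Uniform double in [0, 1)."""
    return (next_u64(state) >> np.uint64(11)) * (1.0 / 9007199254740992.0)


@nb.njit(inline="always", cache=True)
def rand_below(state, n):
    """Uniform integer in [0, n).  Modulo bias is < 2**-32 for our n."""
    return np.int64(next_u64(state) % np.uint64(n))
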