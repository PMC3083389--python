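"""Numba-compiled inner loops for the resource phase.

These implement exactly the documented semantics — the vectorised numpy
formulations are kept in ``resources.py`` docstrings and the test oracles —
but as fused single-pass loops, since the resource phase runs ``t_a`` times
per step and dominates the runtime.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["absorb_sequential", "diffuse_bounded"]


@njit(cache=True)
def absorb_sequential(flat: np.ndarray, perm: np.ndarray, store: np.ndarray,
                      flat_ox: np.ndarray, quota: float) -> float:
    """Sequential absorption in the order given by ``perm``.

    Visiting cells in a uniformly-random global permutation makes the draw
    order within every patch uniformly random, which is the contention rule:
    each cell takes ``min(remaining patch oxygen, quota)``.  Returns the
    total absorbed.  Mutates ``store`` and ``flat_ox`` in place.
    """
    total = 0.0
    for j in range(perm.size):
        i = perm[j]
        p = flat[i]
        a = flat_ox[p]
        if a > 0.0:
            t = a if a < quota else quota
            store[i] += t
            flat_ox[p] = a - t
            total += t
    return total


@njit(cache=True)
def diffuse_bounded(f: np.ndarray, d_c: float) -> np.ndarray:
    """One synchronous bounded-world diffusion pass.

    Each patch keeps ``(1 - d_c)`` of its oxygen plus the ``d_c/8`` shares
    addressed to off-grid neighbours; each existing neighbour receives
    ``d_c/8`` of the patch's pre-update value.  Mass-conserving by
    construction.
    """
    w, h = f.shape
    share = d_c / 8.0
    out = np.empty_like(f)
    for x in range(w):
        for y in range(h):
            nb = 0.0
            cnt = 0
            for dx in (-1, 0, 1):
                xx = x + dx
                if xx < 0 or xx >= w:
                    continue
                for dy in (-1, 0, 1):
                    if dx == 0 and dy == 0:
                        continue
                    yy = y + dy
                    if yy < 0 or yy >= h:
                        continue
                    nb += f[xx, yy]
                    cnt += 1
            out[x, y] = (1.0 - d_c) * f[x, y] + share * nb + share * (8.0 - cnt) * f[x, y]
    return out
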