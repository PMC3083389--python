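"""Vessel dynamics: occlusion, fixed-lifespan expiry, homeostatic angiogenesis.

The model keeps a homeostatic target of ``V`` microvessels.  Vessels are lost
either by crowding occlusion (variable-lifespan regime: strictly more than
``t_o`` cells on the vessel's patch) or by fixed-lifespan expiry (age >=
``t_f``).  Angiogenesis then tops the count back up by sprouting new vessels
on hypoxic patches (oxygen < ``t_h``) that hold at least one cell — the cell
is what signals for angiogenesis.  If fewer eligible patches exist than the
deficit, as many vessels as possible are placed and the deficit carries over
to the next step (V is an equilibrium target, not a hard constraint).  A
patch hosts at most one vessel at all times.
"""

from __future__ import annotations

import numpy as np

from .state import SimState, VesselTable, cell_counts

__all__ = ["occlude_variable", "expire_fixed", "angiogenesis"]


def occlude_variable(state: SimState, t_o: int, width: int, height: int) -> int:
    """Remove every vessel whose patch holds strictly more than ``t_o`` cells.

    Returns the number of vessels occluded.  Runs before the resource phase,
    so a newly occluded vessel delivers no oxygen in the same step.
    """
    v = state.vessels
    if v.n == 0:
        return 0
    counts = cell_counts(state.cells, width, height)
    keep = counts[v.flat_index(height)] <= t_o
    removed = int(v.n - keep.sum())
    if removed:
        state.vessels = v.take(np.flatnonzero(keep))
    return removed


def expire_fixed(state: SimState, t_f: float) -> int:
    """Remove vessels with age >= ``t_f``; infinite ``t_f`` means static
    vessels that never expire.  Returns the number removed."""
    v = state.vessels
    if v.n == 0 or not np.isfinite(t_f):
        return 0
    keep = v.age < t_f
    removed = int(v.n - keep.sum())
    if removed:
        state.vessels = v.take(np.flatnonzero(keep))
    return removed


def angiogenesis(state: SimState, n_target: int, t_h: float,
                 width: int, height: int) -> int:
    """Sprout up to ``n_target - v`` new vessels on eligible patches.

    A patch is eligible when its oxygen is strictly below ``t_h``, it holds
    at least one cell, and it has no vessel.  New vessels (age 0) are placed
    uniformly at random without replacement; if eligible patches are scarcer
    than the deficit the remainder carries over implicitly (the deficit is
    recomputed next step).  Returns the number of vessels added.
    """
    deficit = n_target - state.vessels.n
    if deficit <= 0:
        return 0
    counts = cell_counts(state.cells, width, height)
    hypoxic = state.oxygen.ravel() < t_h
    occupied = counts >= 1
    vacant = np.ones(width * height, dtype=bool)
    if state.vessels.n:
        vacant[state.vessels.flat_index(height)] = False
    eligible = np.flatnonzero(hypoxic & occupied & vacant)
    if eligible.size == 0:
        return 0
    k = min(deficit, eligible.size)
    pick = state.rng.choice(eligible, size=k, replace=False)
    new = VesselTable(pick // height, pick % height, np.zeros(k, dtype=np.int64))
    v = state.vessels
    state.vessels = VesselTable(
        np.concatenate([v.x, new.x]),
        np.concatenate([v.y, new.y]),
        np.concatenate([v.age, new.age]),
    )
    return k
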