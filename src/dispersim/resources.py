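"""Oxygen dynamics: injection, 8-neighbour diffusion, absorption, metabolism.

Each 12-hour time step runs ``t_a`` identical sub-updates.  A sub-update
injects ``r_i/t_a`` oxygen units at every vessel patch, performs one
synchronous diffusion pass, lets cells absorb up to ``r_a/t_a`` each from
their host patch (sequentially in random order where several cells share a
patch), and charges each cell ``r_m/t_a`` of stored oxygen for metabolism
(clamped at zero; death is adjudicated later, at the fate stage).

Diffusion is the bounded-world share rule: a patch sends ``d_c/8`` of its
pre-update oxygen to each *existing* neighbour and keeps the shares addressed
to off-grid neighbours, so total mass is conserved exactly (up to float
rounding) without boundary leakage.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._kernels import absorb_sequential, diffuse_bounded
from .config import SimConfig
from .state import CellTable, SimState, VesselTable

__all__ = [
    "inject", "diffuse", "absorb", "metabolize", "absorb_and_metabolize",
    "resource_substep", "resource_phase", "mean_available_resource", "ResourceLedger",
]


@dataclass
class ResourceLedger:
    """Oxygen bookkeeping for one or more sub-updates.

    ``injected`` enters at vessels, ``absorbed`` moves grid -> cell stores,
    ``metabolized`` leaves cell stores.  The closure identity
    ``delta(total oxygen) = injected - metabolized`` (absorption is an
    internal transfer) holds to float tolerance and is asserted in tests.
    """

    injected: float = 0.0
    absorbed: float = 0.0
    metabolized: float = 0.0

    def add(self, other: "ResourceLedger") -> None:
        self.injected += other.injected
        self.absorbed += other.absorbed
        self.metabolized += other.metabolized


def inject(oxygen: np.ndarray, vessels: VesselTable, amount: float) -> None:
    """Add ``amount`` oxygen units to every vessel patch, in place.

    Vessel patches are distinct by construction (one vessel per patch)."""
    oxygen[vessels.x, vessels.y] += amount


def diffuse(oxygen: np.ndarray, d_c: float) -> np.ndarray:
    """One synchronous diffusion pass; returns the new field.

    new = (1 - d_c) * f  +  (d_c/8) * sum(existing neighbours)
                         +  (d_c/8) * (8 - #existing neighbours) * f
    """
    if d_c == 0.0:
        return oxygen.copy()
    return diffuse_bounded(oxygen, d_c)


def absorb(oxygen: np.ndarray, cells: CellTable, quota: float,
           rng: np.random.Generator) -> float:
    """Cells draw oxygen from their host patches, sequentially per patch.

    Each cell takes ``min(remaining patch oxygen, quota)``; where several
    cells share a patch they draw in a fresh uniformly-random order, so a
    patch is never driven negative and contention carries no positional
    bias.  Returns the total amount absorbed.  Mutates ``oxygen`` and
    ``cells.store`` in place.
    """
    n = cells.n
    if n == 0 or quota <= 0.0:
        return 0.0
    h = oxygen.shape[1]
    flat = cells.flat_index(h)
    # visiting cells in a uniformly-random global permutation makes the
    # within-patch draw order uniformly random
    perm = rng.permutation(n)
    return absorb_sequential(flat, perm, cells.store, oxygen.ravel(), quota)


def metabolize(cells: CellTable, cost: float) -> float:
    """Charge each cell ``cost`` stored oxygen, clamping at zero.

    Returns the total actually metabolised (cells cannot go into debt)."""
    if cells.n == 0:
        return 0.0
    used = np.minimum(cells.store, cost)
    cells.store -= used
    return float(used.sum())


def absorb_and_metabolize(oxygen: np.ndarray, cells: CellTable, r_a: float,
                          r_m: float, t_a: int, rng: np.random.Generator
                          ) -> tuple[float, float]:
    """One sub-update's absorption (quota ``r_a/t_a``) then metabolism
    (cost ``r_m/t_a``); returns (absorbed, metabolized) totals."""
    absorbed = absorb(oxygen, cells, r_a / t_a, rng)
    used = metabolize(cells, r_m / t_a)
    return absorbed, used


def resource_substep(state: SimState, config: SimConfig) -> ResourceLedger:
    """One sub-update: inject -> diffuse -> absorb -> metabolize."""
    led = ResourceLedger()
    per_vessel = config.r_i / config.t_a
    inject(state.oxygen, state.vessels, per_vessel)
    led.injected = per_vessel * state.vessels.n
    state.oxygen = diffuse(state.oxygen, config.d_c)
    led.absorbed, led.metabolized = absorb_and_metabolize(
        state.oxygen, state.cells, config.r_a, config.r_m, config.t_a, state.rng)
    return led


def resource_phase(state: SimState, config: SimConfig) -> ResourceLedger:
    """Run the ``t_a`` resource sub-updates of one time step."""
    led = ResourceLedger()
    for _ in range(config.t_a):
        led.add(resource_substep(state, config))
    return led


def mean_available_resource(oxygen: np.ndarray) -> float:
    """Mean oxygen per patch currently unabsorbed — the 'available resource'
    whose spatial/temporal heterogeneity drives selection for migration."""
    return float(oxygen.mean())
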