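"""World state: cell and vessel tables, the oxygen grid, and initialisation.

Cells and vessels are stored struct-of-arrays (one numpy array per field) so
that the per-step update rules vectorise; a table row is one agent.  Cells
occupy lattice patches (several cells may share a patch); a patch hosts at
most one vessel.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .config import SimConfig

__all__ = ["CellTable", "VesselTable", "SimState", "init_state", "cell_counts"]


@dataclass
class CellTable:
    """Columnar table of cells.

    ``x``/``y`` are patch coordinates (always interior: edge patches are
    absorbing), ``store`` the per-cell oxygen reserve ``n_i``, ``p`` the
    migration propensity in [0, 1], ``m`` the maximum migration distance
    (continuous, >= 0), and ``thr`` the per-cell reproduction threshold
    (present only when the threshold is evolvable).
    """

    x: np.ndarray
    y: np.ndarray
    store: np.ndarray
    p: np.ndarray
    m: np.ndarray
    thr: Optional[np.ndarray] = None

    @property
    def n(self) -> int:
        return self.x.size

    def flat_index(self, height: int) -> np.ndarray:
        """Row-major patch index x*height + y for each cell."""
        return self.x * height + self.y

    def take(self, idx: np.ndarray) -> "CellTable":
        return CellTable(
            self.x[idx], self.y[idx], self.store[idx], self.p[idx], self.m[idx],
            None if self.thr is None else self.thr[idx],
        )

    @staticmethod
    def empty(evolvable_threshold: bool = False) -> "CellTable":
        z = np.zeros(0)
        zi = np.zeros(0, dtype=np.int64)
        return CellTable(zi, zi.copy(), z, z.copy(), z.copy(),
                         z.copy() if evolvable_threshold else None)

    @staticmethod
    def concat(tables: list["CellTable"]) -> "CellTable":
        tables = [t for t in tables if t.n > 0] or tables[:1]
        has_thr = tables[0].thr is not None
        return CellTable(
            np.concatenate([t.x for t in tables]),
            np.concatenate([t.y for t in tables]),
            np.concatenate([t.store for t in tables]),
            np.concatenate([t.p for t in tables]),
            np.concatenate([t.m for t in tables]),
            np.concatenate([t.thr for t in tables]) if has_thr else None,
        )


@dataclass
class VesselTable:
    """Columnar table of microvessels: patch coordinates and age in steps."""

    x: np.ndarray
    y: np.ndarray
    age: np.ndarray

    @property
    def n(self) -> int:
        return self.x.size

    def flat_index(self, height: int) -> np.ndarray:
        return self.x * height + self.y

    def take(self, idx: np.ndarray) -> "VesselTable":
        return VesselTable(self.x[idx], self.y[idx], self.age[idx])

    @staticmethod
    def empty() -> "VesselTable":
        zi = np.zeros(0, dtype=np.int64)
        return VesselTable(zi, zi.copy(), zi.copy())


@dataclass
class SimState:
    """Complete mutable simulation state for one run."""

    t: int
    oxygen: np.ndarray          # (width, height) non-negative oxygen field
    cells: CellTable
    vessels: VesselTable
    rng: np.random.Generator
    emigrants_this_step: int = 0

    def total_oxygen(self) -> float:
        """Grid oxygen plus all cell stores (the conserved ledger quantity)."""
        return float(self.oxygen.sum() + self.cells.store.sum())


def cell_counts(cells: CellTable, width: int, height: int) -> np.ndarray:
    """Number of cells on each patch, as a flat array of length width*height."""
    return np.bincount(cells.flat_index(height), minlength=width * height)


def init_state(config: SimConfig) -> SimState:
    """Construct the seeded initial state.

    ``init_cells`` cells are placed uniformly at random on *interior* patches
    (an edge patch would make a cell an emigrant by rule, so seeding one there
    would inject spurious t=0 emigration).  Vessels occupy every patch in the
    uniform regime, otherwise ``n_vessels`` distinct patches chosen uniformly.
    The oxygen field starts at zero.  Identical ``(config, seed)`` yields a
    bit-identical state; the draw order is fixed (cell positions, phenotypes,
    then vessel positions).
    """
    rng = np.random.default_rng(config.seed)
    w, h = config.width, config.height
    c = config.init_cells

    x = rng.integers(1, w - 1, size=c).astype(np.int64)
    y = rng.integers(1, h - 1, size=c).astype(np.int64)
    if config.init_mode == "fixed":
        p = np.full(c, float(config.p0))
        m = np.full(c, float(config.m0))
    else:  # uniform_random
        p = rng.uniform(0.0, config.p_max, size=c)
        m = rng.uniform(0.0, config.m_max, size=c)
    store = np.full(c, float(config.init_store))
    thr = np.full(c, float(config.n_r)) if config.threshold_evolvable else None
    cells = CellTable(x, y, store, p, m, thr)

    if config.vessel_regime == "uniform":
        flat = np.arange(config.n_patches, dtype=np.int64)
    else:
        flat = rng.choice(config.n_patches, size=config.n_vessels, replace=False).astype(np.int64)
    if config.vessel_regime == "fixed_lifespan" and np.isfinite(config.t_f):
        # pre-existing vasculature has mixed ages: stagger uniformly over one
        # lifespan so expiry proceeds in rolling cohorts rather than the whole
        # vessel population collapsing and regrowing in lockstep every t_f steps
        ages = rng.integers(0, max(int(config.t_f), 1), size=flat.size).astype(np.int64)
    else:
        ages = np.zeros(flat.size, dtype=np.int64)
    vessels = VesselTable(flat // h, flat % h, ages)

    oxygen = np.zeros((w, h), dtype=np.float64)
    return SimState(t=0, oxygen=oxygen, cells=cells, vessels=vessels, rng=rng)
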