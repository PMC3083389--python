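"""Per-step scheduler, full-run driver, and metric collection.

Phase order within one 12-hour time step:

1. vessel loss — crowding occlusion (variable regime) or lifespan expiry
   (fixed regime); nothing in the uniform/static regimes;
2. angiogenesis top-up toward the homeostatic vessel count (fixed and
   variable regimes only — the others hold v = V by construction);
3. ``t_a`` resource sub-updates (inject, diffuse, absorb, metabolize);
4. cell phase — fate partition, deaths removed, dividing parents replaced by
   two daughters (inert until the next step), movers execute their movement
   attempt, emigrants removed and counted;
5. vessel ages and the clock advance; per-step metrics are collected.

A run executes ``n_steps`` steps and summarises the final ``window`` steps
(the equilibrium window).  Extinction terminates a run early and flags the
summary invalid rather than silently averaging a short window.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .cells import FATE_DEATH, FATE_DIVIDE, FATE_MOVE, classify_fates, make_daughters, move_cells
from .config import SimConfig
from .resources import ResourceLedger, mean_available_resource, resource_phase
from .state import CellTable, SimState, init_state
from .vasculature import angiogenesis, expire_fixed, occlude_variable

__all__ = ["StepMetrics", "RunSummary", "step", "run", "collect_metrics"]

#: per-step metric column order used for traces
TRACE_COLUMNS = ["t", "n_cells", "n_vessels", "mean_p", "mean_m", "emd",
                 "emigrants", "mean_available", "deaths", "divisions",
                 "mean_threshold"]


@dataclass
class StepMetrics:
    """Metrics for one completed time step.

    ``emd`` is the expected migration distance, the product of the population
    mean migration propensity and mean maximum migration distance — the
    expected distance a cell travels in one time step.  Population means are
    NaN when no cells remain.
    """

    t: int
    n_cells: int
    n_vessels: int
    mean_p: float
    mean_m: float
    emd: float
    emigrants: int
    mean_available: float
    deaths: int = 0
    divisions: int = 0
    mean_threshold: float = math.nan
    ledger: Optional[ResourceLedger] = None
    emigrant_store: float = 0.0


@dataclass
class RunSummary:
    """Equilibrium-window averages for one run, plus provenance.

    Each metric is the mean of its per-step value over the final ``window``
    steps.  ``valid`` is False when the run went extinct before completing
    ``n_steps`` (the window would be short, so it is not averaged).
    """

    mean_p: float
    mean_m: float
    emd: float
    emigrants_per_step: float
    mean_available: float
    mean_cells: float
    mean_vessels: float
    mean_threshold: float
    steps_run: int
    extinct: bool
    valid: bool
    seed: int
    config: dict

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in (
            "mean_p", "mean_m", "emd", "emigrants_per_step", "mean_available",
            "mean_cells", "mean_vessels", "mean_threshold", "steps_run",
            "extinct", "valid", "seed")} | {"config": self.config}


def collect_metrics(state: SimState, emigrants: int = 0, deaths: int = 0,
                    divisions: int = 0) -> StepMetrics:
    """Population means over living cells plus world-level metrics.

    With zero cells the phenotype means are NaN (undefined markers) and the
    emigrant count stands as given.
    """
    c = state.cells
    if c.n:
        mean_p = float(c.p.mean())
        mean_m = float(c.m.mean())
        mean_thr = float(c.thr.mean()) if c.thr is not None else math.nan
    else:
        mean_p = mean_m = mean_thr = math.nan
    return StepMetrics(
        t=state.t, n_cells=c.n, n_vessels=state.vessels.n,
        mean_p=mean_p, mean_m=mean_m, emd=mean_p * mean_m,
        emigrants=emigrants, mean_available=mean_available_resource(state.oxygen),
        deaths=deaths, divisions=divisions, mean_threshold=mean_thr,
    )


def step(state: SimState, config: SimConfig) -> StepMetrics:
    """Advance the state by one time step; returns the step's metrics."""
    w, h = config.width, config.height

    # 1-2: vessel loss, then homeostatic angiogenesis
    if config.vessel_regime == "variable_lifespan":
        occlude_variable(state, config.t_o, w, h)
        angiogenesis(state, config.n_vessels, config.t_h, w, h)
    elif config.vessel_regime == "fixed_lifespan":
        expire_fixed(state, config.t_f)
        angiogenesis(state, config.n_vessels, config.t_h, w, h)

    # 3: resource dynamics
    ledger = resource_phase(state, config)

    # 4: cell phase.  The fate partition is fixed at phase entry; deaths,
    # divisions and movements are then independent of one another (no rule
    # reads other cells' positions within the phase), so iteration order is
    # immaterial and the phase vectorises.
    cells = state.cells
    threshold = cells.thr if cells.thr is not None else config.n_r
    fates = classify_fates(cells.store, threshold)
    deaths = int((fates == FATE_DEATH).sum())
    dividers = np.flatnonzero(fates == FATE_DIVIDE)
    movers = np.flatnonzero(fates == FATE_MOVE)

    daughters = make_daughters(cells.take(dividers), config, state.rng)
    emigrated = move_cells(cells, movers, state.oxygen, config.movement, state.rng)
    emigrants = int(emigrated.sum())
    emigrant_store = float(cells.store[emigrated].sum())

    survivors = cells.take(np.flatnonzero((fates == FATE_MOVE) & ~emigrated))
    state.cells = CellTable.concat([survivors, daughters])
    state.emigrants_this_step = emigrants

    # 5: clock
    state.vessels.age += 1
    state.t += 1

    metrics = collect_metrics(state, emigrants=emigrants, deaths=deaths,
                              divisions=dividers.size)
    metrics.ledger = ledger
    metrics.emigrant_store = emigrant_store
    return metrics


def run(config: SimConfig, collect_trace: bool = False
        ) -> RunSummary | tuple[RunSummary, pd.DataFrame]:
    """Run ``n_steps`` steps from the seeded initial state and summarise the
    final ``window`` steps.

    Extinction (zero cells) terminates the run early; the summary is then
    flagged ``extinct`` and, if fewer than ``window`` post-extinction steps
    were completed, ``valid=False``.  With ``collect_trace`` the full
    per-step metrics table (one row per time step) is returned as well.
    """
    state = init_state(config)
    window = config.window
    tail: list[StepMetrics] = []
    trace_rows: list[list] = []
    extinct = False

    for _ in range(config.n_steps):
        metrics = step(state, config)
        tail.append(metrics)
        if len(tail) > window:
            tail.pop(0)
        if collect_trace:
            trace_rows.append([metrics.t, metrics.n_cells, metrics.n_vessels,
                               metrics.mean_p, metrics.mean_m, metrics.emd,
                               metrics.emigrants, metrics.mean_available,
                               metrics.deaths, metrics.divisions,
                               metrics.mean_threshold])
        if state.cells.n == 0:
            extinct = True
            break

    valid = (not extinct) and len(tail) == window

    def _mean(attr: str) -> float:
        vals = [getattr(m, attr) for m in tail]
        return float(np.mean(vals)) if vals else math.nan

    summary = RunSummary(
        mean_p=_mean("mean_p"), mean_m=_mean("mean_m"), emd=_mean("emd"),
        emigrants_per_step=_mean("emigrants"), mean_available=_mean("mean_available"),
        mean_cells=_mean("n_cells"), mean_vessels=_mean("n_vessels"),
        mean_threshold=_mean("mean_threshold"),
        steps_run=state.t, extinct=extinct, valid=valid,
        seed=config.seed, config=config.to_dict(),
    )
    if collect_trace:
        return summary, pd.DataFrame(trace_rows, columns=TRACE_COLUMNS)
    return summary
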