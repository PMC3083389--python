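"""Cell fate, division with truncated-normal mutation, and movement.

Fate is a strict partition on the stored-oxygen level ``n_i``:

* ``n_i = 0``            -> death,
* ``n_i > n_r``          -> division (store split equally; phenotypes mutate
  with probability ``mu`` per daughter per phenotype via truncated normals),
* ``0 < n_i <= n_r``     -> movement attempt (move with probability ``p_i``).

Movement realises the continuous phenotype ``m_i`` as a step count
``k = floor(m_i) + Bernoulli(frac(m_i))`` (unbiased: E[k] = m_i).  Each step
goes to one of the nine closest patches — the current patch and its eight
neighbours.  The random strategy picks uniformly among the nine; gradient
ascent moves to the oxygen-richest of the nine (ties broken uniformly) and
stops for good if the current patch is itself the maximum.  A cell landing on
an edge patch leaves the neoplasm: it is removed and counted as an emigrant,
the model's proxy for the first step of metastasis.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from .config import SimConfig
from .state import CellTable

__all__ = [
    "FATE_DEATH", "FATE_DIVIDE", "FATE_MOVE",
    "classify_fates", "decide_fate", "sample_truncated_normal",
    "make_daughters", "move_cells",
]

FATE_DEATH, FATE_DIVIDE, FATE_MOVE = 0, 1, 2

# the nine closest patches, row-major; index 4 is the current patch
_OFFX = np.array([-1, -1, -1, 0, 0, 0, 1, 1, 1])
_OFFY = np.array([-1, 0, 1, -1, 0, 1, -1, 0, 1])
_CENTER = 4


def classify_fates(store: np.ndarray, threshold: np.ndarray | float) -> np.ndarray:
    """Vectorized fate partition; ``threshold`` may be scalar or per-cell."""
    fates = np.full(store.shape, FATE_MOVE, dtype=np.int8)
    fates[store <= 0.0] = FATE_DEATH
    fates[store > threshold] = FATE_DIVIDE
    return fates


def decide_fate(store: float, threshold: float) -> int:
    """Scalar fate rule: death at 0, division strictly above the threshold,
    otherwise a movement attempt."""
    if store <= 0.0:
        return FATE_DEATH
    return FATE_DIVIDE if store > threshold else FATE_MOVE


def sample_truncated_normal(mean: np.ndarray | float, sd: float, low: float,
                            high: float, rng: np.random.Generator,
                            size: int | None = None) -> np.ndarray | float:
    """Draw from a normal(mean, sd) truncated to [low, high].

    ``mean`` may be an array (one draw per element).  ``high`` may be inf.
    """
    if sd <= 0:
        raise ValueError("sd must be > 0")
    if not low < high:
        raise ValueError("require low < high")
    mean = np.asarray(mean, dtype=np.float64)
    a = (low - mean) / sd
    b = (high - mean) / sd
    out = stats.truncnorm.rvs(a, b, loc=mean, scale=sd,
                              size=size if size is not None else mean.shape or None,
                              random_state=rng)
    return out


def _mutate(values: np.ndarray, mu: float, sd: float, low: float, high: float,
            rng: np.random.Generator) -> np.ndarray:
    """Each entry independently mutates with probability ``mu`` by a
    truncated-normal redraw centred on its current value."""
    out = values.copy()
    if mu <= 0.0 or values.size == 0:
        return out
    hit = rng.random(values.size) < mu
    k = int(hit.sum())
    if k:
        out[hit] = sample_truncated_normal(values[hit], sd, low, high, rng)
    return out


def make_daughters(parents: CellTable, config: SimConfig,
                   rng: np.random.Generator) -> CellTable:
    """Two daughters per parent: each inherits the parent's patch and half
    its store (exactly conserving oxygen), with phenotypes mutated
    independently per daughter and per phenotype with probability ``mu``.

    The propensity kernel truncates to [0, 1]; the distance kernel to
    [0, inf).  With an evolvable reproduction threshold, each daughter's
    threshold mutates with probability ``mu_thr`` (sd ``sd_thr``), bounded
    below by ``n_r_floor``.
    """
    rep = lambda a: np.concatenate([a, a])
    x, y = rep(parents.x), rep(parents.y)
    store = rep(parents.store) * 0.5
    p = _mutate(rep(parents.p), config.mu, config.sd_p, 0.0, 1.0, rng)
    m = _mutate(rep(parents.m), config.mu, config.sd_m, 0.0, np.inf, rng)
    thr = None
    if parents.thr is not None:
        thr = _mutate(rep(parents.thr), config.mu_thr, config.sd_thr,
                      config.n_r_floor, np.inf, rng)
    return CellTable(x, y, store, p, m, thr)


def move_cells(cells: CellTable, movers: np.ndarray, oxygen: np.ndarray,
               movement: str, rng: np.random.Generator) -> np.ndarray:
    """Execute movement attempts for ``cells`` rows indexed by ``movers``.

    Mutates ``cells.x``/``cells.y`` in place and returns a boolean mask over
    *all* cells marking those that emigrated (reached an edge patch) and must
    be removed.  Cells are interior before the call, so the 3x3 patch
    neighbourhood always exists; a cell that lands on an edge stops there and
    is flagged.
    """
    emigrated = np.zeros(cells.n, dtype=bool)
    if movers.size == 0:
        return emigrated
    w, h = oxygen.shape

    attempts = rng.random(movers.size) < cells.p[movers]
    m = cells.m[movers]
    whole = np.floor(m)
    k = whole.astype(np.int64) + (rng.random(movers.size) < (m - whole))
    k[~attempts] = 0

    remaining = k.copy()
    active = np.flatnonzero(remaining > 0)
    while active.size:
        idx = movers[active]
        if movement == "random":
            cells.x[idx] += rng.integers(-1, 2, size=active.size)
            cells.y[idx] += rng.integers(-1, 2, size=active.size)
        else:  # gradient ascent over the nine closest patches
            xs = cells.x[idx][:, None] + _OFFX[None, :]
            ys = cells.y[idx][:, None] + _OFFY[None, :]
            vals = oxygen[xs, ys]
            is_max = vals == vals.max(axis=1, keepdims=True)
            keys = rng.random(is_max.shape) * is_max
            choice = keys.argmax(axis=1)
            rows = np.arange(active.size)
            cells.x[idx] = xs[rows, choice]
            cells.y[idx] = ys[rows, choice]
            # a cell already at a local maximum stays put for the rest of
            # the attempt, even if it had capacity to move further
            remaining[active[choice == _CENTER]] = 0
        on_edge = ((cells.x[idx] == 0) | (cells.x[idx] == w - 1) |
                   (cells.y[idx] == 0) | (cells.y[idx] == h - 1))
        emigrated[idx[on_edge]] = True
        remaining[active] -= 1
        remaining[active[on_edge]] = 0
        active = np.flatnonzero(remaining > 0)
    return emigrated
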