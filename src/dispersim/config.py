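"""Simulation configuration: schema, defaults, and validation.

The model world is a ``width x height`` lattice of patches.  Oxygen (standing
in for any diffusible, vessel-delivered resource) is injected at microvessel
patches, diffuses to the eight lattice neighbours, and is consumed by cells.
Cells carry two heritable motility phenotypes — the migration propensity
``p`` (per-step probability of attempting a move) and the maximum migration
distance ``m`` (expected number of single-patch steps per attempt) — which
mutate at division via truncated-normal kernels.

Every tunable of the model lives in :class:`SimConfig`.  Raw key/value
mappings (e.g. parsed from a YAML file or CLI overrides) are turned into a
validated config by :func:`validate_config`, which applies defaults, resolves
regime-dependent fields and raises :class:`ConfigError` naming the offending
key on any out-of-range or inconsistent value.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Any, Mapping

__all__ = ["SimConfig", "ConfigError", "validate_config", "REGIMES", "MOVEMENTS", "INIT_MODES"]

#: Vessel regimes.  ``uniform``: one static vessel on every patch (spatially
#: homogeneous input); ``static``: V vessels fixed for the whole run;
#: ``fixed_lifespan``: vessels expire after ``t_f`` steps and are replaced by
#: angiogenesis; ``variable_lifespan``: vessels are occluded when more than
#: ``t_o`` cells crowd their patch and replaced by angiogenesis.
REGIMES = ("uniform", "static", "fixed_lifespan", "variable_lifespan")
MOVEMENTS = ("random", "gradient")
INIT_MODES = ("fixed", "uniform_random")


class ConfigError(ValueError):
    """Raised for invalid or inconsistent configuration values."""


@dataclass(frozen=True)
class SimConfig:
    """Fully resolved, validated simulation parameters.

    Construct via :func:`validate_config` rather than directly, so that
    regime-dependent resolution (e.g. the uniform regime forcing one vessel
    per patch) and range checks are applied.

    Attributes
    ----------
    width, height:
        Lattice dimensions in patches; the world has ``P = width * height``
        patches.  Edge patches are absorbing for cells (emigration).
    n_vessels:
        Homeostatic vessel count ``V``.  In the uniform regime this equals
        ``P`` (one vessel per patch).
    vessel_regime:
        One of :data:`REGIMES`.
    t_f:
        Vessel lifespan in time steps for the fixed-lifespan regime;
        ``math.inf`` in the static and uniform regimes.
    t_o:
        Occlusion threshold (variable-lifespan regime): a vessel is removed
        when *strictly more than* ``t_o`` cells occupy its patch.
    t_h:
        Hypoxia threshold in oxygen units; angiogenesis targets patches with
        oxygen strictly below ``t_h`` that hold at least one cell.
    total_input:
        Total oxygen input to the system per time step, summed over all
        vessels.  Each vessel delivers ``r_i = total_input / n_vessels``,
        so varying vessel number keeps the system-wide input constant.
    t_a:
        Number of resource sub-updates (inject, diffuse, absorb, metabolize)
        per 12-hour time step.
    d_c:
        Diffusion fraction in [0, 1]: each sub-update a patch sends
        ``d_c/8`` of its oxygen to each existing lattice neighbour and keeps
        the shares addressed to off-grid neighbours (mass-conserving bounded
        world).
    r_a:
        Maximum oxygen a cell can absorb per time step (``r_a/t_a`` per
        sub-update).
    r_m:
        Metabolic cost per cell per time step (``r_m/t_a`` per sub-update);
        stores clamp at zero and a cell with an empty store dies at the next
        fate stage.
    n_r:
        Reproduction threshold: a cell divides when its store strictly
        exceeds ``n_r``, splitting the store equally between two daughters.
    threshold_evolvable, mu_thr, sd_thr, n_r_floor:
        Optional evolvable reproduction threshold: each daughter's threshold
        mutates with probability ``mu_thr`` by a truncated-normal kernel of
        s.d. ``sd_thr`` bounded below by ``n_r_floor``.
    mu:
        Mutation probability per daughter and per phenotype at division.
    sd_p, sd_m:
        Truncated-normal mutation standard deviations for ``p`` (truncated to
        [0, 1]) and ``m`` (truncated to [0, inf)).
    movement:
        ``random`` — each of the k steps goes to one of the nine closest
        patches (the current patch and its eight neighbours) uniformly;
        ``gradient`` — each step ascends to the oxygen-richest of the nine,
        stopping at a local maximum.
    init_cells, init_mode, p0, m0, p_max, m_max, init_store:
        Initial population: ``init_cells`` cells placed uniformly at random
        on interior patches, each with ``init_store`` oxygen units.
        ``fixed`` mode gives every cell phenotypes ``(p0, m0)``;
        ``uniform_random`` draws them uniformly from ``[0, p_max]`` and
        ``[0, m_max]``.
    n_steps, window:
        Run length in time steps and the equilibrium averaging window (the
        final ``window`` steps) over which summary metrics are computed.
    seed:
        Seed for the single per-run PCG64 generator.
    """

    width: int = 64
    height: int = 64
    n_vessels: int = 100
    vessel_regime: str = "variable_lifespan"
    t_f: float = math.inf
    t_o: int = 20
    t_h: float = 1.0
    total_input: float = 25000.0
    t_a: int = 10
    d_c: float = 0.2
    r_a: float = 20.0
    r_m: float = 5.0
    n_r: float = 240.0
    threshold_evolvable: bool = False
    mu_thr: float = 0.01
    sd_thr: float = 20.0
    n_r_floor: float = 120.0
    mu: float = 0.01
    sd_p: float = 0.1
    sd_m: float = 1.0
    movement: str = "random"
    init_cells: int = 400
    init_mode: str = "fixed"
    p0: float = 0.05
    m0: float = 1.0
    p_max: float = 0.6
    m_max: float = 6.0
    init_store: float = 120.0
    n_steps: int = 5000
    window: int = 200
    seed: int = 0

    @property
    def n_patches(self) -> int:
        return self.width * self.height

    @property
    def r_i(self) -> float:
        """Per-vessel oxygen delivery per time step, ``total_input / V``."""
        return self.total_input / self.n_vessels

    def replace(self, **changes: Any) -> "SimConfig":
        """Return a re-validated copy with ``changes`` applied."""
        raw = dataclasses.asdict(self)
        raw.update(changes)
        return validate_config(raw)

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        d["r_i"] = self.r_i
        return d


_FIELDS = {f.name for f in dataclasses.fields(SimConfig)}


def _require(cond: bool, key: str, msg: str) -> None:
    if not cond:
        raise ConfigError(f"config key '{key}': {msg}")


def validate_config(raw: Mapping[str, Any] | None = None, **overrides: Any) -> SimConfig:
    """Build a validated :class:`SimConfig` from a raw mapping plus overrides.

    Unknown keys, out-of-range values and regime inconsistencies raise
    :class:`ConfigError` naming the offending key.  Regime resolution:

    * ``uniform`` forces ``n_vessels = width * height`` (one vessel per
      patch); supplying a different explicit value is an error.
    * ``uniform``/``static`` force an infinite vessel lifespan.
    * ``fixed_lifespan`` requires a finite ``t_f >= 1``.
    """
    values: dict[str, Any] = {}
    merged: dict[str, Any] = dict(raw or {})
    merged.update(overrides)
    explicit = set(merged)
    for key, val in merged.items():
        if key == "r_i":
            raise ConfigError("config key 'r_i': derived as total_input / n_vessels; set those instead")
        if key not in _FIELDS:
            raise ConfigError(f"config key '{key}': unknown parameter")
        values[key] = val

    cfg = dataclasses.replace(SimConfig(), **values)

    _require(cfg.vessel_regime in REGIMES, "vessel_regime", f"must be one of {REGIMES}")
    _require(cfg.movement in MOVEMENTS, "movement", f"must be one of {MOVEMENTS}")
    _require(cfg.init_mode in INIT_MODES, "init_mode", f"must be one of {INIT_MODES}")

    _require(int(cfg.width) >= 3, "width", "must be >= 3")
    _require(int(cfg.height) >= 3, "height", "must be >= 3")
    _require(0.0 <= cfg.d_c <= 1.0, "d_c", "must lie in [0, 1]")
    _require(int(cfg.t_a) >= 1, "t_a", "must be >= 1")
    _require(0.0 <= cfg.mu <= 1.0, "mu", "must lie in [0, 1]")
    _require(0.0 <= cfg.mu_thr <= 1.0, "mu_thr", "must lie in [0, 1]")
    for key in ("r_a", "r_m", "total_input", "t_h", "n_r", "init_store"):
        _require(getattr(cfg, key) >= 0, key, "must be >= 0")
    for key in ("sd_p", "sd_m", "sd_thr"):
        _require(getattr(cfg, key) > 0, key, "must be > 0")
    _require(int(cfg.init_cells) >= 0, "init_cells", "must be >= 0")
    _require(0.0 <= cfg.p0 <= 1.0, "p0", "must lie in [0, 1]")
    _require(cfg.m0 >= 0, "m0", "must be >= 0")
    _require(0.0 <= cfg.p_max <= 1.0, "p_max", "must lie in [0, 1]")
    _require(cfg.m_max >= 0, "m_max", "must be >= 0")
    _require(int(cfg.n_steps) >= 1, "n_steps", "must be >= 1")
    _require(1 <= int(cfg.window) <= int(cfg.n_steps), "window", "must satisfy 1 <= window <= n_steps")
    _require(int(cfg.t_o) >= 0, "t_o", "must be >= 0")
    _require(0 <= cfg.n_r_floor <= cfg.n_r, "n_r_floor", "must lie in [0, n_r]")

    # regime-dependent resolution
    p = int(cfg.width) * int(cfg.height)
    if cfg.vessel_regime == "uniform":
        if "n_vessels" in explicit and int(merged["n_vessels"]) != p:
            raise ConfigError(
                f"config key 'n_vessels': uniform regime requires one vessel per patch "
                f"(V = {p}), got {merged['n_vessels']}"
            )
        cfg = dataclasses.replace(cfg, n_vessels=p, t_f=math.inf)
    elif cfg.vessel_regime == "static":
        cfg = dataclasses.replace(cfg, t_f=math.inf)
    elif cfg.vessel_regime == "fixed_lifespan":
        _require(math.isfinite(cfg.t_f) and cfg.t_f >= 1, "t_f",
                 "fixed_lifespan regime requires a finite lifespan >= 1")

    _require(1 <= int(cfg.n_vessels), "n_vessels", "must be >= 1")
    _require(int(cfg.n_vessels) <= p, "n_vessels", f"must not exceed the patch count ({p})")

    # normalize integer-typed fields
    cfg = dataclasses.replace(
        cfg,
        width=int(cfg.width), height=int(cfg.height), n_vessels=int(cfg.n_vessels),
        t_a=int(cfg.t_a), t_o=int(cfg.t_o), init_cells=int(cfg.init_cells),
        n_steps=int(cfg.n_steps), window=int(cfg.window), seed=int(cfg.seed),
        t_f=float(cfg.t_f),
    )
    return cfg
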