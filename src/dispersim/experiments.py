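"""Experiment harness: parameter sweeps, named presets, and summaries.

The central experiment varies the degree of spatial heterogeneity (vessel
count ``V``) and temporal heterogeneity (fixed vessel lifespan ``t_f``) on a
log-spaced grid and asks how much cell migration evolves under each regime.
Per-vessel delivery ``r_i = total_input / V`` rescales automatically, so the
system-wide oxygen input is identical across conditions.

Every (condition, replicate) cell of a sweep derives its RNG seed from
``(base_seed, condition labels, replicate)`` through ``SeedSequence``, so
seeds do not depend on the order conditions are run in and partial sweeps
reproduce exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Sequence

import numpy as np
import pandas as pd

from .config import SimConfig, validate_config
from .simulation import run

__all__ = [
    "SweepSpec", "condition_seed", "run_sweep", "condition_means",
    "sweep_correlations", "run_preset", "PRESETS",
    "log_spaced_vessel_counts", "log_spaced_lifespans",
]

#: metric columns copied from RunSummary into result tables
_METRICS = ["mean_p", "mean_m", "emd", "emigrants_per_step", "mean_available",
            "mean_cells", "mean_vessels", "mean_threshold", "steps_run",
            "extinct", "valid", "seed"]


def log_spaced_vessel_counts(n: int = 5, lo: int = 30, hi: int = 600) -> list[int]:
    """Log-spaced vessel counts spanning [lo, hi] (default 30-600)."""
    return [int(round(v)) for v in np.geomspace(lo, hi, n)]


def log_spaced_lifespans(n: int = 4, lo: float = 4, hi: float = 500) -> list[int]:
    """Log-spaced vessel lifespans in time steps spanning [lo, hi]."""
    return [int(round(v)) for v in np.geomspace(lo, hi, n)]


@dataclass
class SweepSpec:
    """Fixed-lifespan sweep: vessel counts x lifespans x replicates."""

    vessel_counts: Sequence[int] = field(default_factory=log_spaced_vessel_counts)
    lifespans: Sequence[int] = field(default_factory=log_spaced_lifespans)
    movement: str = "random"
    replicates: int = 3
    base_seed: int = 0
    overrides: dict[str, Any] = field(default_factory=dict)


def condition_seed(base_seed: int, *labels: int) -> int:
    """Deterministic 31-bit seed keyed by (base_seed, labels), independent of
    the order in which conditions are executed."""
    ss = np.random.SeedSequence((int(base_seed),) + tuple(int(v) for v in labels))
    return int(ss.generate_state(1)[0] % (2 ** 31))


def _summary_row(summary) -> dict:
    return {k: getattr(summary, k) for k in _METRICS}


def run_sweep(spec: SweepSpec) -> pd.DataFrame:
    """Run the full sweep; one row per (vessel count, lifespan, replicate).

    Extinct/invalid replicates are retained in the table (flagged by the
    ``valid`` column) but excluded from condition means downstream.
    """
    rows = []
    movement_code = 0 if spec.movement == "random" else 1
    for v in spec.vessel_counts:
        for t_f in spec.lifespans:
            for rep in range(spec.replicates):
                seed = condition_seed(spec.base_seed, v, t_f, rep, movement_code)
                cfg = validate_config(dict(
                    vessel_regime="fixed_lifespan", n_vessels=v, t_f=float(t_f),
                    movement=spec.movement, seed=seed, **spec.overrides))
                row = {"n_vessels": v, "t_f": t_f, "rep": rep,
                       "movement": spec.movement}
                row.update(_summary_row(run(cfg)))
                rows.append(row)
    return pd.DataFrame(rows)


def condition_means(df: pd.DataFrame, by: Sequence[str] = ("n_vessels", "t_f")
                    ) -> pd.DataFrame:
    """Replicate means per condition over valid replicates only.

    Adds ``n_valid`` / ``n_invalid`` replicate counts per condition."""
    valid = df[df["valid"]]
    metrics = ["mean_p", "mean_m", "emd", "emigrants_per_step",
               "mean_available", "mean_cells", "mean_vessels"]
    out = valid.groupby(list(by), as_index=False)[metrics].mean()
    counts = df.groupby(list(by), as_index=False)["valid"].agg(
        n_valid="sum", n_invalid=lambda s: int((~s).sum()))
    return out.merge(counts, on=list(by))


def sweep_correlations(df: pd.DataFrame) -> dict:
    """Pearson correlations across sweep condition means.

    Returns r for the three headline relations: emigrants/step vs expected
    migration distance, available resource vs expected migration distance,
    and available resource vs emigrants/step.
    """
    from .stats import pearson_and_regression

    cm = condition_means(df)
    out = {
        "emigrants_vs_emd": pearson_and_regression(cm["emd"], cm["emigrants_per_step"]),
        "available_vs_emd": pearson_and_regression(cm["mean_available"], cm["emd"]),
        "available_vs_emigrants": pearson_and_regression(
            cm["mean_available"], cm["emigrants_per_step"]),
        "n_conditions": len(cm),
    }
    return out


def heterogeneity_regressions(df: pd.DataFrame) -> dict:
    """Two-factor regressions of each outcome on log vessel count and log
    lifespan, at replicate level: the test of whether increasing spatial
    heterogeneity (fewer vessels) and temporal heterogeneity (shorter
    lifespans) select for migration (negative slopes)."""
    from .stats import ols

    valid = df[df["valid"]]
    X = np.column_stack([np.log(valid["n_vessels"]), np.log(valid["t_f"])])
    return {outcome: ols(X, valid[outcome].to_numpy(),
                         names=["log_n_vessels", "log_t_f"])
            for outcome in ("emd", "emigrants_per_step")}


# ---------------------------------------------------------------------------
# presets: the named study experiments

def _run_conditions(conditions: list[dict], replicates: int, base_seed: int,
                    overrides: dict[str, Any]) -> pd.DataFrame:
    """Shared runner: each condition is {label columns, 'config': {...}}."""
    rows = []
    for ci, cond in enumerate(conditions):
        for rep in range(replicates):
            seed = condition_seed(base_seed, cond.get("seed_key", ci), rep)
            cfg_kw = dict(cond["config"])
            cfg_kw.update(overrides)
            cfg = validate_config(cfg_kw, seed=seed)
            row = {k: v for k, v in cond.items() if k not in ("config", "seed_key")}
            row["rep"] = rep
            row.update(_summary_row(run(cfg)))
            rows.append(row)
    return pd.DataFrame(rows)


def _preset_input_modes(scale: float) -> list[dict]:
    """Uniform input vs 100 static vessels vs 100 variable-lifespan vessels
    (occlusion threshold 20) — the spatial/temporal heterogeneity contrast."""
    return [
        {"condition": "uniform", "seed_key": 0,
         "config": {"vessel_regime": "uniform"}},
        {"condition": "static", "seed_key": 1,
         "config": {"vessel_regime": "static", "n_vessels": 100}},
        {"condition": "variable", "seed_key": 2,
         "config": {"vessel_regime": "variable_lifespan", "n_vessels": 100, "t_o": 20}},
    ]


def _preset_initial_conditions(scale: float) -> list[dict]:
    """Three initial phenotype schemes under variable-lifespan vessels:
    immobile (0, 0), low motility (0.05, 1), and per-cell uniform random
    phenotypes on [0, 0.6] x [0, 6]."""
    base = {"vessel_regime": "variable_lifespan", "n_vessels": 100, "t_o": 20}
    return [
        {"condition": "zero", "seed_key": 0,
         "config": dict(base, init_mode="fixed", p0=0.0, m0=0.0)},
        {"condition": "low", "seed_key": 1,
         "config": dict(base, init_mode="fixed", p0=0.05, m0=1.0)},
        {"condition": "uniform_random", "seed_key": 2,
         "config": dict(base, init_mode="uniform_random", p_max=0.6, m_max=6.0)},
    ]


def _preset_mutation_sd(scale: float) -> list[dict]:
    """Mutation-kernel sensitivity: sd_p in {0.01, 0.1} x sd_m in {0.1, 1}
    under each of the three input modes."""
    conds = []
    key = 0
    for sd_p in (0.01, 0.1):
        for sd_m in (0.1, 1.0):
            for mode in _preset_input_modes(scale):
                conds.append({
                    "condition": mode["condition"], "sd_p": sd_p, "sd_m": sd_m,
                    "seed_key": key,
                    "config": dict(mode["config"], sd_p=sd_p, sd_m=sd_m),
                })
                key += 1
    return conds


def _preset_evolvable_threshold(scale: float) -> list[dict]:
    """Evolvable reproduction threshold (mutation rate 1e-2, sd 20 units,
    initial 240, floor 120) under the three input modes."""
    conds = []
    for mode in _preset_input_modes(scale):
        conds.append({
            "condition": mode["condition"], "seed_key": mode["seed_key"],
            "config": dict(mode["config"], threshold_evolvable=True,
                           mu_thr=0.01, sd_thr=20.0, n_r=240.0, n_r_floor=120.0),
        })
    return conds


#: neoplasm-size scaling: grid sides for 1024..16384 patches with vessels
#: scaled 1:41 so vessel density is constant; lifespan fixed at 6 steps.
_SIZE_SCALING_GRIDS = [(32, 25), (46, 50), (64, 100), (90, 200), (128, 400)]


def _preset_size_scaling(scale: float) -> list[dict]:
    grids = _SIZE_SCALING_GRIDS
    if scale < 1.0:
        grids = grids[:max(2, int(round(len(grids) * scale)))]
    conds = []
    for i, (side, v) in enumerate(grids):
        conds.append({
            "condition": f"{side}x{side}", "patches": side * side,
            "n_vessels_label": v, "seed_key": i,
            "config": {"vessel_regime": "fixed_lifespan", "t_f": 6.0,
                       "width": side, "height": side, "n_vessels": v,
                       # per-vessel delivery equals the default r_i
                       # regardless of neoplasm size, so total input and the
                       # supportable population scale with size
                       "total_input": SimConfig().r_i * v},
        })
    return conds


def _preset_granularity(scale: float) -> list[dict]:
    """Resource-dynamics granularity: t_a = 10 vs t_a = 100, variable vessels."""
    base = {"vessel_regime": "variable_lifespan", "n_vessels": 100, "t_o": 20}
    return [
        {"condition": "t_a=10", "t_a": 10, "seed_key": 0, "config": dict(base, t_a=10)},
        {"condition": "t_a=100", "t_a": 100, "seed_key": 1, "config": dict(base, t_a=100)},
    ]


PRESETS = {
    "input_modes": _preset_input_modes,
    "initial_conditions": _preset_initial_conditions,
    "mutation_sd": _preset_mutation_sd,
    "evolvable_threshold": _preset_evolvable_threshold,
    "size_scaling": _preset_size_scaling,
    "granularity": _preset_granularity,
}


def run_preset(name: str, replicates: int = 10, base_seed: int = 0,
               scale: float = 1.0, **overrides: Any) -> pd.DataFrame:
    """Run a named preset experiment; returns a tidy replicate-level table.

    ``scale`` < 1 shrinks the run for desk execution by reducing steps
    (floor 300) and, for the size-scaling preset, dropping the largest
    grids; the scale factor and resulting step count are recorded in every
    row.  Extra ``overrides`` are applied to every condition's config.
    """
    if name not in PRESETS:
        raise KeyError(f"unknown preset '{name}'; known: {sorted(PRESETS)}")
    conditions = PRESETS[name](scale)
    n_steps = overrides.pop("n_steps", None)
    if n_steps is None:
        n_steps = max(300, int(round(5000 * scale)))
    df = _run_conditions(conditions, replicates, base_seed,
                         dict(overrides, n_steps=n_steps))
    df.insert(0, "preset", name)
    df["scale"] = scale
    df["n_steps"] = n_steps
    return df
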