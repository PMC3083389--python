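"""Result writers and snapshot rendering.

All tabular output is tidy CSV (one observation per row, header, stable
column order); run summaries and statistics reports are JSON.  Snapshots
follow the standard rendering convention for this model family: resource
density on a blue (low) to white (high) continuum, vessels as green circles,
cells overlaid with brightness proportional to their stored oxygen.
"""

from __future__ import annotations

import json
import logging
import math
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .config import SimConfig
from .state import SimState

__all__ = [
    "load_config_file", "save_run_outputs", "render_snapshot", "load_snapshot_tables",
]

log = logging.getLogger("dispersim")


def load_config_file(path: str | Path) -> dict:
    """Parse a YAML/JSON key-value config file into a raw mapping."""
    text = Path(path).read_text()
    data = yaml.safe_load(text) or {}
    if not isinstance(data, dict):
        raise ValueError(f"config file {path} must contain a key-value mapping")
    return data


def _jsonable(obj):
    if isinstance(obj, float) and math.isnan(obj):
        return None
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def save_run_outputs(outdir: str | Path, summary, trace: pd.DataFrame,
                     config: SimConfig) -> dict[str, Path]:
    """Write run_summary.json, step_metrics.csv and resolved_config.yaml
    (full provenance including the seed) into ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "summary": outdir / "run_summary.json",
        "trace": outdir / "step_metrics.csv",
        "config": outdir / "resolved_config.yaml",
    }
    d = {k: _jsonable(v) for k, v in summary.to_dict().items()}
    paths["summary"].write_text(json.dumps(d, indent=2, default=_jsonable) + "\n")
    trace.to_csv(paths["trace"], index=False)
    paths["config"].write_text(yaml.safe_dump(config.to_dict(), sort_keys=True))
    return paths


def render_snapshot(state: SimState, outdir: str | Path,
                    config: SimConfig | None = None) -> dict[str, Path]:
    """Write the oxygen grid as a CSV matrix, cell and vessel tables as tidy
    CSV, and a raster image of the world, into ``outdir``.

    Returns the mapping of artifact names to paths."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.colors import LinearSegmentedColormap

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "grid": outdir / "oxygen_grid.csv",
        "cells": outdir / "cells.csv",
        "vessels": outdir / "vessels.csv",
        "image": outdir / "snapshot.png",
    }

    np.savetxt(paths["grid"], state.oxygen, delimiter=",")
    c = state.cells
    cells_df = pd.DataFrame({"x": c.x, "y": c.y, "store": c.store, "p": c.p, "m": c.m})
    if c.thr is not None:
        cells_df["repro_threshold"] = c.thr
    cells_df.to_csv(paths["cells"], index=False)
    pd.DataFrame({"x": state.vessels.x, "y": state.vessels.y,
                  "age": state.vessels.age}).to_csv(paths["vessels"], index=False)

    cmap = LinearSegmentedColormap.from_list("resource", ["black", "blue", "white"])
    fig, ax = plt.subplots(figsize=(6, 6))
    ax.imshow(state.oxygen.T, origin="lower", cmap=cmap, interpolation="nearest")
    if state.vessels.n:
        ax.scatter(state.vessels.x, state.vessels.y, s=40, facecolors="none",
                   edgecolors="lime", linewidths=1.5, label="vessels")
    if c.n:
        bright = c.store / max(float(c.store.max()), 1e-12)
        # slight jitter inside the patch purely for rendering (cells are
        # tracked at patch resolution)
        rng = np.random.default_rng(0)
        jx = c.x + rng.uniform(-0.3, 0.3, c.n)
        jy = c.y + rng.uniform(-0.3, 0.3, c.n)
        ax.scatter(jx, jy, s=4, c=bright, cmap="Reds", vmin=0, vmax=1, label="cells")
    ax.set_title(f"t = {state.t}: {c.n} cells, {state.vessels.n} vessels")
    ax.set_xlabel("x (patches)")
    ax.set_ylabel("y (patches)")
    fig.tight_layout()
    fig.savefig(paths["image"], dpi=120)
    plt.close(fig)
    return paths


def load_snapshot_tables(outdir: str | Path) -> tuple[np.ndarray, pd.DataFrame, pd.DataFrame]:
    """Reload a snapshot's grid matrix, cell table and vessel table."""
    outdir = Path(outdir)
    grid = np.loadtxt(outdir / "oxygen_grid.csv", delimiter=",", ndmin=2)
    cells = pd.read_csv(outdir / "cells.csv")
    vessels = pd.read_csv(outdir / "vessels.csv")
    return grid, cells, vessels
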