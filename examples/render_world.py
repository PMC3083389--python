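"""Simulate a while and render the world: oxygen field, vessels, cells.

Writes oxygen_grid.csv, cells.csv, vessels.csv and snapshot.png (resource
density blue->white, vessels as green circles, cells shaded by stored
oxygen) into examples_out/.
"""

from dispersim import init_state, render_snapshot, step, validate_config

cfg = validate_config(dict(
    vessel_regime="variable_lifespan", width=48, height=48, n_vessels=40,
    total_input=10000.0, n_steps=300, window=50, seed=11,
))
state = init_state(cfg)
for _ in range(300):
    step(state, cfg)

paths = render_snapshot(state, "examples_out", cfg)
print(f"{state.cells.n} cells, {state.vessels.n} vessels at t={state.t}")
print("wrote:", ", ".join(str(p) for p in paths.values()))
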