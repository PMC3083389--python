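# Methods

`dispersim` is an agent-based lattice model of the evolution of cell
migration inside a neoplasm whose resource supply is spatially and
temporally heterogeneous.  This note records the model, its parameters and
units, the design choices made where the design was genuinely open, and what
the simulated conditions do and do not show.

## The model

**World.**  A `width x height` grid of patches; each patch stores a
non-negative amount of a diffusible resource, called oxygen throughout
(glucose or any vessel-delivered factor would behave identically).  One time
step represents 12 hours.  Cells occupy patches (several per patch allowed);
a patch hosts at most one microvessel.  Edge patches are absorbing for
cells: a cell that reaches the edge has left the neoplasm and is removed and
counted as an *emigrant* — the model's proxy for the first step of
metastasis.

**Resource dynamics.**  Each time step runs `t_a` identical sub-updates of a
difference equation on the oxygen field:

1. every vessel patch receives `r_i / t_a` units, with `r_i = R_total / V`
   so that the system-wide input per step is constant no matter how many
   vessels carry it;
2. one synchronous diffusion pass: each patch sends `d_c / 8` of its oxygen
   to each of its eight lattice neighbours; shares addressed to off-grid
   neighbours are retained by the source patch, so diffusion conserves mass
   exactly on the bounded grid;
3. each cell absorbs `min(available, r_a / t_a)` from its host patch; where
   several cells share a patch they draw sequentially in a fresh uniformly
   random order, and a patch can never be driven negative;
4. each cell pays `r_m / t_a` from its internal store for metabolism,
   clamped at zero (death is adjudicated at the fate stage, not here).

**Cell fate.**  With internal store `n` and reproduction threshold `n_r`,
fate is the strict partition: `n = 0` → death; `n > n_r` → division;
`0 < n ≤ n_r` → a movement attempt.  A dividing cell is replaced by two
daughters on its patch, each holding exactly half the parent's store;
daughters act from the next step on.  At division each daughter's migration
propensity `p ∈ [0, 1]` and maximum migration distance `m ≥ 0` are mutated
independently with probability `µ`, by redrawing from a normal centred on
the parental value with s.d. `sd_p` (truncated to [0, 1]) or `sd_m`
(truncated to [0, ∞)).  Optionally the reproduction threshold itself is an
evolvable phenotype (probability `µ_thr`, s.d. `sd_thr`, hard floor
`n_r_floor`).

**Movement.**  A non-dividing, non-dying cell attempts to move with
probability `p`.  Since `m` is continuous but steps are discrete, the
realised step count is `k = floor(m) + Bernoulli(frac(m))`, which is
unbiased (`E[k] = m`).  Each of the `k` steps targets one of the cell's nine
closest patches (its own plus the eight neighbours).  Under *random*
movement the target is uniform among the nine; under *gradient ascent* it is
the oxygen-richest of the nine (ties broken uniformly at random), and a cell
already at a local maximum stays there for the rest of the attempt even if
it had capacity to move further.  Any step that lands on an edge patch ends
the cell's life in the model and increments the emigrant count.

**Vasculature.**  Four regimes.  *uniform*: one immortal vessel on every
patch (spatially homogeneous input).  *static*: `V` immortal vessels at
fixed random positions.  *fixed_lifespan*: vessels expire `t_f` steps after
creation.  *variable_lifespan*: a vessel is occluded when strictly more than
`t_o` cells crowd its patch.  In the two dynamic regimes, angiogenesis
restores the homeostatic count `V` each step by sprouting age-0 vessels on
patches that are hypoxic (oxygen < `t_h`), hold at least one cell (the
hypoxic cell is what signals for vessel growth), and have no vessel.  If
eligible patches are scarcer than the deficit, the shortfall simply carries
to the next step: `V` is an equilibrium target, not a hard constraint, and
`v ≤ V` holds at all times.

**Step order.**  Vessel loss → angiogenesis → `t_a` resource sub-updates →
cell phase → ages and clock advance.  Occlusion precedes the resource phase,
so a vessel occluded this step delivers no oxygen this step.

**Outcome metrics.**  Per step: population mean propensity `mean_p`, mean
maximum distance `mean_m`, their product `emd = mean_p × mean_m` (the
*expected migration distance*, the expected distance a cell travels per
step), emigrants per step, and the mean *available resource* per patch —
oxygen currently standing in patches, i.e. input not yet absorbed.  A run
summary averages each over the final `window` steps (default 200).
Extinction ends a run early and flags its summary invalid rather than
averaging a short window.

## Parameters, units, defaults

| name | meaning | default | unit |
|---|---|---|---|
| `width, height` | lattice size | 64 x 64 | patches |
| `n_vessels` (V) | homeostatic vessel count | 100 | — |
| `t_f` | vessel lifespan (fixed regime) | ∞ | steps |
| `t_o` | occlusion crowding threshold | 20 | cells |
| `t_h` | hypoxia threshold for angiogenesis | 1 | oxygen units |
| `total_input` (R_total) | system-wide input per step | 25 000 | oxygen units |
| `t_a` | resource sub-updates per step | 10 | — |
| `d_c` | diffusion fraction per sub-update | 0.2 | — |
| `r_a` | max absorption per cell per step | 20 | oxygen units |
| `r_m` | metabolic cost per cell per step | 5 | oxygen units |
| `n_r` | reproduction threshold | 240 | oxygen units |
| `n_r_floor` | lowest evolvable threshold | 120 | oxygen units |
| `µ`, `µ_thr` | mutation probability per daughter | 0.01 | — |
| `sd_p`, `sd_m`, `sd_thr` | mutation kernel s.d. | 0.1, 1.0, 20 | — / patches / units |
| `init_cells` (C) | founding population | 400 | cells |
| `init_store` | founder store | 120 | oxygen units |
| `p0, m0` | founder phenotypes (fixed init) | 0.05, 1 | — / patches |
| `n_steps`, `window` | run length, averaging window | 5000, 200 | steps |

**How the resource economy was calibrated.**  Oxygen units are arbitrary;
only ratios matter.  The economy was tuned, before any outcome experiment
was analysed, to satisfy three qualitative requirements of the modelled
biology: (i) a stable persistent population (~5 000 cells at the defaults,
set by `R_total / r_m`); (ii) oxygen gradients spanning several patches
around an isolated vessel (set by `d_c` and `t_a`); and (iii) actual
crowding occlusion in the variable-lifespan regime.  The third requirement
is the binding one: a vessel patch is only occluded if more than `t_o`
cells accumulate on it, which requires the per-vessel delivery `r_i` to
exceed roughly `(t_o + 1) × (r_m + n_r/(2 T_res))`, where `T_res ≈ 23`
steps is the mean residence time of a cell with the founding phenotypes.
With `d_c = 0.2`, `r_m = 5` and `R_total = 25 000` (so `r_i = 250` at
`V = 100`), vessels at the homeostatic density are occluded about once per
step system-wide, giving a mean vessel lifespan of order 10² steps —
temporal heterogeneity on the timescale the variable-lifespan regime is
meant to create.  Under a slower economy occlusion never fires and the
variable regime silently degenerates into the static one.

**Rate of evolution.**  The mutation s.d.s control how fast the phenotypes
can respond to selection, and are an empirical choice; both `sd_p ∈ {0.01,
0.1}` and `sd_m ∈ {0.1, 1}` are exposed (and swept by the `mutation_sd`
preset).  The defaults use the faster pair (0.1, 1.0) so that desk-scale
runs of 1 500–2 500 steps measure evolved quasi-equilibria rather than
initial conditions; with the slow pair the expected migration distance is
still drifting after 5 000 steps and window means mostly reflect the
founding phenotypes.

## Seeding and reproducibility

Each run draws from a single `numpy` PCG64 generator seeded with
`config.seed`; identical `(config, seed)` reproduces a run bit-for-bit.
Sweeps derive every replicate's seed from
`SeedSequence((base_seed, condition labels…, replicate))`, so seeds are
keyed by condition, not by execution order: partial or re-ordered sweeps
reproduce the same rows.

The cell phase is vectorised.  This is faithful because the fate partition
is fixed at phase entry and no within-phase rule reads another cell's
position: deaths, divisions and movement attempts are mutually independent
given the start-of-phase state, so "iterate cells in random order" and
"update all cells at once" define the same distribution over outcomes.
Random within-patch ordering *is* preserved where it matters — contention
for patch oxygen during absorption, implemented as a single pass over a
global random permutation of the cells (which induces a uniform random
order inside every patch).  The absorption pass and the diffusion stencil
are compiled with numba; they implement exactly the documented update rules
and are verified against straight-line Python references in the tests.

## Experiment presets

* `input_modes` — uniform input vs 100 static vessels vs 100
  variable-lifespan vessels (`t_o = 20`).
* `initial_conditions` — founder phenotypes (0, 0), (0.05, 1), or per-cell
  uniform random on [0, 0.6] x [0, 6], under variable-lifespan vessels.
* fixed-lifespan sweep (`SweepSpec`) — log-spaced vessel counts in
  [30, 600] x lifespans in [4, 500]; `r_i` rescales with `V` automatically.
* `mutation_sd` — the 2x2 kernel grid above under each input mode.
* `evolvable_threshold` — heritable reproduction threshold (µ = 10⁻²,
  s.d. 20, start 240, floor 120).
* `size_scaling` — grids of 1 024–16 384 patches with vessels scaled 1:41
  (25–400) at `t_f = 6`, per-vessel delivery held constant so larger
  neoplasms receive proportionally more input.
* `granularity` — `t_a` = 10 vs 100 (results should be insensitive).

Desk-scale defaults (48x48 grids, 1 500 steps, 3 replicates for the sweep)
keep a full experiment in minutes on one CPU; every output row records the
scale used.  The full-scale settings (5 000 steps, 10 replicates, 64x64)
remain available through the same interfaces.

## Numerical choices and edge cases

* Diffusion is synchronous (all patches update from the pre-update field)
  and exactly mass-conserving; conservation is asserted to 1e-9 relative
  tolerance in tests, and a per-step oxygen ledger (injected − metabolized −
  carried away by emigrants) is checked against the change in total system
  oxygen.
* Metabolism clamps stores at zero instead of allowing debt; the fate rule
  tests `n = 0` exactly, so a cell that ran dry this step dies next step.
* Division splits the store by exact halving, conserving oxygen to the bit.
* Strict inequalities: division requires `n > n_r` (a store of exactly
  `n_r` moves); occlusion requires strictly more than `t_o` cells.
* Truncated-normal draws use the inverse-CDF sampler of
  `scipy.stats.truncnorm` with per-element means; a rejection-sampling
  oracle cross-checks the law in tests.
* Gradient-ascent ties are broken uniformly at random among co-maximal
  patches; if the current patch ties for the maximum it may be selected,
  which ends the attempt.
* In the fixed-lifespan regime the founding vessels get ages staggered
  uniformly over one lifespan, modelling a pre-existing vasculature of mixed
  ages.  With identical ages the entire vasculature would expire and regrow
  in lockstep every `t_f` steps — a pure initialization artifact that, at
  long lifespans, drops a global vascular collapse into the measurement
  window.  Staggering turns vessel renewal into rolling cohorts of about
  `V/t_f` per step.
* Founding cells are placed on interior patches only (an edge placement
  would be an instant, meaningless emigration) and founders start with
  `init_store = n_r/2` — the store of a daughter whose parent had just
  crossed the division threshold.
* Empty-population metrics are NaN-flagged, never silently zero.

## What the simulated conditions do and do not show

The generator *is* the study system: all inputs are synthetic and seeded,
and every reported number is an equilibrium-window average over replicate
simulations.  The model abstracts away vascular network topology and flow,
angiogenic-factor diffusion, cell–cell mechanics and adhesion, within-patch
spatial structure (cells are tracked at patch resolution; continuous
coordinates would change nothing in the update rules and exist only as
render jitter), and emigration through vessels or lymphatics — cells can
leave only across the neoplasm boundary, which understates emigration
relative to a real tumour.  Passing experiments therefore demonstrate the
selection-for-dispersal mechanism — spatial and temporal resource
heterogeneity selecting for migratory phenotypes, with emigration as a
by-product — not a quantitative forecast for any real neoplasm.  Outcomes in
small worlds are sensitive to boundary effects (the size-scaling preset
quantifies this), and desk-scale runs trade equilibration depth for speed:
condition orderings and correlations are stable at that scale, individual
evolved values are not.
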