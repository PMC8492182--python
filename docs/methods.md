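# Methods

## The world

Both models run on a `LandscapeSeries`: categorical biome rasters on one
shared equal-area grid (square cells, default 50 km, row 0 northernmost,
projected coordinates through cell centres), indexed by slice dates in
years BP at millennial spacing. Time lookup is nearest-neighbour with
ties to the older slice; categorical biomes are never interpolated, so
the landscape is a step function of time and a slice "takes effect" half
an interval before its nominal date (the 3000 BP slice governs all dates
below 3500 BP). A single-slice series is treated as constant in time.
Grid-edge cells are not border cells by virtue of the map edge: only
in-bounds unsuitable or nodata neighbours make a cell a border cell,
because the edge is a cropping artefact, not an ecological boundary.

## Equation-based model

Front speed comes from the time-delayed Fisher form
`v = 2*sqrt(a*D)/(1 + a*tau/2)` with diffusion `D = <Delta>^2/(4*tau)`.
At the defaults (a = 0.025/yr, <Delta> = 50 km, tau = 30 yr) this gives
1.050 km/yr, the classic pace of farming expansions. The speed is
monotone in `a` and `<Delta>` throughout the swept ranges (`a*tau < 2`).

Least-cost distances are Dijkstra shortest paths (scipy's sparse csgraph)
over the 16-direction move set — 8 queen steps plus 8 knight steps, which
reduces the directional bias of pure queen connectivity. Edge weight is
the Euclidean centre-to-centre length times the arithmetic mean of the
endpoint frictions. Arithmetic-mean friction is the package's documented
contract; raster-GIS toolchains often average *conductances* instead, which
differs on heterogeneous edges. The null model (uniform friction) is
unaffected by the choice, and the alternative model's qualitative delay
is preserved; only the exact magnitude of mixed-edge costs shifts.
Friction must be ≥ 1 on land (forest is the unit-cost reference; other
biomes can only delay), and nodata cells are impassable. Unreached cells
and cells whose implied arrival postdates the simulation horizon carry an
explicit unreached flag, never a placeholder date; converting unreached
to the end date is an evaluation policy, not a model output.

## Cellular automaton

State: continuous population per cell, arrival date per cell, current
suitability mask. Parameters and defaults: carrying capacity K = 1
person/km² (2500 per cell), annual growth a = 0.025/yr, emigration at
saturation ε = 0.30 per generation with linear density dependence
(γ = 1), generation time τ = 30 yr, leapfrog radius 150 km, run window
5000 → 500 BP. A run starts with a single origin cell at K, which begins
dispersing in the first generation.

Per generation, in order: (1) if the effective biome slice changed,
apply the environmental update; (2) logistic growth on every inhabited
cell; (3) synchronous dispersal. Synchrony (all flows computed from the
post-growth state, then applied at once) removes any dependence on cell
iteration order, and the automaton contains no randomness, so identical
configurations give bit-identical runs.

Dispersal: each inhabited cell emits `ε_t N` migrants, split equally over
the 8-neighbours that are suitable and below K (strictly; K doubles as
the "densely settled" threshold). A border cell of the habitable area
whose whole neighbourhood is blocked instead splits its migrants equally
over all suitable, unsaturated cells within 150 km beyond the
8-neighbourhood (an equal split mirrors the neighbour rule; nearest-only
targeting would be an alternative). With no target anywhere, migrants
stay and growth saturates the cell at K. Receiving cells may transiently
exceed K — logistic growth pulls them back, which is simpler than
proportional capping and conserves population exactly. A consequence
worth knowing: total population can dip slightly during the
overshoot-and-relax cycle around saturation even though dispersal itself
conserves mass.

Environmental updates relocate the whole population of each newly
unsuitable cell to available 8-neighbours under the new mask, falling
back to the leapfrog ring (the border-cell precondition cannot apply to a
cell that just left the mask, so the distance rule alone governs), and
otherwise remove it as an extinction, reported per generation. Arrival
records are never erased.

### Settlement and floating-point underflow

With continuous populations, a cell is inhabited as soon as it holds any
positive population, so the null-model front advances exactly one cell
per generation — the ring-expansion behaviour the test oracle encodes.
The literal migrant flow `ε(N/K)N` at the front tip, however, decays
super-exponentially and underflows double precision after about nine
cells, which would artificially slow the front to its demographic speed.
Settlement is therefore decided on the exact predicate — an available
target of any inhabited cell is colonized, because the flow is
mathematically positive — and seeds whose computed inflow underflowed are
floored at the smallest positive double (5e-324; immeasurable against
cell populations of order 10³, so conservation is unaffected at double
resolution). Setting `min_viable_density` above zero replaces this rule
with the literal received-density test, suppressing infinitesimal
colonization. Under the default rule, CA arrival dates are determined by
geometry (ring expansion, leapfrogging, environment switches) and are
independent of a and ε; demography governs population sizes and
extinction magnitudes, not dates.

## Evaluation

Dates enter as median calibrated ages (`site_id,x,y,med_cal_bp`);
calibration happens upstream. `bin_earliest` keeps the oldest date per
square 100-km bin anchored at the projection origin — anchoring at the
origin rather than the data bounding box keeps the selection independent
of the date set (the retained-site count is sensitive to anchoring, so
the convention is fixed and documented). Ties break by site id. `rmse`
matches each site to its containing cell and reports
`sqrt(mean((sim − obs)²))` with per-site diagnostics; sites on unreached
cells are clamped to the simulation end date by default (charging the
model for never arriving) or dropped and counted under the `drop` policy.
Evaluation against the binned set is the default; callers may pass the
full table.

`parameter_sweep` runs a one-at-a-time design over each model's swept
parameters — growth rate and mean displacement for the EBM, growth rate
and emigration rate for the CA (displacement is fixed at one cell by the
neighbour rule) — across named scenarios, deduplicating the repeated
all-default row: 5+5 values give 9 unique combinations per scenario.

## Synthetic data

The corridor scenario emulates the one environmental feature the analysis
turns on: habitable patches connected by a corridor that opens partway
through the run. Default geometry: 40×40 grid of 50-km cells; forest
blocks spanning columns 0–15 and 24–39; an eight-column savanna gap; a
one-cell-wide zigzag corridor (two vertical legs five columns apart —
beyond the 150-km leapfrog reach, so the corridor cannot be short-cut)
that turns to forest at the 3000 BP slice. The corridor path is ~21
generations long so that, with the slice taking effect at 3470 BP,
far-block arrivals (2870 BP at the corridor exit) genuinely postdate the
nominal opening; the straight gap stays narrow so the cost-4 EBM delay
(~1100 yr) lands near the observed dates rather than overshooting.

Date tables sample reached cells without replacement; observed age =
arrival − Exponential(lag_mean = 200 yr) + Normal(0, noise_sd = 100 yr),
truncated to (0, start]. The exponential lag encodes "dates mostly
postdate first arrival" in the simplest form; the defaults are plausible
for regional radiocarbon records and make no claim of realism. Sampling
is the only stochastic stage anywhere in the package and is fully
seed-determined.

What the generator does *not* emulate: real geography and coastlines, a
seven-biome legend, spatially autocorrelated dating error, taphonomic
loss, or site-density gradients. Passing the scenario-recovery test shows
the pipeline can distinguish forest-dependent from forest-independent
dynamics when the signal exists; it does not validate any particular
reconstruction of the real expansion.

## Problem sizes and defaults in the test suite

The bundled fixture uses the 40×40 corridor landscape, 150 generations,
80 dated sites, and sweeps of 5 values per parameter × 2 scenarios ×
2 models (36 runs); the full suite, including the 50×50 ring-expansion
oracle, runs in a few seconds on one core.

## Known limitations

- Rivers, terrain and coastlines are absent from the friction surface;
  only land cover enters.
- No social barriers, competition or cultural diffusion — the automaton
  models a single expanding population in an empty landscape.
- The EBM evaluates against one static biome slice; only the CA sees the
  dynamic landscape.
- Raster I/O supports the ESRI ASCII grid format (text); GeoTIFF is not
  read or written.
- Whether leapfrog migrants should split equally or target the nearest
  cells is unknowable from first principles; the equal split is the
  default and documented contract.
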