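# Methods

## Scope and framing

`paleodiff` models the earliest phase of migration into unoccupied
territory, where movement is driven by resource geography rather than by
conflict or organisation. Population is a continuum density per group —
"agents" in the loose sense of interacting population parcels, not
discrete individuals — on a rectangular grid of square cells. The model
is fully deterministic: given a terrain, a seed list and a configuration,
every run is bit-identical. The only randomness anywhere in the package
is in the synthetic-terrain generator, controlled by its own seed.

## Habitability scoring

**Altitude.** `D_alt` is piecewise linear in altitude `A` (m): 1 at 0 m
falling to 0.3 at 300 m (settlement density drops quickly with the first
few hundred metres), rising to 0.5 at 2100 m (high plains and plateaus
remain attractive), then falling to 0 at 4100 m, the hard habitability
cut-off. The three interior breakpoints are continuous by construction;
cells below sea level score 0. The middle band is
`((A − 300)/9 + 300)/1000`, the unique linear piece joining 0.3 at 300 m
to 0.5 at 2100 m.

**Relief.** The local relief of a cell is the absolute deviation of its
altitude from the mean over the von Neumann 5-cell stencil, in units of
1000 m. Above 300 m the deviation is additionally scaled by `300/A`, so
a given absolute roughness matters less on high ground where terracing
and slope adaptation are assumed; above the cut-off relief is moot and
set to 0. Sea and nodata neighbours are excluded from the stencil mean
(a coastal cell is not penalized for sitting next to deep water), and
border cells use the stencil members that exist. Land classes follow the
relief: flat (`d ≤ L_flat = 0.2`), tolerable (`0.2 < d ≤ L_tol = 0.5`),
uninhabitable beyond. `L_flat` is sometimes quoted as 0.25; 0.2 is the
default here because it is the value consistent with the class table,
and the parameter is configurable.

**Water.** `D_riv` is 1 within `r_full = 2` km of a freshwater source
(water can be carried), decays as `(r_full/S)²` to `r_max = 10` km and
is 0 beyond. Three alternative decay modes are provided: `linear` (a
linear ramp over the same range), `extended_range` (inverse square with
doubled reach), and `wide_power_law` (radii of 10 and 50 cells with a
`S**-0.0435` middle piece, kept for comparison even though the weak
exponent makes an almost-flat profile). With several sources the field
is evaluated at the nearest source, which preserves the [0, 1] bound; a
`sum_clipped` aggregate (sum over all sources, clipped at 1) exists for
sensitivity checks but is quadratic in the number of sources.

**Site rating.** The raw rating multiplies desirabilities according to a
case table. Precedence, from most to least specific: uninhabitable cells
rate 0; cells with poor water access (`D_riv ≤ 0.5`) rate
`D_alt²·D_surf`; "higher planes" — read here as cells above 2100 m, the
start of the high-altitude desirability band — rate `(D_alt·D_riv)⁴`;
flat land rates `D_surf²·D_alt·D_riv`; tolerable land rates
`(D_surf·D_alt·D_riv)²`. The raw products can fall well below the
canonical class ranges, so by default they are affinely rescaled per
land class onto flat → [0.5, 1] and tolerable → [0.25, 1], using the
min/max over habitable cells of that class on the grid in hand; a class
whose raw ratings are all identical maps to the upper bound, since there
is no spread to preserve. The rescaling is toggleable
(`rescale_rating=False` returns raw products).

**Carrying capacity.** `P_best` is the arithmetic mean of a
location-based optimum (`½ D_surf + ½ D_alt`) and a water-based optimum
(`D_riv`), scaled by the global ceiling `P_max = 10⁷` persons. Sea,
freshwater, nodata and uninhabitable cells carry `R_in = P_best = 0` and
can never hold population.

## The diffusion engine

Rating-driven diffusion of this kind is often written as a bundle of
per-boundary rules that do not cohere into one well-posed update — in
particular, a rating that *grows* linearly with population makes
crowding attractive and is dimensionally unbounded. The engine therefore
implements one self-consistent update — the *canonical* mode — that
keeps every qualitative contract the model is meant to satisfy:

- the effective rating falls linearly with population,
  `R = R_in·max(0, 1 − P/(2 P_best))`: `R(0) = R_in`, `R(P_best) =
  R_in/2`, `R(2 P_best) = 0`;
- flow is directed toward higher rating: each cell frees a mobile pool
  `μ·P·(1 − R)` (mobility ceiling `μ = 0.25` per step), apportioned to
  habitable neighbours in proportion to their ratings, and each directed
  pool splits at the boundary as `F_in : F_out = R_nbr : R_self` with
  `F_in + F_out = 1`;
- immigration ceases at twice the carrying capacity and emigration is
  then maximal — both emerge from `R = 0` rather than needing a separate
  rule;
- flows carry the group composition of their source cell — proportional
  mixing, the simplest defensible admixture bookkeeping;
- births add `g·P_g·R` per group (default `g = 0.1`; 0.001 is the
  documented slow alternative), and cell totals are clamped at `P_max`.

A *literal* mode implements the alternative piecewise rating update for
comparison: below capacity the rating rises with slope
`(1 − R_in)/P_best`, the population term is multiplied by the coupling
constant `C` (default 1), and the result is clipped to [0, 1]; the flux
stage is shared. The literal rating rises with population below
capacity, so it rewards aggregation — this is precisely the behaviour
the canonical mode replaces, and both modes satisfy conservation and
positivity.

The update is synchronous: all fluxes are computed from the pre-step
state and applied at once, which avoids sweep-order artifacts and makes
mirror-symmetric inputs provably stay symmetric. The neighbourhood is
von Neumann 4 by default (Moore 8 by configuration). Update order within
a step: ratings → fluxes → births → clamp. Since outflow from a cell is
capped by `μ·P`, populations can never go negative; with `g = 0` the
flux stage conserves total mass exactly (measured drift is at the
10⁻¹⁵ level over 1000 steps).

**Sea links.** Land components are found by connected-component
labelling; for every pair of components the closest coastal cell pair is
linked iff the sea span between them (centre distance minus one cell) is
at most `sea_gap_max = 25` km. Link flux is damped by `cell_size/gap`,
so a 25 km crossing is 25× slower than a land boundary; wider gaps are
absolute barriers. The hard cut-off is part of the model; the damping
law is this package's own choice of the simplest monotone penalty.

**Seeding.** Groups enter at habitable cells with a positive population
and an optional delayed `start_step`; delayed entry can equivalently be
emulated through initial-population ratios such as 10³:10¹:10¹:10¹:10⁵,
and both mechanisms are available.

## Contact statistics

First contact between groups g and h is the earliest step at which some
cell holds at least `contact_threshold` (default 1 person — "meet" is
otherwise undefined) of both groups. The engine records contacts online
at every step; `detect_contacts` recomputes them by scanning a recorded
trajectory, and the two routes are tested against each other. The
distance parameter divides the contact matrix by its largest finite
off-diagonal entry; never-contacting pairs stay infinite and are dropped
(with a warning) from the Pearson correlation rather than imputed. Zone
summaries aggregate per-group populations over a user-supplied integer
label raster; no canonical zone boundaries ship with the package.

## Synthetic terrains

The generator emulates just enough landscape structure to exercise every
code path: coastal plains below 300 m, a high interior ridge with a low
pass, a shoulder in the 2100–4100 m band, one peak above the cut-off, a
relief-walled crag (uninhabitable class), and 1-cell-wide meandering
river polylines kept strictly interior so they never sever a landmass.
Smoothed Gaussian noise (default ±30 m) gives the rating classes
within-class spread. It does **not** emulate drainage realism, soil,
climate or coastline fractality — so passing tests demonstrate the
mechanics of scoring, diffusion and contact timing, not geographic
fidelity to any real region. Real-data runs use the same interfaces via
ESRI ASCII grids.

The oracle fixtures (1×2 two-cell system, 1×21 strip, 31×31
mirror-symmetric island, 50×50 two-valley island) seed populations of
order half the cell carrying capacity (5×10⁶) where the test requires
visible movement in a conservative (`g = 0`) run: on uniform terrain
with near-maximal rating the mobile pool `μ·P·(1 − R)` is otherwise
vanishingly small — a model property, not an artifact.

## Numerical choices and problem sizes

- Distances are Euclidean between cell centres; the water-distance field
  uses an exact Euclidean distance transform and is tested against the
  all-pairs brute force.
- Degenerate cases: a grid with no freshwater yields an all-infinite
  distance field (warning) and `D_riv = 0`, leaving the poor-water
  rating case active; a cell whose neighbours all rate 0 emits nobody;
  an empty seed list yields an all-zero trajectory.
- Tie-breaks never arise: the update is a closed-form simultaneous map,
  with no ordering over cells.
- Default problem sizes — 50×50 grids, 1000–2000 steps — run in seconds
  on one core and are large enough to exhibit front propagation,
  crowding saturation and ridge/sea barriers; all statistics scale
  linearly in cells × steps.

## Known limitations

- The correlation against real F_ST data (and hence any headline r
  value) requires the real DEM/hydrology rasters and a published F_ST
  vector, none of which ship here; the package validates the machinery
  on synthetic landscapes and accepts real matrices via CSV.
- Group admixture is proportional mixing only; there is no model of
  assimilation, conflict or cultural boundary maintenance.
- Resource accumulation, farming, village formation, soil fertility and
  temperature gradients are deliberately out of scope, as is any
  reprojection/datum handling of input rasters.
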