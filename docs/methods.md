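# Methods

This note documents the model implemented in lgraf, the choices made where
the design was genuinely open, and what the test suite does and does not
demonstrate.

## Model and assumptions

lgraf generates a snapshot of a smallholder agricultural landscape; there is
no temporal dynamics and no environmental heterogeneity — every crop is
equally suitable everywhere. The driving assumptions are that households
settle along roads, that they clear fields near their homes, and that the
size structure of households, villages and fields can be summarized by
univariate distributions. Everything else (field adjacency patterns, patch
shapes, crop mosaics) emerges from the placement process.

### Size distributions

All four size distributions (household area, village size, field size,
inaccessible-patch area) share one parameterization: a kind in {constant,
uniform, normal, log-normal} plus a *natural-scale* mean and sd (ha for
areas, households for village sizes). Log-normal parameters are
moment-matched: `μ_log = ln(m²/√(s²+m²))`, `σ_log = √ln(1+s²/m²)`, so the
configured mean and sd are the moments of the draws themselves. Uniform
draws live on `[m−√3·s, m+√3·s]` (the moment-matched support; a non-positive
lower bound is a configuration error). Normal draws are truncated below at a
floor of 0.01 (redraw) because sizes must be positive. `sd = 0` degenerates
to the constant for every kind.

Hectares convert to whole cells by nearest integer with a floor of one cell
(`max(1, round(A / (c/100)²))`); the cell side `c` should be chosen near the
smallest field size of interest (the default 50 m gives 0.25 ha cells).

### Roads

Roads are dimensionless polylines; the road mask is their supercover: a cell
is flagged iff a segment intersects its *closed* square, so diagonal runs
leave no gaps. Three sources:

* **GeoJSON import** — line features are fitted onto the landscape extent by
  an affine map of their bounding box (an axis with zero extent is centered)
  and clipped. Shapefile input is not supported; convert to GeoJSON.
* **Straight roads** — full-span horizontal/vertical roads with alternating
  orientation starting from a random one; each offset is drawn uniformly
  among rows/columns at least `min-dist-roads` from every same-orientation
  road; roads are appended until the requested number of road cells is
  reached or no admissible offset remains (the shortfall is accepted and
  logged).
* **Noise-guided walkers** — a fractal value-noise elevation field
  (`perlin-octaves` octaves, amplitude decay `perlin-persistence`) over
  which walkers step cell by cell. A walker starts on a boundary cell
  heading toward a target on the opposite boundary and, at each step,
  scores the neighbor cells inside its forward cone (half-angle
  `cone-angle/2`) by `dist-weight · (normalized distance to target) +
  (1−dist-weight) · elevation`, moving to the minimum. Later walkers branch
  from random road cells; once such a walker has left the `min-dist-roads`
  neighborhood of its origin it avoids stepping within that distance of
  foreign road cells whenever an alternative candidate exists. With
  `dist-weight = 1` on flat terrain a walk is a monotone shortest path —
  the documented limiting case.

### Settlement

The household roster is built under the chosen setup type; expected areas
are sampled and converted to cells up front. Village sizes are drawn in
order and filled sequentially; the last village absorbs the remainder so
household totals are exact. Village centers are drawn uniformly among road
cells by rejection (≤ 10⁴ tries) against the pairwise minimum distance;
infeasible constraints are relaxed to the best candidate found, with a
warning. Home-bases use an expanding-radius search around the village
center: the nearest ring that still has road-cell capacity (fewer than
`households-per-cell` home-bases) is found and a cell drawn uniformly
within it. This realizes "random placement around the center" while keeping
villages compact; a distance-kernel alternative would spread tails further
but the expanding search is simpler and fully determined by the cap.

### Inaccessible areas

Patch sizes are drawn until their sum reaches the configured landscape
fraction (the list is minimal: dropping the last patch would undershoot).
Each patch is seeded at a random cell — or random road cell under
`road-connected` — and grown as a square block (side `⌈√n⌉`, row-major,
trimmed to exactly `n`), skipping occupied cells and completing on the
nearest free cells by expanding search. Roads crossing a patch keep their
road flag; the land-cover class becomes inaccessible. These cells are never
owned, cropped, or counted as agricultural area.

### Field establishment

Per loop, growing households are visited in a fresh seeded shuffle (avoiding
a systematic first-mover advantage). A household draws a field size and
attempts it only when the field would bring its realized area closer to its
expected area (`R+f < E`, or `|R+f−E| < |R−E|`); otherwise it stops growing.
The first field is exempt from this rule — every household establishes at
least one field, which keeps small households from dropping out when the
field-size distribution sits above their expected area.

An attempt picks a start cell under the current strategy and tries to place
a rectangle of `w = max(1, round(√(n/s_f)))` by `⌈n/w⌉` cells (random
orientation, row-major fill trimmed to `n`, all four anchor corners tried).
Strategy s3 anchors at the most recent search origin (the last tried start
cell), which distinguishes it from s1's home-base anchor. Strategy s4
requires the cell and all eight neighbors to be free `others` cells, which
excludes boundary cells. Search radii are capped at the grid diagonal.
After `change-strategy` consecutive failures the household moves to the next
strategy in its list; when the list is exhausted it draws a fresh size, and
after three consecutively exhausted sizes it stops growing (the bound
guarantees termination on crowded maps; the redraw count is otherwise
unconstrained). Fields may cover road cells and the owner's home-base cell;
inaccessible cells are never eligible.

Under the area setup type the whole loop also halts at the end of a sweep
once total field cells reach the configured proportion. The realized
agricultural fraction therefore lands slightly *below* the target on
average (≈ −0.7 pp at the 50 % default conditions): per-household stopping
is near-symmetric around each expected area while the roster only just
covers the target.

### Crop assignment

Cell quotas are `q_l = round(fr_l · total field cells)` with the fill-up
crop absorbing any shortfall from `Σ fr_l < 1`. In fraction mode, fields are
visited in seeded random order and each takes the crop with the largest
remaining quota deficit — a greedy rule that tracks quotas within one field
size, tighter than independent random draws on small landscapes. In
specialization mode, three steps: (1) randomly drawn households are marked
specialists of crop *l* (all fields set to *l*) until specialist area
reaches `fr_l,spec · q_l`; (2) remaining fields are filled greedily as in
fraction mode; (3) an enforcement sweep promotes randomly chosen mixed
cultivators of *l* to specialists until the realized household-level
specialization — pure cultivators over all cultivators of *l* — meets
`fr_l,spec`. The sweep is needed because the cultivator count is unknown
until fields are assigned; it can only push realized levels *above* the
configured minimum, which is the documented direction of deviation.
Specialization is counted over households, not area: the level is defined by
what share of households farm the crop exclusively.

### Landscape metrics

Patches are connected components of a class mask (8-connectivity by
default; 4 available). Perimeters count rook-adjacent edges to non-class
cells including the landscape boundary. With `a_ij` patch areas (cells),
`p_ij` perimeters (edges), `E = Σ p_ij`, `n` class cells and `Z` landscape
cells:

* `LSI = E / min_E`, `min_E` the edge of the maximally compact arrangement
  of `n` cells (`m = ⌊√n⌋`: `4m` if `m² = n`; `4m+2` if `n ≤ m(m+1)`; else
  `4m+4`);
* `LPI = 100 · max(a_ij)/Z`;
* `PCI = 100 · [1 − E/Σ(p_ij √a_ij)] / [1 − 1/√Z]` (undefined for `Z = 1`);
* mean patch area in ha; patch count.

All metrics are undefined (None) on an empty mask. The habitat class
("others") excludes road-flagged cells: roads act as patch separators.

## Defaults

The package defaults (see `lgraf.config.Config`) describe a plausible
smallholder region at 50 m resolution: 100×100 cells (2500 ha), 500 road
cells at spacing ≥ 5, log-normal household areas 2 ± 1 ha, log-normal field
sizes 1 ± 0.5 ha, log-normal village sizes 20 ± 10 households at spacing
≥ 10 cells, home-base cap 4 per cell, strategies s1–s4 with
`change-strategy` 3, shape factor 1, one crop. They are the package's own
choices; any study should set them from survey or remote-sensing data.

## What the synthetic conditions do and do not show

All tests run on generated landscapes and synthetic road fixtures. They
demonstrate the internal contracts — distribution recovery at low density,
quota and specialization semantics, metric formulas against brute-force
oracles and hand computations, byte-level reproducibility — on lattices up
to 100×100 cells. They do not validate realism against classified satellite
maps, real road networks, or survey-derived parameter sets, and say nothing
about behavior at near-saturation agricultural fractions (> 0.8), where
shortfalls and relaxation warnings become routine.

Test and acceptance problem sizes were chosen to keep the suites quick:
bound checks across the parameter hypercube run at 50×50 cells, the
regression-direction experiment at 80×80 with 50 hypercube points, the
headline checks at the full 100×100.

## Numerical choices and degenerate inputs

* Ties in distance-ordered searches are broken by seeded shuffle; all
  randomness flows from one master seed through fixed, named per-stage
  substreams (changing the crop scheme cannot perturb the road network).
* Rounding is `floor(x+0.5)` (half-up), not banker's rounding.
* Crop-fraction sums are validated with tolerance 1e-9.
* Empty masks, zero-length requests and `sd = 0` all take defined, tested
  paths; infeasible village spacing relaxes with a warning, insufficient
  road capacity for home-bases is a hard error.

## Known limitations

* No shapefile reader (GeoJSON only); no geographic projections — the
  landscape frame is a local Cartesian grid.
* The straight-road and walker road algorithms are this package's own
  reconstructions of the cited family of generators; their parameter
  semantics are documented above and normative here.
* No road hierarchies or widths, no temporal growth, no per-household
  strategy heterogeneity, no spatial clustering controls for crops beyond
  specialization.
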