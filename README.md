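# lgraf

**lgraf** is a process-based landscape generator for smallholder-dominated
agricultural mosaics, written for landscape ecologists and modellers who need
realistic gridded land-use maps — e.g. as initial conditions for spatial
simulation models, or as a stand-alone tool for landscape-scale scenario
analysis. Instead of tuning abstract spatial statistics the way neutral
landscape models do, lgraf simulates the human process that shapes these
landscapes: household agents settle in villages along a road network and
establish fields in their vicinity until empirically calibratable size
distributions are realized.

## The model

A landscape is a `w × h` lattice of square cells of side `c` meters, initially
all of the aggregate non-agricultural class *others*. Generation proceeds in
stages:

1. **Roads** — polylines in landscape coordinates, either imported from a
   GeoJSON line layer, generated as full-span straight roads with a minimum
   spacing, or carved by walkers over a fractal elevation surface. A cell is a
   road cell iff a polyline intersects its closed square.
2. **Settlement** — a household roster is built under one of three setup types
   (fixed number of households `n_h`, fixed number of villages `n_v`, or fixed
   agricultural proportion `n_a`; the other two quantities emerge). Each
   household draws an expected area `A_i ~ F_hh` (normal or log-normal,
   natural-scale mean/sd in ha); village sizes come from their own
   distribution; village centers sit on road cells a minimum distance apart
   and each household gets a home-base on a road cell near its center
   (capped per cell).
3. **Inaccessible areas** (optional) — square-ish patches (plantations,
   protected areas) drawn from a size distribution until a target landscape
   fraction is covered; never available to households.
4. **Field establishment** — households loop, each drawing a field size
   `f ~ F_field` and attempting a rectangular field (aspect controlled by a
   shape factor `s_f ≥ 1`; width `≈ √(f/s_f)`) located by ordered search
   strategies: near the home-base (s1), near own fields (s2), expanding
   nearby search (s3), or only on cells fully surrounded by free cells (s4),
   switching strategy after `n_strat` consecutive failures. A household
   attempts a field only while it brings its realized area closer to `A_i`
   (its first field is always established); under the area setup the loop
   halts when the landscape-level target is reached.
5. **Crop assignment** — up to five crops with landscape fractions `fr_l`
   (Σ ≤ 1, a fill-up crop absorbs the rest). Optionally, household-level
   specialization: a level `fr_l,spec` = 0.7 for crop *l* means ≥ 70 % of the
   households cultivating *l* cultivate it exclusively; single-field
   households are specialists by construction, so realized levels can exceed
   the input.
6. **Metrics & export** — five class-level metrics in the FRAGSTATS raster
   tradition (patch count, mean patch area, LSI, LPI, cohesion) on any class
   mask; seven map products exported as ESRI ASCII rasters plus roster and
   metrics tables.

One master seed fans out into independent per-stage random substreams, so
runs are byte-reproducible and stages can be varied independently.

## Worked example

```sh
python examples/generate_landscape.py
```

generates a 100×100-cell landscape (2500 ha) with 500 road cells, log-normal
household areas (2 ± 1 ha), log-normal field sizes (1 ± 0.5 ha) and a 50 %
agricultural target, and prints:

```
households:            607
villages:              30
fields:                1324
road cells:            591
agricultural fraction: 0.4976
```

607 households emerged from the 50 % area target (1250 ha / ≈2 ha each); the
realized agricultural fraction lands just below the target because each
household stops once another field would move it further from its expected
area. `examples/landscape_metrics.py` prints the five class-level metrics per
land-cover class, and `examples/crop_specialization.py` shows the
specialization contract:

```
input specialization 0.0 -> realized 0.432, 97 oil-palm patches
input specialization 0.5 -> realized 0.576, 91 oil-palm patches
input specialization 1.0 -> realized 1.000, 84 oil-palm patches
```

— realized specialization never falls below the input level (0.432 at input
0 is the single-field-household baseline), and stronger specialization
aggregates the crop into fewer patches.

The same pipeline is available as a CLI:

```sh
lgraf generate --config config.yml --out out/ [--seed N]
lgraf metrics --raster out/agri_binary.asc --class-code 1
lgraf fixture-roads --style grid --n 4 --seed 1 --out roads.geojson
```

Configuration files are flat YAML using the generator's canonical parameter
names (`setup-type`, `prop-agricultural-area`, `hh-area-mean_ha`,
`field-strategies-id`, `LUT-1-fraction`, ...); see `docs/methods.md`.

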