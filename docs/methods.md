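# Methods

## Model and assumptions

The package scores a categorical landcover raster for rewilding potential in
four stages (priority → suitability → function → rewilding) and aggregates
positive-score cells into ranked management units. The underlying assumptions:

- The landscape is stationary during planning: no succession, disturbance or
  re-scoring over time.
- The ecological function (here seed dispersal) is spatially limited by two
  provider traits only — a dispersal threshold from seed sources and a
  circular home range around a residence cell — and both are isotropic.
- Habitat suitability is binary: a cell either can or cannot host the
  provider. Population dynamics, Allee effects and predation pressure are
  folded into the management attribute (e.g. snake-control method), not the
  score.
- Priorities are per-landcover-class expert values; within-class variation
  (stand age, canopy condition) is not represented.

## Geometry conventions

All distances are Euclidean centre-to-centre in projected metres. A cell is
inside a circular neighborhood iff its centre is within the radius of the
focal centre (boundary inclusive for the density/suitability neighborhoods;
for the rewilding sum the membership is strict `d < R`, immaterial because
the weight is 0 exactly at `R`). Neighborhoods are truncated at the raster
boundary and fractions use the in-bounds, non-NoData denominator, so cells on
an island's coast are not penalised for off-map ocean. NoData cells are
excluded from every numerator and denominator and cannot be targets.
Rasterization assigns each cell the class of the first polygon (input order =
priority order) covering its centre; the per-class area fidelity report
guards against centre-sampling distortion on coarse grids.

The home-range density question — whether the "native forest within the home
range" fraction is taken over all cells or only land cells — is answered
here as: over all in-bounds non-NoData cells. With the ocean mapped as a
water *class* (not NoData), open water therefore dilutes the native fraction
of coastal cells, which matches the ecological reading (ocean is not forage
area but is part of the circle).

## Parameters

| parameter | unit | default | meaning |
|---|---|---|---|
| `cell_size` | m | 30 | grid resolution; keep ≤ 1/10 of the largest function distance (`suggest_resolution` enforces the rule) |
| `home_range_radius` R | m | 1083 | radius of the provider's diurnal home range; bounds the rewilding aggregation and the suitability food check |
| `dispersal_threshold` T | m | 500 | 99th-percentile dispersal distance; hard cutoff of the function score |
| `min_native_fraction` | — | 0.10 | minimum native-forest fraction within R for a cell to be suitable |
| `priority_table` | — | intact 1.0, degraded 0.8, thicket 0.6 | expert function-need per landcover class; unlisted classes 0 |
| `alpha` | — | 0.5 | weight on seed-source density vs proximity in the function score |
| `proximity` | — | linear | `1 − d*/T` decay, or `step` (1 anywhere within T) |
| `normalization` | — | neighborhood-weight | divide the rewilding sum by the local weight total (scores comparable across landscapes); `landscape-max` rescales by the best cell instead |
| `connectivity` | — | 8 | unit clustering neighbourhood (4 also available) |
| `min_cells` | cells | 1 | smallest component kept as a unit |
| `aggregator` | — | mean | unit score: `mean` favours intense small units, `sum` favours large ones |

Neither ordering of R and T is required; both just have to be positive.

## Design choices where the design was open

- **Function-score combination rule.** Density and proximity both have to
  matter, the score has to live in [0, 1], vanish past the dispersal cutoff,
  be maximal inside saturated intact forest and monotone in both terms. The
  convex combination `P·[α·D + (1−α)·(1 − d*/T)]` is the simplest rule with
  those properties; α is exposed rather than fixed, and the exact formula
  string used is written into every run manifest.
- **Rewilding normalization.** Dividing by the neighborhood's own weight
  total makes the score a weighted *average* of reachable function scores:
  stable under map edits, comparable across islands, and exactly equal to FS
  when the home range collapses below one cell. Max-normalization is kept as
  an option for users who want "best site = 1" semantics.
- **Priority and suitability are independent layers.** A developed cell can
  be suitable (the provider nests in towns) while having priority 0; it then
  receives a rewilding score purely from surrounding forest function, which
  is what makes town-adjacent-to-forest sites rank well.
- **Units never span attribute boundaries**, because a unit is managed one
  way; connected-component labelling runs inside each attribute label.
  Tie-breaks in ranking are fully deterministic (score, then area, then the
  topmost-leftmost member cell) so ranked output is reproducible.

## Synthetic landscapes

The generator emulates a patchy island: multi-source region growing places
seeds per class and grows frontiers with effort proportional to each class's
remaining area quota; `patch_cohesion` biases selection toward candidates
with many same-class neighbours (compact blobs at 1, ragged growth at 0). A
blocked class re-seeds at a fresh unassigned cell, so realized class
fractions match their targets up to quota rounding. With `coastline` set, an
ellipse-with-radial-noise island is wrapped in water with a two-cell sand
shore, and fractions apply to the interior. The island scenario
(`guam_like_scenario`) uses the published parameter set and stamps one
deterministic intact-forest disk (≈69 cells) so downstream monotonicity tests
are always well-posed.

What the generator does **not** emulate: real spatial autocorrelation
structure (roads, elevation, hydrology), class adjacency preferences (thicket
abutting degraded forest), anisotropy, or mapping error. Passing tests on
these landscapes therefore demonstrates the *algorithmic* contracts (score
definitions, cutoffs, monotonicities, determinism), not predictive skill on
any real island.

## Numerics

- Neighborhood fractions are computed by integer convolution (exact counts,
  no floating-point accumulation), distances by an exact Euclidean distance
  transform on the cell lattice scaled by the cell size, and the rewilding
  sum by direct (non-FFT) convolution with the linear-decay kernel.
  Brute-force all-pairs oracles in the test suite agree to ≤ 1e−9.
- Layers are float64 in memory, float32 on disk, NoData −9999. Test
  comparisons use 1e−9 (primitives) and 1e−12 (hand-computed formula cases).
- `distance_to_nearest` returns `inf` when the grid has no target cell; the
  function score then vanishes via the cutoff, not via an error.
- Degenerate inputs: a neighborhood radius below the cell size warns and
  degenerates to the focal cell; an empty target set gives a zero layer; a
  landscape with no suitable cells completes with an all-NoData rewilding
  layer, zero units and a warning.
- Default problem sizes: the island scenario is 300×300 cells (≈ 81 km² at
  30 m), which resolves the 1083 m home range (36 cells) while keeping a full
  pipeline run in seconds; oracle cross-checks use random grids up to 50×50.

## Known limitations

- Single species, single function; no trade-off or complementarity analysis.
- No corridor or connectivity modelling between units, no land-ownership or
  economic-cost layers, and no temporal re-runs under simulated succession.
- Binary suitability only; the continuous variant is deliberately out of
  scope.
- Geographic (degree-unit) CRSs are rejected by a name heuristic rather than
  a full CRS database; inputs must arrive in a metre-based projection.
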