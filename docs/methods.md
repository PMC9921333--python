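# Methods

## Routing model

Each edge carries a base cost `Ct` equal to its length in metres and, per
exposure type, a normalised environmental cost coefficient `ce ∈ [0, 1]`.
The composite edge cost is `Ce = Ct + Ct·ce·s`: the environmental penalty
is proportional both to the exposure level and to the distance over which
it is experienced, and the sensitivity `s` sets its weight. At `s = 0`
the model is pure shortest-path routing; as `s → ∞` the routing minimises
`Σ Ct·ce` (exposure-metres) and distance becomes a tie-break.

Least-cost search is Dijkstra over the undirected network. The search is
implemented in-package because reproducibility across batch runs requires
a fully specified tie-break: labels are ordered by `(cumulative cost,
edge-id sequence)`, so among exactly equal-cost paths the
lexicographically smallest edge-id sequence wins. Edge weights are
strictly positive, which preserves the label-setting property under this
ordering. Batch runs use one single-source tree per (origin, exposure,
sensitivity) rather than per-pair searches.

The sweep uses eleven sensitivities spanning seven decades
(`0.1 … 10⁶`); the three exposure surfaces vary on very different scales,
so both weak and extreme weights are needed to surface all distinct
alternatives. Routes identical as edge sequences are deduplicated,
keeping the smallest sensitivity that produced them. A diagnostic warns
when a selected optimal route used the largest sensitivity — a sign the
sweep may not have converged for that pair.

**Optimal-route selection.** Among sweep candidates whose detour fraction
`(L − L₀)/L₀` is at most the cap (default 0.15, boundary included with
1e-6 relative tolerance), the route with the best length-weighted mean of
the optimised exposure is selected — minimum for AQI and noise, maximum
for GVI — with ties broken by shorter length, then smaller sensitivity.
Cumulative composite cost is not comparable across different `s` values,
so mean exposure is the default selection criterion; selection by lowest
composite cost is available via `RoutingConfig(selection="cost")`. If no
candidate strictly improves on the shortest route, the shortest route is
returned with `improved=False` and zero exposure change.

## Exposure assignment

- **AQI raster** (ESRI ASCII, square cells): edges sample the grid every
  5 m along their geometry (endpoints included) and average the non-nodata
  samples. 5 m is well below the 13 m cell size of typical AQI layers, so
  the mean approximates an exact length weighting; an edge entirely over
  nodata is missing.
- **Noise polygons** (Lden dB): exact length-weighted mean over the
  polyline, computed by peeling the line against polygons in descending
  dB order — where polygons overlap the maximum dB applies, the
  conservative health-oriented rule. Uncovered portions contribute a
  configurable 40 dB background. Averaging is arithmetic in dB, matching
  how mean route noise is conventionally reported and thresholded; an
  energetic (logarithmic) mean is provided as an alternative.
- **GVI** joins per edge id; ids absent from the table stay missing.
- **Imputation** fills missing values with the length-weighted network
  median, which stays inside the observed range and is robust to a few
  extreme edges. Non-missing values are never altered.

The `ce` mappings (table in the README) are linear and configurable. The
noise ramp spans 45–75 dB so that the 55 dB high-daytime-noise threshold
sits at `ce = 1/3`; below 45 dB the penalty is zero, above 75 dB it
saturates.

## Population aggregation

OD pairs contribute equally (unweighted) or in proportion to their trip
counts (trip-weighted). Catchments are Voronoi cells of the station
coordinates (Euclidean, via GEOS) clipped to a rectangular study
boundary; aggregation is by departure station. Time budgets assume a
constant cycling speed (default 15 km/h, a typical urban bike-share
speed, configurable and echoed in outputs); an edge's travel minutes
count toward an exposure class (`AQI > 2`, `noise > 65 dB`, `GVI > 0.2`)
when the edge's mean exposure strictly exceeds the threshold. Mean
additional distance and mean exposure change are reported conditional on
an improving route existing, with the conditioning `n` alongside. The
detour distribution uses the *unconstrained* maximal-improvement route
per pair and reports the share of pairs (and trips) whose maximal
improvement already lies within the cap.

## Similarity

Routes are buffered at 5 m with round caps and joins (fixed for
reproducibility). The shared-route proportion is Jaccard,
`area(A∩B)/area(A∪B)`; because the denominator is a genuine modelling
choice, intersection-over-mean-area is available behind a flag and the
measure used is recorded in every output row. When an exposure has no
improving route for a pair, the shortest route stands in as that
exposure's optimal route in similarity computations — without this, the
similarity statistics would silently drop exactly the pairs where route
alternatives are scarce. Pearson correlations of route-mean exposures are
computed per route set; zero-variance inputs yield a flagged missing
value rather than a number.

## Synthetic city

The generator emulates a compact bike-share service area:

- **Network**: `grid_n × grid_n` jittered grid (default 12 × 12 at 100 m
  spacing, jitter 10 m, clipped to 0.45·spacing to stay planar). Grids
  have `2n(n−1)` edges and are always connected.
- **Exposure surfaces**: three iid standard-normal lattices
  (half-spacing cells) smoothed with a Gaussian kernel (σ = 2 cells),
  standardised and mixed through the Cholesky factor of the target
  correlation matrix (defaults +0.7 AQI–noise, −0.5 AQI–GVI, −0.4
  noise–GVI, near values observed along real shortest cycling routes). A
  radial gradient raises AQI and noise and lowers GVI toward the centre,
  mimicking a loud, polluted urban core. Values map linearly (clipped)
  into AQI [1, 5] centred near 1.9, noise [45, 80] dB centred near
  62 dB, GVI [0, 0.6] centred near 0.25. A smoothing length at or beyond
  the lattice extent leaves no spatial variation, so that limit produces
  exactly constant fields. Edges take the lattice value at their
  midpoint; matching ESRI ASCII rasters and 5 dB-band noise polygons can
  be emitted to exercise the assignment code path. An optional
  `ring_road` flag plants a loud core wrapped in a quiet green ring, used
  as an end-to-end recovery scenario.
- **Stations and trips**: stations occupy distinct nodes, sampled with
  probability decaying with distance from the centre (denser downtown);
  trip counts are multinomial over ordered OD pairs with gravity weights
  `exp(−β·distance)` (default β = 1e-3 per metre, i.e. a 1 km decay
  length; default 20 stations, 50,000 trips — the real system's 242
  stations and 3.1 M trips at desk scale).

Identical configurations (including the seed) give bit-identical cities.
What the generator does **not** emulate: road-class hierarchies and speed
differences, one-way streets, temporal (diurnal/seasonal) exposure
variation, GPS-like route deviation from modelled paths, and station
rebalancing. Passing tests therefore demonstrate correctness of the
computational pipeline under realistic correlation structure, not
calibration to any particular city's levels.

## Numerical choices

- Stored edge lengths must match polyline arc length within 1e-6
  relative tolerance; zero-length edges are rejected.
- Snapping uses the nearest node as routing terminal (nearest edge is
  diagnostic only), with exact ties broken by smallest id; this avoids
  mutating the graph by edge splitting, at the cost of up to half an
  edge length of terminal error.
- The detour cap is inclusive (`≤ 0.15`) with 1e-6 relative slack.
- Coordinates must be planar metres; inputs whose coordinates fit in
  lon/lat bounds are rejected rather than silently mis-measured.
- Voronoi cell/station matching, route deduplication and all groupbys
  iterate in sorted order, so outputs are byte-stable across runs.

## Problem sizes

The bundled test suite and the acceptance script run the pipeline at the
generator's default scale (144 nodes, 264 edges, 20 stations, 380 OD
pairs; a full batch is ~700 single-source Dijkstra trees) plus smaller
grids for oracle comparisons — sizes chosen so every check enumerates or
verifies exhaustively where an oracle exists.

## Known limitations

- Node snapping (no edge splitting) biases very short OD pairs.
- The arithmetic dB mean understates perceived loudness relative to an
  energetic mean on heterogeneous routes (the alternative is provided).
- The raster sampling mean is an approximation of exact cell/segment
  length weighting; at the default 5 m interval the error is far below
  exposure-data uncertainty.
- Gravity trips are independent multinomial draws; real trip tables have
  overdispersion and temporal structure.
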