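# Methods

## Accessibility model

The package measures potential spatial accessibility — probable,
model-based access of a demand population to a service, as opposed to
observed utilization — with the floating catchment area family. All
four configurations are special cases of one engine. Let `t_ij` be the
drive time from region *i*'s centroid to hospital *j*, `S_j` the
hospital's bed count, and `D_i` the region's (possibly
severity-weighted) demand. A decay scheme assigns every travel time a
weight `w(t)`: for the plain 2SFCA, `w(t) = 1` for `t ≤ d0` and 0
beyond; for the enhanced E2SFCA, `w(t)` is a step function over nested
zones (defaults: 1.00 on (0, 5], 0.68 on (5, 10], 0.22 on (10, 15], 0
beyond 15 min). Then

- step 1: `R_j = S_j / Σ_i w(t_ij) · D_i`
- step 2: `A_i = Σ_j w(t_ij) · R_j`

Severity weighting enters only through `D_i = Σ_c w_c · n_ic` in step 1
(default category weights 1/2/3/4 for mild/moderate/severe/very
severe); the step-2 sum of ratios is never reweighted by severity.
Because the same `w` and the same symmetric travel times appear in both
steps, the model conserves supply exactly: whenever no facility has an
empty catchment, `Σ_i D_i A_i = Σ_j S_j`. The test suite checks this
identity to 1e-9 relative tolerance and the acceptance script measures
the realised error (~1e-16, i.e. floating-point round-off only).

Assumptions inherited from the model family: demand and supply interact
only within the catchment weights; all demand inside a zone is
homogeneous; travel is symmetric and single-mode (car, free-flow
speeds); hospital capacity is adequately proxied by beds.

### Conventions and degenerate cases

- Catchment boundaries are upper-inclusive (`t ≤ d0`, `t ≤ b_r`), with
  `t = 0` in the innermost zone. The convention is centralized in
  `zone_of` and documented there, so changing it is a one-line edit.
- A facility whose catchment holds zero (weighted) demand gets
  `R_j = 0` and a logged warning rather than being dropped or raising:
  result shapes stay stable, and the conservation identity's
  precondition becomes observable.
- Unreachable region–facility pairs carry `inf` travel time and weight
  0; a region reaching no facility scores 0, not NaN.
- Severity weights passed to a non-severity method are rejected loudly;
  silently ignoring them would make configurations ambiguous.
- The zone weights (1.00, 0.68, 0.22) are treated as data, not derived
  from a Gaussian: the generating parameterization is not fixed by the
  sources this package follows, and any strictly decreasing weight set
  in (0, 1] is accepted.

## Travel times

Roads are undirected polylines with one of four hierarchy classes;
free-flow speeds default to 80/60/40/30 km/h
(expressway/main/secondary/local), so a 1 km local segment costs
exactly 2.0 minutes. Segment endpoints are snapped to micro-metre
precision to form graph nodes; where duplicate node pairs occur the
faster edge wins. Origins and destinations attach to their nearest
network node by Euclidean distance; access/egress time from the point
to its node is ignored (no access-time model is assumed). Shortest
paths are Dijkstra trees grown from each destination; unreachable pairs
record `inf` rather than raising, so partial networks degrade
gracefully. A precomputed long-format matrix CSV can replace this whole
stage. Demand-weighted centroids (`weighted_centroid`) are available
when individual-level points exist.

## Synthetic city generator

The generator emulates the structure of a mid-sized metropolis as seen
by the accessibility method, with defaults matching the registry-data
setting the package targets:

| parameter | default | meaning |
|---|---|---|
| `n_regions` | 68 | neighbourhoods, tiled as the most nearly square r×c grid (4×17) |
| `grid_extent` | 16 000 m | square city footprint (~258 km²) |
| `n_facilities` | 22 | hospitals |
| `bed_range` | (55, 750) | beds, log-uniform (right-skewed sizes) |
| `total_population`, `disability_rate` | 1 186 000, 16186/1186000 | gives 16 186 disability records |
| `severity_mix` | (1693, 4603, 7010, 2880)/16186 | registered severity mix; the exact counts are used because the printed 4-decimal fractions do not sum to 1 |
| `type_mix` | (6206, 4864, 2127, 1835, 1154)/16186 | disability types, bookkeeping only |
| `road_class_shares` | (0.10, 0.20, 0.30, 0.40) | class mix of the grid's edges; chosen as a plausible urban hierarchy (few expressways, many local streets) — no source value exists |
| `facility_scale` | 0.05 | hospital placement probability ∝ exp(−d/scale·extent) from the centre: a compact central cluster |
| `demand_centre`, `demand_scale` | (0.35, 0.35), 0.30 | demand decays from an off-centre (south-west) focus |
| `demand_noise_sd` | 1.0 | lognormal rate noise; reproduces an order-of-magnitude spread in per-region disability rates |

The geography defaults encode the centre-rich/periphery-poor pattern
typical of rapidly urbanised cities — hospitals clustered centrally,
demand heaviest in central and south-western neighbourhoods, peripheral
areas more than 15 minutes from care — which is exactly the regime
where distance decay matters ("decay-consistent geography"). Under
these conditions the enhanced configurations out-correlate the plain
ones against closest-facility time in ~86% of seeds, and severity
weighting moves each rho by far less than the plain-vs-enhanced gap.

All draws flow from one seeded NumPy generator in a fixed order
(demand noise, region totals, severity/type splits, facility sites,
beds, road classes), so a seed is bit-reproducible; individual-level
points use a separate child stream (`seed`, 1) so they never perturb
city-level draws. Coordinates are planar metres; there is no geodesy.

What the generator does **not** emulate: realistic street topology
(it is a lattice), one-way streets and traffic, census population
surfaces, geocoding error, within-region demand clustering beyond
uniform scatter, hospital specialization. Passing tests therefore show
that the method implementation is correct and that its qualitative
behaviour holds under the stated geography — not that any specific
real city's numbers are reproduced.

## Evaluation machinery

- **Spearman rho** with average ranks for ties, two-sided p from the
  large-sample t approximation; an exact pairing-permutation p-value is
  offered for n ≤ 10. Constant vectors raise instead of returning 0.
- **Pairwise exclusion** of regions with unreachable closest facility,
  with the exclusion count logged.
- **Summaries** use the sample (n−1) standard deviation; the
  high-access share counts scores strictly above the threshold and
  reports both count and percentage (one decimal).
- **Classification** applies shared, upper-inclusive interval edges
  (explicit breaks or quantiles) so choropleths of different methods
  are comparable; the default is quantile classification because no
  canonical break set exists.
- **Overlay** is the per-region arithmetic mean of the four scores.

## Problem sizes and numerics

The test suite and acceptance script run entirely on generated data:
50 default-sized cities (68×22) for the Monte-Carlo ranking check, 100
compact 9-region/3-facility cities for the conservation identity, 100
random ≤10×≤5 instances against the double-loop reference, and ≤10-node
road graphs against exhaustive path enumeration. Engine-vs-oracle
agreement is asserted at 1e-12 absolute, conservation at 1e-9 relative,
rank-correlation oracles at 1e-12. These sizes keep the full suite
under ten seconds while exercising every code path at the default study
scale.

## Known limitations

- Free-flow speeds overstate congested travel; no time-of-day or
  multi-modal variation.
- Bed count is a crude supply proxy (no physicians, occupancy, or
  case-mix).
- The stepwise decay is discontinuous at zone breaks; a facility moving
  across a break changes weight discretely.
- Severity weights are ordinal multipliers (1–4) with no empirical
  calibration; results should be read as sensitivity analyses over that
  choice.
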