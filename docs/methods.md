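# Methods

## The problem

Groups of radar-tracked search flights are compared to decide whether the
searching animal is guided by generalized landscape memory (here:
elongated ground structures, "edges") or searches at random. All analyses
are per-bee: a trajectory is reduced to a feature vector, the per-group
feature distributions are compared pairwise by a nonparametric effect
size, and a low-dimensional embedding orders the groups geometrically.

## Coordinate and compass conventions

Positions are Cartesian meters relative to the release site (x east,
y north). Bearings are compass degrees, clockwise from north. The
16 sectors of the directional analysis are *centered* on the compass
winds: sector 0 (N) spans [348.75°, 360°) ∪ [0°, 11.25°), half-open,
clockwise. The default radar sits at (−38, −162) m from the release site
(derived from the printed geographic coordinates of the two instruments
by a local equirectangular projection), has a 900-m range and a 150°-wide
blanking sector; the blanking bounds are configurable and default to
[150°, 300°), i.e. centered on SW, since only the width and rough
orientation of the unscanned sector are known.

## The random-search null model

A model bee starts at the release site with a uniformly random heading
and flies `n_steps = 10 000` steps of unit length. Heading increments are
`arctan` of i.i.d. normal draws (sd 0.25), filtered once, forward-only
with zero initial conditions, by a 10th-order digital Butterworth low-pass
filter with normalized cutoff 0.05 — this gives smoothly curving flight.
Two rules fold the heading by 180°:

* **outer envelope** — whenever the distance from the release site
  exceeds `1 + k/10` unit lengths, where `k` is the loop index;
* **inner disk** — whenever the bee comes closer than 0.1 unit lengths
  to the release site.

Under the default semantics both rules apply at *every step* spent in the
triggering zone, and `k` advances at each outer fold: a fold-back at the
envelope is what starts a new, slightly larger loop. The envelope
therefore ratchets outward smoothly and the walker can never escape it.
This choice was made after quantifying the alternative reading (one fold
per boundary crossing, re-armed only after leaving the zone, `k` advancing
at returns to the inner disk, available as
`SimulatorConfig(fold_mode="event", loop_increment="inner")`): there a
near-tangential fold can strand the walker just outside the never-re-armed
threshold, after which it drifts away unconstrained. Across 1,000 seeded
runs of that variant, ~40 % of paths never escaped (median distance
~2 unit lengths) while the rest escaped to 100–500 units; the resulting
bimodal, heavy-tailed distance distribution has no stable median, which
contradicts the premise of the unit-length calibration (below). Under the
default semantics, per-path median distances concentrate to a few percent
(q10–q90 ≈ ±4 %), every 10 000-step run returns to the inner disk at
least ~9 times, and the final loop index is ≈340.

The raw path is smoothed by a centered moving average of length 25
(window truncated at the ends, no padding), scaled by the unit length
(default 2.22 m) and translated so the first smoothed point is exactly
the release site — the truncated moving average would otherwise displace
the start by the mean of the first 13 raw points. Fixes are timestamped
at 3-s intervals; downstream statistics use fractions of points, so only
the ordering matters. Distances from the release site are exactly linear
in the unit length (same seed), so `calibrate_unit_length` needs a single
simulation batch at u = 1: `u = median(reference distances) / median(unit
distances)`. The default calibration batch is 200 paths, for which the
pooled-median sampling error is well below 1 %.

**Model S vs R.** Model R is the same path restricted to radar-visible
fixes. With the default contained dynamics the model bee stays within
~80 m of the release site, which the radar sees completely, so R and S
coincide for the null model itself; the mask matters for real tracks,
wider-ranging configurations and the masked synthetic groups used in the
pipeline demos.

**Edge bias (synthetic cohorts).** The biased variant adds
`weight × wrap(target − heading)` to each step's heading increment at
integration time, where the target is the bearing to the nearest point of
the chosen edge (attraction) or, when a preferred angle is set, the
heading closest to the current one among the four headings making that
acute angle with the local edge direction. Weight 0 reproduces the
unbiased model bitwise under the same seed. Weight 0.5 toward the edge
through the release site roughly triples the time spent within 25 m of
it — a deliberately strong, recoverable effect; the generator is meant to
produce cohorts with *known* structure for pipeline validation, not to
imitate bee cognition.

**RNG.** Each bee draws from `SeedSequence([master_seed, group_index,
bee_index])`, so cohorts are reproducible bee-by-bee and independent of
generation order.

## Preprocessing

Fix tables (CSV: `bee_id, group, t_s, x_m, y_m`) are read per bee, sorted
by time; bees with non-increasing timestamps are rejected with a warning.
Coordinates are shifted so the release site is the origin. For the
heat-map and edge analyses each trajectory is resampled by inserting 10
linearly interpolated points between consecutive fixes (positions and
times); gaps are bridged linearly. "Relative time" everywhere means the
fraction of resampled points.

## Features

* **Directional profile** — fraction of points per 16-sector compass bin
  around the release site; points within 1 m of the release are excluded
  (undefined bearing; 1 m is far below radar resolution). Profiles can be
  additively normalized by the per-sector median of a reference group
  (the Model-R cohort by convention), so 0 means "same probability as the
  median reference bee" and values may be negative.
* **Heat map** — 19 × 18 grid of 100-m tiles, tile "99" centered on the
  release site (columns 0–9, A–I west→east; rows 0–9, A–H north→south).
  Each resampled point spreads mass 1/n uniformly over the axis-aligned
  square of half-width 50 m around it; per-tile mass is the exact
  rectangle-overlap area (deterministic and grid-resolution-free, unlike
  a post-hoc matrix convolution). Off-grid mass is dropped and the map
  renormalized to sum to 1. Half-width 25 m is available by parameter
  where the narrower reading of the kernel size is wanted. With
  half-width 0 the construction reduces to plain histogram binning
  (asserted in tests).
* **Edge features** — each point is assigned to its nearest edge
  (Euclidean distance to the polyline; ties to the lowest edge index) and
  a half-open distance range [0,10), [10,25), [25,50), [50,75),
  [75,100) m, or to "rest" beyond 100 m: 21 zones. Flight direction per
  point is the central difference of its neighbors (one-sided at the
  ends; zero displacements inherit the last defined heading). The angle
  to the edge is the acute angle between flight direction and the local
  segment direction, folded into [0°, 90°] and binned in six 15° ranges
  (the 90° perpendicular case lands in the last bin). The 4 × 5 time
  fractions and 4 × 5 × 6 angle fractions give 140 features; "rest" is
  carried as a 141st bookkeeping column. By construction
  Σ time_near + rest = 1 and the six angle bins of a zone sum to that
  zone's time fraction.

## Effect sizes

`mes(a, b)` is the fraction of sample *a* strictly above the median of
*b*, counting values exactly equal to that median at half weight — so
identical samples give exactly 0.5 regardless of ties. `Δmes = |mes − 0.5|`
is direction-free; the direction (which group lies higher) is kept as
metadata. Significance codes default to `*`/`**`/`***` at
Δmes ≥ 0.2/0.3/0.4 and are configurable. Kruskal-Wallis (tie-corrected,
chi-square p) is provided as a complement; the degenerate all-identical
case returns H = 0, p = 1. **No multiple-testing correction is applied**
— effect sizes, not p-values, are the primary statistic, and reports
state this. Per-pair discrimination counts, and top-k (default 25)
discriminant rankings with per-edge counts and cumulative Δmes (scaled so
k × 0.5 ≙ 100 %), summarize the 140-feature tables.

## Embedding

PLS uses the SIMPLS construction on column-centered (unscaled) X
(bees × 342 heat-map fractions) and Y (binary group indicator): unit-norm
orthogonal scores, X-loadings as the renderable "support vectors", and
percent of X variance explained per component (the variance convention is
stated in all outputs; requesting more components than the rank of X
truncates). Minimum-volume enclosing ellipsoids are computed by
Khachiyan's algorithm (tolerance 1e−6, containment enforced by a final
inflation to the farthest generating point); degenerate point sets
(repeated points, collinear/coplanar clouds) fall back to a
ridge-regularized shape matrix and are flagged. Ellipsoid surfaces are
resampled deterministically with 441 points from a 21 × 21
azimuth × inclination grid (poles kept once; the freed slots are re-padded
along the equator at azimuths chosen to avoid collisions, preserving the
exact count). The separatrix is a linear soft-margin SVM (C = 1, balanced
class weights, deterministic solver) trained on the pooled surface
samples of the two sides' ellipsoids — not on the raw bee scores — and is
reported as a unit normal and offset; the signed distance of a bee is
`normal · score − offset`. Separatrix normals can be pulled back through
the PLS loadings and rendered as grid matrices normalized to [−1, +1].

## Pipeline

`run_pipeline(RunConfig)` validates the landscape before any simulation,
then writes per stage: the cohort CSV, directional profiles (raw and
normalized) with pairwise tables, heat-map matrix and per-tile pair
counts, edge features with pairwise tables and top-discriminant
summaries, PLS scores/loadings, per-group ellipsoids, separatrix
coefficients, signed-distance tables and a manifest echoing seed and
parameters. Output is deterministic given the master seed (asserted
byte-for-byte in tests). The `beesearch` CLI (`simulate`, `features`,
`discriminate`, `embed`, `run-all`, `fixture`) is a thin layer over the
same functions.

## Test and demonstration scales

The bundled landscape fixture reproduces the study area's layout: four
parallel SW→NE polylines — a borderline through the release site, two
irrigation channels 611 m apart flanking it, and a row of bushes 30 m SE
of the radar. Simulator-based tests run the full 10 000-step study
configuration; cohort sizes in the recovery experiments are 12–16 bees
per group, matching the real group sizes (5–16). The parameter-recovery
acceptance experiment uses 20 replicate cohorts of 15 + 15 bees;
mass-conservation checks use 1,000 generic random-walk trajectories.

## Known limitations

* The null model is phenomenological: no aerodynamics, wind, energetics
  or vision. Its contained default dynamics keep the model bee within
  ~80 m of the release site — far less than real foragers range — so
  absolute spatial scales of synthetic cohorts are not comparable to
  radar data; all validation statistics are relative (fractions,
  effect sizes, orderings).
* The synthetic edge bias is a heading blend, not a model of landmark
  perception; passing recovery tests shows the *pipeline* detects known
  structure, not that real bees behave this way.
* mes is reported without multiple-testing correction across the 140-
  to 342-feature tables, mirroring the effect-size-first analysis
  convention; treat per-feature stars as descriptive.
* Geographic projections, map overlays and interactive 3-D exports are
  out of scope; all outputs are plain CSV/JSON.
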