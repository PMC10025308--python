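# beesearch

Analysis of central-place search flights tracked by harmonic radar.

When a honeybee forager is released at an unfamiliar site it searches in
loops that return repeatedly to the release point. Whether those loops are
pure random search or are shaped by landscape memory can be decided by
comparing groups of bees — reared in different home landscapes — against
each other and against a random-search null model. `beesearch` implements
that full comparison pipeline:

* **Null model** — a looping random-search walker: unit-length steps with
  heading increments `arctan(N(0, 0.25²))` passed through a 10th-order
  Butterworth low-pass filter (normalized cutoff 0.05), folded back by 180°
  whenever it strays beyond an excursion envelope of `1 + k/10` unit
  lengths (loop index `k`) or re-enters a 0.1-unit inner disk at the
  release site; the raw path is smoothed with a length-25 moving average
  and scaled by a unit length (2.22 m by default, calibratable to a
  reference cohort's median distance). Model **S** keeps all fixes; model
  **R** keeps only fixes visible to the radar (900 m range, 150° blanking
  sector). A biased variant steers the walker toward — or at a preferred
  angle to — a chosen edge, giving synthetic cohorts with a known,
  tunable guidance effect.
* **Features per bee** — fraction of time in 16 compass sectors around the
  release site; a spatial occupancy heat map over a 19 × 18 grid of 100-m
  tiles (342 fractions summing to 1, built by exact area-overlap of a
  50-m half-width square around each resampled fix); and 140 edge features
  (time near each of 4 edges in 5 distance ranges, plus the distribution
  of the flight angle relative to the nearest edge in six 15° bins).
* **Discrimination** — the measure of effect size based on Cohen's U3:
  `mes(a, b)` is the fraction of sample *a* above the median of *b*
  (ties at half weight), `Δmes = |mes − 0.5| ∈ [0, 0.5]`, coded
  `*`/`**`/`***` at Δmes ≥ 0.2/0.3/0.4; Kruskal-Wallis tests as a
  complement. No multiple-testing correction is applied.
* **Embedding** — SIMPLS partial least squares of the heat-map matrix
  against the group indicator (3 components), minimum-volume enclosing
  ellipsoids (Khachiyan) per group in score space, 441-point ellipsoid
  surface resampling, a linear soft-margin SVM separatrix between sets of
  groups, and signed distances of bees to that separatrix as the
  group-ordering statistic.

## Worked example

Three synthetic groups with graded edge attraction (weights 0, 0.25, 0.5
toward the borderline through the release site), embedded and ordered by
the separatrix between the extreme groups — `examples/03_heatmap_pls_separatrix.py`:

```
X variance explained per PLS component: [0.861 0.083 0.031]
cumulative: [0.861 0.945 0.976]

Median signed distance to the separatrix (unbiased vs strongly biased):
group
W0    -0.216
W25    0.058
W50    0.212

Pairwise Δmes on the signed distances:
  W0 vs W25: Δmes = 0.50 ***
  W0 vs W50: Δmes = 0.50 ***
  W25 vs W50: Δmes = 0.50 ***
```

Three PLS components explain 97.6 % of the heat-map variance; the median
signed distance grows monotonically with the attraction weight, so the
hyperplane fitted only between the extreme groups orders the intermediate
group correctly, and every pair is maximally separated (Δmes = 0.5). The
other examples cover the null model itself (`01`), directional profiles
with additive normalization by the Model-R median (`02`), and the
edge-feature discrimination with top-25 discriminant summaries (`04`).

A thin CLI wraps the same library calls:

```sh
beesearch fixture test-area --out landscape.yaml
beesearch simulate --landscape landscape.yaml --n-bees 16 --out fixes.csv
beesearch run-all --config run.yaml --seed 1 --out results/
```

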