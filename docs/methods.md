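# Methods

## Model

`isofuzz` implements a three-tier hierarchical fuzzy system over 18 crisp
measurements per participant: for each isokinetic mode (60, 180, 300 deg/s),
the right/left agonist–antagonist peak-torque ratio (`ratio_R`, `ratio_L`,
in %) and the right/left peak-torque-to-body-mass values for the away
(extension) and toward (flexion) movements (`away_R`, `away_L`, `toward_R`,
`toward_L`, in Nm/kg).

All membership functions are trapezoids T = (l, k1, k2, r): 0 outside
[l, r], 1 on the kernel [k1, k2], linear flanks. A degenerate flank
(l = k1 or k2 = r) takes the kernel value at the shared point, so
(0, 0, 0, 45) has membership 1 at x = 0.

Inference in every module is Mamdani with minimum for AND, truncation (min)
for implication and pointwise maximum for aggregation; the source system
only documents centre-of-gravity defuzzification, so the operator triple is
this package's (standard) choice. Defuzzification is the exact centroid of
the aggregated piecewise-linear membership function (see *Numerical
choices*).

### Tier structure

| tier | module | inputs | output levels | rules | consequent law |
|---|---|---|---|---|---|
| 1 | maximal torque (per mode) | ratio_R, ratio_L: low/med/high | 3 | 9 | level = 1 + #med |
| 1 | relative torque (per mode) | away_R/L, toward_R/L: low/high | 5 | 16 | level = 1 + #high |
| 2 | mode combiner (per mode) | e_MT, e_RT: low/high | 3 | 4 | level = 1 + #high |
| 3 | final | e_K60, e_K180, e_K300: low/high | 4 | 8 | level = 1 + #high |

The maximal-torque law is deliberately non-monotone: a mid-range
hamstring/quadriceps ratio signals muscular balance, so both-medium scores
highest and any drift toward low or high is penalized symmetrically. All
other modules are "the more, the better". The final tier depends only on
the *count* of high inputs, hence is invariant under permutations of the
three mode scores.

Crisp tier outputs are re-fuzzified by the next tier with
low = (0, 0, 0, 1), high = (0, 1, 1, 1) on [0, 1].

### Input set derivation

Mode-60 input sets are fixed by the published system definition. For modes
180 and 300 only low/medium/high *measurement ranges* are published, so the
package derives the sets by the convention that exactly regenerates every
published mode-60 set from the mode-60 ranges (this regeneration is itself
a test):

* ratio variables (3 sets, ranges low (0, a), medium (m1, m2), high
  (h1, M)): low = (0, 0, 0, m1), med = (0, m1, m2, M),
  high = (m2, M, M, M);
* torque variables (2 sets): with c_lo / c_hi the midpoints of the low and
  high ranges, low = (0, 0, c_lo, c_hi), high = (c_lo, c_hi, M, M).

All derived boundaries live in the default configuration
(`isofuzz/data/default_model.json`, reproducible by
`build_default_model()`) and are user-overridable via JSON/YAML.

### Output sets and boundary extension

An n-level output variable divides [0, 1] evenly: level i has kernel at
(i−1)/(n−1) with supports one spacing wide. The two extreme sets are then
mirrored outward — (0, 0, 0, s) becomes (−s, 0, 0, s) and symmetrically at
the top — so a fully fired extreme rule defuzzifies to exactly 0 or exactly
1 instead of being pulled inward by the one-sided support. The final output
variable uses exact thirds (1/3, 2/3) for its four levels; published
three-decimal boundary values (0.333/0.667) are treated as rounded thirds,
which is what makes the single-mode outcome exactly 1/3.

## Numerical choices

* **Aggregation** builds an explicit piecewise-linear function: breakpoints
  of every clipped consequent plus every crossing between two clipped
  segments, so the pointwise max is exact, not sampled.
* **COG** integrates each linear segment in closed form
  (area (μ0+μ1)Δx/2, moment Δx·(x0(2μ0+μ1)+x1(μ0+2μ1))/6). The test suite
  keeps an independent trapezoidal-rule grid oracle (step 1e-5) and checks
  agreement to 1e-6 over 1,000 random firing combinations.
* **Zero mass** (no rule fired) raises an error; with covering partitions
  and full Cartesian rule bases it cannot occur for in-domain inputs, so a
  silent default would only mask a misconfigured model.
* **Clamping**: measurements outside a variable's domain are clamped with a
  logged warning (dynamometer exports can slightly exceed nominal ranges);
  NaN/missing values are row-level errors, never imputed. Tier-2/3 inputs
  outside [0, 1] (beyond 1e-9) are errors, since they can only come from a
  broken caller.
* Analytic equality tests use absolute tolerance 1e-9; all arithmetic is
  double precision.

## Cohort statistics

`descriptive_stats` reports n, mean, sample SD (n−1 denominator), min, Q1,
median, Q3, max. Sample SD is the convention that reproduces the published
group summaries (the population SD does not). Quartiles use linear
interpolation between order statistics (type 7); the convention behind the
published quartiles is undocumented, so quartiles are reported but not
certified against them — though type 7 does match the published values for
all three groups. Input order never affects results (values are sorted
first). `spearman` is Pearson correlation of mid-ranks (scipy), with
errors for length mismatch or constant vectors. Results are printed at
8 decimals, matching the reference tables.

The package bundles the published per-participant outcome scores of the
three study groups (n = 28/19/46) as CSV fixtures for validating the
statistics; the raw dynamometer measurements behind them were never
deposited, so per-participant score recomputation and the published
Spearman correlations (0.576–0.749) against raw measurements are out of
reach by construction.

## Synthetic cohorts

The generator stands in for the undeposited raw data. Each measurement is
drawn from a normal distribution truncated to its variable domain,
per-group and per-mode. The three default profiles are honest inventions
chosen once from typical knee-dynamometry values:

* ratio locations near the balanced kernel for the trained-strong groups,
  drifting upward (quadriceps-dominant) for the weakest, SD 8 %;
* torque/body-mass locations ordered deaf untrained > deaf soccer players >
  hearing soccer players with 0.15–0.45 Nm/kg separations, SD 0.35 Nm/kg;
* group sizes 28/19/46 as in the study.

These separations make the scored group medians order deaf untrained >
deaf players > hearing players (the ordering reported for the real
cohorts) in essentially every seeded replicate; the suite requires ≥ 9 of
10. What the synthetic cohorts do **not** emulate: within-participant
correlation across modes and sides (values are sampled independently),
measurement error structure, and the real groups' absolute score levels —
synthetic medians run higher than the published ones. Passing tests
therefore demonstrate the model's structural behaviour and the pipeline's
correctness, not agreement with any real population.

## Problem sizes

Property suites run on deliberately modest grids: 21-point grids for
symmetry checks, 5–7-point grids per axis for monotonicity, 10,000 random
profiles for the normalization sweep, and 10 seeded replicates of the full
93-participant cohort for the median-ordering property. These sizes give
dense coverage of the low-dimensional input spaces while keeping the whole
suite under a minute of compute.

## Known limitations

* The direction of the published ratio input is ambiguous in its source
  (hamstring/quadriceps vs. quadriceps/hamstring); the package consumes a
  percentage on the documented domain ([0, 100] at 60/180 deg/s, [0, 150]
  at 300 deg/s) and leaves the direction to the user.
* Mode-180/300 ratio domains ending at 100/150 are implied by the published
  ranges, not stated as fuzzy sets; the derivation convention is documented
  above and overridable.
* Only trapezoidal sets and Mamdani inference are supported — no Gaussian
  sets, ordered fuzzy numbers or Sugeno-type systems, and no rule learning.
* Group-comparison hypothesis testing is out of scope; the pipeline reports
  descriptive statistics and Spearman correlation only.
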