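# Methods

This note documents every formula the package implements, the interval and
degenerate-case conventions chosen, and the statistical structure the
synthetic generator plants.  Notation: a city has demand zones
(traffic-analysis-zone grid cells) indexed by `i` or `k` with population
`D_i`, and hospitals indexed by `j` with supply score `S_j`; `d_ij` is the
road-network travel distance between zone `i` and hospital `j`.

## Entropy weight method

Raw indicator panels (rows = observation units, columns = indicators) are
first min-max normalized per column:

    r = (v - min) / (max - min)            (positive orientation)
    r = (max - v) / (max - min)            (negative orientation)

A constant column is normalized to all zeros — it carries no information
and must end with weight zero.  For indicator `i` over `n` units, shares
`f = r / sum(r)` (uniform `1/n` when the column sum is zero), entropy

    H_i = -(1 / ln n) * sum_f f ln f       with 0 ln 0 := 0,

and weight `w_i = (1 - H_i) / (m - sum H)` over the `m` indicators.
Weights sum to 1; an all-constant panel raises an error (weights
undefined).  Because min-max normalization absorbs affine rescaling, the
weights are invariant to the units the raw indicators are measured in.

Composite scores are weighted sums of normalized values, optionally over a
column subset (a "layer"), with optional renormalization of the subset
weights.

## Carrying capacity: kernel-decay 2SFCA

The two-step floating catchment area method with a distance-decay kernel

    G(d) = 0.75 * (1 - (d / d0)^2)   for d <= d0,   else 0.

`G(0) = 0.75`, falling smoothly to 0 at the catchment radius `d0`.  The
degenerate `d0 = 0` reduces to an indicator weight (1 at distance 0).

**Threshold.**  `d0` is the maximum over demand zones of the distance to
the nearest hospital — the smallest radius at which no zone is left
without a reachable hospital.  The supply-side analogue (maximum over
hospitals of the nearest-zone distance) is available via `side="supply"`.

**Step 1** computes each hospital's supply-to-demand ratio within its
catchment:

    R_j = S_j / sum_{k : d_kj <= d0} G(d_kj) * D_k

A hospital whose catchment contains no positively weighted demand gets
`R_j = 0` and is flagged.

**Step 2** sums reachable ratios per zone.  Two modes:

- `"paper"` (default): `A_i = sum_{j : d_ij <= d0} R_j` — a plain sum, the
  form commonly used in applied capacity studies.
- `"symmetric"`: `A_i = sum_j G(d_ij) * R_j` — the kernel applied in both
  steps.  This mode conserves total supply exactly:
  `sum_i D_i A_i = sum_j S_j` whenever every hospital has demand in range.
  The conservation identity is an acceptance criterion (checked to 1e-9
  relative on random instances; observed error is at machine precision).

The asymmetric `"paper"` mode does **not** conserve supply; both modes are
first-degree homogeneous in supply and inverse-homogeneous in demand.

**Grading.**  Capacity values are classed by Jenks natural breaks — the
exact dynamic-programming optimum of within-class sum of squared
deviations over contiguous partitions of the sorted values (verified
against exhaustive enumeration).  Classes are half-open from below with
the top class closed; the five default grade labels are, ascending,
`lower, low, middle, high, higher`.  Grade summaries report counts and
percentage shares rounded half-up to two decimals.

## Coupling coordination degree

Per year, a supply index `X` and a demand index `Y` (entropy-weighted
composites of the supply and demand indicator layers, weighted jointly
over all indicators):

    C = [4XY / (X + Y)^2]^k        coupling degree, k = 2
    T = alpha*X + beta*Y           comprehensive index, alpha = beta = 0.5
    D = sqrt(C * T)                coupling coordination degree

`C = 1` iff `X = Y > 0`; the both-zero case is defined as `C := 0` ("no
system present") even though the limit along `X = Y -> 0+` would be 1 —
a deliberate, documented convention.  The radical form `D = sqrt(CT)` is
the default; the plain product is available via `radical=False`.

`D` is graded into eight bands with lower edges
0, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9 (labels from "Disordered" to "Better
coordination").  Bands are half-open from below — `D = 0.3` falls in the
second band — and the top band includes `D = 1`.

The series also reports the **crossover year**: the first year with
`X > Y` strictly, i.e. when supply development overtakes demand.

## Bivariate LISA

The bivariate local Moran statistic per zone:

    I_i = z_x,i * (W z_y)_i

with z-scores using the population (1/n) standard deviation and
row-standardized spatial weights `W` (k-nearest-neighbor on coordinates,
or queen contiguity on grid indices).  `x` is the zone's supply level —
either the IDW-interpolated hospital score surface read at the centroid,
or the sum of scores within the cell — and `y` is population.

Significance uses **conditional permutation**: `z_x,i` is held fixed while
the other zones' `y` values are randomly reassigned to `i`'s neighbors;
the two-sided pseudo p-value is `(count(|I_perm| >= |I_obs|) + 1) /
(n_perm + 1)`.  Significant zones are labeled by the signs of `z_x,i` and
the observed lag: HH (high supply, high surrounding population), LL, and
the mismatch quadrants HL and LH.  Isolated zones are never significant.
The implementation is verified against a naive loop oracle, and the null
rejection rate is calibrated (≈ alpha on independent data).

## Demand typing

Hospitals are clustered by K-means (k-means++, 10 restarts) on five
z-scored workload indicators: total, outpatient, emergency and inpatient
visits, and discharges.  The cluster count is suggested by the **elbow
rule**: the `k` maximizing the discrete second difference
`WCSS(k-1) - 2 WCSS(k) + WCSS(k+1)` of the within-cluster
sum-of-squares curve.  When no bend clearly dominates (best second
difference under 3x the runner-up — a design parameter, not a fitted
one) the choice is flagged low-confidence; the second-difference rule is
only decisive when the true clusters are comparably separated, so the flag
matters in practice.

Clusters are ranked into **demand levels** by their mean standardized
workload, descending — level 1 is the heaviest-workload group.  A
per-indicator one-way ANOVA across clusters checks that the groups differ
(significance at alpha = 0.01); it requires at least two clusters with at
least two members each and is skipped (and flagged in the provenance)
otherwise.

## IDW interpolation

Inverse distance weighting with power 2 by default:
`z(p) = sum w_j z_j / sum w_j`, `w_j = d(p, x_j)^-power`, exact at data
points, optionally restricted to the nearest `max_neighbors` points.
Values are convex combinations of the data, so the surface never exceeds
the data range.

## Synthetic city generator

The generator produces inputs with exactly the structure the analyses
assume, so each analysis can be validated by recovering what was planted:

- **Population field**: smoothed white noise (Gaussian filter, sigma 1.5
  cells) rescaled to a configurable range — spatially autocorrelated, as
  LISA assumes.
- **Hospitals**: placed with probability proportional to population
  squared; a latent supply level correlates with local population at a
  target Pearson correlation (resampled until within ±0.1 of the target);
  beds and personnel are affine in the latent level, the ordinal grade
  (1-3) follows its terciles.
- **Mismatch zones**: optional quadrants where hospital resources are
  scaled down (x0.2, grade demoted) or up (x3, top grade) — recoverable
  both as depressed/elevated 2SFCA capacity and as LISA clusters.
- **Road network**: a 4-neighbor lattice over cell centroids; OD distances
  are shortest paths, not straight lines.
- **Workload tiers**: each hospital belongs to one of four planted tiers
  (probabilities 0.15/0.40/0.20/0.25) combining a volume magnitude
  (8/6/4/2) with a tier-specific case-mix profile (inpatient-heavy hubs,
  outpatient-heavy general hospitals, emergency-heavy district hospitals,
  ambulatory community facilities), times per-hospital and per-indicator
  multiplicative noise.  K-means typing recovers the tiers with adjusted
  Rand index 1.0 at default settings.
- **Yearbook**: 34 years of 17 indicators (8 supply, 9 demand) with
  multiplicative growth and noise; the supply layer grows slowly before
  2005 and faster after, so the normalized supply index crosses above the
  demand index late in the series — giving the CCD analysis a nontrivial
  trajectory from low to high coordination bands.

## Reproducibility

Every stochastic stage is driven by explicit seeds; `run_pipeline` reports
a SHA-256 digest over the numeric report content plus a config hash, and
identical (config, seed) pairs reproduce the digest exactly.

## Limitations

- Travel distances are network lengths, not travel times; no modal split.
- The `"paper"` 2SFCA mode double-counts supply across overlapping
  catchments (by construction); use `"symmetric"` when conservation
  matters.
- Entropy weights are computed jointly over both layers in the CCD series,
  so a layer's internal weighting depends on the other layer's dispersion.
- The elbow rule is only reliable for comparably separated clusters; treat
  the low-confidence flag as a real warning.
- Conditional permutation p-values are pseudo p-values; with `n_perm`
  permutations the smallest attainable value is `1 / (n_perm + 1)`, and
  no multiple-comparison correction is applied across zones.
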