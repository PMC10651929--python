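# Methods

This note documents the models and procedures implemented in `mobifood`, the
parameters that matter, the generative model behind the synthetic world, and
the numerical and design choices made where more than one reasonable option
existed.

## Stay detection

Pings are clustered per user by a greedy sequential rule. Let the open
cluster hold pings p₁…pₖ. Candidate p_{k+1} is admitted iff, after
inclusion, max_i haversine(pᵢ, c) < d_roam, where c is the coordinate-wise
median (median latitude, median longitude) of the members. On violation the
cluster closes — emitted as a stay iff it holds ≥ `min_events` pings and
spans ≥ `min_duration_min` — and the violating ping opens the next cluster.
The first and last member ping give the stay's start and end.

Defaults: `d_roam_m = 50`, `min_duration_min = 5`, `min_events = 2`.

Choices a different implementation could reasonably make differently:

- **Distance metric.** Haversine on WGS84 with Earth radius 6,371,000 m,
  shared by the generator, the detector and POI attribution so the simulated
  and measured worlds agree.
- **Strict inequality** at exactly d_roam: a ping at exactly 50 m from the
  centroid is excluded.
- **Discarded clusters.** A closed cluster failing the event/duration floors
  is dropped whole; its pings are not reassigned to neighbors.
- **No intra-stay time-gap cap.** Two co-located pings hours apart can form
  one stay; the upstream data's sampling cadence makes long silent gaps
  within a dwell genuinely ambiguous, and no cap is imposed.
- **Observation day** = local calendar date with ≥ 1 detected *stay* (not
  ≥ 1 raw ping), so trips/day uses the same event basis as trip counts.
  All timestamps are interpreted in one fixed study-region local time.

Trips are trajectories between consecutive stays: `max(0, n_stays − 1)`.

## POI attribution and outlet classification

POIs are represented as points (their centroid). A stay is attributed to the
haversine-nearest POI iff that distance is strictly below `d_max_m = 200`;
equidistant ties break to the smallest POI id for reproducibility. `is_food`
is a category-set membership test; `is_ff` additionally requires the
normalized outlet name (case-folded, punctuation stripped, whitespace
collapsed) to open with a normalized chain brand, so "McDonald's #1234"
matches "mcdonalds". Brand matching is deterministic; there is no manual
review step.

## User metrics

- A stay belongs to the daily period of its **start** time; periods are
  half-open: [00:00, 11:00), [11:00, 16:00), [16:00, 24:00) local.
- *FF visits/time* = 100 × (# observed (date, period) slots containing ≥ 1
  FF stay) / (# observed slots). A slot is observed iff ≥ 1 stay starts in
  it (configurable in principle to a ping basis; the stay basis keeps every
  metric on one event stream).
- *FF visits/food* = 100 × n_FF_visits / n_food_visits; undefined (NaN,
  user excluded from aggregation) when the user has no food visits. Every
  attributed stay counts as one visit, including repeat same-day visits.
- *Trips/day* = trips / observation days.
- **Home neighborhood** = the neighborhood (point-in-polygon on stay
  centroids) holding the largest total stay duration overlapping the
  nightly 22:00–06:00 window (wrapping midnight). Activity is measured by
  duration, not ping count. Ties break by stay count, then smaller id.
  Users with zero nighttime stay time have no home of record and drop out
  of aggregation.

## Aggregation and rescaling

Per neighborhood: arithmetic mean and **population variance (ddof 0)** of
user metrics over resident users; neighborhoods with fewer than
`min_users = 5` users are dropped with a warning (small cells are noisy and
privacy-hostile; the threshold is a package choice, not a study constant).
Percentage measures are rescaled by /10, mapping 0–100% onto 0–10, so one
scaled unit = 10 percentage points — this is what makes a "1-unit increase"
interpretable as a 10-point increase in exposure. Trips/day already lives
within 0–10 on realistic data and is left unscaled by default; a min-max
[0, 10] alternative (`trips_scaling="minmax"`) is provided because a
percentage-style /10 has no meaning for a rate. Linear rescaling commutes
with averaging, so scaling before or after aggregation is equivalent; the
min-max alternative does not commute and is applied after.

## Survey exclusions, descriptives, models

Exclusions run sequentially — missing residence, rural residence, missing
study variable — with per-rule counts; a record removed earlier is not
recounted. Descriptive comparison reports per-category counts and column
percentages over non-missing values, with a Pearson chi-square test of the
full-vs-analytic × category table (scipy; Yates continuity correction
applies to 2×2 tables by default).

FF intake (never < infrequent < moderate < frequent) is fit by maximum
likelihood multinomial logit with reference "never"; obesity and diabetes by
binary logit. Adjusted models add age group, gender, race/ethnicity,
education and income as treatment-coded dummies, reference = first listed
category. Fits are **unweighted** (no survey design weights). CIs are Wald
on the log-odds scale; AIC = −2·loglik + 2k with k counting every estimated
coefficient including intercepts (summed over outcome-category blocks for
the multinomial). Newton optimization, tolerance 1e-8, max 500 iterations;
non-convergence, non-finite or implausibly large (> 50) standard errors
raise a `ModelFitError` naming the model — separation is surfaced, never
silently reported. Akaike weights use min-AIC subtraction for stability.

## Sensitivity machinery

Tract change = (year B − year A) for three percentage variables: % of the
population above 200% of the Federal Poverty Limit, % Black or African
American alone, % Hispanic or Latino. Outliers per variable by (1) Tukey
fences — x > Q3 + 1.5·IQR or x < Q1 − 1.5·IQR, quartiles by linear
interpolation between order statistics (fences depend on this convention;
it is the numpy default) — and (2) |x − mean| > 2 sample sd (ddof 1); the
analysis set is the union over the three variables. Fences are computed on
signed deltas. The stability quantile z solves P(|X| < z) = 0.95 as the
empirical 95th percentile of |delta|, linear interpolation. Both rules use
strict inequalities, so constant change vectors yield no outliers.

Refits drop respondents in outlier tracts and re-estimate the six primary
models (2 exposures × {intake multinomial, obesity, diabetes}); per-term OR
percentage changes above 10% are flagged as meaningful. The confounder check
adds scaled trips/day to the disease models and reports the change in the
FF-exposure AOR.

## The synthetic world

The generator emulates the *conditions* of a mobility–survey linkage study,
not any particular city:

- **Geometry.** Neighborhoods are grid cells (default 12 cells of 2 km) on
  a local planar grid anchored at a fixed lat/lon; tracts are vertical
  strips within cells (default 4 per neighborhood). Distances use the same
  haversine as the pipeline.
- **POIs.** Default 30 per neighborhood, 60% food; the FF share of food
  outlets is drawn per neighborhood from `ff_fraction_range`. FF outlets
  carry chain-brand names with store numbers; classification from names and
  categories must therefore recover the planted flags exactly.
- **Behavior.** Each user lives at a home anchor (users spread evenly over
  neighborhoods) and on each day dwells at home overnight, optionally at a
  work site (p = 0.7), and makes a food-outlet visit in each daily period
  with p = 0.4. The FF-vs-other choice of each food visit is Bernoulli with
  the home neighborhood's planted propensity (defaults evenly spaced over
  0.05–0.35, monotone in neighborhood id so the ordering is recoverable).
  Home and work anchors are placed ≥ 250 m from any POI so residential
  dwells stay distinct from commercial visits.
- **Measurement.** Pings arrive at irregular 5–15 min intervals and are
  jittered with isotropic Gaussian noise whose scale is set so the median
  radial error equals the configured accuracy (21 m): for Rayleigh radial
  error, σ = accuracy / √(2 ln 2). Whole (day, period) blocks are dropped
  with probability 0.2, mimicking phones out of service. Days are
  exchangeable — no day-to-day behavioral autocorrelation is simulated.
- **Survey.** Respondents draw a residential tract uniformly, categorical
  demographics from fixed urban-survey marginals, FF intake from a
  multinomial logit on the neighborhood's *true* scaled exposure
  (propensity × 10) with planted log-ORs (defaults ln 1.13 / ln 1.26 /
  ln 1.35 for infrequent/moderate/frequent), and obesity/diabetes from
  logistic models (defaults ln 1.16 and ln 1.15 per scaled unit; intercepts
  set for ≈ 25% and ≈ 11% prevalence at the mean exposure). Covariate
  effects default to zero, so the unadjusted exposure model is the true
  model and recovery is free of noncollapsibility bias; planting covariate
  or trips/day effects is supported for confounding scenarios.
- **Tract demographics.** Year-A percentages are uniform draws; year-B adds
  N(0, sd) change with sds (8.0, 5.0, 7.5 points) chosen so the 95th
  percentiles of |change| sit near 16 / 10 / 15 points; designated outlier
  tracts (default 2) shift by +30 points on all three variables. Values are
  clipped to [0, 100].

What the generator does **not** emulate — and hence what passing tests do
not show about real data: road-network trajectories and travel pings,
device heterogeneity, spatially clustered POI density, population-density
differences across neighborhoods, within-user behavioral autocorrelation,
residential self-selection, and any form of differential privacy noise.
Parameter-recovery results certify the pipeline's correctness under the
stated generative model, not the substantive findings of any real study.

## Problem sizes and validation design

- Unit oracles: stay detection is checked against a brute-force pure-Python
  greedy oracle on 200 random 50-ping tracks whose jitter scale straddles
  the 50 m decision boundary; attribution against an all-pairs
  nearest-neighbor oracle on random 100-stay/50-POI instances.
- Estimator calibration: 200 survey replicates at n = 5000 fit on the true
  scaled exposure; 95% CI coverage is required in [0.92, 0.98] and mean
  log-OR bias below 0.02 for the planted frequent-intake (OR 1.35) and
  obesity (OR 1.16) effects. Null calibration uses 200 replicates at
  n = 2000 with all planted effects zero; the acceptance band for the
  rejection rate, 5% ± 3 Monte-Carlo sigma → [0.004, 0.096], was fixed
  before running.
- Sensitivity stability: the homogeneous-effects refit check runs at
  n = 20,000 respondents with the two planted outlier tracts plus
  noise-flagged tracts removed (≈ 6% of respondents). The size was chosen
  by a power calculation so that sampling noise in the full-vs-subset OR
  difference (≈ 0.6% sd) sits well below the 2% band being verified.
- End-to-end runs use 90–600 users over 3–7 days; the within-vs-across
  neighborhood variance contrast is checked at 45 observation days per
  user, because the contrast's precondition is long per-user observation.
- Pipeline recovery (`validate_recovery`) passes a parameter when the
  estimate sits within 3 SE of the planted value (the 95% CI coverage flag
  is reported alongside); a joint rule requiring five simultaneous 95% CIs
  to cover would fail ≈ 1 in 4 healthy runs.

## Known limitations

- Stays attributed to a POI merely because a dwell occurred nearby are not
  distinguishable from true visits; the synthetic anchors' POI buffer
  sidesteps this, real data cannot.
- The multinomial fit requires the reference category "never" to be present
  in every (sub)sample; sensitivity refits that empty a category are
  skipped with a diagnostic rather than refit on a collapsed outcome.
- Measured contextual exposures carry neighborhood-level sampling error,
  which attenuates regression coefficients relative to the planted values;
  `validate_recovery` therefore separates the measurement check (rank
  correlation, tolerance band) from the estimator check (coverage on the
  true exposure).
- Geocoding, survey weights, multilevel models and margin-of-error
  propagation for the demographic tables are out of scope.
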