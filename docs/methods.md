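# Methods

`csarima` implements cluster-based seasonal local modeling (C-SARIMA) for
short- to mid-term forecasting of continuous glucose monitoring (CGM) data
in type 1 diabetes, together with the individualized ARIMA/ARIMAX
comparators and the evaluation machinery needed to assess it.  This note
records the model, the conventions the implementation fixes where the
methodology leaves room, the numerical choices, and the limits of what the
synthetic test bed can show.

## The model

CGM traces are uniformly sampled at 5 minutes, in mg/dL, with an explicit
missing mask.  The pipeline is per subject:

1. **Segmentation.** Each self-reported meal anchors a postprandial period
   (PP): the window from the meal's grid slot up to 4 h (48 samples) or the
   next meal, whichever comes first, NaN-padded to length 48, plus the 5
   pre-meal samples ("presamples").  PPs with more than 18 missing samples
   (1.5 h) in their observed region are discarded.  On training data only,
   gaps strictly shorter than 30 min are linearly interpolated beforehand.
2. **Clustering.** The 48-sample windows are grouped by fuzzy C-means with
   the partial-distance strategy (PDSFCM): for a window *x* with observed
   index set *I* and prototype *v*,
   d²(x, v) = (48/|I|) · Σ_{k∈I} (x_k − v_k)², which equals the squared
   Euclidean distance on complete windows.  Memberships w_ij ∈ [0, 1] with
   Σ_i w_ij = 1 follow the standard update
   w_ij = 1 / Σ_k (d²(x_j, v_i)/d²(x_j, v_k))^{1/(m−1)}; prototypes are
   membership^m-weighted means taken per coordinate over the windows that
   observe that coordinate, so they are always complete.  The cluster count
   nC and fuzzifier m are chosen by exhaustive grid search minimizing the
   Fukuyama–Sugeno index
   FS = Σ_ij w_ij^m [d²(x_j, v_i) − ‖v_i − v̄‖²] (lower is better), with v̄
   the weighted grand mean of the windows.
3. **Identification.** For each cluster, the assigned PPs are concatenated
   chronologically as `[5 presamples | 48 window samples]` blocks, giving an
   artificial series with enforced seasonality S = 53.  A
   SARIMA(p,d,q)(P,D,Q)_53 model with intercept is identified per cluster by
   exhaustive BIC grid search; estimation is exact maximum likelihood via
   the state-space form, with missing entries handled by the Kalman filter
   (never imputed).
4. **Forecasting.** At mealtime a session opens with the 5 presamples.
   After a burn-in of 3 observed post-meal samples, every new sample
   triggers: membership weights of the observed prefix against the
   prototypes (same update as above, fitted m), one forecast per cluster
   model, and the output ŷ(t+PH|t) = Σ_i w_i ŷ_i(t+PH|t) for horizons
   PH ∈ {30, 45, 60, 75} min (6/9/12/15 steps).
5. **Evaluation.** RMSE between predictions and observed targets per PP and
   horizon; per-subject medians, cohort median [q1–q3]; paired comparison
   between methods gated by a Shapiro–Wilk normality test (paired t-test if
   normality is accepted, Wilcoxon signed-rank otherwise, α = 0.05).

Benchmarks: an individualized ARIMA (CGM only) and ARIMAX (CGM + CHO +
insulin as impulse-encoded exogenous inputs with distributed lags 0..X−1 per
input).  They are not meal-reset — they condition on the full test history up
to each origin — and are paired with targets by exactly the same PP logic as
the C-SARIMA forecaster.

## Conditioning of local forecasts (design choice)

A local model's seasonal terms reference lag 53 — the same slot of the
*previous* period of that cluster.  If a forecast session conditioned only on
`presamples | prefix` (at most 53 samples), every seasonal lag would be
unobserved, the Kalman state would fall back to its stationary prior, and
each local forecast would decay to the model intercept: the cluster shape
would never enter the prediction, defeating the purpose of clustering.  We
therefore filter each local model over
`cluster training series | presamples | prefix`: the current PP is treated
as the next season of the cluster's artificial series, which is precisely
the structure the model was identified on.  Test PPs are never chained to
each other — every meal opens a fresh session from the (static) training
context.  The bundle stores one context per cluster for this reason.

## Implementation conventions

Where the methodology is underdetermined, the implementation fixes the
following (all covered by tests):

- **Grid snapping**: sample timestamps snap to the nearest 5-min slot, ties
  toward the earlier slot; duplicate slots keep the last record.
- **Discard rule**: the 18-missing-sample limit counts sensor dropouts in
  the observed region only; NaN padding from an early next meal is
  structural and exempt (otherwise every short PP would be discarded,
  contradicting the padding construction).
- **Gap filling** is strict: a gap of exactly 30 min (6 samples) is not
  interpolated; edge gaps never are.
- **Fuzzifier grid** is {1.2, 1.4, …, 3.0}: the membership update is
  singular at m = 1, so the conventional grid starting at 1 is truncated
  above the crisp limit.
- **Zero distances** in the membership update split the weight uniformly
  over the zero-distance clusters.
- **Initialization**: memberships drawn row-wise from Dirichlet(1) with a
  seeded generator; 5 restarts by default, best final objective kept;
  convergence when the largest membership change is below 1e-5 or after 200
  iterations.
- **Cluster-size floor**: grid cells whose smallest hard-assigned cluster
  has fewer than 3 PPs are rejected — a seasonal model cannot be identified
  on fewer periods.
- **FS separation term** uses the plain Euclidean distance (prototypes are
  complete by construction).
- **Hard assignment** for concatenation is argmax membership, ties to the
  lowest cluster index; PPs concatenate in chronological order to preserve
  slow drift.
- **Intercept**: models with d = D = 0 carry a free intercept; any
  differencing removes it (it would be unidentified).
- **Non-convergence**: a fit that fails to converge (or errors numerically)
  is flagged and excluded from the grid search rather than crashing; BIC
  ties break toward fewer parameters, then the lexicographically first cell.
- **Burn-in** counts observed samples, so missing slots extend the wait;
  after burn-in, a missing sample freezes the weights but forecasts still
  update (the filter records the slot as unobserved).
- **Pairing**: a prediction is evaluable when its target slot lies inside
  the PP's observed region and is itself observed; pairs are shared
  verbatim between C-SARIMA and the benchmarks.
- **Percentiles** use linear interpolation between order statistics.
- **Comparison unit** is the per-subject median RMSE (configurable to
  per-PP pairing).
- **ARIMAX information advantage**: future exogenous values inside a
  horizon are taken from the log — meal and bolus amounts are announced at
  mealtime — and this is deliberate: the comparator is defined as the method
  that uses more input.

## Numerical acceleration

Two measures keep exact-likelihood estimation tractable at S = 53:

- **Chandrasekhar recursions** replace the standard Riccati update whenever
  the series is fully observed (they are invalid with missing data or
  time-varying intercepts); this cuts a typical seasonal fit from ~30 s to
  ~8 s with bit-identical likelihoods.
- **Batched multi-origin forecasting**: h-step forecasts from *every*
  origin are obtained from one Kalman pass by propagating the predicted
  state through the transition matrix, instead of re-filtering per origin.
  The filter is causal, so the results match the incremental per-sample
  loop exactly (tested to 1e-9 relative).

## Synthetic test bed

The generator emulates the structure of free-living CGM studies: a
circadian sinusoidal baseline (default amplitude 15 mg/dL around
120 mg/dL, trough near 03:00), three daily meals with 30-min timing
jitter, meal excursions drawn from a small set of archetype response
shapes (gamma-density-shaped curves parameterized by peak rise,
time-to-peak and decay time), AR(1) sensor noise (sd 5 mg/dL, lag-1
correlation 0.6), clipping to the 40–400 mg/dL device range, and missing
gaps from a seeded point process with geometric lengths calibrated to a
~12% missing fraction — inside the 3–18% range such studies report.  Meal
anchor slots are protected from deletion (meals are self-reported
independently of sensor dropouts).  Default span 56 days (8 weeks), test
split the last 10 calendar days.

What it does **not** emulate: exercise and stress effects, insulin-glucose
dynamics (logged insulin is consistent but not causal for the trace),
sensor drift/compression artifacts, and meal-to-meal response variability
beyond additive noise.  Passing tests therefore show the machinery is
correct and that the method behaves as designed when its structural
assumption (a small set of recurring postprandial shapes) holds; they do
not certify accuracy on clinical data.

## Problem sizes used in tests and the acceptance script

Exhaustive identification at the production grids (nC up to 30; 960 SARIMA
cells; AR/MA up to 20) is a batch job, not a test.  The test suite and the
acceptance script therefore run the full pipeline at reduced sizes chosen
as the package's desk-scale defaults: an 18-day synthetic subject with a
6-day test split, cluster search over nC ∈ {2,3,4}, m ∈ {1.6, 2.0}, a
seasonal grid of p = 1, q ∈ {0,1}, P = 1 at S = 53, and a benchmark grid
AR ∈ {1,2,3,6}, MA ∈ {0,1}, I ∈ {0,1}.  Property tests of the estimation
machinery use the scaled-down seasonal convention S = 10.  The production
defaults remain the full grids; nothing in the library changes between the
two regimes except the grid configuration passed in.

## Known limitations

- Estimation cost grows steeply with S; the full 960-cell seasonal grid at
  S = 53 on weeks of data takes hours of CPU (offline training, as the
  methodology intends).
- The ARIMAX regression structure (distributed lags applied to both inputs
  independently, order shared) is one reasonable reading of an
  under-specified comparator.
- Cluster count selection on real free-living data tends to many clusters;
  with few training PPs per cluster the seasonal fits become fragile — the
  3-PP floor is a guard, not a cure.
- Timestamps are naive; daylight-saving transitions are the caller's
  problem.
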