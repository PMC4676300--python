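# Methods

This note documents the models and estimators implemented in
`ecohorizon`, the defaults chosen where the design was genuinely open,
and what the synthetic-data generators do and do not emulate.

## Forecast proficiency and horizons

A *proficiency curve* records forecast quality as a function of forecast
distance. For time-series forecasts, quality is computed in sliding
windows over lead time; each window is labelled by the centre of its
time span, which keeps curves symmetric under time reversal. Window
length defaults to 10 samples (20 for the slower eco-evolutionary
observables, whose series are 400 generations long), step 1; both are
arguments everywhere. Windows in which the truth or the forecast has
zero variance yield a missing value that is propagated, never imputed —
substituting 0 would bias every downstream horizon. R² defaults to the
squared Pearson correlation of observed and predicted (invariant to
linear rescaling of the forecast); the `1 - SSres/SStot` convention,
which additionally penalises bias, is available by flag.

The *forecast horizon* is the first distance at which the curve crosses
the usefulness threshold in the stated direction, linearly interpolated
between the adjacent sampled points. A curve that starts on the
crossing's target side has horizon 0; a curve that never crosses has
horizon +infinity — the two ends of the scale are meaningful, not error
states. Only the first crossing defines the horizon; later re-entries
and exits are reported separately as *blind spots* (maximal
sub-threshold intervals, with their complement partitioning the curve's
support exactly).

With replicate forecasts the per-replicate horizons form a
distribution. Infinite horizons are ranked above every finite value;
the median is +infinity when more than half the replicates never cross;
the mean is reported over finite values with the infinite count
alongside. Percentile bands use linear interpolation between order
statistics, except that interpolating into an infinite order statistic
yields +infinity (numpy's interpolation would produce NaN from
inf - inf). The default band is the 25th–75th percentile; narrower
bands such as 55th–65th are an argument.

Two summary routes exist and are deliberately both exposed: the horizon
of the replicate-mean proficiency curve, and the distribution of
per-replicate horizons. They need not agree (the mean of crossings is
not the crossing of means); experiments accept `horizon_mode` or report
both.

*Fitted-curve horizons*: when a sampled curve is noisy, a parametric
decay family — exponential `a exp(-d/tau)`, logistic sigmoid, or a
shape-preserving monotone spline — is least-squares fitted
(`scipy.optimize.curve_fit`) and the horizon solved on the fitted
function (dense bracketing + Brent refinement). The 95% pointwise
confidence envelope, obtained by the delta method from the fit
covariance, is intersected with the threshold to give a horizon
interval. On noiseless exponential data the crossing is recovered to
1e-6; on noisy data (sigma = 0.05, 30 points) the interval covers the
generating horizon in ~95% of seeds. How to propagate curve-fit
confidence bands to horizon ranges is a genuine design choice; the
envelope-intersection rule used here is simple and conservative but not
the only possibility.

## Lyapunov route

For a deterministic one-dimensional map, the largest Lyapunov exponent
is estimated two independent ways: (i) *twin-run divergence* — iterate
from x0 and x0 + delta_0, regress ln|difference| on time over the
growth phase only (the fit stops at the first step where separation
exceeds 25% of the reference orbit's sampled range, since exponential
divergence is a small-separation approximation); and (ii) the *orbit
average* of ln|f'(x_t)| after burn-in, available when the map has an
analytic derivative. The two routes agree within 0.05 for the logistic
map across the chaotic regimes tested, and route (ii) reproduces the
known value ln 2 at r = 4 to 0.01.

The predictability time is `T_p = ln(Delta/delta_0)/lambda` for
lambda > 0, infinite otherwise, where delta_0 is the initial-condition
uncertainty and Delta the required precision. `T_p` is governed by
1/lambda and depends only logarithmically on delta_0 and Delta —
halving delta_0 buys exactly ln2/lambda extra steps. The formula is a
heuristic scale, not a metric-based horizon; cross-module agreement is
therefore asserted only qualitatively (finite vs infinite, ordering in
lambda). Multidimensional spectra (Benettin/QR) are out of scope; for
simulated communities only twin-run divergence of the state vector
would be exposed, and only the largest exponent matters for
predictability.

## Chaotic Ricker experiment

Truth: `N_{t+1} = N_t exp(r (1 - N_t/K_t))` with r = 3.0 (chaotic),
K0 = 100, N0 = K0/2, 100 generations. The carrying capacity drifts
linearly, `K_t = K0 + K_step t` ("rate of change" read as a linear
trend; a single step change is available by flag since the phrase is
ambiguous). Demographic stochasticity, when enabled, replaces each
generation's size by a Poisson draw with the deterministic expectation
as mean — the canonical discrete-birth noise, which makes N = 0
absorbing and the trajectory integer-valued.

The forecasting model is always deterministic: stochasticity is a
property of the true dynamics, never of the forecaster. Parameter
uncertainty enters through the forecaster's parameters, drawn from
normals centred on the truth with SD = CV x value, truncated at zero
for r and N0 (resampled, capped retries) and untruncated for K_step.
When the truth is stochastic it is re-simulated per replicate (a flag
restores a single shared truth).

Per replicate: draw parameters, simulate the forecast, windowed
correlation against truth, per-replicate horizon at threshold 0.5 (the
conventional arbitrary choice). Results are bit-reproducible from
(configs, seed). Under these conditions mean proficiency decays from
~1 to below 0.1 within ~25 generations in every uncertainty cell of
CV(r), CV(N0) in {1e-3, 1e-2, 1e-1} x {1e-3, 1e-2, 1e-1} (200
replicates per cell); the median horizon is non-increasing in each CV
axis; and demographic stochasticity in the truth collapses the horizon
below the matched deterministic median in every cell. High uncertainty
in r flattens the effect of uncertainty in N0 (the interaction
pattern): chaos amplifies whichever error is largest.

## Eco-evolutionary community experiment

The community model is a Gaussian-kernel trait-based competition model
(the standard formulation of resource-axis competition): species i with
trait x_i has carrying capacity
`K_i(t) = K_max exp(-(x_i - theta_t)^2 / (2 sigma_K^2))` around the
fluctuating resource optimum theta_t, competition coefficients
`alpha_ij = exp(-(x_i - x_j)^2 / (2 sigma_alpha^2))`, and Ricker-type
abundance updates. Evolution, when enabled, moves traits up the
per-capita growth gradient at rate h (a deterministic
quantitative-genetics reading; mutation-driven stochastic evolution is
out of scope). Extinction below a threshold is absorbing and extinct
species' traits freeze. This model is a reconstruction from a verbal
description; every width and rate is config-exposed, and only ordering
properties — not numeric horizon values — are asserted about it.

Defaults: 10 species, traits equally spaced on [-2, 2], sigma_K = 1,
sigma_alpha = 0.5, r_max = 1, K_max = 100, h = 0.05 when evolution is
on, 400 generations in the forecast experiment. The environment theta_t
is a stationary AR(1) process with marginal SD 1.0 and lag-1
autocorrelation 0.5 — fluctuations comparable to one resource-kernel
width, autocorrelated enough that windows contain real signal.

Environmental uncertainty has two components: intrinsic stochasticity
(the AR(1) draw itself) and the forecaster's imperfect knowledge of it
(independent N(0, sigma_u^2) noise added to the series the forecaster
sees). By default each replicate draws its own true environment and
truth trajectory; the horizon distribution then integrates over both
components, which makes its medians stable rather than hostage to one
environmental realisation. A `fixed_environment` flag shares a single
truth across replicates, in which case sigma_u = 0 makes all replicates
identical (zero-width bands). Evolution is never in the forecasting
model. The focal species defaults to the one whose trait is nearest the
long-run optimum.

Two observables are tracked: one species' abundance, and total biomass
(unit per-capita mass, so biomass = summed abundance). Under these
conditions the median biomass horizon is at least the median abundance
horizon at every uncertainty level, and both shrink as sigma_u grows.
The mechanism: evolutionary trait change redistributes abundance among
species (hitting the focal species hard) while density compensation
buffers the total, and the total also tracks the environmental signal
shared between truth and forecaster. Replicates whose proficiency curve
is entirely undefined (focal species extinct throughout — a
zero-variance observable) are recorded as horizon 0.

## Spatial and phylogenetic pipelines

*Distance decay*: similarity of every site pair — Sørensen
`2|A∩B|/(|A|+|B|)` on presence sets (the fraction of correctly
"predicted" occurrences when one community forecasts the other) or
Pearson correlation of square-root-transformed abundances — binned by
geographic distance (planar Euclidean for x/y in km; haversine when
coordinates are flagged lon/lat); per-bin means form the curve and the
spatial horizon is its falls-below crossing.

*Host use*: a binomial GLM (statsmodels IRLS, deviance tolerance 1e-8,
max 50 iterations; tiny ridge penalty available under complete
separation) models whether a herbivore uses a plant from the
herbivore's host breadth (raw count; log by flag) and the plant's
phylogenetic distance to another known host, operationalised as the
*minimum* patristic distance over the herbivore's known hosts.
Predictions are partitioned into 12 distance slices — equal-count by
default, which protects per-slice AUC from tiny classes; equal-width by
flag — and AUC (rank statistic, ties counting one half) is computed per
slice. Slices lacking both outcome classes are missing and skipped by
horizon estimation, never interpolated across. Because proficiency
*rises* with distance here, the horizon is the rises-above crossing:
the distance beyond which forecasts become useful. Slice-regression
fits are unweighted by slice size.

## Synthetic fixtures: what they emulate, and what not

Every generator is a pure function of (spec, seed), and every generated
object satisfies its type's invariants. Because the generating
parameters are known, each downstream estimator has a parameter-recovery
test; these are the package's substitute for external survey data.

*Spatial communities*: species occupy noisy range discs (radius drawn
within +/-50% of the decay scale, occupancy 0.95 inside / 0.02
outside), with log-normal abundances whose median decays from the range
centre. Adjacent sites then share almost everything and similarity
decays on the generating scale; an earlier design using smooth
exponential occupancy probabilities was rejected because independent
Bernoulli draws cap similarity far below 1 even at zero distance,
degenerating the horizon. Not emulated: anisotropy, environmental
gradients, spatial abundance autocorrelation beyond the range
structure, observation effort.

*Phylogenies*: pure-birth (Yule) trees, built in-house on dendropy
node primitives so the seeded RNG stream is owned by this package; tips
are extended to the present (ultrametric) and labelled deterministically.

*Host use*: per herbivore, seed hosts cluster within clades with
probability 0.8 (nearest-relative attachment), emulating family-level
specialisation; remaining plants' use follows the logistic law in
(breadth, min patristic distance). On ultrametric trees the min
distances concentrate in a tied atom at twice the tree depth (every
plant across the root from all hosts is equidistant), and under a plain
logistic law the near slices carry the largest predictor variance — so
slice AUC does *not* rise with distance. The generator therefore adds
short-range idiosyncratic label noise: with probability
`0.95 exp(-d/60 MYA)` a record's outcome is replaced by a fair coin.
This encodes the biological reading that host use among close relatives
of a known host is hit-or-miss (within-clade chemistry varies) while
use across distant clades is reliably determined, and it is what makes
proficiency rise with phylogenetic distance. Passing pipeline tests
therefore show that the estimators recover structure *of this kind*;
they do not validate the logistic-plus-idiosyncrasy law against real
interaction data.

*Replicate curves*: noisy exponential or linear decay curves whose
noiseless version crosses a stated threshold exactly at a stated
horizon — known-answer inputs for the horizon estimators.

## Numerical choices and limitations

- Thresholds are checked against the metric's range; crossings on flat
  segments resolve to the segment's far end; ties at the threshold
  count as not-yet-crossed for falls-below (strict inequality defines
  the bad side).
- The truncated-normal parameter sampler resamples up to 1000 times
  before failing loudly; CVs of 0 short-circuit to the exact value.
- JSON reports serialise infinite horizons as the string `"inf"` with
  an `is_infinite` flag, and carry the seed and a sha256 digest of the
  canonicalised configuration.
- Problem sizes in the test-suite experiments (200 replicates per
  Ricker cell, 100 replicates x 3 levels for the community model, 50
  seeds per fixture sweep) were chosen as the smallest ensembles whose
  Monte-Carlo orderings are stable across master seeds.
- Known limitations: no probabilistic-forecast scores (CRPS, log
  score); no multivariate/combined horizons; no attractor-reconstruction
  Lyapunov estimation from observed series; no fitting of the process
  models to data; the eco-evolutionary model is a reconstruction whose
  quantitative outputs should not be compared to any published figure.
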