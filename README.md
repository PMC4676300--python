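# ecohorizon

Forecast horizons for ecological dynamics: how far — in time, space, or
phylogeny — can a useful forecast be made?

Ecological forecasts degrade with distance. A population forecast loses
skill with lead time; a community-composition "forecast" from a nearby
site loses skill with kilometres; a prediction of which plants a
herbivore will eat changes quality across a phylogeny. `ecohorizon`
turns any such proficiency-vs-distance relationship into a single
interpretable number, the **forecast horizon**: the distance at which
*forecast proficiency* (correlation, R², error statistics, AUC,
community similarity — any metric with a declared orientation) crosses a
*usefulness threshold*. Because multiple forecasts (parameter draws,
stochastic replicates) give a distribution of proficiencies, the horizon
comes with a distribution too: medians, percentile bands, and counts of
replicates whose forecast never degrades (infinite horizons).

The package is aimed at population and community ecologists studying
predictability itself: which uncertainties (parameters, initial
conditions, environment, demographic stochasticity, evolution) shorten
horizons, and how predictability depends on the level of ecological
organisation or the dimension along which one forecasts.

## What is inside

- **`proficiency`** — trajectories, forecast ensembles, and
  moving-window proficiency curves (Pearson correlation, bias / MSE /
  RMSE / MAE, R²), plus replicate aggregation with percentile envelopes.
- **`horizon`** — threshold-crossing estimators: first-crossing horizons
  with linear or step interpolation, horizon distributions (infinities
  ranked above all finite values), parametric decay-curve fits
  (exponential, logistic, monotone spline) with 95% confidence intervals
  propagated to the crossing, and forecast *blind spots* (interior
  sub-threshold windows).
- **`lyapunov`** — the analytic route: the largest Lyapunov exponent
  lambda from twin-trajectory divergence or the orbit average of
  ln|f'(x)|, and the predictability time
  `T_p = ln(Delta/delta_0) / lambda` (infinite for lambda <= 0).
- **`ricker`** — the chaotic Ricker population model
  `N_{t+1} = N_t exp(r (1 - N_t/K_t))` with drifting carrying capacity,
  optional Poisson demographic stochasticity, and a full
  parameter-uncertainty forecast experiment (CVs on r, N0, K_step).
- **`ecoevo`** — a trait-based competitive community on a resource axis
  (Gaussian carrying-capacity and competition kernels, AR(1)
  environmental fluctuation, optional gradient-dynamics trait
  evolution), with a forecast experiment comparing single-species
  abundance against total community biomass under environmental
  uncertainty.
- **`dimensional`** — spatial and phylogenetic pipelines: Sørensen and
  square-root-abundance Pearson similarity, distance-decay curves,
  patristic distances from Newick trees, a binomial GLM of herbivore
  host use (host breadth + phylogenetic distance), per-distance-slice
  AUC curves, and rising-crossing horizons.
- **`fixtures`** — seeded synthetic-data generators (spatial communities
  with a known similarity-decay scale, Yule trees, host-use tables from
  a known logistic law, replicate proficiency curves with a known
  horizon) so every estimator has a parameter-recovery test.
- **`io` / `cli`** — plain CSV/Newick/JSON readers and writers and the
  `ecohorizon` command-line tool.

## Worked example

How quickly does chaos turn a slightly mis-specified model useless? Run
the Ricker experiment with 1% uncertainty in the growth rate and 0.1% in
the initial population:

```bash
ecohorizon ricker-horizon --cv-r 0.01 --cv-n0 0.001 --reps 200 --seed 42
```

```json
{
  "crossing": "falls_below",
  "threshold": 0.5,
  "metric": "correlation",
  "unit": "generation",
  "horizon": {"is_infinite": false, "value": 6.630986423670309},
  "median_horizon": {"is_infinite": false, "value": 6.888706848262393},
  "band": [{"value": 0.0}, {"value": 10.934170788423192}],
  "n_replicates": 200,
  "n_infinite": 0,
  "seed": 42
}
```

The median replicate's windowed correlation with the true (chaotic)
trajectory drops below the 0.5 threshold **6.9 generations** ahead; the
mean proficiency curve crosses at 6.6. A 1% error in r buys you about
seven generations of useful forecast. With `--cv-r 0 --cv-n0 0` every
replicate equals the truth and the horizon is reported as `"inf"` — a
perfectly specified deterministic model never degrades.

The analytic cross-check for a chaotic map:

```bash
ecohorizon lyapunov --map logistic --param 3.6 --x0 0.3 --delta0 1e-5 --steps 60
```

reports `lambda = 0.213` and a predictability time `Tp = 43.3` steps:
with initial uncertainty 1e-5 and required precision 0.1, errors grow by
a factor e^lambda per step until they swamp the forecast.

Other entry points work the same way: `ecoevo-horizon` (abundance vs
total-biomass horizons under environmental uncertainty),
`spatial-horizon` (distance-decay of community similarity, km),
`phylo-horizon` (host-use AUC over phylogenetic distance, MYA — a
*rising* crossing, since relatives of known hosts are the hard cases),
`horizon-from-curve` (any proficiency curve stored as CSV), and
`fixtures` (synthetic input generators).

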