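# Methods

## Problem setting

The task is direct multi-step forecasting of one environmental channel
(soil temperature, °C) from a uniformly sampled multichannel greenhouse
sensor record (default cadence 20 minutes; channels: soil temperature,
air temperature, air humidity, soil moisture, light, soil conductivity,
carbon dioxide).  For a lookback window of T0 steps of target history
X = [x_1..x_T0] and covariate history Z, the model predicts the full
distribution of the next H target values C = [x_{T0+1}..x_{T0+H}] jointly
(H ∈ {1, 3, 6}, i.e. 20–120 minutes), not recursively — multi-step error
accumulation through fed-back predictions is avoided by construction.

## Preprocessing

* **Gap repair.** Missing cells are filled by linear interpolation between
  the nearest observed neighbours, y = y0 + (x − x0)(y1 − y0)/(x1 − x0);
  on the uniform grid this is pandas' linear interpolation.  Leading and
  trailing gaps take the nearest observed value (two neighbours don't
  exist there; the choice is ours).
* **Chronological split.** n_train = floor(0.70·n), n_val = ceil(0.15·n),
  n_test = the remainder.  This floor/ceil/remainder rule is the unique
  one reproducing the canonical 4036/866/865 partition of a 5767-point
  record at 70/15/15.
* **Scaling.** Min-max per channel, x' = (x − xmin)/(xmax − xmin), with
  statistics fitted **on the training block only** to keep validation and
  test information out of the transform.  The target channel's fitted
  range (xmax − xmin) is the normalization constant A used by the
  interval-width metrics.  (Whether scaling statistics should use the full
  series was genuinely open; train-only is the leakage-safe choice.)
* **Windowing.** Half-open, 0-based windows: sample i = history [i, i+T0),
  future [i+T0, i+T0+H); windows are built per partition so no sample
  straddles a partition boundary.

## The forecaster

Each block b receives the current residual of the target window, pooled by
its stack's kernel k (non-overlapping max pooling, ceil-padded so a ragged
tail is kept), concatenated with the *unpooled, flattened* covariate
history (covariates condition the prediction but are never backcast).  A
two-hidden-layer ReLU MLP of width `mlp_units` emits

* a **backcast** at full resolution T0, subtracted from the next block's
  input (each block models what its predecessors missed), and
* **forecast knots** — max(ceil(H/d), 1) values per output channel for
  stack downsampling factor d — up-sampled to H by linear interpolation
  with knots at equally spaced positions across [0, H−1] and endpoints
  pinned.  With d = 1 the interpolation is the identity; with d ≥ H a
  single knot yields a constant forecast.

The model forecast is the sum of all block forecasts.  Defaults: 3 stacks
(coarse → fine: pooling kernels (4, 2, 1), downsampling (4, 2, 1)), 1
block per stack, width 128, lookback 12.  MLP depth (2 hidden layers), the
ceil-padding of pooling, the knot-count formula ceil(H/d), and linear (as
opposed to, say, cubic) interpolation are this package's choices where the
architecture family leaves them open; each is pinned by a structural test.

**Probabilistic head.**  The Gaussian variant carries two output channels
per step through the same knot machinery, summed across blocks:
μ = w·h + b and σ = softplus(w·h + b) + 10⁻⁶ (the floor prevents
degenerate likelihoods; softplus is read as the natural-log form
ln(1 + eˣ)).  Training minimizes the mean per-step Gaussian NLL
½ln(2πσ²) + (c − μ)²/2σ².  Prediction intervals at confidence level
1 − α (default 0.90) take the empirical α/2, 0.5 and 1 − α/2 quantiles of
`n_samples` Monte-Carlo draws per step (default 500; the calibration tests
use 10 000); draws are independent across steps, which is sufficient for
per-step quantiles.  The interval median is the reported point forecast.

**Training.**  Adam (lr 10⁻³), batch size 32, at most 500 epochs, early
stopping when validation loss has not improved for `patience` = 50
consecutive epochs, best-validation weights restored.  The point
forecaster trains on MAE, matching the point objective of the
hyperparameter search.  All weights, shuffling and MC draws are seeded;
runs are bit-reproducible.  The networks run on a small in-repo
reverse-mode autodiff tape over float64 numpy, single-threaded.

**Comparison interval constructors.**  Error fitting: a Gaussian-kernel
density (Silverman bandwidth) is fitted per horizon step to validation
residuals and its α/2 / 1−α/2 quantiles (numeric CDF inversion, no
sampling) are added to the point forecast.  Bootstrap: the same quantiles
of 2 000 seeded resamples of the residual pool.  Quantile variant: three
pinball-loss heads at α/2, 0.5, 1−α/2, sorted at prediction time to
enforce ordering.  Residual pools are kept per horizon step because
multi-step errors grow with the step.

## Feature selection

Channels at lag 1 ("previous time period" values) form the feature table;
a gradient-boosted tree regressor with default settings (LightGBM with
gain importances by default; XGBoost available) ranks them by normalized
split gain.  Backward elimination then walks prefixes of that *fixed*
ranking from all features down to one, refitting on the chronological head
and scoring RMSE on the tail (val fraction 0.2); the minimum-RMSE subset
wins, ties to the smaller subset.  Re-ranking per round and multi-lag
expansions are deliberately out of scope.  A known limitation: when the
validation block is small, RMSE differences between adjacent subset sizes
can sit below sampling noise, and the min-RMSE rule then occasionally
keeps a spurious feature; the recovery test uses a ~300-point validation
block, where subset differences are resolved.

## Hyperparameter search (SMPSO)

The integer search box is: blocks per stack [1, 5], MLP width [100, 500],
pooling kernel [2, 5], downsampling factor [1, 5], lookback [5, 24]; one
vector is shared across stacks.  Objectives are validation MAE (of the
interval median) and validation CWC of the 90% interval, both minimized,
in scaled units (A = 1).  The swarm update is

v ← χ·(w·v + c1·r1·(pbest − x) + c2·r2·(leader − x)),  w = 0.1,
c1, c2 ~ U(1.5, 2.5),  χ = 2/|2 − φ − √(φ² − 4φ)| for φ = c1 + c2 > 4
else 1,

with velocities clamped to ±(upper − lower)/2 per dimension and position
clamping that reverses the velocity sign at a bound.  15% of the swarm
receives polynomial mutation (η = 20) each iteration.  The external
archive (capacity 50) keeps mutually nondominated entries, prunes by
NSGA-II crowding distance (boundary entries never pruned), and supplies
leaders by binary tournament on crowding distance.  Positions decode by
round-half-up with clamping; evaluations are memoized by decoded key, and
failed trainings become sentinel objectives that never enter the archive.
Defaults: swarm 20, 25 iterations — desk scale.  The final configuration
is the knee point: min-max normalize archived objectives and take the
entry nearest the ideal (0, 0), ties to lower CWC (how a single solution
is picked from a Pareto set is a convention of this package).  Inside the
pipeline the search runs once at the largest requested horizon and the
winner is reused for the smaller horizons.

## Synthetic data generator

Each channel is mean + diurnal sinusoid + AR(1) noise
(e_t = ρ·e_{t−1} + sd·w_t, stationary start), and soil temperature
additionally receives β·(air_temperature(t − ℓ) − mean_air) with defaults
β = 0.35, ℓ = 6 steps (2 h) — the minimal structure exhibiting the
phenomena that motivate the method: diurnal cycles, cross-channel
coupling with a time lag, autocorrelated noise, and missing records
(injected uniformly, default rates 0–0.5%).  Default scale is ~80 days at
20-minute cadence (5760 points), matching a spring-season deployment; the
channel means/amplitudes are set to plausible greenhouse values (air
24 ± 6 °C peaking mid-afternoon, humidity in antiphase, soil 25 °C damped
and delayed).  Every channel draws from an RNG stream keyed by
(seed, channel name), so adding channels never perturbs existing ones.

Because all stochastic terms are AR(1), the conditional law of the target
h steps ahead given the history is Gaussian with mean
det(t0+h) + ρ^h·(x_{t0} − det(t0)) and sd = noise_sd·√(Σ_{k<h} ρ^{2k}),
where det(·) includes the observed lagged air deviation (requiring
ℓ ≥ h).  This closed form is the oracle for the sigma-recovery and
calibration tests.

**What the generator does not emulate** — regime changes (ventilation
events, irrigation spikes), heteroscedastic sensor noise, weather fronts,
long-memory trends, correlated missingness.  Passing tests therefore
demonstrate correctness and calibration of the machinery under a
well-specified data law, not field performance on real greenhouse data.

## Evaluation metrics

RMSE, MAE, MAPE (in %) for point forecasts; PICP (closed-interval
membership — boundary hits count as covered), PINAW, PINRW (normalized by
the target's training range A) and CWC = PINAW·(1 + γ·e^{−η(PICP−μ)}),
γ = 1[PICP < μ], μ = 0.80, η = 1 for intervals.  Multi-step evaluation
pools all horizon steps of all windows into one set (a per-step breakdown
is emitted as diagnostics).  All metrics are verified against independent
loop-based oracles to 10⁻¹².

## Problem sizes used by the test suite

The statistical suites run at deliberately modest sizes chosen so that
each property is resolvable with margin: sigma recovery uses 40-day
records over 10 seeds; interval calibration 70-day records (≈5 000
points) over 5 seeds with 10 000 MC draws; the optimizer exactness checks
use enumerable integer toys (21 and 121 candidates); the end-to-end smoke
run uses 5-day records with a swarm of 8 for 5 iterations.

## Known limitations

* σ is trained per step under an independence assumption across steps;
  joint trajectory sampling (and hence path-dependent quantities like the
  probability of a 2-hour excursion) is out of scope.
* MAPE is undefined near zero observations; the implementation refuses
  targets below 10⁻⁸ in magnitude — evaluate in original units, not
  scaled ones.
* Backward elimination inherits the variance of its validation RMSE
  estimates (see above); with few validation points prefer the ranking
  itself over the exact subset boundary.
* The swarm search shares one configuration across stacks and across
  horizons; per-stack and per-horizon searches would enlarge the space
  beyond desk scale.
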