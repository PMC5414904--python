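# Methods

This note documents the statistical models, the synthetic-data generator,
the numerical choices, and the known limitations of `surveygrid`.

## Data model

The unit of observation is a survey cluster: a georeferenced primary
sampling unit with `m` respondents of whom `k` are positive for the
indicator, summarised as the proportion `y = k/m`. Cluster coordinates are
*reported* coordinates: to protect respondent confidentiality the release
process displaces each cluster by a random offset of up to 2 km (urban
strata), 5 km (rural), with 1% of rural clusters allowed up to 10 km. All
analysis therefore operates on displaced coordinates; true coordinates
exist only inside the synthetic generator, for evaluation.

Covariates are single-band rasters on a common planar metric grid
(default 1 km cells, row 0 at the top, pixel-centre registration, NaN for
missing). Heterogeneous sources are harmonized with `resample_to_grid`
(nearest / bilinear / mean-aggregate). Geographic (lon/lat) inputs are out
of scope: they must be projected to planar metres first, which keeps the
core free of CRS machinery.

## Displacement-aware covariate extraction

Because the reported point may be anywhere within the displacement cap,
covariates are not read at the point but averaged over a buffer whose
radius matches the cap of the stratum: 2 km urban, 5 km rural (the 1%
far-rural clusters keep the 5 km buffer — their identity is unknown to an
analyst of real releases, so a larger buffer cannot be targeted at them).
Buffer membership is by cell-centre inclusion; an empty buffer falls back
to the nearest non-missing cell; a cluster with no usable value in some
layer is dropped and logged. For nonlinear models, `buffer_monte_carlo`
instead draws uniform points in the same disc and reads nearest cells,
either averaged per cluster or kept as replicate rows. Design-matrix
columns are z-scored, and the scaling is stored for later grid prediction;
numerically constant columns are centred but not scaled.

## Covariate selection

1. **VIF filter.** `VIF_j = 1/(1 − R²_j)` from regressing column *j* on
   the remaining columns plus an intercept. Filtering is iterative-greedy:
   the largest-VIF column is removed and VIFs recomputed until all are
   below the threshold (default 3; ties broken by column order; exact
   collinearity reported as +∞). One-shot filtering over-removes under
   shared collinearity, which is why recomputation matters.
2. **Jackknife sensitivity.** The baseline score is the mean held-out
   pseudo-R² of an OLS scorer over ten random 70/30 splits. Each covariate
   is left out in turn on the same splits; the best-scoring deletion is
   accepted while its score stays within a tolerance (0.005 in explained
   variance) of the full-set baseline, then the search repeats. This prunes
   covariates whose deletion costs nothing (pure-noise columns) while any
   informative covariate's deletion drops the score past the tolerance and
   stops the search; the selected set therefore never scores more than the
   tolerance below the full set. Covariate-wise (not cluster-wise)
   deletion is implemented, matching the selection-of-covariates purpose.

## Spatial Gaussian-process model

`y(s) = X(s)'β + v(s) + e(s)` with `v` a zero-mean stationary Gaussian
process with Matérn ν = 1 covariance `σ_v² (κd) K₁(κd)`, `κ = √8/range`
(so correlation ≈ 0.14 at the practical range), and `e ~ N(0, σ_e²)`.
ν = 1 corresponds to the SPDE operator power α = 2 in two dimensions, the
standard default for this model class; ν is not reliably estimable and is
fixed. The covariance is handled densely — no mesh or sparse
approximation — because cluster counts up to a few thousand are well
within dense-Cholesky reach; the SPDE is treated as the definition of the
field, not as a numerical method.

* **Likelihood.** Gaussian on cluster proportions, matching the
  MSE-centric validation under which the models are compared. A binomial
  likelihood would weight clusters by size; with roughly constant `m` per
  survey the Gaussian treatment loses little and keeps every diagnostic on
  the proportion scale.
* **Estimation.** Empirical Bayes: (σ_v², range, σ_e²) maximize the
  profile log marginal likelihood (β replaced by its GLS solution at each
  candidate), optimized by bounded L-BFGS on log-parameters from several
  data-driven starts (scales set by the OLS residual variance and the
  coordinate span). A 1e-10 diagonal jitter stabilizes the Cholesky.
* **Prediction.** Conditional Gaussian mean and standard deviation at new
  sites; the default sd is that of the latent smooth surface (matching
  smooth uncertainty maps), with the nugget addable by flag. Reported
  means are clamped to [0, 1]. The predictive sd omits hyperparameter and
  β uncertainty — it is a plug-in quantity, not a full posterior.

## Feed-forward network

One hidden layer; every node computes the weighted sum of its inputs plus
a bias and applies the logistic activation, so the output lies in (0, 1).
Training is full-batch gradient descent with momentum on mean squared
error; weights start Uniform(−0.5, 0.5). Hidden size and learning rate are
tuned by repeated random 70/30 sub-sampling (default ten repeats) within
the training data; the chosen configuration is retrained over several
restarts on a fixed 70/30 split and the restart with the best validation
MSE wins. Non-finite losses mark a diverged restart, which is logged and
skipped; only if every restart diverges does fitting fail. Predictive
uncertainty comes from an ensemble of independently seeded refits (sd
across members; an ensemble of one reports sd 0 with a warning).

## Validation

Random splits are 70/30 (train/test) repeated ten times by default, or
60/20/20 (train/valid/test) above a configurable cluster-count threshold
(default 2000), the scheme used for large surveys. Metrics on the held-out
set:

* `MSE`, `RMSE = √MSE`, `MAE`;
* pseudo-R² `exp_var = 1 − MSE/var(obs)` with **population**
  (divide-by-n) variance, so the trivial mean model's in-sample MSE equals
  `var(obs)` and its pseudo-R² is exactly 0 — this reproduces the
  arithmetic of standard comparison tables (e.g. 1 − 0.016/0.065 ≈ 0.75);
* bias `B = (mean(pred) − mean(obs))/σ_obs`. The published description of
  this statistic names its ingredients (σ_obs and the two means) and its
  purpose (a sign-preserving summary of systematic over/under-estimation)
  without a legible closed form; the form adopted here is the simplest one
  consistent with both. It is invariant under common shifts and positive
  scalings of observed and predicted values.

`var(obs)` is computed on the evaluation subset (not the full dataset),
which makes the trivial-model identity exact. Per-repeat reports are
aggregated by averaging MSE, MAE, var(obs) and bias, then recomputing RMSE
and pseudo-R² from the averages so the internal identities still hold.
Model selection: highest explained variance, ties broken by lower RMSE
then lower MAE.

## Synthetic worlds

The generator emulates the study conditions end to end:

* **Covariate fields** — standardized Gaussian random fields with
  approximately Gaussian autocorrelation `exp(−(d/ℓ)²)`, made by smoothing
  white noise (correlation lengths beyond half the grid extent switch to
  exact simulation on an anchor lattice with kriging interpolation, which
  preserves the low-frequency structure a moving-average filter loses);
  optional distance-to-random-points layers mimic accessibility and
  distance-to-feature covariates.
* **Latent surface** — `p(s) = g⁻¹(β₀ + Σ βᵢ covᵢ(s) + v(s))` with `v` a
  Matérn ν = 1 field simulated spectrally (Fourier filtering of white
  noise with the Matérn spectral density on a doubled periodic domain,
  normalized analytically to the target marginal variance). The logit link
  is the default (guarantees p ∈ (0,1)); the identity link with clamping
  is available to mirror the Gaussian treatment of proportions.
* **Clusters** — true locations uniform over non-missing cells, stratum
  from an urban mask (by default the top quartile of a designated
  urbanization covariate, standing in for census-bureau urban/rural
  status), positives Binomial(m, p) at the cell's true proportion.
* **Displacement** — uniform angle and Uniform[0, L] radius with L the
  stratum cap; a simple random 1% of rural clusters (count rounded to the
  nearest integer) is flagged and allowed 10 km. The release procedure
  specifies only the caps, not the within-cap distance law; the uniform
  radius is the simplest cap-respecting rule, and tests assert only the
  caps, the flagged fraction, and the mean L/2 implied by this choice.

The default demo is a 60×60 km country at 1 km resolution, four random
fields plus one distance field (correlation length 8 km), coefficients
(−0.3, 0.8, −0.5, 0.4, 0, 0.3) on the logit scale, spatial residual
variance 0.3 with 15 km range, 400 clusters of 25 respondents — cluster
counts, survey sizes and signal strengths typical of a national household
survey round. What the synthetic worlds do *not* emulate: multistage
sampling weights, within-cluster covariate heterogeneity at sub-cell
scale, non-stationary covariate effects, and measurement error in the
covariate rasters themselves. Passing tests therefore demonstrate
correctness of the machinery and recoverability under the stated model,
not mapping accuracy on real surveys, which varies widely by country and
indicator.

## Pipeline and reproducibility

`run_pipeline` executes simulate → extract → select → fit → validate →
predict → report, validating each stage's inputs against the type
invariants before running (grid geometry agreement, count bounds,
displacement caps). Every stage derives its RNG seed as
`crc32(f"{master_seed}:{stage}") mod 2³¹` — a pure function of the master
seed and the stage name — so reruns are bit-reproducible and changing one
stage leaves earlier outputs untouched. The run manifest records the
config, the derived seeds and the package version, and suffices to
re-execute the run. The CLI (`surveygrid simulate|extract|select|
validate|fit|predict|report|run`) is a thin wrapper that executes the
stage prefix ending at the named stage.

## Numerical choices and degenerate inputs

* Matérn covariance at d = 0 is set to σ_v² exactly (the `x K₁(x) → 1`
  limit); Bessel underflow at huge distances is mapped to 0.
* GP fitting requires ≥ 10 clusters; the ANN ≥ 30 rows; VIF requires more
  rows than columns + 1.
* Zero observed variance in a validation set flags pseudo-R² and bias as
  NaN sentinels rather than raising.
* A 1×1 grid yields a single-draw field; an empty cluster list displaces
  to an empty list; a single covariate always passes the VIF filter.
* Fitted-model files record coefficients, hyperparameters and scalings
  with a format version; training-state matrices are not serialized
  because the manifest makes the fit exactly reproducible by rerun.

## Limitations

* Hyperparameter and coefficient uncertainty are not propagated into
  predictive standard deviations (plug-in empirical Bayes).
* The Gaussian likelihood ignores binomial sampling variation differences
  between clusters of different sizes.
* Dense covariance algebra scales as O(n³); beyond a few thousand
  clusters a sparse or low-rank method would be needed.
* No reprojection: all inputs must share one planar metric grid.
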