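# Methods

## Model

Observed age-standardized rates `y_it` (deaths per 100,000; area `i = 1..S`,
year `t = 1..T`) are modelled as log-normal: `z_it = ln y_it` is Gaussian
with mean

```
mu_z_it = beta_0 + sum_m (beta_m + b_im) X_itm + u_i + v_i + phi_t + delta_it
```

and homoscedastic variance `sigma_z^2`. The printed notation of log-normal
regressions sometimes indexes the observation variance by cell; here a
single `sigma_z^2` is used, matching the description of a single log-scale
standard deviation. A heteroscedastic option is deliberately out of scope.

Components:

* **Covariate effects.** `X_itm` are risk factors, standardized to mean 0 /
  sd 1 over observed cells before fitting (the standardization record is
  attached to the results so effects can be mapped back to native units).
  `beta_m` is the global association; `b_im ~ N(0, tau_bm^2)` are
  exchangeable area deviations, giving each area its own time-constant
  coefficient `beta_m + b_im`. This realizes per-country association maps;
  a time-varying coefficient is out of scope.
* **Spatial effects.** `u` follows the intrinsic CAR (Besag) prior on the
  queen-contiguity graph, precision `Q_s / tau_u^2` with `Q_s = D − A`;
  `v ~ N(0, tau_v^2 I)` is exchangeable. Families: `iid` (only v), `besag`
  (only u), `bym` (both — the classical convolution).
* **Temporal effects.** `phi` is exchangeable or a random walk of order 1
  or 2 (`Q_t = D'D` for the order-k difference operator `D`).
* **Space-time interaction.** `delta` has precision structure
  `Q_delta / tau_d^2` with `Q_delta` one of the four Kronecker forms over
  the area-major interaction vector: I = `I⊗I`, II = `I⊗Q_t`,
  III = `Q_s⊗I`, IV = `Q_s⊗Q_t`. The structured factors always come from
  the contiguity graph's ICAR and the temporal family's walk order, so all
  3×3×4 = 36 structure combinations are well defined; combinations that
  collapse onto a simpler type (II or IV with an exchangeable temporal
  family) warn rather than fail, keeping the candidate grid at 36.

Rank deficiencies: ICAR = number of graph components (one sum-to-zero
constraint per component); RW1 = 1 (constant); RW2 = 2 (constant + linear);
interaction IV = `S·T − (S − d_s)(T − d_t)` by the Kronecker rank rule.
Every structure carries an orthonormal null-space basis used as its
constraint basis.

### Scaling of intrinsic structures

Raw intrinsic precision structures give the variance parameter a
*conditional* meaning whose marginal consequence varies enormously with
size: an unscaled RW2 over 20 points has smallest positive eigenvalue of
order 1e-5, so a nominal variance of 0.05 yields marginal swings of several
log units. Both the generator and the sampler therefore rescale each
ICAR/RW structure by its generalized variance — the geometric mean of the
marginal variances under the structure's pseudo-inverse (the `scale.model`
convention of modern disease mapping) — so a variance parameter of `v`
produces draws with typical marginal variance `v` regardless of graph or
series length. Interaction factors are scaled before the Kronecker product.
The unscaled constructors remain the public primitives (ranks and
constraints are scale-invariant); `scale_structure` exposes the rescaling.

## Priors

Supplementary prior specifications were not available; the package uses
weakly-informative conjugate defaults, all exposed on `HyperPriors`:
inverse-gamma(shape 1, rate 0.01) on every variance (including
`sigma_z^2`), Normal(0, 100²) on the intercept, Normal(0, 10²) on each
global coefficient.

## Fitting

A systematic-scan Gibbs sampler with conjugate full conditionals. Design
points:

* **Eigenbasis updates.** Missing outcome cells are imputed from their
  Gaussian full conditional each sweep, so every structured block sees a
  homoscedastic residual and its full conditional diagonalizes in the
  eigenbasis of its structure matrix: spatial and temporal blocks are S×S /
  T×T eigen-solves done once, and each interaction type reduces to
  elementwise operations after rotating the residual by the factor
  eigenvectors (types II/III are block-diagonal; type IV diagonalizes in
  the Kronecker eigenbasis). One sweep costs O(S²T + ST²).
* **Constraints.** After each update a structured block is re-centred
  against its constraint basis (per-component sum-to-zero for ICAR;
  constant, and for RW2 also linear, for the walk; null coordinates zeroed
  in the eigenbasis for interactions). Stored draws are orthogonal to their
  constraint bases to ≤1e-8. A consequence of detrending RW2 is that a
  global linear time trend is not separately identified; the generator uses
  the same convention, so simulation and inference agree.
* **Blocked coefficient update.** `beta_m` and its deviations `b_im` mix
  poorly under one-at-a-time scans (their sum is well identified, the split
  is not). The sampler draws `beta_m` with `b` marginalized out — each
  area's projection `c_i/s_i` is `N(beta_m + b_im, sigma^2/s_i)`, hence
  marginally `N(beta_m, sigma^2/s_i + tau_bm^2)` — then `b | beta`. This
  raised the coefficient effective sample size from ~6% to ~25% of draws
  and makes nominal-coverage checks pass at moderate chain lengths.
* **Variances** are inverse-gamma updates with shape increments of half the
  structure rank (not half the dimension) for intrinsic blocks.
* **Determinism.** Each chain's generator is seeded
  `default_rng([seed, chain])`; identical settings give bit-identical
  draws.
* Defaults: 2 chains × 5,000 iterations, 2,000 burn-in, thinning 1. The
  experiments below use shorter chains (stated per experiment) chosen so
  effective sample sizes stay in the hundreds.

Missing covariate cells are forward-filled within area, then area-mean
filled, with an imputation log attached to the fit metadata. Missing
outcome cells are treated as unknowns (Gibbs imputation).

## Model selection

Step one screens candidate risk factors by Pearson correlation (Spearman
exposed as an option) with `z` over pooled observed area-year cells —
pooling matches the likelihood's granularity. Pairs with pairwise `|r|`
above 0.7 ("highly correlated"; threshold configurable) are resolved
greedily from the most collinear pair downward, dropping the member with
the weaker outcome correlation. Constant covariates are dropped with a
warning.

Step two fits every candidate structure and reports: WAIC (primary
criterion; lppd via log-sum-exp, penalty = summed draw-wise variance of the
pointwise log likelihood), DIC (plug-in deviance at the posterior means of
`mu_z` and `sigma_z^2` — a focused-DIC simplification; when only a
log-likelihood array is available the half-variance form `var(D)/2` is used
instead), LPML from harmonic-mean CPOs computed in log space (unstable
cells flagged and excluded with a warning), bias and RMSE of posterior-mean
arithmetic-scale fitted rates against observed rates, their Pearson
correlation, and wall time. Ties break by DIC, then maximal LPML, then
RMSE. Per-candidate MCMC seeds are derived from the master seed and the
structure label so results are independent of evaluation order. A failed
fit becomes a `failed` row, not a fatal error. The pipeline's exported
comparison table omits wall time so reruns with one seed are byte-identical
(timings live in the run manifest).

## Hotspots

The threshold `q_t` is the median of the *observed* rates across areas
within year `t` (the data define the norm, not the fitted surface).
Exceedance is evaluated on the log scale — `p_it = P(mu_z_it > ln q_t)`,
i.e. the geometric-mean rate against `q_t`; the arithmetic-mean reading
would simply shift both sides by `sigma_z^2/2`. An area-year is a hotspot
iff `p_it > 1 − alpha` strictly (ties at the cutoff are not hotspots),
`alpha = 0.05` by default.

## Synthetic data

The generator emulates the study's shape — ~183 areas in 5 regions, 20
yearly time points, log-normal rates around 10–13 per 100,000 — while
remaining fully controlled:

* Graphs: a near-square lattice with queen contiguity, or Voronoi cells of
  seeded uniform points (`random_planar`), both with matching GeoJSON
  polygons so the file-format paths are exercised end to end.
* Covariates: i.i.d. standard Normal per area-year (10 by default, named
  for the study's retained risk factors), optionally given a covariate
  correlation matrix, then standardized *exactly* to mean 0 / sd 1 so
  stated effect sizes live on the scale the model fits on.
* Effects: drawn from the (scaled) intrinsic Gaussians orthogonal to their
  constraint bases; noise `N(0, sigma_z^2)`.
* Defaults: intercept `ln 12`; variances 0.10 (spatial), 0.05
  (unstructured), 0.05 (temporal), 0.02 (interaction), 0.01 (coefficient
  deviations); `sigma_z^2 = 0.05`; effect sizes ±0.05 alternating. These
  keep the grand-mean rate near the low teens at the study size.
* The truth record stores every component including the noise, so `z` is
  reconstructible exactly; the same seed regenerates everything
  bit-identically.
* The hotspot scenario multiplies chosen areas' true rates by a factor
  (default 3) in all years over a near-flat baseline: between-area sds
  (~0.07 in log units) are kept below the posterior resolution
  `sqrt(sigma_z^2 / T)`-shrinkage scale, so the elevated set is the unique
  set of areas genuinely above the yearly medians and false positives
  measure classification error, not baseline heterogeneity.

What the generator does **not** emulate: reporting biases and
underregistration, age-standardization arithmetic (rates arrive
standardized), realistic covariate marginals/temporal persistence, and
population weights. Passing recovery and calibration tests therefore shows
the machinery is correct under the model's own assumptions, not that the
model is adequate for any particular real surveillance panel.

## Experiment sizes

The shipped checks use deliberately modest problem sizes chosen to give
stable verdicts: coefficient recovery at S=30, T=10 with BYM+RW2+type I,
beta = (0.5, −0.3), 20 replicates, 2 chains × 2,000 iterations (burn-in
800); structure selection at S=20, T=8 comparing the generating type-I
structure to a type-IV rival over 20 replicates; hotspot calibration with 5
of 50 areas elevated ×3 over 10 seeds; sampler-vs-closed-form agreement on
a 10×5 panel with the variance fixed, judged in Monte-Carlo standard errors
with a conservative effective-sample-size allowance of n/10.

## Known limitations

* One observation variance for all cells; no offsets or population weights
  in the likelihood.
* Exchangeable (not spatially structured) coefficient deviations.
* DIC's plug-in uses posterior means of `(mu_z, sigma_z^2)` only.
* Harmonic-mean CPO estimators are noisy for influential cells; LPML is a
  comparison device here, not a precise cross-validation score.
* The exceedance rule is unadjusted for multiplicity across area-years.
* Percent effects are reported per standardized unit; native-unit effects
  require the attached standardization record.
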