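# Methods

## Model

`shashnorm` fits probabilistic normative models: a per-subject likelihood
`y_n ~ L(theta_i(x_n))` whose parameters are regressions on covariates,
with a site random effect in the mean.  Four likelihood variants share the
mean/scale structure and differ in how skew and tail weight are handled:

| variant | likelihood | skew/tail parameters |
|---|---|---|
| `N`   | Gaussian | none |
| `So1` | SHASH with location/scale applied after the transform | constants |
| `Sb1` | moment-standardised SHASH (`SHASH_b`) | constants |
| `Sb2` | `SHASH_b` | linear regressions on the design matrix |

The `SHASH_b` family is the package's centre of gravity.  In the plain
location/scale family the mean depends on the skew parameter and the
variance on the tail parameter, which both hampers interpretation and
induces strong posterior correlations that slow gradient-based samplers.
Standardising the base law by its analytic mean `m(1)` and standard
deviation `eta` before applying `mu` and `sigma` makes `mu` exactly the
distribution mean and `sigma` exactly its standard deviation for every
shape; the two families remain isomorphic (each `Sb` member is an `So`
member under an affine re-mapping, which the tests verify).

Assumptions worth keeping in mind:

* batch (site) effects enter the **mean only**, as an exchangeable random
  intercept `tau_s = mu_tau + sigma_tau * nu_s`, `nu_s ~ N(0,1)`
  (non-centred, which is what hierarchical NUTS wants).  Site effects in
  the scale or shape are deliberately not modelled; skew and kurtosis are
  central moments and are unaffected by per-site shifts.
* sex is a covariate, not a batch dimension.
* the scale is heteroskedastic through `softplus` of a linear predictor,
  so variance can vary smoothly with age/sex but is shared across sites.

## Design matrix

`[5 cubic B-spline bases of age, raw age, sex]`, seven columns.  The
spline is clamped with a single interior knot at the midpoint of the
training age range, giving exactly five basis functions that sum to one;
the raw-age column preserves a global linear trend under the spline's
limited support.  Knot positions are derived from the training ages and
persisted with the model; prediction-time ages outside the span are
clamped with a logged warning.  One defensible alternative (more distinct
knots, hence more basis functions) would change column count; the 5+2
layout is fixed as this package's contract.

## Priors

Standardised-response scale assumed (the preprocessing standardises each
response on the training split).  Locations/scales, with the second
argument of `N` a variance:

* `w_mu ~ N(0, I)`, `mu_tau ~ N(0,1)`, `sigma_tau ~ half-normal(1)`,
  `nu_s ~ N(0,1)`
* `w_sigma ~ N(0, I)`, `tau_sigma ~ N(1,1)` (softplus is near identity
  above zero, so the implied scale sits near 1 on standardised data)
* `Sb1`/`So1`: `eps ~ N(0,1)`, `delta_raw ~ N(1,1)`
* `Sb2`: `w_eps ~ N(0, 0.2 I)`, `tau_eps ~ N(0, 0.2)`,
  `w_delta ~ N(0, 0.2 I)`, `tau_delta ~ N(1, 0.3)`

The tail parameter is mapped through `delta_link(x) = softplus(10x)/10 +
0.3`.  The 0.3 floor keeps the sampler away from the region where the
standardising moments explode (the variance of the base law grows
enormously as `delta -> 0`, driven by the Bessel factor in the moment
formula); the 10x/10 scaling makes the link nearly linear on (0, 1).  The
floor is a *sampling* device: the raw density functions accept any
`delta > 0`.

## Numerical choices

* **Log-space density.**  The log-density is computed as
  `log delta + log cosh(S) - log sqrt(1+x^2) - log sqrt(2 pi) - xi^2/2`
  with a stable `log cosh`; the linear-space `cosh` factor would overflow
  long before |x| reaches the supported 1e6.
* **Scaled Bessel evaluation.**  `P(q)` uses exponentially scaled
  `K_v(1/4)` (`kve`), which absorbs the `e^{1/4}` prefactor exactly and
  avoids overflow of the raw Bessel values at the orders reached by the
  fourth moment near the delta floor.
* **Shape-derivatives by central differences.**  Gradients of the
  log-joint are analytic except for `d m(1) / d(eps, delta)` and
  `d eta / d(eps, delta)`, which would require the derivative of `K_v`
  with respect to its order; these two scalar maps are differentiated by
  central differences (relative step 1e-5).  Tests compare the assembled
  gradient against full numerical differentiation.
* **Quadrature oracles integrate the whole line.**  Truncated windows
  (even ±12 standard deviations) lose ~4e-4 of mass for the heaviest
  supported tails (`delta = 0.3`); the test oracles therefore use adaptive
  quadrature with infinite limits split at the mean, which is accurate to
  machine precision across the supported shape grid.
* **Links and inverses.**  `softplus` via `logaddexp` (safe to |x|~1e3);
  `delta_link_inv` is exact above the floor but, within float epsilon of
  0.3 (unconstrained values below about -2), the forward map is absorbed
  and the inverse is only defined to that absorption.
* **Degenerate inputs.** `delta <= 0`, `sigma <= 0`, zero-variance
  z-scores, single-chain R-hat, unseen-at-fit batch labels and zero-sd
  standardisation columns all raise descriptive errors rather than
  propagating NaNs.  Sites unseen at *prediction* time receive the
  group-mean offset.

## Inference

The sampler is an in-package No-U-Turn sampler: recursive doubling with a
slice variable, maximum tree depth 10, divergence threshold 1000 on the
energy error.  Warmup (the burn-in) adapts the step size by dual averaging
(target acceptance 0.85) and re-estimates the inverse mass at 50% and 80%
of warmup from the preceding warmup segment — a dense covariance estimate
when the segment is long enough, else diagonal.  The dense mass matters
here: the spline basis sums to one, so the spline weights, the group
intercept and the site offsets are only jointly identified, and the
resulting posterior correlations would otherwise force very small steps.
Initialisation is prior means plus jitter scaled per coordinate (weight
coordinates shrink with the RMS of their design column).  Runs with more
than 5% divergent post-warmup transitions raise rather than returning
silently biased draws.

Defaults follow the sampling protocol the package is built around: two
chains of 1500 iterations, first 500 discarded, 1000 retained per chain.
Convergence is summarised by R-hat; the default is the rank-normalised
split-chain variant (computed by arviz), with the classic between/within
Gelman-Rubin ratio available via `method="classic"`.  1.05 and 1.1 are the
conventional warn/fail thresholds.  `rhat_trajectory` evaluates R-hat on
growing chain prefixes for convergence-versus-length plots.

MAP estimation maximises the same log-joint with L-BFGS on the
unconstrained scale (the links make it smooth and unbounded), best of
several jittered restarts.  MCMC z-scores are the per-draw scores averaged
over retained draws — with a degenerate posterior they reduce exactly to
the point-estimate score, and on synthetic fits they correlate > 0.99 with
MAP scores, which is why MAP is the default estimator for routine scoring.

## Synthetic cohorts

`simulate_cohort` draws ages uniformly on the configured range, sex as
Bernoulli, site offsets as `N(0, offset_scale^2)` (or pinned explicitly),
and responses exactly from the generative model at a stored truth, so
truth-scored z-scores are standard normal by construction and recovery/
coverage tests need no external data.  The default configuration — 5 sites
of 200 subjects, ages 20–80, offset sd 0.5 on the standardised scale, a
weak linear age trend and a sex effect in the mean — is chosen to be small
enough for interactive MCMC while leaving the shape parameters clearly
identified.  `simulate_nonlinear_skew_cohort` interpolates the shape
parameters linearly in age (for example skew +0.8 at the youngest age to
−0.8 at the oldest), emulating phenotypes whose conditional skew changes
sign across the lifespan; a constant-shape model fitted to such data
leaves opposite residual skew in the two age halves, which the
covariate-dependent-shape variant removes.

What the generator does **not** emulate: real phenotype marginals
(Freesurfer-like volumes), realistic per-site sample-size imbalance,
missingness, covariate measurement error, or site effects in scale/shape.
Passing tests therefore demonstrate internal consistency — the estimators
recover the processes they assume — not robustness to the full messiness
of real multi-site data.

## Evaluation

Deviation scores invert the generative transform,
`z = xi((y - mu)/sigma * eta + m(1))`, reducing to `(y - mu)/sigma` at the
Gaussian member.  Centile curves push the Gaussian levels {-3,...,3}
through the forward transform (the 0.1, 2.3, 15.9, 50, 84.1, 97.7, 99.9
percentiles); monotonicity in the level is guaranteed by monotonicity of
the transform.  Fit quality: skew and excess kurtosis (fourth standardised
moment minus 3) of the z-scores, both 0 under a correct fit; qq data as
paired theoretical/empirical quantiles (rendering left to the caller); and
per-site-pair |AUC − 0.5| with the rank (Mann-Whitney) statistic, midrank
ties — 0 means the model's scores carry no residual site signal.  The
moments report can be produced per cross-validation fold and averaged, or
on concatenated folds; per-fold averaging is the default in the CLI
workflow.

## Preprocessing

Responses are feature-wise standardised (mean/sd from the declared fit
split only, applied everywhere, inversion record stored with the model).
An optional log transform precedes standardisation for strictly positive,
severely skewed phenotypes; it is an explicit per-response modelling
choice, never auto-detected, and on its own does not remove
non-Gaussianity — it is complementary to the SHASH likelihood, not a
substitute.  Stratified k-fold splitting stratifies on site-by-sex cells
and drops cells with fewer than 10 subjects before splitting, so every
retained site appears in every training split.

## Problem sizes used in the checks

The automated checks run at desk scale, chosen so the full suite and the
reproduction script each complete comfortably on one CPU: convergence and
R-hat on 5 sites × 200 subjects with the full two-chain 1500/500 protocol;
site-effect removal on 3 sites × 300 with MAP scoring; interval-coverage
smoke on five replicates of 5 sites × 300 with shortened chains
(1000/400); misspecification contrast on a single site of 2000.  Analytic
anchors (normalisation, moments, standardisation identities, the
centile-percentile table) are checked by quadrature at tolerance 1e-6 or
exactly.

## Known limitations

* Shape parameters are weakly identified along an (eps, delta) ridge at
  moderate n; point estimates show mild ridge bias (both drawn upward
  together) that vanishes with n, and interval coverage is nominal only
  asymptotically.
* No variational inference, transfer learning to new sites, multi-
  dimensional batch effects, or batch effects in scale/shape.
* The sampler is NumPy-based and single-threaded; wall-clock cost grows
  linearly in subjects and roughly with tree depth, and `Sb2` costs a few
  times `Sb1` per draw (per-subject standardising moments).
* Model bundles store draws/points as binary arrays alongside the JSON
  manifest; they are runtime artefacts, not an interchange format.
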