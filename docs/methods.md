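# Methods

This note records the statistical models, numerical choices and design
decisions behind `phylospatial`, and what the simulation-based tests do
and do not demonstrate.

## Geometry

All distances are haversine great-circle distances on a sphere of radius
6371.0088 km (the IUGG mean Earth radius; overridable per call).
Longitudes are circular and wrapped into [−180, 180) on ingest;
ellipsoidal corrections (≤ ~0.5%) are irrelevant at the continental
scales of cross-cultural data and are out of scope. Coincident points are
legal: kernels handle them through the nugget, never through silent
coordinate jitter, and the inverse-distance weights use a 1 km distance
floor.

## Autocorrelation diagnostics

Moran's *I* uses the classical Cliff–Ord moments. The default variance is
the randomization (kurtosis-corrected) formula; the normality formula and
a Monte-Carlo permutation null (B = 999 by default, seeded; exhaustive
enumeration available for tiny n) are cross-checks. Analytic p-values are
two-sided — clustering and dispersion are both detectable. The default
weights are raw inverse great-circle distance without row
standardization, the common residual-diagnostic choice; k-nearest and
exponential-kernel schemes are provided, and the weights scheme is always
reported with the result because the statistic's scale depends on it.
Residual diagnostics standardize on Pearson residuals. The Mantel test
correlates strictly-lower-triangle entries and permutes rows and columns
of one matrix jointly, one-sided ("greater") by default; partial Mantel
is deliberately not offered.

## Covariance models

Spatial kernels: exponential `exp(−d/ρ)` and Matérn with half-integer
smoothness ν ∈ {0.5, 1.5, 2.5} (closed forms; ν = 0.5 reproduces the
exponential exactly, which is tested to machine precision). Parameters
are the marginal variance σ², the range ρ in km and the nugget τ².

Phylogenetic covariance is the Brownian-motion shared-path covariance
from a rooted tree with branch lengths, or, when only a hierarchical
classification is available, the fraction of shared nested levels
(counted from the coarsest level to the first mismatch) with unit
diagonal — the simplest monotone map from a classification to a valid
correlation matrix; the per-level increments are equal by default and the
choice is isolated in one function.

Combination rescales both components to unit diagonal first, so
`σ²_s K_s + σ²_p K_p + τ² I` has interpretable marginal variance
components; a non-negative weighted sum of PSD matrices stays PSD.

## The naive GLM

Logistic fits use damped-free IRLS with convergence at max |score| <
1e−8 or relative deviance change < 1e−10, Wald standard errors from the
inverse observed information, 95% intervals at the 1.959964 normal
quantile, odds ratios as exp(β), and AIC = 2k − 2ℓ. Quasi-separation is
detected as any |β| > 15 while the deviance still falls and raised as an
error naming the worst coefficient. The Gaussian family is the exact
least-squares solution; its AIC counts the error variance as a
parameter. Both Wald and likelihood-ratio tests are available since
published analyses rarely say which they used.

## The spatial GLMM

Model: `y_i ~ family(g⁻¹(x_iᵀβ + u_i))` with `u ~ MVN(0, Σ(θ))` and
`Σ = σ²_s K_s(ρ) + σ²_p K_p + τ² I`.

*Binomial family.* The marginal likelihood is approximated by a Laplace
expansion: `ℓ_L = log f(y|η̂) − ½ûᵀΣ⁻¹û − ½ log det(I + ΣW)` with `W`
the Bernoulli weights at the mode. The inner problem finds the *joint*
penalized mode of (β, u) by Newton iterations with step halving
(penalized IRLS), which profiles the fixed effects out of the outer
problem — the same device lme4 uses — so the outer quasi-Newton
(L-BFGS-B, finite differences, projected-gradient tolerance 1e−5, with a
Nelder-Mead restart on failure, all on the log scale of σ²_s, ρ, τ²,
σ²_p) works in at most four dimensions. Any variance parameter can be
pinned; fixing all of them at zero short-circuits to the exact GLM, which
is tested to 1e−6. Wald covariance for β is `(Xᵀ(W⁻¹+Σ)⁻¹X)⁻¹`, the
Laplace-approximate marginal information; uncertainty in θ is not
propagated (standard practice, and the main reason CI coverage sits near
0.93 rather than 0.95 in the recovery study).

Variance parameters are estimated by REML by default: the outer objective
additionally integrates the fixed effects out (a ½ log det(Xᵀ(W⁻¹+Σ)⁻¹X)
penalty, the same integration glmmTMB's REML performs). Plain ML
(`reml=False`) under-estimates the variance components when the data
carry only a handful of effectively independent regions, which makes the
Wald test on β anticonservative — on strongly confounded null worlds the
matched-replicate type-I error was 0.09 under ML and 0.07 under REML.
The *reported* log-likelihood and AIC are always the ML marginal
evaluated at the chosen θ̂, so model comparison against the naive GLM
stays on one scale.

*Gaussian family.* The marginal likelihood is available exactly — the
nugget is the residual variance and `y ~ N(Xβ, Σ)` — so the fit is
generalized least squares with the normal equations verified internally;
the Laplace machinery is not approximated here, it *is* the closed form.

Numerical guards: nugget floor 1e−6 (× var(y) for Gaussian outcomes),
Cholesky with escalating diagonal inflation on near-singular Σ, barrier
(+∞ objective) rather than crash at non-PSD proposals, and optimizer
bounds log ρ ∈ [0, log 20015]. AIC counts fixed effects plus *free*
variance parameters. ρ estimation is joint with σ² on the log scale; a
fixed-ρ profile grid is available for flat likelihoods. The Laplace
objective is invariant to row order (tested).

The spatial ML estimator has known finite-sample quirks that the tests
deliberately leave visible: on a minority of binary realizations the
likelihood prefers short-range/low-variance fields, and the Laplace
binary fit attenuates β̂ by roughly 10% at n = 300 — both are properties
of the method, not of this implementation (multiple starting points agree).

## Synthetic worlds

`build_world` is a pure function of (spec, seed); a single root
SeedSequence spawns independent streams for points, environment field,
environment noise, latent field and outcome, so components can be varied
independently. Points are uniform in a lon/lat box or clustered
(uniform parent points, Gaussian local-tangent jitter with a stated km
scale — adequate below ~500 km). The environment combines a
cos(latitude) gradient, a Gaussian random field and white noise in stated
variance shares (normalized, each component standardized), mimicking
smooth, latitudinally patterned covariates like humidity. The outcome is
Bernoulli(logit⁻¹(β₀ + β_env·env + u)) or Gaussian, with u drawn by
Cholesky from the kernel covariance. A degenerate single-class binary
outcome triggers one regeneration with the intercept recentred, then an
error.

Named presets define the study conditions:

* `iid_scenario` (n = 100): no spatial structure anywhere; the
  calibration baseline.
* `confounded_scenario` (n = 300): no true effect; six macro-regional
  clusters; covariate and latent-field ranges (3500 km) much longer than
  the cluster scale, latent variance 4. Concentrating the information
  into a handful of effectively independent regions is what drives the
  naive test's false-positive rate above 50%; with more, smaller
  clusters the inflation is milder (~3× nominal), and with *fewer*
  regions the variance parameters become so poorly identified that even
  the corrective model's error rate drifts above nominal — six regions
  is the window where the naive test fails badly while the spatial
  model stays calibrated.
* `recovery_scenario` (n = 300): simulate from the model itself with
  β_env = 0.8, σ²_s = 1, ρ = 1000 km and a mostly-noise covariate — a
  covariate sharing the field's structure would add spatial-confounding
  attenuation on top of estimator error, which is a different question.
* `tone_humidity_mimic` (n = 527): the structural mimic of a global
  binary-trait dataset — prevalence ≈ 0.42, six macro-regions, strong
  long-range field, no true effect; most replicates give a significant
  naive fit and residual Moran z ≫ 2.

What these worlds do *not* emulate: realistic language-family phylogenies
tied to the point process, anisotropy, coastlines/landmasses, covariate
measurement error, and diffusion dynamics. Passing tests therefore show
that the workflow behaves correctly *when spatial structure is the
confounder*, not that any particular real dataset is free of other
confounding.

## Verdicts and experiments

`compare_models` classifies the focal covariate at α = 0.05 (configurable)
into spatially_robust / explained_by_space / no_association /
space_revealed and reports ΔAIC = AIC_naive − AIC_spatial.
`fpr_experiment` re-seeds each replicate from a root seed (all seeds
reported), fits both models, and reports rejection rates with
Clopper-Pearson 95% intervals. Reports embed the config hash and seeds;
rerunning with the same inputs is byte-identical.

## Problem sizes used in the test suite

Calibration uses 500 i.i.d. replicates at n = 100; the
confounding/correction study 200 replicates at n = 250; parameter
recovery 100 replicates at n = 300; the acceptance script uses 400/100/80
replicates for the same three studies plus 20 mimic replicates at
n = 527. These sizes give binomial Monte-Carlo error of 1–3 percentage
points on the reported rates while keeping a full run in the minutes
range on one CPU.

## Known limitations

* Laplace (not quadrature or MCMC): adequate at these n, slightly
  attenuated for binary outcomes; dense linear algebra limits n to a few
  thousand.
* Wald inference on β ignores variance-parameter uncertainty.
* No SAR/CAR models, Conley errors, local Moran, Geary's C or partial
  Mantel; no ellipsoidal distances; no tree inference.
* The classification-based relatedness assumes equal information per
  nesting level.
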