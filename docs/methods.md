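# Methods

## Model

`trajmix` fits growth mixture models (GMMs) to irregular serial BMI data.
Subject *i* with observation ages *t<sub>i1</sub> … t<sub>im</sub>* (decimal
years, centered) and sweep indices *j<sub>i1</sub> … j<sub>im</sub>* belongs
to one of *K* latent classes. Conditional on class *k*,

  y<sub>i</sub> ~ MVN( X<sub>i</sub> β<sub>k</sub>,
  Z<sub>i</sub> Ψ<sub>k</sub> Z<sub>i</sub>′ + R<sub>ik</sub> )

with

- X<sub>i</sub>: polynomial design in centered age, degree 1–3 (default
  cubic). Centering defaults to the third measurement occasion (23.64 y for
  males, 26.00 y for females) for numerical stability.
- Z<sub>i</sub>: random intercept and slope columns. Quadratic and cubic
  growth terms carry no random effects (their variances are structurally
  zero); without that constraint cubic mixtures on 3–5 observations per
  subject are practically unestimable.
- Ψ<sub>k</sub>: random-effect covariance. Only the intercept variance may
  differ by class; the slope variance and intercept–slope covariance are
  shared across classes (a flag can fix the covariance at zero).
- R<sub>ik</sub>[a,b] = σ<sub>j<sub>a</sub>k</sub> σ<sub>j<sub>b</sub>k</sub>
  ρ<sub>k</sub><sup>|j<sub>a</sub>−j<sub>b</sub>|</sup>: residual SDs are
  sweep-specific (heteroskedastic over occasions) and optionally
  class-specific; residual correlation is AR(1) **on the sweep index**, the
  measurement occasion. The AR lag is occasion count, not age difference,
  because the residual SDs are themselves occasion-indexed; sweeps are
  roughly a decade apart so a first-order occasion structure is the natural
  discretisation.
- π<sub>k</sub>: mixing proportions.

Each subject contributes only their observed sweeps (rows/columns of the
covariance are subset); there is no imputation, i.e. standard
missing-at-random maximum likelihood.

Model fit is compared by BIC = −2·loglik + p·ln(n). Classification
sharpness is summarised by relative entropy
1 − Σ<sub>ik</sub>(−p<sub>ik</sub> ln p<sub>ik</sub>)/(n ln K); entropy is
reported but never used to choose K, since it is not a measure of fit.

## Estimation

EM with multi-start. The E-step is exact (log-space, log-sum-exp). The
M-step is an ECM sweep:

1. π<sub>k</sub> = mean of posteriors (closed form);
2. β<sub>k</sub> by posterior-weighted GLS at the current covariance
   (closed form);
3. covariance parameters by L-BFGS on unconstrained transforms (log for
   SDs and variances, atanh for ρ, the intercept–slope covariance raw) with
   an analytic gradient of the expected complete-data log-likelihood. The
   inner optimiser runs a capped number of iterations (default 12); the
   update is kept only if it does not decrease the EM objective, so the
   observed-data log-likelihood is non-decreasing (generalised EM).

Subjects are grouped by observed-sweep pattern so all linear algebra is
batched; a Cholesky failure inside the line search returns a large objective
value and the optimiser backtracks.

Initialisation: per-subject ridge-stabilised polynomial fits (ages rescaled
so the penalty acts on O(1) coefficients, intercept unpenalised) give
(intercept, slope) features; k-means on standardised features seeds start 1,
and further starts perturb the class intercepts with seeded Gaussian noise
(SD = 0.5 × pooled BMI SD). All starts get a short EM run (default 20
iterations); the best 10 by log-likelihood run to convergence (relative
log-likelihood change < 1e−6, max 500 iterations). Starts are discarded,
not fatal, when a class collapses (π<sub>k</sub> < 1/n or a residual SD
< 1e−4). Everything is deterministic given the seed.

Defaults follow common mixture-modelling practice (50 starts, best 10
completed); the test-suite and acceptance runs use fewer starts and smaller
samples, chosen so the full suite completes in well under half an hour on a
single core — the problem sizes used are stated in each test.

Ψ positive semi-definiteness is validated on user-supplied parameters; during
optimisation only the positive-definiteness of the marginal covariance V is
enforced (via Cholesky), matching how mainstream mixture software treats the
random-effect covariance.

## Class ordering and labels

Classes are relabelled after fitting so the fitted mean BMI at centered age 0
is ascending; class 1 is always the lowest trajectory. This removes label
switching between starts and seeds. Modal assignment breaks posterior ties
toward the lower class.

## Model selection

`fit_grid` fits K = 1…7 crossed with a cumulative ladder of covariance
structures: sweep-heteroskedastic residuals; + class-specific residuals;
+ AR(1); + class-specific intercept variance. `select` picks the BIC
minimum (default) or a BIC elbow (first K whose gain falls below 1% of the
initial gain — useful when BIC creeps downward without a clear minimum).
Plausibility of the chosen solution (class sizes, trajectory crossings) is
reported for human review, never automated: it is a judgement criterion.

## 3-step covariate analysis

The corrected class-membership regression is Vermunt's maximum-likelihood
3-step variant with modal assignment (the approach behind the R3STEP
option): the K×K error matrix Q[s,t] = P(assigned s | true t) is estimated
from the step-1 posteriors, then class membership is regressed on covariates
by maximising Σ<sub>i</sub> log Σ<sub>t</sub> P(C=t|x<sub>i</sub>;γ)·Q[W<sub>i</sub>,t]
with Q fixed. Standard errors come from the inverse observed information
(central-difference Hessian, step 1e−5); CIs are Wald on the log-odds scale
and exponentiated, hence asymmetric around the OR. The uncorrected
(Q = identity) regression is provided as the comparison baseline; with
imperfect classification its estimates are attenuated toward the null, which
is the motivation for the correction. The BCH weighted variant and one-step
(covariates-in-mixture) estimation are out of scope.

Q's columns are renormalised after flooring zero cells at 1e−12. Cohort is
dummy-coded with the earliest cohort as reference; the lowest class is the
outcome baseline.

## Synthetic data generator

The generator emulates three British birth cohorts measured at five target
ages each (1946 cohort: 11, 15, 26, 36, 43 y; 1958: 11, 16, 23, 33, 42 y;
1970: 10, 16, 26, 34, 42 y), with the later cohorts' adult sweeps flagged as
self-reported. Per subject: a latent class is drawn from a cohort-specific
simplex; a random intercept/slope pair from the class's Ψ; observation ages
are target ages plus uniform ±0.5 y jitter (exercising irregular-age
handling); residuals are Gaussian AR(1) over sweeps with sweep-specific SDs;
sweeps are independently retained with per-cohort probabilities chosen so
the share of subjects with ≥4 observations lands near 85% / 81% / 71%.

Cohort effects are induced through the class simplices (the class mix of
each cohort), not through an explicit logit model; the implied true odds
ratios are cross-product ratios of the simplices, computed analytically by
`implied_odds_ratios` for recovery tests. Class mixes in the default
scenario are the modal class shares of each cohort–sex stratum; the class
mean curves are cubics through anchor points chosen so each class behaves
like its archetype (lowest: normal range throughout; middle: high-normal to
mid-overweight; increasing: low-normal to upper overweight; highest: mild
overweight to obesity). **The curve coefficients are synthetic package
defaults, not estimates from any cohort.** Dispersion defaults: residual SD
rising 1.0→2.5 kg/m² over sweeps, ρ = 0.5, class intercept SDs
(1.2, 1.5, 1.8, 2.5), slope SD 0.06, intercept–slope correlation 0.2. Under
these defaults the relative entropy of the true posteriors is ≈ 0.55,
i.e. class overlap comparable to what real serial BMI data produce.

`default_scenario(n_classes=3)` provides a variant with the middle class
merged into the lowest (mix probabilities summed). The full four-class
structure deliberately leaves the middle and increasing classes overlapping
near the centering age, so resolving all four requires of the order of 10⁴
subjects; the three-class variant's classes are mutually well-resolved at a
few hundred subjects and is used for end-to-end demonstrations and the
acceptance run's odds-ratio pipeline.

What the generator does **not** emulate: non-Gaussian BMI skew, informative
(MNAR) dropout, secular drift within cohort, self-report bias (available as
an option, default 0), and measurement-batch effects. Passing tests
therefore demonstrate correctness of the estimation machinery under the
stated model, not robustness to real-data violations of it.

## Numerical choices

- Densities and posteriors in log space throughout; log-sum-exp for mixtures.
- BIC uses the number of subjects (not observations) as n.
- Convergence: relative observed log-likelihood change below `tol`
  (default 1e−6).
- Degenerate inputs: empty datasets, uncentered datasets, mixed-sex
  datasets (without an explicit override) and K·(degree+2) > n are rejected
  up front with specific errors.
- Percentages in reports are rounded half-up to 1 decimal.
- Adult BMI bands use the fixed cut-offs 18.5 / 25 / 30 kg/m²; child bands
  require a user-supplied age-specific cut-off table (the reference child
  cut-off curves are licensed data and not shipped).

## Known limitations

- The middle and increasing classes of the default scenario overlap
  strongly near the centering age (by design — so do their real-world
  counterparts). With a few thousand subjects, BIC tends to merge them;
  resolving all four classes by BIC requires sample sizes of the order of
  10⁴, matching the scale at which such models are fitted in practice. See
  the class-enumeration test for the empirical behaviour.
- ECM with a capped inner optimiser trades per-iteration cost against
  iteration count; weakly separated mixtures can need several hundred EM
  iterations near convergence.
- The 3-step correction assumes the step-1 model (and hence Q) is correctly
  specified and ignores sampling error in Q, as is standard.
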