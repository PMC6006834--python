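# Methods

`realist-sem` quantifies realist context–mechanism–outcome (CMO)
configurations with structural equation modelling on linked two-level
survey data: individual respondents nested in GP practices, individual
survey items joined to practice-level patient-experience percentages.
This note records the model, the estimation machinery, the synthetic-data
design, and the numerical and design choices a maintainer would want to
know, together with their rationale.

## The structural model

Each CMO binds three concepts — a context, a mechanism (the mediator) and
the shared outcome — to data through one of four measurement modes:

* **observed** — a single variable used as-is;
* **reflective** — a latent variable causing 3–5 indicators (confirmatory
  factor model), identified by fixing the reference indicator's loading to
  1 and freeing the latent variance;
* **formative** — a composite: the indicators regress *into* the concept
  with the first weight fixed to 1 and the composite disturbance fixed to
  0, so the composite is an exact weighted sum of its indicators and is
  identified through its outgoing paths;
* **categorical** — a context expanded into baseline-contrast dummy
  variables, each receiving its own context→mechanism and direct paths.

The compiled model uses the all-y parameterization

```
Sigma(theta) = Lambda (I - B)^-1 Psi (I - B)^-T Lambda^T + Theta
```

with observed singletons promoted to degenerate latents (loading 1, zero
residual), so every structural path lives in B.  Every CMO contributes a
free context→mechanism path, a shared mechanism→outcome path, and (by
default) a direct context→outcome path.  Exogenous nodes get free
variances and pairwise covariances — this is the convention that fixes the
degrees of freedom, so it is part of the model contract.  Residual
correlations between indicators are never added automatically; they are
accepted explicitly (the study-motivated case is correlated satisfaction
items inside the self-esteem factor).  Only recursive (cycle-free) path
structures are supported.

Ordinal Likert items enter as numeric codes treated as continuous; truly
categorical columns are refused by the engine with a pointer to that
convention.  Mixed categorical/continuous measurement models are out of
scope — they are known to converge poorly at this design's sample sizes.

## Estimation

Maximum likelihood minimises

```
F_ML(theta) = ln|Sigma(theta)| + tr(S Sigma^-1) - ln|S| - p
```

with S the divisor-*n* covariance of listwise-complete rows (the deleted
count is logged in the fit result and report provenance).  The chi-square
statistic is `T = (n-1) F_min` and the RMSEA denominator uses `(n-1)` — a
matched convention pair.

**Optimizer.** Start values: loadings 1, structural paths 0, residual
variances half the observed variance, latent variances half the reference
indicator's variance (full variance for promoted singletons), and free
covariances between two promoted observed singletons at their sample
covariance (their block is saturated, so this is the natural moment
start).  A quasi-Newton (L-BFGS-B) warm start with the analytic gradient
runs first; Fisher-scoring steps (expected information, eigenvalue-floored)
then drive the gradient to `max|dF/dtheta| < 1e-6`, with an observed-Hessian
modified-Newton step every tenth iteration and on any stall.  The mixed
scheme exists because the formative composite creates a quartic-flat ridge
when its outgoing paths are small: pure quasi-Newton crawls (thousands of
iterations), scoring alone converges only linearly along the ridge, and
the occasional exact-curvature step resolves it.  Non-convergence is a
flagged result, never an exception; non-positive-definite Sigma during the
search is handled by line-search backtracking.  All tolerances and
iteration caps are surfaced in `FitOptions`.

**Standard errors.** Naive: inverse observed information, `(2/n) H^-1`
with H the Hessian of F at the optimum (finite differences of the analytic
gradient); a singular information matrix raises an error naming the least
identified parameter.  Cluster-robust: the sandwich `A^-1 B A^-1` where A
is the Hessian of the casewise log-likelihood sum and B the outer product
of cluster-summed casewise scores; with singleton clusters this reduces
exactly to the HC0 estimator.  No small-sample factor is applied by
default; a `G/(G-1)` flag exists.  The bread's eigenvalues are floored at
`1e-12` of the spectral radius so that a numerically singular ridge cannot
produce a negative-variance sandwich.

**Standardization.** Coefficients are multiplied by
sd(predictor)/sd(outcome) using model-implied variances — a standardized
path is the outcome change per standard-deviation unit of the predictor —
and the covariance of all standardized estimates is propagated by the
delta method (numerical Jacobian through the standardization map, robust
parameter covariance inside).

**Modification indices** are univariate score tests for freeing a fixed
residual covariance: `MI = (n/2) g^2 / h_part`, with the partial
information taken from the *expected* (Fisher) information rather than the
observed Hessian.  At a restricted optimum with misfit the observed
Hessian's partial information can collapse along weakly identified
directions and inflate an MI far beyond its likelihood-ratio refit; with
expected information the MIs agree with LR refits to within ~5–20% and are
positive by construction.  The expected parameter change accompanies each
MI.  Candidates are restricted to residual covariances — the only
modification type the workflow sanctions.

## Mediation

For each CMO, `a` is the standardized context→mechanism coefficient, `b`
the standardized mechanism→outcome coefficient, and the decomposition is

```
indirect = a * b              SE by delta method:
total    = direct + indirect  sqrt(b^2 var(a) + a^2 var(b) + 2ab cov(a,b))
```

with symmetric normal-theory 95% intervals and significance defined as the
interval excluding zero (robust SEs).  The proportion mediated uses the
magnitude convention `|indirect| / (|direct| + |indirect|)`: with
same-signed components it equals the naive ratio (0.140 and 0.514 give
21%), and it remains meaningful when direct and indirect effects oppose
(0.088 indirect against −0.078 direct gives 53%), where the signed formula
would exceed 1.  When both components are zero the proportion is reported
missing.

## Fit indices

The independence baseline frees variances and fixes all covariances, so
its optimum is closed-form: `F_baseline = -ln|R|` with R the sample
correlation matrix and `df_baseline = p(p-1)/2` (the engine-fitted
baseline agrees and serves as a cross-check in the tests).  Then

```
RMSEA = sqrt(max(T - df, 0) / (df (n-1)))
CFI   = 1 - max(T - df, 0) / max(T_b - df_b, T - df, 0)
TLI   = ((T_b/df_b) - (T/df)) / ((T_b/df_b) - 1)
```

with strict good-fit verdicts RMSEA < 0.06 and CFI/TLI > 0.95.  CFI cannot
exceed 1; TLI can and is reported uncapped (a capping option exists).  The
plain ML statistic feeds the indices even when robust standard errors are
used for inference — scaled (robust) chi-square corrections are out of
scope, and the index report carries that caveat.  A saturated model (df=0)
reports the indices as missing with an explanation.

## The synthetic generator

The generator emulates the linked design the analysis assumes: by default
276 individuals in 178 practices (mean cluster size ≈ 1.55), seven
contexts, three mechanisms, one outcome.  Its defaults are the study
conditions; key constructions:

* **Standardized-by-construction coefficients.** Structural equations
  consume sample-standardized scores, so the configured `a`, `b` and
  `direct` values *are* standardized coefficients, and disturbance
  variances are solved as one minus the systematic variance (an explained
  variance ≥ 1 raises the non-positive-definite error naming the
  offender).
* **Mechanism→outcome coefficients.** The published record prints direct
  effects and indirect products per CMO but not the separate `a` and `b`
  path values, so the fixture fixes `b` once (health literacy 0.10,
  assertiveness 0.10, convenience 0.35 — plausible magnitudes) and derives
  each `a = indirect / b`.  Every published direct and indirect value is
  reproduced exactly in the generating truth; the ease-of-getting-through
  CMO has direct 0.514, indirect 0.140, proportion mediated 0.21.
* **Two-level structure.** Exogenous practice-level percentages (clear
  information, ease of getting through, the four healthcare-experience
  indicators) are constant within practice.  *Endogenous* percentage
  measures (convenience, obtaining an appointment) carry individual
  variation plus an independent per-variable practice random effect
  (default share 0.30; individual-level scores use 0.05).  Making them
  cluster-constant would contradict the individual-level structural model
  being fitted — a practice-constant variable cannot linearly depend on
  individual predictors — so the generator trades that bit of realism for
  a correctly specified target model, which is what parameter-recovery
  testing requires.  Per-variable (rather than shared) random effects
  induce within-cluster dependence without distorting the cross-variable
  covariance structure.
* **Scaling.** `SyntheticConfig.scaled(n)` grows the number of practices
  proportionally, keeping the mean cluster size at the study's ≈1.55.
  Holding 178 practices fixed while n grows would leave every
  practice-level estimate with the sampling error of 178 draws no matter
  how large n became; scaling both levels is what makes large-n recovery
  checks meaningful.
* **Ordinal indicators** are thresholded continuous scores
  (`discretize_to_likert`, right-closed intervals, codes 1..k).
  Thresholds for internet use, lifts, public transport and the
  health-literacy score come from the published category frequencies;
  satisfaction/affect items use plausible skewed distributions.  Exogenous
  ordinal scores (internet use, the transport indicators) enter the
  structural equations through their observed codes, keeping the fitted
  model exactly linear in what it sees; reflective indicators and the
  ordinal health-literacy mechanism are coarsened after the structural
  draw, which mimics the attenuation real Likert measurement produces.
* **Travel time** is log-normal with (mu, sigma) solved from the printed
  median 4.80 and IQR 2.76–7.88; it enters the transport composite on its
  raw minute scale.
* **Cosmetics.** Sex (61.2% female), age band and occupation are generated
  to the published marginals, marked categorical, and excluded from the
  model; they exist so pipeline I/O behaves like real survey data.
  Missingness is MCAR per cell at a configurable rate (default 0).

What the generator does **not** emulate: postcode-based record linkage,
GIS road-network travel times, survey weighting, informative missingness,
and real-world misspecification (the fixture's model is correct by
construction).  Passing recovery and fit-index tests therefore shows the
estimator and indices behave as designed under the assumed model — it does
not validate the substantive model against real primary-care data, which
is not distributable.

## Calibration results and known limitations

* **Formative composite under weak signal.**  A composite's weights are
  identified only through its outgoing paths.  When those paths are near
  zero the weight directions are ridges: fits still converge (the mixed
  optimizer handles the flat curvature), but Wald inference on the
  composite's standardized effects degrades.  In a 100-replication null
  calibration (all generating paths zero, n = 2000), every direct and
  indirect significance flag fired within Monte-Carlo range of its nominal
  5% level — except the transport composite's direct-effect flag, which
  fired 23 times.  The delta-method robust SE is unbiased there (mean SE
  0.0352 against an empirical SD of 0.0353 across replications); the
  over-firing comes from the estimator's non-normal, sup-type distribution
  when the weights adapt to noise, which no consistent SE can repair.
  Composite-context significance tests should therefore be read
  cautiously when the composite shows little relation to anything —
  a caveat inherent to free-weight composites, not specific to this
  implementation.
* **Heywood cases** (negative residual-variance estimates) are retained
  with a recorded warning rather than constrained away.
* **Missing data** is handled by listwise deletion with a logged count;
  full-information ML is a possible extension.
* **Ordinal treatment**: treating Likert codes as continuous attenuates
  loadings and paths involving coarse scales; the generator reproduces
  this honestly rather than hiding it.  Polychoric alternatives are out of
  scope.

## Problem sizes used by the test and acceptance suites

Chosen to make every property measurable at desk scale: fixture recovery
uses one draw at n = 50 000 (≈32 246 practices); fit-index behaviour uses
20 replications at n = 5 000; null calibration uses 100 replications at
n = 2 000 (≈1 290 practices), where standard errors are asymptotically
trustworthy while a replication fits in about a second; unit-level
recovery checks run at n = 1 000–5 000.  The acceptance script derives its
two seeds from the single `--seed` argument (recovery draw: the seed
itself; fit-index draw: seed + 6).
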