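# Methods

## Models

All models share the exact binomial measurement model for arm-level counts,
`y_ik ~ Binomial(n_ik, expit(θ_ik))` for treatment `k` in study `i`, with
`θ_ik` the arm log odds. Zero-event arms need no continuity correction
under this likelihood and are left untouched. The structural layer differs:

* **Model 1** (contrast-based, observed arms). Each study has a reference
  treatment `b_i` (the lowest-numbered treatment present; treatment 1 in
  every in-scope dataset). `θ_ik = α_i + δ_ik` with fixed-effect intercepts
  `α_i` and `δ_ik ~ N(μ_k − μ_b, σ_c²)`, `δ_ib = 0`. Restricted here to
  two-arm studies (the multi-arm correction for this parameterization is
  out of scope; models 2–4 handle multi-arm designs natively).
* **Model 2** (contrast-based, all possible arms). Contrast vectors
  `δ_i = (δ_i2..δ_iK) ~ MVN(μ^c, Σ^c)` for every study, whether or not an
  arm was observed; intercepts `α_i1` refer to treatment 1 throughout. An
  equivalent symmetric arm-based form `θ_ik = α_i + μ_k + η_ik`,
  `η_i ~ MVN(0, Σ^a)` is provided; under vague normal intercept priors the
  two forms have the same posterior, which the test suite checks by fitting
  both.
* **Model 3** adds random intercepts `α_i1 ~ N(μ_1^a, σ_a²)`, independent
  of the contrasts.
* **Model 4** (arm-based) models the whole arm vector,
  `θ_i ~ MVN(μ^a, Σ^a)`, so intercepts and effects may be correlated. The
  contrasts of interest are `μ_k^c = μ_k^a − μ_1^a`. An equivalent
  contrast-based form for `(α_i1, δ_i)` is implemented and used as a
  cross-check.

**Heterogeneity.** Common heterogeneity (CH) gives every pairwise contrast
one variance `σ_c²`: `Σ^c = σ_c² P_{K−1}(0.5)` (models 2–3),
`Σ^a = 0.5 σ_c² I` (model 2 AB form), and the compound-symmetry
`Σ^a = σ_a² P_K(ρ^a)` for model 4, where `P_n(ρ)` is the unit-diagonal
matrix with off-diagonals `ρ` and `σ_c² = 2σ_a²(1−ρ^a)`. `ρ^a` must lie in
`(−1/(K−1), 1)` for positive definiteness. Non-common heterogeneity (NCH)
leaves the covariance unstructured. Model 1 is CH-only: model 2 subsumes
its NCH extension with positive-semidefiniteness doing the work of
second-order consistency constraints.

## Priors

* Location parameters (intercepts, overall means): `N(0, 1000)` with 1000 a
  *variance* (sd ≈ 31.6), effectively flat.
* Contrast heterogeneity: `log σ_c² ~ N(−2.13, 1.58²)`, a lognormal of the
  kind derived from large empirical collections of binary-outcome
  meta-analyses for log-OR heterogeneity in pharmacological-versus-placebo
  comparisons. This is a configurable stand-in: the analysis that motivated
  this package used an evidence-based prior whose exact parameters are not
  published in its main text, and several corticosteroids-network
  quantities (see "Known discrepancies") are sensitive to this choice only
  weakly, the model-4 variance decomposition more so.
* Arm heterogeneity (model 3's `σ_a²`; model 4's second variance):
  `log σ_a² ~ N(−1, 2²)`, weakly informative, acknowledging that
  underlying-risk variation is usually larger than contrast heterogeneity.
* Model 4 CH: *independent* priors on the two interpretable quantities —
  contrast variance `σ_c²` and arm variance `σ_a²` — truncated to the
  positive-definite region, with `ρ^a = 1 − σ_c²/(2σ_a²)` derived. A
  uniform prior on `ρ^a` was rejected because it couples the arm variance
  to the contrast-variance prior: with an informative (small) `σ_c²` prior
  it drags `σ_a²` down as well, which contradicts treating the two
  heterogeneities as separate quantities needing separate priors.
* NCH: inverse-Wishart with `dim + 2` degrees of freedom; the scale matrix
  is moment-matched so that the prior mean of every log pairwise contrast
  variance equals the CH prior's location (and, for model 4, the arm
  variance matches the arm prior's location). At these degrees of freedom
  the IW family cannot also match the prior spread, so the NCH priors are
  somewhat more informative than the CH ones; `sample_prior` exposes
  prior-predictive draws so the match can be inspected.

## Sampler

Adaptive random-walk Metropolis-within-Gibbs, vectorized across studies.
Overall means are drawn by exact conjugate Gibbs steps (they enter
linearly with normal priors); study-level latents take componentwise
adaptive random-walk steps targeting 0.44 acceptance, with adaptation
confined to burn-in; variance components move on log scales; NCH
covariances are drawn from their conjugate inverse-Wishart full
conditionals after Gibbs-imputing the unobserved components of each
study's latent vector. CH models instead marginalize the unobserved
components analytically (an exact MVN marginalization — "describing all
possible arms has no impact on the fit"). Initialization uses empirical
logits with a 0.5 continuity correction (initialization only), prior
medians for variances.

Default chain regime: single chain, 50 000 burn-in updates, 200 000
further updates thinned to every 20th (10 000 retained draws).
Autocorrelation diagnostics are computed on the thinned chain. The test
suite and the acceptance script use reduced chains (2 000/8 000 thinned to
every 2nd, and 10 000/40 000 thinned to every 4th, respectively) — sizes
chosen so the full suite runs in minutes while Monte Carlo error stays
within the stated test tolerances. Posterior summaries are medians with
central 95% intervals (linear-interpolation quantiles); Monte Carlo
standard errors of medians use the arviz quantile-MCSE estimator.

Equivalent parameterizations fitted by *different* samplers (model 1 vs 2;
CB vs AB forms of models 2 and 4) serve as the engine's cross-validation;
a further oracle test checks a single-study posterior against direct
numerical integration.

## Estimands

`μ_k^c` are conditional (within-study) log odds ratios. For models with
random intercepts, marginal treatment means `π_k = E[expit(θ_ik)]` are
computed per posterior draw by 32-node Gauss–Hermite quadrature over the
fitted between-study normal (model 3: intercept and contrast
heterogeneity added, independent by construction; model 4: the arm's
marginal variance), and marginal contrasts `g(π_k) − g(π_k′)` follow on
the logit, identity (risk difference) or log link. Conditional odds ratios
are non-collapsible: they sit further from 1 than marginal ones, the two
converging as heterogeneity vanishes (tested). For fixed-intercept models
the supported absolute-effect route is `external_target`: apply the
conditional contrast to an externally supplied underlying risk, by default
plugging in the posterior draw of the mean contrast; a flag integrates
contrast heterogeneity by quadrature instead (the plug-in version
understates heterogeneity-induced spread, which is logged in the
docstring). Only a point-valued external risk is supported.

## Hypothetical datasets

Ten deterministic datasets (scenarios 1–5 × subtypes a/b) for treatments
X, Y, Z with Y and Z truly identical, built to reveal when between-study
information and design selection bias the Z-vs-Y contrast. The X-arm log
odds run from −2 to 0 (overall event fraction ≈ 25%); arm sizes are 200
(50 in scenario 3); effects are 0 (scenario 1), 0.5 (scenarios 2–3), or
linear in the X log odds with mean 0.5 and slope ∓0.5/1.2 (scenarios 4–5
— the slope calibrated so the design-stratified mean effects differ by
exactly ∓0.5 in subtype b, matching the reported bias of the direct
comparison). Subtype a interleaves six Y-X with five Z-X designs across
the grid; subtype b puts five Y-X studies on the low half and five Z-X
studies on the high half (the exact grid spacing is the package's choice;
only the endpoints, counts and halves are prescribed). Counts are expected
counts rounded half-up, so regeneration is bitwise identical; binomial
sampling is available behind a flag. `design_bias_oracle` recomputes the
design-stratified bias from the stored truth as a generator self-check.

What the generator does *not* emulate: sampling noise (by default),
multi-arm studies, unequal arm sizes, and treatment-by-study interactions
beyond the linear underlying-risk rule — so passing bias-pattern tests
demonstrates the models' structural behavior on clean data, not
performance on messy real networks.

## Numerical choices

Quantile rule: linear interpolation of order statistics everywhere.
Constant-chain autocorrelation returns 0 with a warning rather than NaN.
Proposals leaving the positive-definite region of a covariance are
rejected by giving them −∞ density, never surfaced to the user. The
compound-symmetry precision and log-determinant use closed forms; small
conditional-MVN imputations add a 1e-10 diagonal jitter before Cholesky.
Ties in the half-up rounding of expected counts cannot occur at the
default sizes, but the rule is fixed anyway.

## Known discrepancies and limitations

On the corticosteroids network, the model-4 CH variance decomposition
under these priors settles at a moderate correlation (ρ^a ≈ 0.3–0.4 with
σ_c ≈ 1.2, σ_a ≈ 1.1) rather than the near-1 correlation the original
analysis of this network reported. This is not a sampler artifact: the AB
and CB forms of model 4 (independent code paths) agree, and a per-study
2-D quadrature of the integrated likelihood with treatment means profiled
out confirms the posterior mode's location — the high-correlation
configuration sits several log-likelihood units lower and would only be
reached under a substantially more informative prior on the heterogeneity
variances than the published evidence bases support. Quantities that
depend on this decomposition (ρ^a itself, the model-4 minus model-3 arm-SD
gap, and the size — though not the sign — of the posterior slope of the
treatment-7 effect on σ_a) should therefore be read as prior-sensitive;
the between-model contrast differences (models 1/2 vs 3) are robust to
this choice. Fitted models assume consistency and normal random effects;
inconsistency terms, non-binary outcomes, contrast-level (two-stage)
likelihoods, dose/class structures and informative missingness models are
out of scope.
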