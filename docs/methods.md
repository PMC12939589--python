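# Methods

`radsurv` implements a stability-based biomarker discovery and risk
stratification workflow for right-censored survival cohorts with
high-dimensional radiomic feature tables, together with a synthetic cohort
generator that reproduces the statistical structure the workflow assumes.
This note records the models, the defaults and why they were chosen, the
numerical conventions, and what the synthetic experiments do and do not
demonstrate.

## The selection-frequency ranking protocol

The core model is the Cox proportional hazards model with an elastic-net
penalty.  For coefficients β and mixing value α ∈ [0, 1], a fit at penalty
weight λ minimizes

    -ℓ(β)/n + λ [ α‖β‖₁ + (1-α)/2 ‖β‖₂² ]

where ℓ is the Breslow log partial likelihood.  λ is normalized per
observation (the glmnet convention), so λ values are comparable across
subsamples of different sizes.  Rather than interpreting a single fitted
model, the protocol measures *selection stability*:

1. Draw a Monte-Carlo subsample of the cohort — by default 80% of
   patients, without replacement.  Subsampling (rather than bootstrap
   resampling) avoids duplicated rows, which would distort risk sets and
   cross-validation.
2. For each α on the 11-point grid {0.0, 0.1, …, 1.0}, select λ by
   10-fold cross-validation (folds stratified by event status so every
   fold retains events) minimizing the mean held-out partial-likelihood
   deviance, then refit on the whole subsample at the chosen λ.
3. Record every feature with |β| > 1e-8 as *selected* in that model.
4. Repeat for `n_runs` subsamples; with the default 100 runs the protocol
   evaluates 100 × 11 = 1100 models.  A feature's *selection frequency*
   is the number of models that selected it; features are ranked by
   descending frequency with competition ("1224") ranking, so tied counts
   share the better rank.

Only the radiomic features enter the penalized model; age, gender and
stage are reserved for the downstream stratification, where their
prognostic value is compared against the selected biomarker's.

Numerical choices:

- **Cross-validated deviance.** The held-out deviance uses the
  Verweij–Van Houwelingen form, −2·(ℓ_full(β̂_train) − ℓ_train(β̂_train)),
  which evaluates the held-out contribution without breaking risk sets in
  small folds.  Ties in the deviance curve resolve to the larger (more
  parsimonious) λ.
- **λ path.** A geometric path of `n_lambda` values (default 30; the
  heavy repeated-protocol experiments use 8) descending from λ_max, the
  smallest λ with an all-zero lasso solution, computed from the gradient
  of the partial likelihood at β = 0.  The path floor is
  `lambda_min_ratio` · λ_max (default 0.05).  For the ridge end of the
  grid λ_max is computed with α floored at 0.01, since pure ridge has no
  finite all-zero λ.
- **Solvers.** Fits with α > 0 and λ > 0 use coordinate-descent
  elastic-net Cox path fitting; unpenalized (λ = 0) and pure-ridge
  (α = 0) fits use the package's damped Newton–Raphson maximizer of the
  Breslow partial likelihood with an exact ridge Hessian.  Tied event
  times use the Breslow approximation throughout, and censored rows tied
  with an event time remain in that time's risk set.
- **α = 0 counting.** A ridge fit is dense — every coefficient is
  non-zero almost surely — so by default the α = 0 column counts every
  exposed feature as selected without spending a cross-validation on it
  (`ridge_dense=True`).  Setting `ridge_dense=False` forces the explicit
  CV + fit.
- **Standardization.** Features are standardized to unit variance within
  each subsample; coefficients are reported on the standardized scale.
  Features with zero variance in a subsample are dropped from that fit
  (logged, β = 0) and counted as unexposed rather than unselected.
- **Failure accounting.** A fit that fails to converge (or a λ selection
  whose every path value fails) is excluded with a per-feature failure
  counter, so selection counts are never silently deflated:
  count + not-selected + failures = total models for every feature.

## Redundancy and the representative biomarker

Top-ranked features are typically strongly inter-correlated.  The
candidate set for redundancy analysis is the rank-1 tie group when it has
at least two members, otherwise the top five by count.  For candidates
the package computes the Spearman rank correlation matrix (average ranks
at ties) and each candidate's representativeness strength score,

    RSS(f) = mean over g ≠ f of |ρ(f, g)|,

selecting the candidate with maximal RSS; ties break by higher selection
frequency, then name.  RSS arbitrates only genuine ties: when the rank-1
feature stands alone, it is the representative outright and the
correlation report over the top five serves as context — otherwise a
clear frequency winner could be displaced by a pair of mutually
correlated lower-ranked features inflating each other's RSS.  |ρ| ≥ 0.6 is reported as a redundancy *flag*, not
a hard filter; when even the best RSS falls below it the selection is
still defined but a low-redundancy warning is logged.  RSS is invariant
under strictly monotone transforms of any feature, which makes the
representative choice robust to feature scaling conventions.

## Binary data mapping and stratification

Continuous axes (age, biomarker) are dichotomized at the sample median
with the ≤-median convention: values at or below the median form the low
group.  This puts ties at the cut in the low group, is deterministic, and
for an even sample of distinct values yields an exact 50/50 split.  The
medians are always computed from the data at hand, never hard-coded.
Stage maps I and II to Low and IIIa/IIIb to High.  Crossed factors
partition the cohort into a stratum set whose per-cell counts are
exported in long format (the data behind a patient-count heatmap).

Kaplan–Meier curves are estimated from scratch as the product-limit
estimator with Greenwood variance; confidence bands use the complementary
log-log transform so they stay inside [0, 1] (degenerate [1, 1] where
S = 1).  Group comparisons use the standard two-group log-rank test with
hypergeometric variance and a χ²(1) reference; reported p-values are
displayed to two significant figures and floored at "<0.0001".

## Survival-aware SMOTE

Plain SMOTE is undefined for (time, event) pairs.  The adaptation here
synthesizes rows separately within each (class × event-status) stratum:
a seed row and one of its k = 5 nearest minority neighbors (Euclidean
distance on per-stratum standardized features; time, event and clinical
covariates excluded from the metric) are interpolated with a single
uniform weight w applied to the features, the survival time and age;
the event indicator is inherited from the stratum and categorical
covariates copy from the seed parent.  Synthetic counts are apportioned
to event strata by largest-remainder allocation, which preserves each
class's event fraction to within 1/(smallest stratum size).  Every
synthetic row records its two parents and w, so the convex-combination
property is verifiable after the fact.  Strata smaller than k + 1 reduce
k with a warning; a singleton stratum is an error by default
(`skip_singleton_strata=True`, used by the pipeline, skips it instead and
reallocates its share).  Balanced sets exist only for exploratory
subgroup comparisons: by construction of the pipeline they never feed
the ranking or representative-selection stages, and no hazard ratios are
estimated on them.

## The synthetic cohort generator

The generator emulates the structure of a 398-patient NSCLC radiomic
cohort: 107 features in 7 category blocks (first-order 18, shape 14,
GLCM 24, GLSZM 16, GLRLM 16, NGTDM 5, GLDM 14), age, gender, overall
stage, and a right-censored outcome.

- **Features.** A Gaussian copula with exchangeable correlation — 0.6
  within blocks, 0.15 across blocks by default — pushed through
  exp(z/2), giving positive, right-skewed (lognormal) marginals the way
  radiomic texture features look.  The NGTDM block carries the five real
  NGTDM feature names, including *Busyness*.  The implied correlation
  matrix is checked for positive semi-definiteness and invalid requests
  are rejected naming the offending parameters.
- **Hazard model.** Survival times follow a Weibull proportional-hazards
  model (shape 1.1, scale 2.2 years, chosen to put the median survival
  near 1.5 years with a long right tail).  The linear predictor carries
  one planted log hazard ratio of 0.8 per SD on Busyness (standardized by
  its known population moments, so an unpenalized Cox fit recovers the
  planted value), 0.2 per decade of age, 0.25 for male gender and 0.05
  for high stage.  The weak stage effect mirrors a cohort in which stage alone
  does not separate survival; an optional coupling parameter lets stage
  correlate with the planted biomarker when that asymmetry is to be
  broken deliberately.
- **Covariates.** Age ~ Normal(68.1, 10.1) truncated to [30, 95];
  gender male with probability 0.686; stage I/II/IIIa/IIIb with
  probabilities 0.211/0.093/0.348/0.348 (the III mass split evenly
  between IIIa and IIIb, which the reference margins do not resolve).
- **Censoring.** Independent exponential censoring whose rate is solved
  numerically (bisection on the sampled event times) so the expected
  censored fraction matches the 11.8% target; a single-parameter scheme
  independent of the event process.
- **Determinism.** All draws flow from one `numpy` SeedSequence; an
  identical spec and seed reproduces the cohort bit for bit.

What the generator does *not* emulate: real radiomic marginal shapes
beyond positivity and skewness, inter-feature correlation structure
beyond the two-level exchangeable pattern, stage-dependent censoring, or
any image-level provenance.  Passing the synthetic experiments therefore
demonstrates that the pipeline recovers planted signal under the assumed
structure — not that any particular real-data ranking is correct.

## Pipeline and reproducibility

`run_full_pipeline` executes generate/read → rank → redundancy →
stratify → Kaplan–Meier panels → SMOTE-balanced panels → report, writing
every artifact as CSV plus a YAML config snapshot.  Per-stage seeds
derive from the single global seed through a counter-based SeedSequence
scheme, so stages are independently re-runnable yet fully determined;
re-running an identical config reproduces every CSV byte for byte.  When
a synthetic cohort is used, the global seed also determines the cohort
draw (the spec's own seed field is superseded inside the pipeline).

## Problem sizes used by the test suite and acceptance script

The repeated-protocol experiments are run at a scaled design — 20
Monte-Carlo runs × 11 α values per replicate with an 8-point λ path, 20
replicates for the recovery check — which keeps the planted-signal
recovery property crisp while the full 100 × 11 protocol is exercised
once on a 60-patient, 20-feature cohort to verify the model count and
failure accounting, and once at full cohort scale by the acceptance
script.  Censoring calibration is checked at n = 5000.

## Known limitations

- The Monte-Carlo scheme (80% subsampling without replacement) and the
  per-(run, α) counting convention are design choices; other stability
  selection variants (complementary pairs, bootstrap) are out of scope.
- The log-rank test is the only implemented group comparison; weighted
  log-rank families and multivariable Cox inference on the balanced sets
  are deliberately excluded.
- The survival-aware SMOTE interpolates event times within event-status
  strata; this preserves censoring structure but is still a heuristic —
  balanced sets must not be used for absolute survival or hazard-ratio
  estimates.
- With exchangeable block correlation the planted feature is
  statistically exchangeable with its block partners up to the planted
  effect; at small run counts its block neighbors occasionally tie with
  it, which is the expected behavior of frequency ranking under
  redundancy, not a defect.
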