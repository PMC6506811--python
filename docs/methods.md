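# Methods

## Model and estimation

Each feature (metabolite) is modelled independently as a Gaussian linear
mixed model with a single random intercept per subject:

```
y_ij = β₀ + u_i + Σ_k β_k x_ik + ε_ij,   u_i ~ N(0, σ_u²),  ε_ij ~ N(0, σ_e²).
```

Fixed effects are the class label plus declared covariates; categorical
terms use treatment coding against the first declared level (reference), so
coefficients read as offsets from that level, matching the convention of R
model matrices. Numeric covariates enter uncentered: coefficients stay on
the raw covariate scale.

With V(θ) = I + θ²ZZᵀ and θ = σ_u/σ_e, both β and σ_e² have closed-form
generalized-least-squares profiles at fixed θ, so estimation is a
one-dimensional bounded minimization of the profiled REML deviance over
log(θ + ε), θ ∈ [0, 100], ε = 1e-8, convergence tolerance 1e-8
(`scipy.optimize.minimize_scalar`, bounded). The boundary θ = 0 is always
evaluated explicitly and accepted whenever it is at least as good, so
zero-variance random intercepts are exact rather than tiny positives. V is
block diagonal (one block per subject), giving O(n) per deviance
evaluation; no matrix larger than p × p is ever decomposed.

Per-subject random effects are predicted by the standard shrinkage formula
û_i = n_i σ̂_u²/(n_i σ̂_u² + σ̂_e²) · (mean marginal residual of subject i).
Coefficient standard errors come from σ̂_e²(XᵀV⁻¹X)⁻¹ at the REML optimum.

Term significance uses likelihood-ratio chi-square tests: both full and
reduced models are refitted under the ML (not REML) criterion with the same
random-effect structure, and 2Δℓ is referred to χ² with as many degrees of
freedom as the term has design columns. REML likelihoods are not comparable
across fixed-effect structures, hence the separate ML profile. A Wald
chi-square per coefficient is reported as a secondary column because the
test variant used by earlier tooling in this area is ambiguous; the two
agree asymptotically.

Degenerate cases: a constant response yields a flagged degenerate fit with
both variances zero; all-singleton grouping makes σ_u² unidentifiable and
forces θ = 0 with a boundary flag; rank-deficient designs are an error
naming the aliased columns (or, in cross-validation folds where a factor
level can disappear, the aliased columns are dropped, which is what R's
mixed-model fitters do).

## Processed values

The default processed value is the conditional fitted value X β̂ + û_i —
the model's estimate of the noise-free abundance, retaining both the fixed
effects and the subject's predicted offset while removing residual error.
This is the reading adopted for the processing step; because the exact
output convention of comparable tools is not fixed, two alternatives are
exposed as modes: `marginal` (X β̂ only) and `deduct_random` (y − û_i).

## Latent-variable models

PLS-DA encodes the binary class as a centered 0/1 dummy and extracts
components by NIPALS with X- and y-deflation. Weight vectors are unit-norm
and signed so their first nonzero entry is positive, making output
deterministic across platforms. VIP for feature j is

```
VIP_j = sqrt( p · Σ_a SS_a w_aj² / Σ_a SS_a ),   SS_a = q_a² t_aᵀt_a,
```

with unit-norm weights, so mean(VIP²) = 1 identically. OPLS-DA removes
`n_ortho` components orthogonal to the response (w_o = p − (wᵀp)w from the
provisional predictive direction) before fitting one predictive component;
orthogonal scores are exactly uncorrelated with the dummy by construction,
and VIP uses the predictive component only. A rank-1 matrix aligned with
the response is legal: its orthogonal component degenerates to zero.
Standalone defaults are 2 predictive components for PLS-DA and 1 + 1 for
OPLS-DA, with unit-variance autoscaling on — the defaults of the standard R
implementations of these methods.

Class prediction thresholds the predicted dummy value at the midpoint of
the two training class means of the decision score; exact ties resolve to
the first class level.

## Evaluation harness

Cohorts are split subject-wise into repeated k-fold plans (default k = 4,
5 repeats → 20 splits), so no subject ever spans train and test; in paired
designs this also preserves class balance exactly. A sample-level stratified
mode exists for comparison. Per split and arm, only the training fold is
processed (M0: identity; LMM: per-feature mixed models fitted on the fold;
ML: within-subject centering); a PLS-DA (and, for M0/LMM, OPLS-DA) selector
is fitted, features with VIP > 1 are kept (empty selections fall back to
all features, logged), a fresh PLS classifier is trained on the selected
features of the processed fold, and the untouched original-scale test rows
are scored. Test folds are never processed: no mechanism for projecting
unseen samples through a subject-level model exists, and processing them
would leak test-subject information.

Two harness defaults deliberately differ from the standalone latent-model
defaults, because the training matrix (processed) and the test matrix (raw)
are on different noise scales:

- **Centering only, no autoscaling.** Per-feature scale factors estimated
  on a denoised training fold understate the test-fold noise and
  systematically re-weight features at prediction time; centering alone
  avoids the mismatch. Log2 intensities already share a scale, so this is
  also common practice for metabolomics PLS-DA.
- **One predictive component in the final classifier.** A binary dummy
  response spans a single dimension; additional components model X-variance
  and tend to overfit — the same argument that motivates OPLS-DA. The
  selector model keeps the 2-component default.

Arms are compared per metric across splits with a two-sided Wilcoxon
signed-rank test: zero differences dropped, midranks for ties, exact
p-values by dynamic-programming enumeration of all sign patterns when the
effective n ≤ 25 without ties, otherwise a normal approximation with
continuity and tie corrections.

Confusion-matrix ratios with empty denominators (e.g. precision with no
positive predictions) are reported as NaN and excluded from summaries with
a log entry rather than silently imputed.

## Synthetic cohorts

The generator draws paired two-samples-per-subject cohorts directly from
the model above. Default covariate marginals reproduce a 59-patient
colorectal-carcinoma cohort table: age ~ N(62.92, 13.71²) years,
BMI ~ N(27.14, 4.38²) kg/m², P(female) = 16/59, tumor stage I–IV with
probabilities (9, 23, 16, 11)/59, tumor location colon/rectum at
(26, 33)/59. Age and BMI are drawn as unbounded normals — the table gives
only mean ± SD, and any truncation rule would be invented.

Per feature: baseline β₀ ~ N(20, 2²) log2 units; a fraction (default 0.3)
of features get a nonzero class effect with magnitude uniform on
[0.5, 2.0] log2 units and random sign (real effects run in both
directions); covariate coefficients are centered normals with small spreads
(age 0.01 per year, BMI 0.02, sex/location 0.2, stage 0.3 log2 units).
Noise defaults are σ_u = 2 and σ_e = 1 log2 units, i.e. subject variance
four times residual variance — a strongly subject-confounded regime.
Subject intercepts are drawn independently per subject–feature pair, the
model's own assumption.

What the generator does **not** emulate: cross-feature correlation of
subject effects (real subjects shift many metabolites coherently),
heteroscedastic residual noise, non-Gaussian intensity distributions,
batch/technical effects, and missingness. One consequence is worth
spelling out: in a perfectly balanced paired cohort with subject-level
covariates and independent per-feature intercepts, the class-discrimination
statistic every processing arm feeds to PLS collapses to the within-pair
mean difference, so the M0, LMM and ML arms perform near-identically
(differences of ~±0.01 accuracy). Passing arm-comparison tests on such
cohorts therefore demonstrates correctness and absence of leakage, not the
real-data advantage of mixed-model processing, which rests on exactly the
structure the generator omits. Conversely, the variance-reduction and RLA
diagnostics, estimator calibration, and parameter-recovery results transfer
directly.

## Numerical choices and problem sizes

- Optimizer: deterministic 1-D bounded search (no random restarts);
  profiled deviances are unimodal in practice for this model class.
- Zero-variance features are passed through unchanged and listed as
  skipped rather than fitted.
- Round-tripping the processed matrix through CSV preserves 12+ significant
  digits (`%.15g`).
- All randomness flows from explicit integer seeds through
  `numpy.random.default_rng`; same seed → bit-identical cohorts, split
  plans and outputs.
- Test-suite simulations use scaled-down cohorts (tens of subjects,
  tens-to-hundreds of features, 10–50 replicate seeds) chosen so each
  statistical property concentrates well past its asserted threshold while
  the whole suite stays interactive; the per-sample RLA-spread check uses
  300 features because per-sample spread estimates only concentrate with a
  realistic feature count.

## Known limitations

- One random intercept with a single grouping factor; no nested, crossed or
  correlated random effects and no random slopes.
- Binary class labels only; multiclass discriminant analysis is out of
  scope.
- No missing-data handling: missing abundances or covariates are a hard
  error, since no principled imputation is assumed.
- Raw p-values are reported without multiple-testing correction;
  correction policy is left to the caller.
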