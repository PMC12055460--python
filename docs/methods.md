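# Methods

## Estimand and model

The causal contrast is the marginal risk ratio of 30-day tobacco
abstinence at 7-month follow-up under high- versus low-intensity quitline
services,

    RR = E[Y(1)] / E[Y(0)],

identified from observational data under consistency, positivity and
exchangeability given measured baseline covariates (for treatment) and
given treatment plus measured covariates (for censoring).  Estimation is
a two-step marginal structural model:

1. **Weights.**  A logistic model for response (C = 0) given treatment
   and covariates yields IPCW = 1/Pr(C=0 | A, Z), defined for responders
   only; a logistic propensity model yields IPTW = 1/Pr(A=a | Z), the
   reciprocal of the probability of the intensity actually received.
   The analysis weight is their product, IPTCW.
2. **Outcome model.**  Among responders, a Poisson working likelihood
   with log link and design (1, A) is maximized with the weights
   (modified Poisson regression), so the slope is a log risk ratio.
   Because the Poisson variance is misspecified for a binary outcome and
   the weights are not frequency weights, the variance is the robust
   sandwich

       Var(β̂) = A⁻¹ B A⁻¹,  A = Σ wᵢ μᵢ xᵢxᵢᵀ,  B = Σ wᵢ² (yᵢ−μᵢ)² xᵢxᵢᵀ

   (HC0, weighted estimating-equation form).  Confidence intervals and
   p-values are Wald on the log scale.  The sandwich treats the weights
   as known; with estimated weights this is conservative, which the
   bootstrap comparison in the acceptance suite confirms to within 10%.

Unstabilized weights are the headline choice; stabilization (marginal
numerators Pr(A=a) and Pr(C=0|A)) and percentile truncation (default
1/99 when enabled) are opt-in sensitivity options.  In the saturated
intercept+treatment MSM, stabilization numerators are functions of A
alone and therefore cannot move the point estimate — the package's
equivalence test verifies agreement to 1e-6.

Default model covariates mirror the applied analysis: censoring —
treatment, age, race/ethnicity, insurance, geography; propensity — age,
insurance, income.  Age enters weight models as a continuous linear term
by default; `bin_age` adds the six standard age categories as a column
that can be used in predictor lists instead.  Categorical
predictors are coded as indicators against the most frequent level.

### The IPTW formula

The source analysis prints the treatment weight as "Pr[A = 1 | Z]"
without a reciprocal.  This package implements the standard inverse
weight 1/Pr(A = aᵢ | Zᵢ) — the only reading consistent with the name
*inverse* probability of treatment weighting and with the weight-sum
diagnostics (Σ IPTW ≈ 2n).

## Synthetic cohorts

`ScenarioSpec` describes covariate margins, a logistic
treatment-assignment model, a logistic censoring model (which may load on
treatment — the collider arrow), and a log-link outcome model.  Per
subject the generator evaluates both counterfactual risks, draws the two
potential outcomes from a shared uniform (consistency), and blanks Y for
censored subjects.  The true marginal RR is computed analytically from
the risks, not sampled.  One master seed spawns independent substreams
for covariates, treatment, censoring, outcome and missingness, so
toggling missingness never perturbs the other draws.

Risks from the log link are capped at 0.95; a scenario in which the cap
binds for more than 0.1% of subjects is rejected with a message naming
the largest-contributing term.  Within accepted scenarios the cap never
binds, so with no treatment-by-covariate interaction the true marginal RR
equals exp(β_A) exactly (log-link collapsibility).

Covariate margins in the packaged scenarios come from the published
baseline table as integer counts (so probabilities sum to one exactly);
age is truncated normal (mean 48.29, SD 14.95, range 18–94).  Baseline
covariates are drawn independently — the source gives margins only, no
joint distribution — which is the main respect in which the synthetic
world is simpler than real registry data.  Green tests therefore
establish correctness of the estimators under the declared structure, not
robustness to covariate dependence, effect modification, or time-varying
behavior, none of which are generated.

### Packaged scenarios and calibration

Scenario coefficient files live in `src/quitline_ipw/scenarios/*.yaml`.
Slope coefficients are fixed design choices of plausible epidemiologic
magnitude (e.g. older and Medicare-insured registrants receive more
services; uninsured, rural and more-dependent registrants respond less).
Intercepts (and the censoring coefficient on treatment) were calibrated
once, numerically, on a fixed 400k covariate draw to the stated targets —
63.69% high intensity, censoring 60%/48% by arm (i.e. response 40%/52%),
35% quit rate among responders — and frozen into the YAML files.

- `table1_default` (n = 4695): full published margins, confounded
  treatment, covariate- and treatment-dependent censoring, 7% MAR-missing
  income (missingness loads on being uninsured and on online
  registration, intercept calibrated to the 7% target).
- `confounded` / `confounded_selective`: the same structure at larger
  default n, without income missingness; `confounded_selective`
  strengthens the censoring–outcome overlap (uninsured loads 0.9 on
  censoring, −0.45 on outcome).
- `null`: randomized treatment, censoring depends on treatment only,
  β_A = 0.  All four estimators are unbiased here; the true RR is 1
  exactly.
- `selection_bias`: a *stress* scenario for collider bias.  Treatment is
  randomized 50/50; censoring loads on treatment and on four outcome
  predictors (uninsured, NH-White, rural, age), all inside the default
  IPCW covariate set so the censoring model remains correctly specified.
  With the response differential pinned at the study's 40%/52%, the
  asymptotic complete-case bias is bounded near 0.02 on the log-RR scale
  for any collider-parent strength (verified by exact plim computation),
  which is statistically invisible at n = 100 000.  This scenario
  therefore uses a stronger differential — response 30%/65% by arm,
  overall censoring still ≈52% and quit rate still ≈35% — giving an
  asymptotic complete-case bias of ≈ −0.08 log-RR that IPCW removes.
  It demonstrates the *structure* of selection bias, not the magnitude
  observed in any particular quitline.

## Missing income and pooling

Income (7 ordered categories) is imputed under MAR by a
continuation-ratio chain of binary logistic regressions in category
order: model k predicts membership in level k among subjects at level k
or above, fit once among income-observed subjects.  Each of the m
imputations draws parameters from the approximate posterior
N(β̂, V̂) before drawing categories, so between-imputation variance
reflects estimation uncertainty.  Predictors are the outcome plus every
fully observed baseline covariate except registration mode; for censored
subjects the outcome enters as an explicit third "missing" level, keeping
the full cohort imputable.  Degenerate or separated splits fall back to a
smoothed empirical proportion.

Weights are re-estimated and the MSM re-fit within each completed data
set; only the final log risk ratios (and quit rates) are pooled by
Rubin's rules: pooled = mean, T = W̄ + (1 + 1/m)B, df =
(m−1)(1 + W̄/((1+1/m)B))², with B set to exactly zero (df = ∞) when all
estimates are identical.  Pooling on the log scale is standard practice
for ratio estimands.  Whether the source analysis estimated weights
within each imputed data set is not documented; within-imputation
estimation is the defensible default and is flagged as an assumption.

## Numerical choices

- IRLS: statsmodels GLM, max 100 iterations; non-convergence raises with
  the deviance trace.  Fitted probabilities are floored at 1e-6 before
  inversion (count recorded on the weight set); a probability at the
  machine floor raises a positivity error instead.
- Weighted quit-rate CIs use the Kish effective sample size
  n_eff = (Σw)²/Σw².
- Truncation clips at empirical percentiles with linear interpolation.
  Clipping shifts the percentiles of the clipped sample inward, so naive
  re-truncation would keep contracting; `truncate` is a no-op on a set
  already truncated at the same percentiles, making the operation
  idempotent by construction.
- Pearson χ² without continuity correction and pooled-variance t tests
  (matching common statistical-package defaults for descriptive tables);
  a zero expected count raises a structural-zero error rather than
  silently dropping the level.
- Standardized differences for binary levels use
  (p₁−p₂)/√((p₁(1−p₁)+p₂(1−p₂))/2); levels degenerate in both arms
  report SMD 0 with a flag.  |SMD| > 0.1 is flagged as imbalance.

## Limitations

- The sandwich variance ignores weight-estimation uncertainty
  (conservative in the scenarios tested, not guaranteed in general).
- No doubly robust estimator, no covariate adjustment in the outcome
  model, no time-varying treatment or censoring, no survey-calibration
  weighting.
- The imputation chain handles the single income variable only; it is not
  a general chained-equations engine.
- Synthetic covariates are mutually independent; real registry covariates
  are not.
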