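# Methods

## Trial structure and comparison sets

The package models the placebo side of a multiarm platform trial.  Each
placebo patient carries one regimen (route, doses/day, duration); each
treatment defines a matching regimen and an enrollment window (closed
calendar-day interval).  The matched set of a treatment is every placebo
patient whose regimen equals the treatment's regimen and whose enrollment
date lies in the window; the nonmatched set is every other placebo patient
enrolled in the window whose regimen differs.  Matched and nonmatched sets
are disjoint by construction, and the same patient may belong to several
treatments' sets when regimens are shared or windows overlap.  Patients with
an unrecorded regimen are excluded from matched sets always and from
nonmatched pools by default (a config flag can admit them); patients with
missing sex are dropped from the covariate-adjusted hospitalization models
(complete case — a single record cannot move those estimates) but retained in
the PRO models, where imputation handles them.

Two open points were settled as follows.  Windows are explicit configuration
(ISO dates, day resolution); when a dataset carries no windows, the natural
fallback is the span of the treatment's matched enrollment dates.  Nonmatched
pools take *all* chronologically eligible patients; an optional sampling
fraction exposes the alternative of proportional subsampling.

## Synthetic trial generator

The generator draws one placebo population (never duplicating rows) whose
comparison membership is induced purely by regimen and enrollment date.  The
default layout places six regimen cohorts in dated blocks on a
2021-01-15 … 2022-08 calendar such that the seven comparisons come out at
exactly the published sizes (matched/nonmatched 105/97, 319/358, 810/193,
567/171, 322/431, 264/274, 292/265), with 4468 memberships over 2684 unique
patients.  The metformin matched pool is a subset of the fluvoxamine matched
pool (both 10-day oral b.i.d.), 107 early-stage placebo patients enrolled
before every window belong to no comparison, and 3 patients carry no recorded
regimen.  The block layout is an exact solution of the size constraints; it
was solved once by hand and is verified by tests.

Covariates: P(age ≥ 50) = 0.478 with age drawn from a Normal(47, 15.2²)
truncated to the matching side of 50 (and at 18); P(female) = 0.604; sex
missing for exactly one patient; P(BMI ≥ 30) = 0.35 (no published BMI
distribution exists; 0.35 is a plausible obesity prevalence for this
outpatient population and is configurable).  The hospitalization outcome is
Bernoulli with logit = b₀ + b_drift·(day/570) + 0.7·[age≥50] + 0.3·[male] +
0.4·[BMI≥30]; the default drift b_drift = −4.18 moves the base rate from
roughly 17% in early 2021 to under 2% in mid-2022, matching the span of the
published per-arm rates.  There is *no* matched/nonmatched effect in the
generator: placebo is placebo.

PRO instruments use a latent-normal threshold model: each patient has one
latent factor shared by all items (ρ = 0.4), so item marginals equal the
configured category frequencies exactly while items correlate within patient
and across visits.  Day-28 EQ-5D levels put 90% of each dimension at level 1,
giving P(full health 11111) ≈ 0.59 — a majority at the utility ceiling, the
situation the Tobit model exists for.  Missingness blanks both day-28
questionnaires for 15% of patients, MCAR by default; a MAR mode (probability
doubled for age ≥ 50, marginal rate preserved) supports robustness checks.

What the generator does *not* emulate: active treatment arms, site effects on
outcome, within-window temporal interleaving of regimen cohorts (blocks are
contiguous, so some windows have temporally lopsided nonmatched pools — see
Limitations), and real EQ-5D valuation surfaces.

## Event-rate model

Counts x of n are Binomial with a Uniform(0,1) prior on the rate, giving
Beta(x+1, n−x+1) posteriors.  Reported point estimates are posterior means
(x+1)/(n+2) as percentages, rounded half-up to one decimal — this convention
uniquely reproduces the published table's printed values where the raw
proportion does not (e.g. 16.4% at n = 322 has no raw-proportion solution).
Credible intervals are closed-form equal-tailed Beta quantiles (the Monte
Carlo path exists for rate *differences*: four chains of paired draws,
first half of each discarded, 40,000 retained by default — the discard
mirrors burn-in bookkeeping at zero cost even though draws are i.i.d.).
`recover_event_count` inverts a printed percentage to the integer count by
exhaustive scan, erroring when no count is consistent.

## Adjusted odds ratios

Bayesian logistic regression of the outcome on intercept, nonmatched
indicator (the estimand), age ≥ 50, male, BMI ≥ 30, all with Normal(0, 2.5²)
priors — weakly informative, separation-proof, near-flat at these sample
sizes.  BMI enters dichotomized, matching the trial's coding.  The OR point
estimate is the posterior median (robust to the skew of exp); the CrI is the
equal-tailed 2.5/97.5 exp-quantile interval; the equivalence probability is
the posterior mass of 0.8 ≤ OR ≤ 1.2, identical to |OR−1| ≤ 0.2.  Both a
combined nonmatched indicator (default) and one indicator per nonmatched
regimen are supported.

### Sampling

Posteriors are smooth, unimodal and ≤ 8-dimensional, so the engine is an
independence Metropolis–Hastings sampler: the proposal is a multivariate t
(df 10) centered at the penalized mode with 1.1× the Laplace covariance
(exact Hessian for the logistic model, finite-difference Hessian for the
Tobit).  Acceptance rates run 0.6–0.9 and retained draws are near-i.i.d., so
convergence diagnostics are sharp rather than borderline.  Four independent
chains are run from separate seed substreams, first halves discarded
(default 20,000 total iterations → 10,000 retained).  Split-R̂ and
rank-normalized bulk ESS (arviz) are computed per coefficient; the pipeline
warns at R̂ > 1.01 or ESS < 400.  Reduced sizes (4 chains × 2,000) pass the
same gates and are used in tests.

## Dependent-effects meta-analysis

Study-level inputs are the seven group-coefficient posteriors summarized as
(posterior median, posterior SD).  Printed tables can be consumed instead via
`logor_from_ci`, treating a printed 95% interval as Wald on the log scale
with z = 1.959964 (fixed for bit-stable round-trips).

**Covariance.**  Patients are resampled with replacement from the unique
placebo population; every comparison's 2×2 table is rebuilt from resample
multiplicities and its Haldane-corrected (+0.5) unadjusted log-OR recomputed;
the empirical covariance over 1000 replicates estimates the dependence
induced by sharing.  The unadjusted statistic is used because the dependence
is driven by patient sharing, not covariate adjustment (a full adjusted refit
can be plugged in).  Replicates with an empty group are dropped; more than
10% dropped aborts.

**Decoupling.**  `decouple` keeps each study's log-OR and replaces its SE
with an effective independent SE s̃ᵢ.  The bootstrap supplies the dependence
*pattern*; the fitted model supplies the marginal scale — the working
covariance is S = D R D with R the bootstrap correlation and D = diag(model
SEs).  The realization sets s̃ᵢ² = c/wᵢ with wᵢ the row sums of S⁻¹ and
c = Σwᵢ/(1ᵀS⁻¹1), so that inverse-variance pooling of the decoupled
estimates reproduces the GLS pooled point and variance exactly, and a
diagonal S passes SEs through unchanged.  When S⁻¹ has a negative row sum (a
redundant study under strong positive correlation) no positive SE can encode
the negative GLS weight; the weight is floored at a small ε, which preserves
the pooled-variance identity exactly but approximates the pooled point.

**Pooling.**  Fixed-effect inverse-variance with Cochran Q and
I² = max(0, (Q−df)/Q)·100; DerSimonian–Laird random effects (τ² from the
moment estimator, equal to fixed effect whenever Q ≤ df); and a Bayesian
fixed-effect model θᵢ ~ N(μ, s̃ᵢ²), μ ~ N(0, 10²), whose posterior is
conjugate normal and is sampled exactly (arranged as chains with half
discarded for uniform bookkeeping).  The pooled equivalence probability is
the posterior mass of 0.8 ≤ exp(μ) ≤ 1.2.

## Patient-reported outcomes

PROMIS Global-10 is the raw sum of ten 1–5 items (10–50), analyzed by OLS on
group, age ≥ 50, male, BMI ≥ 30 and the baseline total.  EQ-5D-5L states map
to utilities through a `ValueSet` — a total table over all 3125 states
anchored at 11111 → 1.0.  Published national value sets can be loaded from
CSV; the shipped default is a synthetic additive set (level-step decrements
0.05/0.05/0.05/0.06/0.07 per dimension) with the right structural properties
but no valuation pedigree — results under it characterize the machinery, not
any country's tariff.  Because the day-28 utility has a majority at the
ceiling, the group contrast uses Bayesian Tobit regression: observations at
the bound contribute the censored-normal tail probability.  The published
description says "truncated", but a ceiling at the instrument's maximum is
censoring, and the named Tobit model is the censored-data model; it is
implemented as such.  Data *above* the declared bound are a hard error.

Missing day-28 scores are imputed by chained equations with predictive mean
matching (statsmodels `MICEData`; 15 datasets, 10 cycles, 5 donors —
donor/cycle counts are standard defaults, configurable), run per comparison
so the imputation model (group, covariates, baseline, day-28 score) is
congenial with the analysis model.  PMM guarantees imputed values belong to
the observed-donor pool.  Per-imputation estimates (OLS coefficient ± SE, or
Tobit posterior mean ± SD) are combined by Rubin's rules with Barnard–Rubin
small-sample degrees of freedom.  PROMIS rows carry frequentist CIs and
EQ-5D rows Bayesian CrIs; outputs label the interval type per row.

## Numerical conventions

Percentages print at 1 decimal (round half-up), ORs at 2 decimals,
equivalence probabilities at 1 decimal percent.  All randomness descends from
one root seed through named SHA-256 substreams (`derive_seed(seed, stage)`),
so stages rerun in isolation reproducibly and identical runs are
byte-identical.  Problem sizes used by the test suite: reduced MCMC
(4 × 2,000, diagnostics-gated), bootstrap B = 400–1000, 50 replicates for
pooled-interval coverage, 20 for imputation coverage, 10 for Tobit recovery —
sizes chosen so the whole suite completes in a few minutes while keeping
Monte Carlo error well inside the asserted tolerances.

## Calibration results and limitations

- With drift disabled and no group effect (the null configuration), the full
  pipeline's pooled 95% CrI covers OR = 1 in 46/50 seeded replicates, and
  the pooled equivalence probability increases with trial size (mean 0.81 at
  half scale vs 1.00 at full scale over matched seeds).
- With the default drift *enabled*, enrollment-time differences between
  matched and nonmatched groups inside a window act as a genuine confounder:
  some synthetic comparisons show adjusted ORs far from 1 and the decoupled
  Q statistic flags heterogeneity.  This reproduces, in exaggerated form, the
  temporal-bias concern that motivates chronological eligibility windows; it
  is exaggerated because the generator's cohort blocks are contiguous rather
  than interleaved, making some nonmatched pools temporally lopsided.
- Feasible GLS with a bootstrap-estimated covariance is slightly
  anticonservative here: across null replicates the pooled z-scores show a
  modest bias (mean ≈ −0.3) absent from naive independent pooling, because
  estimation error in Σ̂ correlates with estimation error in the effects.
  At the pooled SEs this analysis produces, the effect is visible but does
  not break nominal-level coverage in the calibration experiment.
- The strong negative correlations between concurrent comparisons (each
  other's matched patients serving as nonmatched controls) let GLS pool to a
  much smaller variance than independence pooling would suggest.  This is a
  property of the decoupling contract, not of the data-generating process;
  analyses that should not exploit anticorrelation can pass a diagonal or
  shrunk covariance.
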