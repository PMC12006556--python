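# Methods

`trialcea` implements a within-trial cost-utility analysis for a two-arm
randomised trial comparing swab versus tissue sampling of infected diabetic
foot ulcers, from the UK NHS/PSS perspective at 2021/22 prices. This note
documents the models, the numerical choices, and what the bundled
synthetic-data generator does and does not emulate.

## Outcome construction

**Utilities.** EQ-5D-3L profiles collected at weeks 0, 4, 12, 26, 39, 52
and 104 are scored with the UK general-population time-trade-off value set
(additive decrements; any-problem constant 0.081, N3 term 0.269; the worst
state 33333 scores −0.594). Profiles with any dimension missing are treated
as wholly missing — no partial scoring. The tariff ships as a YAML config
and can be replaced.

**Costs.** Three streams are costed per patient:

* *Hospitalisations* (researcher-collected, continuous): each admission is
  assigned to an HRG-derived category and costed as
  `cost_per_episode + max(0, observed LOS − average LOS) × excess-bed-day
  cost`; amputation admissions add a one-off £529 post-amputation
  rehabilitation cost. When several admissions are recorded for identical
  start/end dates, only the most expensive is kept (ties break on category
  name so the result is order-invariant). The excess-bed-day formula is the
  standard NHS reference-cost convention; the cost tables are stored
  already uprated to 2021/22 and the engine performs no inflation
  arithmetic.
* *Antibiotics* (researcher-collected): units/day × duration × BNF-derived
  unit price; missing duration falls back to a 7-day guideline course,
  missing frequency to a minimum-dosage default, both configurable.
* *Other NHS cost* (self-reported): healthcare-professional contacts from a
  4-week-recall questionnaire, costed at published unit costs and
  extrapolated to the whole interval since the previous visit
  (window cost × interval/4), plus wound-sampling costs (£12 swab, £20
  tissue, £124 bone), charged per sampling occasion.

## Regression models and standardisation

All five regressions share one covariate set: arm, mean-adjusted age
(centred at the sample mean, stored with each fit), sex, number of ulcers,
ulcer area (cm²) and ulcer duration (months), untransformed.

1. **Survival** — lognormal accelerated-failure-time model,
   S(t) = 1 − Φ((log t − x'β)/σ), with right censoring at the
   administrative stop. A selection helper fits exponential, Weibull,
   lognormal and log-logistic AFT models and returns the AIC minimiser
   (BIC reported; disagreement raises a warning). σ is estimated on the
   log scale so PSA draws stay positive.
2. **Utility** — linear mixed model with patient random intercept (REML),
   categorical visit-week main effects and arm×week interactions, so a
   per-week arm contrast exists at every visit. The time structure was an
   open design choice; this is the minimal structure supporting per-week
   arm differences.
3. **Other cost per period** — the same mixed-model structure on the
   extrapolated per-period other-NHS cost (periods are the intervals
   between scheduled visits, labelled by their closing visit).
4. **Hospitalisation** — proportional-odds ordinal logit on the 4-level
   per-period severity scale none < other admission < minor
   amputation/revascularisation < major amputation (worst event in the
   period). A category unobserved in the data is merged upward into the
   next-severe one, with a loud warning. Thresholds are kept in the
   unconstrained parametrisation (first cut, then log-increments) so any
   multivariate-normal parameter draw yields strictly increasing cuts.
5. **Antibiotic prescription** — plain logistic regression on
   any-prescription-in-period. A random-effects logit is deliberately not
   offered: with sparse per-period binary outcomes it routinely fails to
   converge, and the population-average logit is the supported model.

Because several models are non-linear, arm effects are standardised by
**corrected group prognosis**: every patient is predicted under *both*
arms with their own covariates (and their empirical-Bayes random intercept
for the mixed models), and predictions are averaged over the full
population. Incremental results are always tissue − swab.

**Expected QALYs** multiply the fitted survival function by the
conditional utility expectation and integrate: utilities are linearly
interpolated between visit weeks, S(t) is evaluated exactly on a refined
grid (0.1-week steps plus all visit weeks), and the product is integrated
by trapezoid, divided by 52 (1 year = 52 weeks exactly, so the week-104
horizon is 2.0 years). The refined grid keeps the quadrature error of the
product below 1e-4 QALYs against a dense oracle; with instantaneous death
the residual error is bounded by half the first grid step. Utility after
death contributes nothing through the S(t) weighting; there is no separate
death disutility.

**Expected event costs** are built per period: Σ_category P(category) ×
expected category cost for hospitalisation, P(prescription) × expected
course cost for antibiotics, and the mixed-model prediction for other
cost; each period is weighted by the probability of being alive at its
start (so a patient expected to die mid-period is still charged that
period — the convention is configurable in principle and documented here
because the mortality-cost interaction was an open choice). Expected
category costs default to the cost schedule at average stay length and are
replaced by observed within-trial category means when data are available;
the expected course cost is the observed mean antibiotic course cost.

## Missing data

Self-reported streams (EQ-5D and the contact questionnaire) are handled by
available-case analysis and by multiple imputation; researcher-collected
streams (deaths, admissions, antibiotics) are treated as complete and
never imputed.

MI uses fully conditional specification on a patient-wide table (utilities
per visit, other cost per period, with baseline covariates, death
indicator, follow-up time and admission/antibiotic summaries as
predictors). Linear imputation models use proper posterior-predictive
draws (σ² from the scaled inverse-χ², β from its conditional normal, plus
residual noise); binary variables use a logistic model with parameters
drawn from the asymptotic normal. Each chain is initialised from the
observed margins and swept in a fixed order. "100 iterations" of the
source analysis is read as m = 100 imputed datasets with 10 burn-in
sweeps each — the most common reading; both knobs are exposed
(`n_imputations`, `burn_in`) and the test suite and acceptance script use
m = 20 as the package's reduced default problem size. Visits at which the
patient is known dead are excluded from the reconstructed analysis tables
(death is observed, not missing). Pooling of scalar estimates follows
Rubin's rules (total variance = within + (1+1/m)·between).

For deterministic MI reporting the per-imputation CGP results are averaged
(the Rubin point estimate). For MI + PSA — the base case — draws are
cycled over the imputed datasets (parameter uncertainty within each
imputation, between-imputation variability across the cycle).

## Decision layer

Discounting, when enabled, multiplies amounts accruing after week 52 by
1/1.035 — a single-factor second-year adjustment matching the two-year
horizon, applied identically to costs and utilities (off by default; the
source analysis used it as a sensitivity).

ICERs are reported only in the trade-off quadrants; a strategy that is
costlier and less effective is *dominated*, cheaper and more effective
*dominant*. INMB(λ) = λ·ΔQ − ΔC and INHB(λ) = ΔQ − ΔC/λ at λ = £20,000
and £30,000 per QALY, with INHB ≡ INMB/λ by construction.

PSA draws every model's full parameter vector from MVN(θ̂, Σ̂), preserving
within-model correlation; draws are independent *across* the five
separately fitted models, since no joint covariance is estimable — a
documented limitation. For the mixed models the draws cover the fixed
effects; variance-component uncertainty is not propagated. 1000 draws by
default. The CEAC reports the fraction of draws with strictly positive
INMB (ties count against adoption) over λ ∈ [0, 50,000] in £1,000 steps.

## Synthetic-data generator

No patient-level data are deposited for this trial, so the generator
produces datasets with the assumed statistical structure, calibrated to
the published marginals:

* baseline covariates match the published arm-specific moments (age:
  normal 65.7 (11.39) swab / 59.7 (12.98) tissue, truncated to [18, 100];
  sex 86.7%/78.4% male; ulcer area and duration lognormal matched to the
  published medians and IQRs; ulcer count 1 + Poisson(0.32));
* recruitment is uniform over a 155-week window with an administrative
  stop at week 207 (recruitment closed plus one year), so week-104 visits
  exist only for roughly the first two-thirds of recruits;
* outcome streams are drawn from exactly the families the analysis fits
  (lognormal AFT survival; latent mixed-model utility mapped to the
  EQ-5D-3L profile with the nearest tariff score, ties to the smallest
  label, which round-trips exactly with the scorer; proportional-odds
  admissions expanded to concrete costed events; logistic prescription
  with a realistic drug mix; Poisson contact counts), so the regression
  engine is well-specified and parameter-recovery tests are meaningful;
* default effect sizes were set once to land in the published ballpark:
  survival better with tissue (arm log-time coefficient +0.6, giving
  standardised survival ≈0.96/0.89 at week 52), utility lower with tissue
  at week 52 (−0.15) and higher at week 104 (+0.10), antibiotic
  prescription odds higher with tissue (+0.6 on the logit), contact rates
  25% higher with tissue up to week 52;
* missingness has two layers: administrative censoring (monotone, from the
  recruitment calendar) and MAR questionnaire dropout whose per-visit
  probability depends only on age and the previous observed utility, with
  marginal rates calibrated to the published attrition table (week-104
  missing-but-alive fraction ≈ 68–76% of participants). Deaths,
  admissions and antibiotics are never made missing.

What the generator does **not** emulate: informative (MNAR) dropout,
measurement error in self-reported resource use, free-text adverse-event
coding, site effects and recruitment clustering, and correlation between
the outcome streams beyond what the shared covariates and the utility
random intercept induce. Passing tests therefore show that the estimators
recover the truth under the analysis's own assumptions — not that those
assumptions hold in any real dataset.

## Problem sizes and tolerances

Parameter-recovery suites use 200 replicates of n = 500 with a ≥90%
empirical coverage bound on nominal 95% CIs. The end-to-end null-effect
check runs 150 patients, m = 20 imputations and 200 PSA draws and requires
the incremental estimates to sit within 3 Monte-Carlo standard errors of
zero. The acceptance script runs the full pipeline at the default study
size (75 per arm) with 1000 PSA draws and m = 20. Optimiser tolerances are
1e-8 with a 500-iteration cap; non-convergence raises, never passes
silently. Covariance matrices are validated symmetric PSD to 1e-8
(relative); numerical asymmetry below that is symmetrised.

## Known limitations

* The ordinal severity scale collapses heterogeneous admission categories;
  expected category costs are means, so within-category cost variation is
  not propagated into the PSA.
* Across-model independence in the PSA understates (or overstates) joint
  uncertainty to the extent the models' estimation errors are correlated.
* The antibiotic arm effect is modelled on prescription probability; a
  log-cost linear model is a plausible alternative reading of the source
  analysis and can be run through the same mixed-model machinery on
  log-costs, but is not the default.
* MI imputes on the utility scale, not on EQ-5D-3L profiles; imputed
  utilities are not constrained to the 243 tariff values.
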