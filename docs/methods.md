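# Methods

`bpscreen` implements a two-stage procedure for antenatal blood-pressure
screening on synthetic population cohorts, together with the evaluation
machinery (external validation, recalibration, fixed-sensitivity operating
points, sequential rule-out screening) that turns the fitted models into a
screening strategy.

## Measures and outcome definitions

All blood-pressure information enters as mean arterial pressure,
MAP = (SBP + 2·DBP)/3 (mm Hg), computed unrounded from each routine
reading.  Per pregnancy the analysis variables are the *initial* MAP (the
first antenatal measurement, accepted only when taken before 18 completed
weeks) and gestation-specific MAP at 20, 25, 28, 31, 34 and 36 weeks,
taken from the visit closest to the target week within a ±2-week window;
ties in distance resolve to the earlier visit, since that measurement
would have been available first clinically.  Outcomes:

* **Pre-eclampsia (PE)** — primary flag from the pregnancy record
  (mirroring a recorded clinical diagnosis); a visit-based ISSHP
  derivation is provided (`define_preeclampsia_isshp`): at least two
  visits strictly after 20 weeks each showing SBP ≥ 140 and/or DBP ≥ 90
  together with dipstick proteinuria ≥ 1+.  The reading that requires BP
  and proteinuria elevation at the *same* two visits is the default; the
  looser reading (two hypertensive and two proteinuric visits,
  possibly different ones) sits behind `same_visit=False`.
* **Preterm birth** — delivery before 37.0 weeks.
* **Small for gestational age (SGA)** — birthweight below the empirical
  10th centile of residuals from a within-cohort cubic regression of
  birthweight on gestational age at delivery (internal standardisation;
  no sex adjustment).  The flag is location-invariant by construction and
  prevalence is 10% on any complete cohort.

## Stage 1 — MAP normograms

On the *normal-pregnancy subset* (no PE, no essential hypertension, no
diabetes, term delivery, birthweight between the internal 10th and 90th
centiles — roughly 70% of a population cohort) a two-level linear mixed
model is fit per parity stratum (nulliparous / multiparous):

    MAP_ij = x_ij' beta + z_ij' b_i + e_ij,
    b_i ~ N(0, G),  e_ij ~ N(0, sigma2)

* Fixed part: restricted cubic spline of gestational age with knots at
  11, 18, 30, 36, 40 weeks (linear term + 3 restricted terms, truncated-
  power construction scaled by (40−11)² for numerical stability), plus
  BMI-category (WHO cuts 18.5/25/30) and smoking main effects and their
  interactions with every spline term — 25 coefficients per stratum.
* Random part: individual intercept plus random coefficients on the
  linear and first spline terms (3×3 unstructured G).  A different number
  of random terms (1–5) is available via `n_random`.
* Estimation: REML (statsmodels `MixedLM`).  The random-effect design
  columns are rescaled to comparable magnitude internally and G mapped
  back to natural units; without this the variance optimization is poorly
  conditioned (columns spanning three orders of magnitude).  Convergence
  is reported on the fit object, never silently ignored.

An in-package evaluator `marginal_loglik` assembles the exact per-woman
joint normal N(Xβ, ZGZ′ + σ²I) so tests can verify the likelihood against
independently computed multivariate-normal densities.

**Conditional normative values.**  For any woman the expected MAP at a
target gestation, given her initial measurement, is the Gaussian
conditional mean

    E[MAP(t) | MAP(t0)=y0] = m_t + (z_t' G z_0) / (z_0' G z_0 + sigma2) · (y0 − m_0)

with m the fixed-part means of her covariate cell and z = (1, t, s1(t)).
The observed value's variance includes the residual (a noisy reading);
the predicted quantity is the noise-free expected pressure.  The
*deviation* (observed − expected) is the stage-2 predictor of model 3.

Identifiability note: with ~9 visits per woman over 9–41 weeks, the
individual elements of G for the slope/spline terms are only weakly
identified — an independent REML implementation (lme4) reproduces our
estimates to three digits while both can deviate 25–35% from generating
values.  The well-identified quantities, which the conditional normative
actually consumes, are σ² and the marginal trajectory variance
z(t)′Gz(t); parameter-recovery tests target those.

## Stage 2 — prediction models

For each outcome and each index gestation g ∈ {20, 25, 28, 31, 34, 36},
logistic models are fit on women *not yet delivered* at g:

* **Model 1** — early-pregnancy characteristics + initial MAP.
  Candidates: BMI (continuous), height, age ≥ 35, parity (two indicator
  contrasts vs nulliparous), smoking, essential hypertension, previous
  gestational hypertension, diabetes, previous gestational diabetes,
  non-white ethnicity.  Backward elimination drops the group with the
  largest pooled Wald P value until all remaining groups have P ≤ 0.2;
  multi-column groups (parity) are tested jointly; initial MAP is forced.
  Selection happens once, on the full booking population; later
  gestations refit the same term set on their shrinking risk sets (one
  clinical score, re-anchored).
* **Model 2** = model 1 + MAP at g.  **Model 3** = model 1 + deviation at
  g.  **Model 4** = model 1 + both; a rank check on the design is logged
  because the deviation is an affine function of MAP and covariates when
  the normative value is linear in included terms.

Under multiple imputation every model is fit per completed table and the
coefficients pooled by Rubin's rules; with one (complete) table the plain
ML fit is used.  Separation triggers a ridge-penalized fallback with a
logged note.  Women whose PE is diagnosed before g remain in the risk set
(the models predict PE at any stage of pregnancy).

## Missing data

Chained-equations multiple imputation (default m = 20 chains, 10 cycles):
each incomplete variable is refilled from a posterior-draw conditional
model given all other analysis variables *and the outcomes* — Bayesian
linear regression for continuous variables (σ² from the scaled inverse
chi-square, β from its normal posterior, residual noise added), logistic
with parameter draws for binary, multinomial logistic for parity.
Initial fill is a random draw from the observed margin.  Normative values
are never imputed: they are recomputed passively in every completed table
from that table's (possibly imputed) covariates and initial MAP, so
imputation uncertainty propagates into the deviations.  Development and
validation cohorts are imputed separately.  Predictive-mean matching is
not used; the posterior-draw normal model is adequate for the roughly
Gaussian MAP variables and fully specified.

Rubin's rules: pooled estimate = mean; total variance = within +
(1 + 1/m)·between; df = (m−1)(1 + W/((1+1/m)B))².  The multivariate
pooling statistic (Li–Raghunathan–Rubin F reference) backs the joint
Wald tests of backward selection; with m = 1 it degenerates to the
ordinary Wald chi-square.

## Evaluation, recalibration, operating points

* **AUC** — concordance probability by rank statistic (ties counted ½),
  variance by the DeLong placement-value method; under multiple
  imputation AUCs are averaged and variances Rubin-pooled.  Model
  comparisons use a two-sided Wald test with the SE of the paired AUC
  difference from B = 500 bootstrap resamples of individuals.
* **Calibration** — observed event proportions with Wilson intervals
  across tenths of the predicted risk.
* **Recalibration** — logistic fit of the outcome on the development
  model's linear predictor in the validation cohort gives (a, b); the
  recalibrated risk is expit(a + b·lp).  By the logistic score equations
  the recalibrated mean risk equals the observed prevalence
  (calibration-in-the-large = 0).
* **Operating points** — `threshold_for_sensitivity` returns the largest
  threshold keeping at least the target fraction of cases test-positive
  (score ≥ threshold is positive); `classification_metrics` reports the
  full 2×2 table, sensitivity/specificity/PPV/NPV with Wilson intervals
  and likelihood ratios with log-scale intervals, and reports undefined
  ratios as absent with a reason instead of NaN arithmetic.

## Sequential rule-out screening

Model 1 screens everyone at booking; women at or above the threshold are
re-screened with model 2 at 20, 25, 28 and 31 weeks; a woman below the
threshold at any stage exits to low-risk care and is not re-screened;
women delivering between stages exit the flow and are tallied so that
counts conserve exactly at every stage (asserted on every run).  The
single threshold is the unweighted average, over the six index
gestations, of the 99% (or 95%) sensitivity cut of model 2's scores —
computed after an initial booking screen, within the surviving high-risk
group.  The development-cohort threshold is applied to *unrecalibrated*
validation scores, matching the published flowchart construction;
recalibrated models remain available for the operating-point tables.
If the table carries clinical onset times, already-diagnosed cases stay
in the high-risk stream without re-scoring (they are under surveillance);
this is configurable.

## Synthetic cohorts

The generator emulates two UK population cohorts: a development cohort
(n = 13 000, PE ≈ 2.4%) and a validation cohort (n = 3 005, PE ≈ 2.9%,
more overweight/obese and older women, fewer smokers, far more previous
gestational hypertension).  Covariates are drawn from the cohorts'
published category frequencies; BMI is drawn category-first (exact
category marginals) with within-category values uniform (obese:
30 + Exp(2.8)).

**Trajectories.**  Each woman's latent MAP is a per-parity-stratum
population spline (anchored to a curve with a nadir near 20 weeks rising
to ~84 mm Hg at 36 weeks in the unaffected group), centred covariate
offsets (BMI category, smoking, essential/previous gestational
hypertension), an individual random effect on (1, t, s1(t)) with
unstructured covariance (intercept SD 7.2 mm Hg, negative
intercept–slope correlation), and i.i.d. residual (SD 5.3 mm Hg).
Offsets are centred against the configured covariate marginals so the
population mean curve stays anchored.  SBP/DBP pairs are back-generated
with a per-visit pulse-pressure model PP ~ N(45, 5²):
SBP = MAP + ⅔PP, DBP = MAP − ⅓PP, rounded to 1 mm Hg (clinical
convention), so (SBP + 2·DBP)/3 reproduces the latent MAP to ≤ 0.5 mm Hg.

**Visits.**  Booking uniform in [8, 17) weeks, then nominal visits at
20, 25, 28, 31, 34, 36, 38, 40 weeks with N(0, 0.7²) jitter, truncated at
delivery — the standard UK nulliparous schedule.

**Pre-eclampsia.**  Risk is logistic in the woman's random intercept
(0.17 per mm Hg), her post-nadir slope deviation (9.0 per mm Hg/week),
and classical risk factors; the intercept is solved by root-finding on
the realized cohort so mean risk equals the configured prevalence.
Cases receive a pressure ramp of 1.5 mm Hg/week starting 5 weeks before
clinical onset, and onset is *delivery-linked*: onset = delivery −
U(2.5, 6.5) weeks (floored after 20 weeks), with term deliveries of
cases capped at 40.5 weeks — pre-eclampsia is managed by delivering the
baby, so a diagnosed pregnancy neither runs far past term nor stays
trajectory-quiet while undelivered late in gestation.  An independent
onset draw was tried first and rejected: it produces quiet undelivered
cases at 34–36 weeks that a BP-managed case cohort cannot contain, and
it collapses the fixed-sensitivity screening thresholds.  Proteinuria
flags appear after onset (p = 0.9) and at a background rate (0.01)
otherwise.  The covariate log-odds are scaled ×1.5 above the cohorts'
univariate cross-tab odds ratios so the booking model's discrimination
lands in the published 0.77–0.81 AUC band (marginal odds ratios
understate joint discrimination).

**Preterm and birthweight.**  The preterm flag is drawn first (logistic,
OR 7 given PE, base rate solved to the configured marginal prevalence)
and delivery gestation drawn conditional on it (truncated normals on
[28, 36.9] / [37, 43], PE shifting both earlier), so `preterm ==
ga_delivery < 37` holds exactly.  Birthweight follows a gestational-age
curve plus shifts for PE (−290 g, sized so the implied SGA odds ratio
given PE is ≈ 3) and smoking (−170 g) with 430 g residual SD.

**Missingness.**  MAR: per-visit drop probability (default 5%, optional
separate rate after 18 weeks) and per-covariate missingness tilted on
the logit scale by observed smoking status and age — never by the value
being removed.  `apply_missingness` returns a copy; the truth cohort
remains available for recovery tests.

**Validation label noise.**  A clinical-diagnosis noise model
(sensitivity 0.85, specificity 0.995) can be switched on for validation
cohorts to emulate record-based PE labels; the default keeps exact labels.

### What the generator does not emulate

Antihypertensive treatment, twin pregnancies, device/measurement-protocol
error, serial residual correlation beyond the random effects (an AR
extension would be a config addition), sex-specific birthweight
standards, and informative (MNAR) missingness.  Passing tests therefore
demonstrate that the *pipeline* recovers what it assumes, under an
idealised data mechanism — not that real cohorts satisfy those
assumptions.

## Numerical choices and problem sizes

* REML tolerance: statsmodels defaults with lbfgs→cg fallback, 500
  iterations maximum; non-convergence flagged on the fit.
* Stage-1 fits inside large-cohort analyses use a seeded random
  subsample of women per stratum (2 500–3 000 by default); the
  population curves are estimated with ample precision well below the
  full cohort size.
* Acceptance-scale analyses use the cohort sizes of the emulated
  studies (13 000 development, 3 005 validation); parameter-recovery
  checks use 2 000 women × ~9 visits over 5 seeds; bootstrap model
  comparisons use B = 500.
* Degenerate inputs: zero random-effect covariance collapses women onto
  their cell curve (allowed; conditioning then ignores the initial
  value); non-PSD covariance and probabilities outside [0, 1] are
  rejected with explicit messages; empty normal subsets, all-case
  cohorts, and 100%-missing variables raise errors rather than degrade.

## Known limitations

* The conditional normative conditions on the initial measurement only;
  conditioning on several earlier readings (full BLUP) would be a small
  extension of the same Gaussian algebra.
* Backward selection on pooled Wald statistics yields one final model;
  per-imputation selection with majority voting is not implemented.
* The bootstrap AUC comparison resamples one designated completed table
  rather than combining resampling with imputation uncertainty.
* Quantile reference bands for chart display and decision-curve analysis
  are out of scope.
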