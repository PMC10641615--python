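# Methods

This note documents the models, numerical choices and limitations behind the
package, in the order the pipeline runs them.

## Synthetic cohort

The simulator emulates the statistical structure of a Swedish
health-screening cohort (ages 35–65, recruitment 1990–2016) at the level the
downstream analysis needs; it makes no attempt to reproduce any real
database.

**Diet.** Food-group intakes (12 groups, g/day) are log-normal with a
Gaussian copula: right-skewed, non-negative and correlated, which matches
the shape of FFQ intake data.  The default correlation structure encodes a
"prudent vs meat-centred" gradient (vegetables–fruit +0.45, red meat vs
vegetables −0.25, etc.) on top of a weak common factor of 0.10; the full
matrix is configurable and validated for positive definiteness.  Energy and
nutrients are **derived** from the intakes through the composition table
rather than drawn independently, so energy standardisation removes a real
signal.  Default medians were set so that derived energy lands in the
realistic FFQ range and, combined with a 45 % under-reporting probability
and a ×0.70 reporting factor, about 47 % of women and 44 % of men screen as
probable under-reporters (food intake level < 1.2) — the prevalence reported
for Swedish screening cohorts.  Under-reporting multiplies only the
*reported* energy and intakes; `true_*` columns retain the generating truth
for oracle checks.  Because the bias is uniform across foods, the
energy-adjusted score of a reported diet equals that of the true diet — by
design, since that invariance is exactly what energy adjustment provides.

**Reference tables.** The synthetic composition table uses Nordic-magnitude
per-100-g values; the emission table makes red/processed meat dominant
(25 kg CO₂e/kg) with plant groups ≤ 1, the qualitative feature that drives
the sensitivity analyses.  Both are overridable per cell.

**Survival.** Event times follow a Weibull hazard
`h(t) = h₀ k t^(k−1) exp(βᵀx + β_s·s_true)` with shape k = 1 (exponential)
by default; k ≠ 1 exists to build proportional-hazards violations for
diagnostic tests.  Default covariate effects (age +0.09/yr, BMI +0.02,
smoking, education, activity) and baseline hazard 3×10⁻⁴ events/person-month
produce a ~6–8 % death rate over a median ~13 years of follow-up, in the
range of population screening cohorts.  Follow-up is censored at
2016-12-31; months are days/30.4375.  A small fraction of records (0.2 % per
criterion) is deliberately corrupted to exercise the exclusion filters.

**What the simulator does not model:** item-level FFQ responses, covariate–
diet dependence (education does not shift intakes), seasonal or secular
diet trends, competing risks, and differential (non-uniform) misreporting.
Passing tests therefore demonstrate correctness of the estimators under the
stated generating model, not robustness to those real-data features.

## Exclusion filters

Criteria: (i) ≥ 10 % missing intake items or missing portion sizes,
(ii) height outside 130–210 cm, (iii) weight < 35 kg, (iv) BMI < 15 or
missing, (v) age outside 35–65, (vi) food intake level (FIL = reported
energy / Schofield-predicted BMR) outside the 1st–99th percentiles.  Only
BMI treats missingness as exclusion; a missing FIL input leaves the record
unevaluable for (vi) rather than excluded.  FIL < 1.2 flags probable
under-reporting but never excludes.

Choices where the convention was open:

* **BMR equation:** Schofield weight-only, by sex and age band (18–30,
  30–60, ≥ 60), 1 MJ = 239.006 kcal.  Configurable, because the choice
  shifts the whole FIL distribution.
* **Percentile population:** per sex, computed on the records surviving
  criteria i–v, with the linear-interpolation empirical percentile.  Pooled
  computation and other bounds are configurable.
* **Idempotence:** re-estimating percentile bounds on already-filtered data
  necessarily trims a further ~2 % each pass (the 1st percentile of a
  filtered sample sits above the old bound), so no percentile definition
  makes blind re-application a fixed point.  The audit log therefore records
  the bounds used, and re-running with `ExclusionConfig(fil_bounds=...)`
  from the log is exactly idempotent.  Criteria i–v are idempotent
  unconditionally.
* **One observation per subject:** earliest visit (baseline semantics),
  same-date ties broken by input ordinal; configurable to latest.

## Metrics and score

Nutrients are intake-weighted sums of per-100-g amounts; E% fields use
9 kcal/g for fatty acids and 4 kcal/g for added sugar (the 4 kcal/g protein
and 7 kcal/g alcohol constants are fixed but unused by the index).  A
zero-energy diet gets E% = 0 with a warning — it only arises in degenerate
fixtures.  Energy adjustment multiplies gram-based fields by
(2000 or 2500)/energy and leaves E% fields untouched; GHGE is adjusted with
the identical factor (equivalent to recomputing a per-kcal density for a
fixed diet).

The shipped component specification (`sheia15-2015`) is data, not code:
vegetables + fruit 500 g/d; seafood 250 g/week (2–3 × 125 g servings, lower
bound) per day; whole grains 70/90 g/d (women/men); fibre 25/35 g/d; MUFA
10 E%; PUFA 5 E%; SFA 10 E%; red/processed meat 500 g/week per day; added
sugar 10 E%.  The moderation transform `2 − ratio` is what produces raw
values below 0 that the truncation rule recodes; both the transform and the
recommended amounts can be swapped without code changes.  Where a
recommendation is an interval (MUFA, PUFA), the adequacy denominator is the
lower bound.

## Quintiles

Rank-block quantiles within sex × baseline age group (35–44, 45–54, 55–65):
subjects are sorted by (score, subject_id) and cut into five contiguous
blocks whose sizes differ by at most one, remainders to the lowest-numbered
blocks.  With the many tied totals a capped-sum index produces, threshold
quantiles would give badly unbalanced groups; ranking with a deterministic
tie-break also makes labels independent of input row order.  Strata smaller
than the group count warn and yield degenerate labels rather than failing.

## Cox regression

The Newton–Raphson maximiser of the partial likelihood uses Breslow tie
handling by default — matching the convention of the SPSS implementation
this kind of analysis is usually run in — with Efron available and
preferable under heavy ties.  Convergence: |Δ log-lik| < 10⁻⁹ or gradient
max-norm < 10⁻⁶ within 100 iterations, step-halving on any decrease.
Monotone likelihoods (separation) are reported as an explicit non-converged
result naming the runaway term (|β| > 10); rank deficiency (with an implicit
intercept) raises an error listing the collinear terms.  Wald CIs use
z = 1.959964.  Estimates and standard errors were verified against R
`survival::coxph` (both tie methods) and lifelines, and against brute-force
maximisation of the explicit partial likelihood on small datasets.

Model conventions: numeric covariates are centred (affects only the
baseline); age² is the square of centred age, keeping it nearly orthogonal
to age; categorical covariates use reference-level indicators (first
declared level); BMI enters continuously; year of participation enters
continuously.  The basic model adjusts for age and age²; the adjusted model
adds BMI, education, physical activity, smoking and calendar year.

**Purposeful selection** (Bursac): univariable screen at p < 0.25 (block
likelihood-ratio tests, so multi-level factors are screened as a unit);
backward elimination at p > 0.10 unless removal changes any remaining
coefficient by more than 20 % (such covariates are locked in as
confounders); a single re-offer of excluded candidates at p < 0.15.  Every
fit and decision lands in the audit trail.

**Proportional hazards:** Grambsch–Therneau score test on Schoenfeld
residuals against transformed time (rank by default; identity and log
available), per term in the Therneau scaled-residual form and globally;
numerically identical to lifelines' `proportional_hazard_test`.  Fewer than
10 events sets a low-information flag.

## Rank tests

Mid-ranks everywhere; tie-corrected null variances; two-sided p by doubling
the smaller tail; Bonferroni multiplies by the number of tested pairs and
clamps at 1.  Mann–Whitney U enumerates all assignments exactly for N ≤ 12
and otherwise uses the tie-corrected normal approximation with continuity
correction.  Jonckheere–Terpstra switches to its permutation null
automatically when any group has fewer than 5 values.  Permutation p-values
use the add-one rule (b+1)/(m+1) with a recorded seed, so they are never
exactly zero and are reproducible.

## Problem sizes used in the checks

The distributional checks run at sizes chosen to make Monte-Carlo noise
negligible relative to the asserted tolerances: correlation recovery at
n = 20 000 (±0.03); hazard-ratio recovery with 200 cohorts of n = 5000
(Wald-CI coverage asserted within 93–97 %); test calibration with 2000 null
replicates (3σ binomial band around α = 0.05); asymptotic-vs-permutation
agreement at 10⁴ permutations.  The acceptance script simulates a
30 000-subject cohort, large enough for stable medians and sub-percent CI
granularity on the quintile hazard ratios.

## Known limitations

* The simulator's independence of diet and non-dietary covariates means
  confounding-adjustment machinery is exercised by dedicated constructions
  in the tests, not by the default cohort.
* GHGE uncertainty (LCA error) is not propagated; emission factors are
  treated as exact constants.
* Only all-cause mortality is modelled — no competing risks, time-varying
  covariates or frailty.
* Baseline-characteristics tables report raw category percentages;
  age-standardised percentages are not implemented.
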