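# Methods

`trialcea` implements a within-trial economic evaluation of a three-arm
randomized trial from a health-sector perspective: an internet discussion
forum (arm 1, control), forum plus psychoeducation modules (arm 2), and
forum plus psychoeducation plus CBT-based tools (arm 3), followed for 12
months with assessments at months 0, 3, 6, 9 and 12.  Outcomes are
depression severity (MADRS, clinician-rated, 0-60, lower better) for the
cost-effectiveness analysis and SF-6D utilities/QALYs for the cost-utility
analysis.  All amounts are 2018-19 Australian dollars; no discounting is
applied over a 12-month horizon.

## Costing

Intervention delivery is microcosted from a resource ledger.  The website
development/maintenance total is a fixed cost apportioned across the three
arms by complexity shares (0.19/0.38/0.43 in the worked example); computer
leases and personnel time (forum monitoring and debriefing wages, loaded
with 25% employer overheads) are apportioned participant-proportionally
(n_arm / n_total).  Internal arithmetic is exact decimal.  Display
rounding is half-up: line items to cents, per-participant averages to
whole dollars.  An arm's total is the rounded sum of its *unrounded* line
items, and the grand total re-sums the rounded arm totals — this is the
convention under which the worked example's table reproduces exactly to
the cent, and it can leave a one-cent discrepancy between a displayed
total and the sum of displayed line items.

Self-reported service use (counts by category per 3-month recall window)
is priced by a unit-cost table; a wave with no questionnaire has a missing
cost, never zero.  The per-capita delivery cost of a participant's arm is
attached at the 3-month wave; the participant's health-sector total is
delivery plus priced service use over months 3-12.  Baseline (month 0)
cost is a covariate only.  In the base-case "complete-sum" rule the total
is missing unless all four follow-up waves are observed; model-based and
imputation analyses relax this.

The threshold analysis solves for the arm-2 delivery cost c* that
equalizes mean totals with control; because delivery cost enters every
total additively, c* = current delivery cost + (mean_a − mean_b) in closed
form, with the means supplied by any estimator.  The population-rollout
analysis spreads the website (fixed) cost over all potential users
(population × prevalence × the fraction using services for their mental
health, 0.677) while equipment and personnel remain per-participant
variable costs.

## Outcomes

SF-6D scoring is table-driven: utility = 1 − Σ dimension decrements − a
"most severe" term applied once when any dimension sits at its worst
level, clamped at the table's floor.  The published British
general-population coefficient set is licensed and not redistributed; the
package ships a clearly labelled synthetic toy table with the same
structure (six dimensions, monotone decrements, floor 0.29) so the
algorithm is fully exercised, and users supply the licensed table as a
CSV.  Whether the most-severe adjustment applies is configurable and
defaults to on.

QALYs are the trapezoid area under the utility trajectory at months
0/3/6/9/12 (interval 0.25 years, no within-interval interpolation beyond
linear).  Effect differences follow the reporting conventions: QALY
differences are arm minus control; depression differences are expressed
as the intervention's extra improvement (control minus arm on the MADRS
scale), so positive always favours the intervention.

## Estimation

**Base case (MMRM).**  Follow-up costs or utilities are modelled jointly
across the four waves with arm × wave cell means, shared adjustment for
the baseline outcome, sex and national origin, and an unstructured 4×4
within-participant covariance estimated by REML.  Every participant with a
baseline value and at least one observed follow-up contributes, which is
what makes the estimator valid under missing-at-random dropout.  The
implementation profiles the fixed effects out of the restricted
likelihood and optimizes the 10 free parameters of the covariance
Cholesky factor (log-parametrized diagonal) with L-BFGS, grouping
subjects by missingness pattern; with complete data the solution
coincides with closed-form GLS (verified against that formula in tests).
Noise-free inputs are detected and returned as exact least squares with
zero standard errors, since the restricted likelihood is unbounded there.
Wald CIs use the normal approximation, matching the large-sample
bootstrap companions; α = 0.05 two-sided throughout, no multiplicity
adjustment.

Per-wave adjusted differences are cell-mean contrasts.  The total-cost
difference sums the four wave contrasts.  The total-QALY difference
applies the trapezoid AUC weights (0.25, 0.25, 0.25, 0.125 on months
3/6/9/12) to the utility contrasts, with the baseline difference adjusted
to zero — the self-consistent AUC convention, rather than the unweighted
sum of per-wave differences.

**Sensitivity GLMs.**  Identity-link GLMs on per-participant totals:
gamma family for the right-skewed cost total, inverse-Gaussian for QALYs,
each adjusted for the baseline outcome, sex and national origin.
Nonpositive outcomes under a positive-support family are handled by a
configurable policy: shift by half the smallest positive observed value
(default) or fall back to gaussian identity.  Family choice is guided by
the modified Park test — regress log squared residuals on log predictions;
the slope estimates the variance power and the recommended family is the
nearest of gaussian (0), Poisson (1), gamma (2), inverse-Gaussian (3).
Link adequacy combines three checks: the correlation of raw residuals
with predictions, the Pregibon test (refit with the squared linear
predictor added), and a modified Hosmer-Lemeshow F-test that decile mean
residuals are jointly zero.  Note the raw-residual correlation is
identically zero for least-squares fits (residuals are orthogonal to
predictions by construction), so that check is conservative there and
only informative for non-gaussian GLM weighting.

**Missing-data diagnostics.**  Logistic regression of 12-month
completeness (cost and utility observed at every follow-up) on sex,
country, arm and baseline outcomes, reported as odds ratios; degenerate
outcomes and quasi-separation are flagged as errors rather than silently
reported.

## Resampling inference

The bootstrap resamples participants with replacement *within arm*
(preserving the randomized design's arm sizes), applies an incremental
pair estimator to each resample, and always returns exactly B replicates
(failed replicates are redrawn and counted).  ICER classification:
dominant iff ΔC < 0 and ΔE > 0, dominated iff ΔC > 0 and ΔE < 0,
otherwise the ratio; |ΔE| below 1e-9 makes the ratio undefined and the
net monetary benefit λ·ΔE − ΔC is reported instead.

The reordered percentile CI orders the replicates by angle on the
cost-effectiveness plane, starting at the positive-cost axis and
proceeding counterclockwise (NW → SW → SE → NE), so economic preference
is monotone along the ordering; the bounds are the ⌈Bα/2⌉-th and
⌊B(1−α/2)⌋-th order statistics, each labelled by its quadrant (dominant
in SE, dominated in NW, otherwise the ratio), and a distribution touching
all four quadrants is flagged as hard to interpret.  The exact ordering
convention is not uniquely pinned down in the literature this follows, so
the implementation is documented here and validated against a brute-force
comparator-sort oracle rather than assumed.  CEACs count replicates with
strictly positive net monetary benefit; ties count as not cost-effective.

Reported base-case inference pairs the repeated-measures point estimates
with complete-case bootstrap CIs (bootstrapping the adjusted least-squares
mean difference on completers), the same hybrid the evaluation convention
this package follows uses for its headline tables.

**Imputation nested in the bootstrap.**  For each of B resamples, the
wave-level costs, utilities and depression scores are completed once by
chained equations (10 cycles) with predictive mean matching (k = 5
donors), then the GLM incremental pair is computed; the resulting
distribution is summarized by the reordered percentile method.
Imputation models are linear in the baseline outcomes, sex and national
origin plus the current completed values of the other wave-level
variables, and are fit *separately within each randomized group*: donors
never cross arms, so the treatment contrast is not shrunk toward the
pooled mean when missingness is heavy (with ~60-70% of a wave missing and
low predictive R², pooled-donor matching measurably attenuates the arm
difference).  PMM only ever copies observed donor values, so imputations
stay in the observed support.  With no missing data the procedure reduces
exactly to the plain GLM bootstrap under the same seed policy.

## Synthetic trial generator

No trial data are deposited, so the generator is the package's test bed;
its defaults emulate the study conditions:

- **Design**: 102/102/100 randomized (fixed arm sizes, as under permuted
  blocks), 82% female, country mix US 0.385 / Australia 0.335 / other
  0.281, waves at months 0/3/6/9/12.
- **Costs**: per wave and category (medical, psychological, acute care,
  support), a participant-level gamma frailty (shape 1.2, mean 1)
  multiplies gamma intensities (shape 0.3); counts are Poisson given the
  intensity over the unit cost, so priced counts have exactly the stated
  mean and are right-skewed integers.  Category means are calibrated so
  the 12-month arm totals (service use plus delivery cost) sit near
  15,175 / 9,431 / 15,518 with the arm-1-vs-arm-2 gap concentrated in
  acute care, and the arm-1 total-cost SD lands near 17,000.  The
  arm-3 SD printed for the emulated study (~31,000, twice its mean) is
  heavier-tailed than this gamma family produces at the same mean; the
  generator does not chase it, and analyses of real data with such tails
  should expect wider intervals than the synthetic checks suggest.
- **Utilities**: baseline mean 0.63, random intercept SD 0.08, residual
  SD 0.06 (QALY SD ≈ 0.085, within the 0.062-0.094 range being
  emulated), truncated to [0,1]; arm drifts default to the small per-wave
  differences of the emulated tables (arm 2: 0.0005/0.003/0.004/0.004).
- **Depression scores**: baseline mean 21 (SD 8 split 6 between / 5.3
  within), control drifting to 18 by month 12, arm-2 advantages
  4/5.5/3.6/3.8 points and arm-3 advantages 1.1/4.8/2.5/3.6, rounded to
  integers and clipped to 0-60.
- **Missingness**: marginally logistic in sex and wave with intercepts
  solved so population completion hits 39.5/33.9/35.5/29.3% at months
  3/6/9/12 (female completion OR 0.6); across waves a Gaussian copula
  with a single engagement factor (correlation 0.95) makes completion
  patterns nearly nested, keeping ~25% of participants complete at all
  four follow-ups — independent waves at these rates would leave almost
  nobody complete, unlike the ~28% the emulated study retains.  Deletion
  never reads outcome values, so the mechanism is MAR by construction;
  baseline is never removed.  A monotone-dropout switch exists but is off
  by default (observed completion counts are non-monotone).

What passing the synthetic checks does *not* show about real data: the
generator's costs are conditionally gamma-Poisson with a one-factor
frailty (real cost processes have more extreme single-admission outliers),
utilities are generated directly rather than through SF-12 items (an
item-level emission mode exists only to exercise the scoring path), and
missingness is exactly MAR — the sensitivity analyses cannot be validated
against not-at-random mechanisms here.

## Calibration studies (acceptance script / test suite)

`scripts/acceptance.py` recomputes, from scratch at run time: the
microcosting table; ICER arithmetic on tabled incremental pairs; QALY-AUC
agreement with dense numerical integration (1000 random trajectories,
tolerance 1e-12); reordered-CI agreement with the comparator-sort oracle
(100 random replicate sets); CEAC exactness at λ = 0; percentile-CI
coverage for the total-cost difference over 200 complete-data synthetic
trials (n = 304, B = 500) using the stratified unadjusted mean-difference
estimator — the covariate-adjusted estimator's bootstrap intervals run a
little wide under the generator's heavy tails (≈98% empirical coverage),
a known small-sample effect of resampling high-leverage observations, so
the calibration study uses the estimator for which the percentile method
is the textbook match; Park-test family selection rates (500 datasets of
n = 2000 per family); recovery of a planted QALY difference of 0.012 and
total-cost difference of −2858 by the repeated-measures estimator over
200 complete-data replicates; and the imputation-nested bootstrap's
point-estimate bias against a planted −2000 cost difference under the
default MAR mechanism over 100 runs.  The MI recovery scenario uses a
moderate cost level (control ≈ 6,000 over follow-up) with negligible
frailty so the GLM mean model is correctly specified and the planted bias
can be resolved at the stated precision — with the default heavy-tail
model, per-run noise alone (±3,000) would swamp a 200-dollar bias bound,
and the frailty-induced nonlinearity in the baseline covariate is a
separate (documented) source of gamma-GLM attenuation unrelated to
imputation.

Problem sizes in the test suite match the acceptance script; end-to-end
pipeline tests run at B = 120-250 bootstrap iterations, and the `demo`
subcommand defaults to the full B = 1000.

## Known limitations

- The MMRM assumes joint normality of wave outcomes; for costs this is a
  working model (its mean contrasts remain consistent under MAR given the
  covariance structure, but small-sample Wald intervals on heavy-tailed
  costs are approximate — hence the bootstrap companions).
- The gamma identity-link GLM is consistent for arm contrasts only when
  the mean model is correct; under strongly nonlinear baseline-cost
  relationships its weighting can attenuate contrasts (observed and
  documented above).
- Single imputation nested in the bootstrap propagates imputation
  uncertainty through the resampling, not through within-imputation
  pooling; it is the trial convention this package follows, not Rubin's
  rules.
- No value-of-information analysis, no Fieller CIs, no discounting, no
  currency conversion (the USD rate is metadata only).
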