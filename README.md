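# trialcea

Within-trial cost-effectiveness and cost-utility analysis for a
three-arm randomized trial of internet-delivered psychosocial care in
bipolar disorder, from an (Australian) health-sector perspective:
microcosting of intervention delivery, pricing of self-reported service
use, SF-6D utilities and QALYs, adjusted mean-difference estimation,
bootstrap ICER/CEAC inference, and missing-data sensitivity analyses —
plus a synthetic trial generator so the whole pipeline is testable
without access to trial data.

It is written for health economists and trial statisticians who need a
reproducible, scriptable version of the standard within-trial evaluation
workflow.

## The analysis in brief

For arms a (intervention) and b (comparator), with per-participant
12-month health-sector totals C and effects E (QALYs by trapezoid area
under the SF-6D utility trajectory, or depression-score improvement):

- **ICER** = ΔC / ΔE, where ΔC and ΔE are adjusted mean differences
  (baseline outcome, sex, national origin as a-priori covariates).  An
  arm that is cheaper and more effective is *dominant*; costlier and less
  effective is *dominated*; no ratio is reported in those cases.
- **Base case**: repeated-measures linear models of follow-up costs and
  utilities across months 3/6/9/12 with an unstructured within-person
  covariance (REML), using all available waves (valid under missing at
  random).
- **Uncertainty**: nonparametric bootstrap stratified by arm (B = 1000);
  95% CIs for ICERs by the reordered percentile method (replicates
  ordered by angle on the cost-effectiveness plane); CEACs report
  P(λ·ΔE − ΔC > 0) over a willingness-to-pay grid with a headline
  λ = Aus $50,000 per QALY.
- **Sensitivity analyses**: complete-case GLMs (gamma/identity for costs,
  inverse-Gaussian/identity for QALYs, families guided by the modified
  Park test), single imputation (chained equations with predictive mean
  matching) nested in the bootstrap, a population-rollout delivery-cost
  variant, and a threshold analysis on the intervention cost.

See `docs/methods.md` for model details, parameter defaults, and the
synthetic-data generator's calibration.

## Worked example

The microcosting of intervention delivery (website split by complexity
0.19/0.38/0.43; computers and personnel split by arm sizes 102/102/100):

```python
>>> import trialcea as tc
>>> b = tc.microcost_interventions(tc.demo_ledger())
>>> print(b.table.to_string(float_format=lambda x: f"{x:,.2f}"))
                                        arm_1     arm_2     arm_3    overall
item
Website development and maintenance 22,800.00 45,600.00 51,600.00 120,000.00
Desktop computers                    1,204.59  1,204.59  1,180.97   3,590.14
Research assistant (monitoring)     14,778.81 14,778.81 14,489.03  44,046.65
Research assistant (debriefing)      1,477.88  1,477.88  1,448.90   4,404.66
Supervisor (debriefing)              2,689.53  2,689.53  2,636.79   8,015.85
Total intervention cost             42,950.80 65,750.80 71,355.69 180,057.29
Average cost per trial participant     421.00    645.00    714.00     592.00
```

Delivery of the control forum costs Aus $421 per randomized participant,
psychoeducation Aus $645, and psychoeducation + CBT tools Aus $714; these
per-capita amounts are attached at the 3-month wave of each participant's
cost series.

ICER classification on an incremental pair:

```python
>>> from trialcea import IncrementalPair, icer_point
>>> print(icer_point(IncrementalPair(743.0, 3.6, "madrs")))
206
>>> print(icer_point(IncrementalPair(-2858.0, 3.8, "madrs")))
dominant
```

A cost of Aus $743 for 3.6 points of extra depression improvement is Aus
$206 per point; a saving of Aus $2,858 with 3.8 points of improvement is
dominant (cheaper *and* more effective).

End-to-end on a synthetic trial:

```bash
trialcea demo --seed 1 -B 1000 --out demo_output
```

generates the default scenario (304 participants, baseline utility 0.63,
right-skewed costs, ~70% lost by 12 months under a sex-dependent MAR
mechanism), runs all four analysis modes (base case, complete case,
multiple imputation, population-level delivery costs) and writes the
tables, cost-effectiveness planes, CEACs and a run manifest under
`demo_output/`.  Individual steps are available as `trialcea run`,
`simulate`, `microcost` and `ceac`.

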