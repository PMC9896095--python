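# Methods

## Setting and model structure

The package analyses a two-arm pragmatic trial of working-age orthopaedic
outpatients with nonsurgical musculoskeletal disorders: 40 participants
received a short course of specialised manual therapy (index arm), 38
received orthopaedic care as usual (control), with SF-6D quality-of-life
and health-care-cost measurements at 3, 6, 12 and 96 months.

The economic model is a two-state Markov cohort model — *recovered* /
*non-recovered* — with 3-month cycles over a 96-month horizon. The cohort
is closed: no death or other absorbing state is modelled, which is
defensible for a working-age population over eight years, and it means
occupancy fractions sum to one at every cycle (a tested invariant). The
first cycle is the per-protocol period: the whole cohort is non-recovered
and carries an arm-specific utility. From cycle 2 onward, utilities pooled
over both arms by state apply, while costs and transition probabilities
stay arm-specific.

## State classification

Classification is deliberately dual, following the health-care perspective:

* **Cost state.** A participant with any treatment record in a period is
  non-recovered; with none, recovered — they generated no cost, whatever
  their symptoms. Costs, transition probabilities and the reported recovery
  proportions all use this axis.
* **Utility state.** Untreated participants who still report the disorder
  are kept in the non-recovered pool for utility estimation (they are
  "recovered" only in the costing sense). This is why the pooled
  non-recovered utility (0.672 on the packaged tables) averages the treated
  categories *together with* the untreated-but-symptomatic column, while
  the pooled recovered utility (0.812) covers only the untreated
  asymptomatic-equivalent column. This split is the only reading that
  reproduces the published pooled utilities and recovery proportions
  simultaneously, and the package adopts it throughout.

When classifying individual records, the state reported at a follow-up is
determined by the records of the single 3-month cycle ending at that
follow-up. The aggregate tables are silent on the exact window; the
single-cycle convention makes the observed panel the chain's state at the
follow-up itself, which in turn makes the estimator-model round trip exact
(see validation below).

## Input estimation

**Utilities** are count-weighted means over panel cells, `Σ u·n / Σ n`,
rounded to the 3-decimal reporting precision at the estimation surface
(raw values are available via `ndigits=None`). Weighted means are bounded
by their inputs and invariant under cell merging — both property-tested.
On the packaged tables the pooled recovered utility computes to 0.8118
from rounded cells where the trial prints 0.811 (unrounded source data);
the package reports its own computed value.

**Costs** per cycle and arm are means per non-recovered participant. The
per-protocol cycle divides the arm's total by the arm size (all are
considered non-recovered by then). Later record periods divide the period
total by the number of cost-state non-recovered participants in the period
and spread it uniformly over the period's 3-month cycles. The packaged
cost table aggregates baseline–12 and 13–96 months, so the fixture path
spreads each window uniformly across its cycles and uses the treated
headcount at the nearest following follow-up as the denominator (arm size
for cycle 1). This is a modelling choice forced by the windowed reporting;
it is configurable in the record-level estimator, which implements the
per-period contract exactly.

**Transition probabilities** follow the ratio-of-counts estimator: newly
recovered participants divided by the previously non-recovered pool (and
vice versa for relapse), computed on enrolment *fractions* so that the
rare withdrawals shrink denominators without imputation. Between two
follow-ups only the net flow is identifiable from aggregates, so each span
carries a single direction. Spans longer than one cycle are converted to
per-cycle probabilities under a constant hazard,
`p₃ = 1 − (1 − p_span)^(3/span)`, rather than linear division: this keeps
probabilities in [0, 1] and compounds back to the span value exactly
(property-tested to machine precision).

## Discounting

Both costs and effects are discounted at an annual 3% (configurable, can
be disabled). The factor `(1+r)^(−t)` is applied continuously in years at
the cycle midpoint; occupancy itself is accrued for full cycles. An
optional trapezoidal half-cycle correction (averaging the occupancies
bracketing each cycle) is available behind `half_cycle_correction` but off
by default — the midpoint-discounting scheme is the simplest one
consistent with area-under-the-curve QALY accrual. How the original
spreadsheet model discounted (cycle start, midpoint, or yearly steps) is
not documented, which is one reason the published discounted headline
values are matched approximately rather than exactly.

## Incremental analysis

ΔQALY and Δcost are index minus control over the common horizon. Because
the trial's arms differed in baseline utility, the QALY difference is
baseline-adjusted by difference-in-differences: the baseline gap times the
horizon in years is subtracted. The trial's individual baseline utilities
are not published, so they are config inputs defaulting to equal baselines
(a no-op adjustment); the adjustment is shift-invariant by construction
(tested). Dominance quadrants are exhaustive over the sign grid of
(Δcost, ΔQALY); a cost difference with exactly zero effect is reported as
an undefined ICER rather than a number.

Confidence intervals for mean per-participant costs use a seeded
nonparametric percentile bootstrap (10,000 resamples by default).
Percentile intervals are asymmetric for skewed samples, matching the heavy
right tail of health-care costs.

## Validation

The model is validated by comparing predicted against observed recovery
percentages at each follow-up (default tolerance 5 percentage points,
configurable). When the engine is driven by the panel's own estimated
probabilities this comparison is exact — a composition identity, not an
empirical finding — because the net-flow estimator and the single-direction
per-span conversion invert the cohort update. The test suite verifies the
identity to 1e-9; its value on real use is as a wiring check and as a
harness for validating *external* probability inputs against observations.

## Sensitivity analysis

The univariate sensitivity analysis pools all individual 96-month cost
totals across both arms, computes their mean and sample standard deviation
(ddof = 1), and excludes individuals whose total *strictly exceeds*
mean + 2·SD before recomputing per-arm means and bootstrap CIs. Only
high-cost individuals can be excluded, so the after-exclusion mean never
rises; with no exclusions the primary result is reproduced bit-for-bit
(both tested). A degenerate zero SD excludes no one. Note that the rule is
conservative on small samples: in a set like {1, 1, 1, 1, 100} the pooled
SD (≈44.3) is inflated by the outlier itself and the 100 survives — a
known property of SD-based outlier rules, frozen in a unit test.

## The synthetic-trial generator

`mtcea.simulate` emulates the structure the estimators assume, with a
ground-truth ledger for oracle tests:

* two-state chains per participant at 3-month resolution, with per-span
  transition probabilities defaulting to the values implied by the
  packaged state table (control: 0.579, 0.166, 0.077 recovery per span;
  index: 0.725, 0.809 recovery, then 0.167 relapse over 13–96 months),
  converted internally to per-cycle hazards;
* treated (non-recovered) cycles draw an intervention category and a
  log-normal cost (shape 0.6) with category means on the magnitudes of the
  published cost table; the per-protocol cycle uses the arms' actual
  category mix (index: all specialised manual therapy);
* SF-6D measurements at the four follow-ups, normal noise (sd 0.08)
  around state means clipped to [0, 1] — clipping slightly biases means
  within ~2 SD of the bounds toward the interior (≤ about 3·10⁻⁴ at the
  default means), negligible relative to sampling error at test sizes;
* untreated-but-symptomatic flags with probability 0.3 among cost-state
  recovered participants at measurement points, and rare dropout
  (probability 0.01 per later follow-up), mirroring the trial's 95%
  retention.

What the generator does **not** emulate: serial correlation of utilities
within participant beyond the state process, cost dependence on time since
recovery, treatment-seeking behaviour decoupled from the health state
(every non-recovered cycle is billed, which somewhat overstates long-run
costs relative to the trial), crossovers as a behavioural process, or
SF-36 item-level structure. Passing parameter-recovery and null tests
therefore shows the estimators are consistent for the generating process
they assume — not that the trial data satisfy those assumptions.

Because each default span has a single nonzero flow direction, the
net-flow transition estimator is consistent for the generator, and
parameter recovery at 2,000 per arm lands within three binomial standard
errors of the generating values (tested, seeded). An identical-arms
configuration yields incremental endpoints statistically indistinguishable
from zero across seeds (tested with 6 seeds at 400 per arm).

## Numerical and reporting conventions

* Utilities print to 3 decimals, SEK to whole crowns, percentages to
  integers — the trial's precision.
* All computation is in SEK; 10 SEK ≈ 1 EUR is reporting metadata only.
* The index-arm mean 96-month cost uses the originally randomised 40 as
  denominator (which reproduces the published 9,003 SEK); denominators are
  overridable. The control mean computed from the windowed cost table
  (47,784 SEK) differs from the published 49,273 SEK, which is not exactly
  recoverable from the aggregate table under any whole-arm denominator —
  individual withdrawal timing is unpublished — so the published value is
  carried as a constant for the incremental comparison and the computed
  value is reported alongside.
* The index arm's recovery at the first post-protocol follow-up computes
  to 72% from the state table, while the trial reports 69% per protocol;
  the per-protocol assessment is not reconstructible from the aggregates,
  so both are reported and no agreement is forced.
* Deterministic behaviour everywhere: one integer seed drives simulation
  and bootstrap; identical seeds give byte-identical artefacts (tested).

## Problem sizes in the test suite

Parameter recovery uses 2,000 participants per arm; the microsimulation
cross-check of the cohort engine uses 200,000 individual chains on a
16-cycle spec; bootstrap coverage uses 200 replicates of n = 80 with 600
resamples; the null-hypothesis check uses 6 seeds at 400 per arm. These
sizes give standard errors a fraction of the tested tolerances while
keeping the default suite around a quarter of a minute.

## Known limitations

* Only two live states; no probabilistic sensitivity analysis or
  acceptability curves — the analysis mirrors the trial's univariate 2-SD
  design.
* Aggregate-table mode cannot produce individual-level CIs or the
  sensitivity analysis (no individual costs exist there).
* The headline published endpoints that depend on unpublished inputs
  (baseline utilities, the per-cycle probability chart) are approximated
  by the fixture-driven model, not reproduced exactly; the package's own
  computed endpoints are reported with their provenance.
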