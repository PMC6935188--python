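# Methods

This note records the model's assumptions, the conventions chosen where a
convention had to be chosen, the defaults and why, and what the synthetic
inputs do and do not emulate.  It states no empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Decision problem

Two comparisons, never against each other (the tools target different
ages):

1. **Meconium comparison** — screen newborns with meconium FAEE testing
   versus refer all suspected newborns to diagnostic testing.  The model
   starts at birth and runs 18 one-year cycles.
2. **NST comparison** — screen five-year-olds with the NST versus refer all
   suspected children.  The model starts at age 5 and runs 13 cycles.

Effectiveness is discounted years of life with an accurate FASD diagnosis;
costs are 2017 Canadian dollars from the public-healthcare perspective.
Screening saves testing and service costs but forgoes diagnosed years, so
the ICER is read as savings per diagnosed year forgone against a
willingness-to-accept threshold.

## Decision tree and timing conventions

Everyone is screened at the model start (the screening fee is charged for
the whole cohort in cycle 0).  Diagnostic testing — assumed perfectly
accurate by default, with an adjustable sensitivity — happens in the cycle
containing the testing age: age 5 in both comparisons.  In the meconium
comparison this encodes a five-year lag between a positive newborn screen
and testing; crucially, the *no-screening* arm is also tested at age 5, not
at birth (newborns rarely receive the full assessment immediately, and only
this timing is consistent with the two published no-screening rows
differing in both cost and effectiveness).

Conventions that the published description leaves open, and the choices
made here:

* **Half-cycle correction** — mid-cycle evaluation: accruals in cycle $k$
  are discounted by $(1+r)^{-(k+0.5)}$.  A trapezoidal variant (average of
  the cycle-boundary factors) is available via `time.half_cycle`.
* **One-off costs** (screening, testing, re-diagnosis) are discounted at
  the mid-cycle factor of the cycle they occur in — one consistent rule for
  all point costs.
* **Future diagnosis** — missed cases convert at 5%/year *from the testing
  cycle onward* (a missed child has the same chance of being picked up in
  the year the cohort reaches testing age as in any later year), pay
  repeat screening plus testing on conversion, and accrue diagnosed years
  and the diagnosed cost from the conversion cycle.  Starting conversions
  one cycle later is the other defensible reading; it widens the
  effectiveness loss of screening by roughly 5% and was rejected because
  the adopted convention reproduces the published incremental results more
  closely (see `tests/test_acceptance.py`).
* **Pending states** — children with FASD awaiting testing are costed at
  the undiagnosed annual rate (switch: `model.pending_fasd_cost`);
  children without FASD awaiting rule-out at the no-FASD rate.
* **Order within a cycle** — deaths, then scheduled testing, then
  future-diagnosis conversion, then cost/effect accrual.  Occupancies must
  sum to the cohort size after every step (enforced, not assumed).
* **First year of life** — in the meconium comparison every living child
  accrues the newborn cost ($20,265 inflated) in cycle 0 instead of a
  state cost; the NST comparison starts at age 5 and never charges it.
* No terminal value: survivors at age 18 contribute nothing beyond the
  horizon.

## Costs and inflation

The published parameter table lists annual health-service costs before
inflation adjustment ($15,976 first year, $3,426 diagnosed, $2,713
undiagnosed) while the prose reports 2017 dollars ($20,265 / $4,346 /
$3,441).  The connecting factor is never printed, so it is a stored
parameter, defaulting to the least-squares ratio across the three printed
pairs (≈ 1.2685); each pair's individual ratio agrees within 0.1%.  All
modelling runs on the inflated basis by default (`model.cost_basis`), which
is the basis that reproduces the published incremental results; the
pre-inflation basis remains available.  Whether the $3,101 no-FASD annual
cost was itself pre-inflation is unstated; it is inflated by default
(`costs.inflate_no_fasd`), and because the no-FASD group is identical in
both arms this choice cancels out of every incremental result.

The undiagnosed annual cost is not a free number: it is reconstructed from
the diagnosed cost and the psychiatric-care recommendation gap (55.6% of
diagnosed vs 33.0% of assessment-deferred children) as

    c_undiag = c_diag * (1 - share * (1 - r_undiag / r_diag)),

where `share` — the fraction of the diagnosed annual cost attributable to
psychiatric-influenced services — is calibrated (≈ 0.512) so the base-case
inputs reproduce the $2,713 anchor; inflating the result reproduces $3,441
within $2.  The functional form is an assumption (the original derivation
is not public): the simplest form consistent with both anchors and with the
requirement that the cost be recomputable from sampled recommendation rates
in the probabilistic analysis.

## Mortality

State-specific annual death probabilities are the background life-table
rate times an SMR: 3.15 for diagnosed (and pending) FASD, 3.15 × 1.10 for
undiagnosed FASD, and 3.15 for the no-FASD group (children assessed for
FASD are not population-average children), capped at 1.

## Pooling

DerSimonian–Laird on the raw proportion scale reproduces the published
pooled accuracies; a logit-scale option exists but is off by default.  The
between-study SD √τ² is reported as the pooled dispersion.  Two caveats are
inherent to the raw-scale estimator and documented deliberately:

* Near the boundary it is upward-biased: studies observing 100% are capped
  at 99% and receive the smallest imputed variances, hence the largest
  weights.  Synthetic-recovery tests show a bias of about +1 point at a
  true proportion of 0.95 (study sizes 30–200); interior proportions
  recover within 2 SE.
* √τ² does not reproduce the published pooled SDs for the specificities
  (the definition behind those printed values is unstated); no agreement is
  forced, and the probabilistic analysis takes its accuracy SDs from the
  configuration, which carries the published values.

## Probabilistic analysis

5000 draws; every varied parameter sampled independently (sensitivity and
specificity deliberately uncorrelated, which may overstate uncertainty).
Families: beta by moment matching for proportions; normal with SD = 10% of
the mean, rejection-sampled into ±25% bounds (not clipped — clipping would
pile mass at the bounds and shift the mean) for screening and testing
costs; log-normal moment-matched for annual costs, sampled pre-inflation
and then inflated; uniform on 3–7% for the future-diagnosis rate and
1.0–1.2 for the undiagnosed-mortality multiplier; normal truncated below 1
for the SMRs (no group outlives the general population), with the no-FASD
SMR's SD widened to 1.6 × 1.25 = 2.0.  The undiagnosed cost is recomputed
in every draw from the sampled recommendation rates, so draws where the
sampled rates invert can legitimately price undiagnosed above diagnosed
care.  One seeded generator with a fixed draw order makes runs reproducible
(default seed 20190101, a CLI flag).

**Acceptability rule.**  The acceptability curve is a WTA curve, not a
textbook WTP curve: a south-west draw is acceptable at threshold λ when its
savings per diagnosed year forgone, ΔC/ΔE, is **at least** λ; dominant
draws are always acceptable, dominated draws never; a (rare) north-east
draw is judged by ΔC/ΔE ≤ λ.  The curve therefore *decreases* in λ — at a
high enough WTA the savings no longer compensate for the forgone diagnosed
years — which is the direction the published curves show.

## One-way analysis

Ten parameters (tool sensitivity and specificity, diagnostic-test
sensitivity, prevalence, the diagnosed/undiagnosed annual costs, the
testing and screening fees, the future-diagnosis rate, the diagnosed SMR)
are varied to 0.75× and 1.25× of base, all else fixed; entries are sorted
by the ICER swing.  Varied proportions are capped at 0.99 rather than 1.0:
at sensitivity exactly 1 the arms coincide in effectiveness and the ICER is
undefined, which would make the tornado's dominant bar incomputable; 0.99
matches the cap used for perfect study proportions.

## Synthetic life table

The one external input the original analysis uses is a national life
table.  The package generates a stylized stand-in: q(0) = 0.005, then a
flat 0.0002/year to age 18 — plausible Canadian pediatric magnitudes with
an elevated infant term.  Because all-cause child mortality is tiny even
after SMR scaling, results are insensitive to the exact schedule (the
tornado places mortality in the bottom half), and a zero-mortality preset
exists for closed-form checks.  What the synthetic table does not emulate:
real age fine-structure (neonatal vs post-neonatal split, the adolescent
uptick), sex differences, and secular trends.  Passing tests therefore
show correctness of the engine and robustness to small mortality, not
calibration to any specific national schedule; users can supply a real
table as CSV (`age,qx`) everywhere one is accepted.

## Validation strategy

* A vectorized per-individual microsimulation replays the identical
  per-person rules with Bernoulli draws and must agree with the
  expected-value cohort engine within 3 Monte-Carlo SE (200,000 individuals
  at base case; randomized parameter sets in the module tests).  Where a
  parameter choice makes every individual's cost stream identical, the
  match must be exact.
* Closed forms: with zero mortality and zero discounting, no-screening
  diagnosed years are exactly prevalence × cohort × (end age − testing
  age).
* A screen with sensitivity 1, specificity 0 and a free test is
  *identical* to no screening (everyone proceeds to testing); with
  specificity 1 instead, the arms differ by exactly the rule-out testing
  cost of the true negatives.  (The latter is why "perfect screening"
  does not literally collapse the two arms.)
* The pooling estimator was cross-checked against an independent
  random-effects implementation at build time and its outputs frozen into
  the test suite.

## Problem sizes

The shipped defaults are the study's own: 100-child cohort, 18/13 cycles,
5000 probabilistic draws, 200,000 microsimulation individuals in the
heaviest oracle check — all of which run in seconds on one CPU, so nothing
is scaled down.

## Known limitations

* No individual heterogeneity (sex, severity), no criminal-justice or
  education costs, no adult extension, no QALYs — diagnosed years of life
  are the sole effectiveness outcome.
* Diagnostic-test specificity is fixed at 1 (there is no state for a
  false FASD diagnosis); only its sensitivity is adjustable.
* The undiagnosed-cost functional form is an assumption calibrated to two
  anchors; other forms consistent with those anchors would differ away
  from the base case.
* Raw-scale DL pooling is boundary-biased (above) — acceptable here
  because it is the method the pooled inputs derive from, not a general
  recommendation.
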