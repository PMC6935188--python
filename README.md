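# fasdscreen

Cost-effectiveness modelling of screening for fetal alcohol spectrum
disorder (FASD).

Diagnosing FASD requires a costly multi-disciplinary assessment (about
$3870 per child in 2017 Canadian dollars), so screening children suspected
of FASD before referring them to diagnostic testing has been proposed.
Screening is imperfect: false negatives are children with FASD who miss out
on a diagnosis and the services it unlocks.  This package implements a
decision-analytic model that quantifies the trade-off for two recommended
tools — meconium fatty acid ethyl ester (FAEE) testing of newborns and the
Neurobehavioral Screening Tool (NST) for five-year-olds — each compared
with a no-screening strategy in which every suspected child is tested.  It
is written for health-economics analysts who want a transparent, tested,
re-parameterizable implementation of the full pipeline.

## The model

**Accuracy pooling.** Study-level sensitivities and specificities are
pooled with the DerSimonian–Laird random-effects estimator on the
proportion scale: with study variances $s_i^2$ and fixed-effect weights
$w_i = 1/s_i^2$,

$$Q = \sum_i w_i (p_i - \hat\mu_{FE})^2, \qquad
\hat\tau^2 = \max\!\left(0,\; \frac{Q - (k-1)}{\sum w_i - \sum w_i^2 / \sum w_i}\right),$$

and the pooled mean uses weights $w_i^* = 1/(s_i^2 + \hat\tau^2)$.  Studies
without a reported dispersion get $s_i = \sqrt{p_i(1-p_i)/(n_i+1)}$ (the
beta-distribution variance formula), with proportions of 100% capped at
99%.

**Cohort model.**  A hypothetical cohort of 100 children suspected of FASD
(prevalence $\pi = 66.3\%$) is split by a decision tree — screen
positive/negative by tool sensitivity $Se$ and specificity $Sp$, or direct
referral under no screening — and advanced in one-year Markov cycles to age
18 through states *pending testing*, *undiagnosed FASD*, *diagnosed FASD*,
*no FASD* and *dead*.  Meconium testing screens at birth with a five-year
lag to diagnostic testing; the NST screens at age five with none.  Missed
cases convert to diagnosis at 5%/year thereafter, paying repeat screening
and testing.  Mortality multiplies a life table by state-specific
standardized mortality ratios (SMR 3.15 for FASD, +10% if undiagnosed).
Costs (2017 CAD) and years lived with a diagnosis accrue per cycle with a
mid-cycle half-cycle correction and 1.5%/year discounting.  The outcome is
the incremental cost-effectiveness ratio

$$\mathrm{ICER} = \frac{\Delta C}{\Delta E},$$

dollars saved per diagnosed year forgone (screening typically sits in the
south-west quadrant of the cost-effectiveness plane), judged against a
willingness-to-accept (WTA) threshold.

**Sensitivity analysis.**  A ±25% one-way tornado; discount-rate scenarios;
and a 5000-draw probabilistic analysis with beta distributions for
proportions, bounded normals for one-off costs, log-normals for annual
costs (sampled pre-inflation, then inflated), uniforms for the
future-diagnosis rate and undiagnosed-mortality multiplier, and truncated
normals for SMRs.  The cost-effectiveness acceptability curve reports the
probability that screening is acceptable at each WTA threshold.

## Worked example

```python
from fasdscreen import load_parameters, run_comparison_pair, compare, pool_table

pooled = pool_table("meconium")
print(f"pooled meconium sensitivity: {pooled['sensitivity'].mean:.1%}")
print(f"pooled meconium specificity: {pooled['specificity'].mean:.1%}")

params = load_parameters(comparison="meconium")   # built-in base case
no_screen, screen = run_comparison_pair(params)
result = compare(no_screen, screen, params.cohort_size)
print(f"incremental cost:          ${result.delta_cost:,.2f} per 100 screened")
print(f"incremental effectiveness: {result.delta_effect:,.2f} diagnosed years per 100")
print(f"ICER ({result.quadrant}):                ${result.icer:,.2f} saved per diagnosed year forgone")
```

prints

```
pooled meconium sensitivity: 92.5%
pooled meconium specificity: 51.6%
incremental cost:          $-88,584.60 per 100 screened
incremental effectiveness: -38.90 diagnosed years per 100
ICER (SW):                $2,277.40 saved per diagnosed year forgone
```

Screening newborns with meconium testing saves about $88,600 per 100
children screened but forgoes about 39 years of life with an FASD diagnosis
by age 18 — roughly $2,280 saved per diagnosed year forgone.  Whether that
trade is acceptable depends on the decision-maker's WTA threshold; the
probabilistic analysis turns this into an acceptability curve.

The same pipeline is available from the shell:

```sh
fasdscreen run --comparison meconium          # summary table + cycle traces
fasdscreen psa --comparison meconium --draws 5000 --seed 20190101 --plot
fasdscreen oneway --comparison nst            # tornado table
fasdscreen scenarios --comparison meconium --rates 0,0.015,0.03
fasdscreen synth-lifetable --q0 0.005 --flat 0.0002
```

Every input (cohort, tool accuracy, costs, mortality, time, PSA settings)
can be overridden through a YAML/JSON config file (`--config`); the
base case ships at `src/fasdscreen/data/base_config.yaml` along with the
two study tables the pooled accuracies come from.

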