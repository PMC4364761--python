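# Methods

## Population and synthetic cohort

The model population emulates an asymptomatic, statin-naive, intermediate-risk
sample (10-year Framingham CHD risk 6–20%, LDL-C < 160 mg/dL, no diabetes, no
prior CHD/CVD) of n = 1,619 adults cross-classified by ATP III statin
eligibility and CAC stratum (CAC = 0 / 1–99 / ≥ 100).  The published joint
counts are bundled as `cacsim.REFERENCE_COUNTS`:

|                | CAC = 0 | 1 ≤ CAC < 100 | CAC ≥ 100 | total |
|----------------|---------|---------------|-----------|-------|
| ATP III eligible | 226 | 196 | 193 | 615 |
| not eligible     | 454 | 294 | 256 | 1,004 |

`generate_cohort` reproduces these cells exactly when n equals the table
total, or samples them multinomially otherwise.  Baseline ages are drawn
independently of eligibility and stratum from a configurable model; the
default is a truncated normal on [45, 84] with mean 65 and SD 8.  The
source's baseline age distribution is not published in the text we model
from, so this default is a documented stand-in: the acceptance script reports
how the event projections move when the whole cohort is pinned at ages 55,
65 or 75 (≈ ±1 event/1,000 over 5 years).  ATP III eligibility is taken as a
label with the published joint frequencies; lipid values and the "optional
LDL-C goal" randomization behind them are not re-derived.  Sex is not
modelled (no parameter in the registry is sex-specific).

## Event risks and treatment effects

Annual first-event probabilities are stratum- and outcome-specific (CHD:
myocardial infarction, angina, resuscitated arrest; CVD adds stroke and other
cardiovascular death).  Five-year analyses use average annual rates over five
years of follow-up (e.g. CVD: 0.0041 / 0.0109 / 0.0192 for CAC 0 / 1–99 /
≥ 100); ten-year analyses use the ten-year-based rates.  A scenario
multiplier (default 1, 2 in the elevated-rate scenarios) scales event
probabilities only — background mortality is unchanged.

Moderate statins give RR 0.65, intensive statins RR 0.55, constant over the
horizon.  Adherence is a single Bernoulli draw per recommended patient —
probability 0.55 without CAC testing, 0.65 with — fixed for the horizon.
Non-adherent patients are modelled as never-initiators: no benefit, cost,
disutility or statin adverse events.  This is the simplest reading consistent
with adherence scaling the mean benefit; the alternative (non-adherent
patients fill prescriptions without benefit) is available via
`EngineOptions(nonadherent_incur_costs=True)`.  In the CAC strategies the
scan result overrides ATP III: an eligible patient with CAC = 0 receives no
statin.

Case fatality of a first event is 0.100 (CHD) / 0.1026 (CVD) under attained
age 65 and 0.15714 / 0.16265 at 65 and over; the threshold uses the age at
the event cycle, not baseline age.  Background mortality comes from a
bundled single-year life table (`data/us_life_table_2011_synthetic.tsv`), a
synthetic approximation of the US 2011 all-cause period table built by
geometric interpolation of quinquennial anchors of the published magnitude.
Using all-cause rates slightly double-counts cardiovascular death in the
"other-cause" channel; the file is swappable via `load_life_table(path)`.

Statin adverse events: a mild complication occurs once, at initiation, with
probability 0.18 ($180, utility multiplier 0.9941 in that year — a transient
two-day loss of healthy life, not a chronic annual decrement; the chronic
reading is available as `EngineOptions(mild_ae_annual=True)`).  A severe
complication occurs at 1/18,000 per on-statin person-year ($6,500,
multiplier 0.9553 in the year), is fatal with probability 0.09, and survivors
discontinue statins (the expected-value engine neglects the ~5 × 10⁻⁵/yr
discontinuation branch; the microsimulation models it).  CAC scanning adds a
radiation-induced cancer death hazard: the 2 × 10⁻⁵ lifetime risk is spread
uniformly over a 25-year latency window (configurable) with a 0.65 one-year
case fatality — ~5 × 10⁻⁷/yr, numerically negligible but carried.

## Cycle mechanics

One cycle = one year; horizons are 5 or 10 cycles (other values require an
explicit override — no lifetime extrapolation).  Competing risks within a
cycle are resolved without an ordering assumption: each annual probability
`p_c` becomes a hazard `−ln(1−p_c)`, the total transition probability is
`1−exp(−Σ)` and the cause is allocated proportionally to hazards.  Post-event
survivors face only background mortality (first events only; no recurrence or
revascularization pathways).

QALYs: healthy utility is linearly interpolated between anchors 0.84@50,
0.82@60, 0.79@70, 0.74@80, 0.68@90 and clamped outside 50–90, evaluated at
the attained age each cycle.  The state at the end of a cycle determines its
accrual: a nonfatal event year accrues `u·m` (m = 0.8351 CHD / 0.8272 CVD),
the next year `u·(1+m)/2`, later years `u`; death accrues nothing from the
event cycle onward.

Discounting: 3%/year applied to costs, QALYs and (by default) event counts.
Cycle payoffs are discounted as end-of-year flows, factor `1.03^−(k+1)` for
cycle k — the convention under which the model reproduces the reference
event projections at both horizons; the annuity-due convention (`1.03^−k`,
first cycle undiscounted) is available as
`EngineOptions(discount_timing="start")` and changes totals by exactly one
factor of 1.03.  No half-cycle correction is applied (documented limitation).
Undiscounted event counts are always reported alongside
(`events_per_1000_undiscounted`).

Two engines share this parameterization.  The expected-value engine
propagates exact per-patient state-occupancy fractions, splitting each
recommended patient into adherent/non-adherent branches weighted by the
adherence probability; it is deterministic given the cohort and is used for
the scenario grid and break-even search.  The microsimulation draws
individual trajectories from per-patient uniform streams
(`CommonRandomNumbers`) shared across strategies within a simulation, so that
strategy contrasts are paired: the adherence stream makes adherence nested in
its probability, and the transition/allocation/fatality streams make treated
events a subset of untreated ones.  At 10⁵ patients the two engines agree
within Monte-Carlo error (tested at 3 binomial SEs).

## Costs and economics

All amounts are 2011 USD.  Base-case components: CAC scan ($100; $75/$150/
$250 variants) once per scanned patient, statins ($180/yr; $50/$1,000
variants) per on-statin healthy year, event costs (nonfatal/fatal CHD
$64,400/$49,000; CVD $55,700/$43,500) once at the event, and adverse-event
costs.  Optional components (off in the base case): age-interpolated
productivity costs in the event year (anchors $6,500→$200 CHD, $7,900→$200
CVD over ages 40–80), a $15.20 time cost per scan, and an incidentaloma
re-scan penalty applied as the expected 0.08 × $250 per scanned patient.
Productivity costs are charged in the event year only.

Pairwise comparisons classify dominance (cheaper and more effective) and
otherwise report the ICER with a $50,000-per-unit threshold decision
(symmetric in the south-west quadrant: giving up effect is acceptable at
savings above the threshold per unit).  Scenario decision labels follow a
frontier-style rule: alternatives are screened pairwise against ATP III, and
the favored strategy is the most effective acceptable alternative — this,
rather than maximum net monetary benefit, reproduces the reference decision
labels in events-valued scenarios where treating everyone is most effective
but a CAC strategy has higher NMB.  CEACs use the standard max-NMB rule among
the three mutually exclusive strategies with ties split equally; acceptance
therefore sums to 1 at every threshold.

## Probabilistic sensitivity analysis

Each simulation draws one value per distributed parameter — triangular RRs
and adherence, beta case fatalities and adverse-event probabilities, gamma
costs (mean/SD parameterization, shape = (m/s)², scale = s²/m), triangular
±20% scan and statin costs — independently (no parameter correlation), holds
utilities and radiation constants fixed, resamples the cohort, and
microsimulates the three strategies with common random numbers.  Event-rate
betas keep the published means with an effective sample size of 5,000
(configurable `event_rate_ess`): the published table gives no variance for
these rates, so their PSA spread is an explicit modelling dial.  Note the
triangular adherence distributions are right-skewed (means 0.65 and ~0.717 vs
modes 0.55 and 0.65), so PSA means sit above the base-case points — a
property of the stated distributions, not an implementation choice.  The
reference design is 1,000 simulations × 2,000 patients; the bundled
acceptance run uses a seeded 250 × 1,000 design, which reproduces the
acceptance fractions to well within their Monte-Carlo spread at a fraction of
the cost.

The break-even scan cost solves, by bisection on the expected-value engine,
for total discounted cost parity between the CAC ≥ 1 strategy and ATP III;
because the scan is a one-time cost the incremental cost is linear in it and
bisection is exact to tolerance.  An absent sign change over the bracket
raises `NoBreakevenError`.

## What the generator does and does not emulate

The synthetic cohort reproduces the joint eligibility × CAC composition,
stratum-specific mean annual risks, and a plausible age structure.  It does
not model: age–CAC or age–eligibility correlation (in reality CAC prevalence
rises steeply with age), sex, individual risk-factor gradients within a
stratum, secular statin drift into the cohort, or correlated parameter
uncertainty.  Passing tests therefore show fidelity to the stated population
summaries and model mechanics, not calibration to any individual-level data.

## Numerical choices and degenerate inputs

Probabilities are clipped below 1 before hazard conversion; a non-finite
combined hazard raises rather than propagating.  Zero-total classification
tables raise on percentage requests.  Exact-mode generation requires n equal
to the table total.  Hazard multipliers must be non-negative (0 is allowed
for null-model checks).  Tie-breaks: CEAC winners within 10⁻⁹ NMB split
equally; effect ties in decision labels go to the cheaper strategy.  All
randomness flows through `numpy.random.Generator` seeded per run, with PSA
simulations drawing from `SeedSequence(seed).spawn(n_sims)` so results are
reproducible and independent across simulations.

## Problem sizes used in the bundled checks

Deterministic results use the exact n = 1,619 cohort.  The
microsimulation/expected-value agreement check uses 10⁵ patients; the PSA
acceptance check uses 250 simulations × 1,000 patients; the scenario grid
evaluates all 52 rows with the expected-value engine.  These sizes keep the
full test suite and the acceptance script in the tens of seconds while
leaving Monte-Carlo error far inside the asserted tolerances.

## Known limitations

First events only, 5/10-year horizons, no lifetime extrapolation, no
statin–antihypertensive/aspirin synergy or non-cardiovascular statin
effects, no dose titration or re-scanning, independence of age and CAC in
the generator, all-cause (rather than non-CVD) background mortality, and an
approximate uniform-over-latency allocation of the radiation risk.
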