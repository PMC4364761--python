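# cacsim

A Markov cohort model of the cost-effectiveness of coronary artery calcium
(CAC) testing to guide statin allocation in asymptomatic, intermediate-risk
adults (10-year Framingham CHD risk 6–20%, LDL-C < 160 mg/dL, statin-naive).

Clinicians deciding whom to treat with statins for primary prevention can
(1) follow ATP III cholesterol guidelines, (2) treat every intermediate-risk
patient, or (3) scan for CAC and treat by score — statins for CAC ≥ 1
(moderate intensity for 1 ≤ CAC < 100, intensive for CAC ≥ 100) or only for
CAC ≥ 100.  `cacsim` simulates the same cohort under all strategies and
compares first coronary heart disease (CHD) and cardiovascular disease (CVD)
events, discounted costs (2011 USD) and quality-adjusted life years (QALYs)
over 5- and 10-year horizons, for health-economics researchers and students
of decision modelling.

## Model

Patients occupy states {healthy, post-event (years 1, 2, later), dead}.  Each
annual cycle a healthy patient faces competing risks of a first CHD/CVD event
(stratum-specific annual probability `p_s`, reduced by the statin relative
risk RR = 0.65 moderate / 0.55 intensive for adherent users), background
mortality from a US life table, and rare statin / radiation deaths.  Risks
combine through constant hazards: the per-cycle transition probability is
`1 − exp(−Σ_c −ln(1−p_c))`, allocated to causes in proportion to their
hazards.  A first event is absorbing for event counting; a fatal fraction
(age < 65 vs ≥ 65) dies.  QALYs accrue as age-interpolated utilities `u(a)`
times multiplicative decrements — statin disutility 0.99616, adverse-event
multipliers, and a post-event decrement `m` (0.8351 CHD / 0.8272 CVD) that
tapers linearly over two years (`m`, then `(1+m)/2`, then 1).  Costs and
outcomes are discounted at 3%/year.  Strategy comparisons report incremental
cost-effectiveness ratios (ICERs), dominance, decision labels at a $50,000
willingness-to-pay threshold, and cost-effectiveness acceptability curves
(CEACs) from a probabilistic sensitivity analysis (PSA) that re-draws every
parameter from its beta/gamma/triangular distribution and resamples the
cohort each simulation.

See `docs/methods.md` for assumptions, parameter provenance and conventions.

## Worked example

```python
import cacsim as cs

# Reclassification implied by the published eligibility x CAC counts
print(cs.reclassification_summary(cs.REFERENCE_COUNTS, cs.CACStratum.LOW).rounded())
# (34.0, 14.0, 20.0)  -> treating CAC>=1 adds a net 20.0% of the population

# Base-case 5-year CHD model on the exact n=1,619 cohort
outs = cs.evaluate_strategies(cs.ScenarioSpec(outcome="chd", horizon=5), seed=1)
for name, o in outs.items():
    print(f"{name:>9}: {o.events_per_1000:5.1f} events/1000  "
          f"${o.cost_per_patient:7,.0f}/patient  {o.qalys_per_patient:.3f} QALYs")
#      atp3:  31.8 events/1000  $  2,153/patient  3.438 QALYs
# treat_all:  27.9 events/1000  $  2,193/patient  3.435 QALYs
#   cac_ge1:  26.3 events/1000  $  2,045/patient  3.438 QALYs
```

Treating by CAC ≥ 1 averts ~5 first CHD events per 1,000 persons over five
years relative to ATP III while costing ~$110 less per patient — it
*dominates* both alternatives.  The same machinery drives the 52-scenario
decision grid (`run_scenario_grid`), the PSA and CEACs (`run_psa`,
`PSAResult.ceac`), and the break-even search for the CAC scan cost at which
the strategy stops being cost-saving (`find_breakeven_cac_cost`, ≈ $208 in
the base case).

A CLI mirrors the library:

```sh
cacsim run --outcome cvd --horizon 5 --seed 1 --out out/
cacsim grid --seed 1 --out out/
cacsim psa --n-sims 250 --n-patients 1000 --seed 1 --out out/
cacsim breakeven --seed 1
```

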