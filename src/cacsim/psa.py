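"""Probabilistic sensitivity analysis, the published scenario grid, and the
CAC-cost break-even search.

A scenario fixes the mean CAC scan and statin costs, the horizon, the CAC
treatment threshold, the outcome definition (CHD vs CVD), the valuation of
effects (averted events vs QALYs), an event-rate multiplier, and whether
indirect / incidentaloma costs are included.  The scenario grid evaluates the
three competing strategies (ATP III, treat all, one CAC strategy) with the
deterministic expected-value engine and summarizes each row with a decision
label.  The PSA re-draws parameters (per their distributions) and the cohort
each simulation, runs the microsimulation with common random numbers across
strategies, and feeds acceptability curves.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from . import economics
from .cohort import CohortTable, JointClassificationTable, REFERENCE_COUNTS, assign_event_hazards, generate_cohort
from .engine import CommonRandomNumbers, EngineOptions, StrategyOutcome, run_cohort
from .parameters import LifeTable, ParameterSet, build_parameter_set, load_life_table
from .strategies import StrategySpec, assign_treatment

__all__ = [
    "ScenarioSpec",
    "PSAResult",
    "evaluate_strategies",
    "run_psa",
    "run_scenario_grid",
    "table_grid_specs",
    "find_breakeven_cac_cost",
    "NoBreakevenError",
]


@dataclass(frozen=True)
class ScenarioSpec:
    """One cell of the scenario grid (defaults are the base case)."""

    cac_cost: float = 100.0
    statin_cost: float = 180.0
    horizon: int = 5
    treat_threshold: str = "ge1"  # 'ge1' or 'ge100'
    outcome: str = "chd"  # 'chd' or 'cvd'
    valuation: str = "events"  # 'events' or 'qalys'
    rate_multiplier: float = 1.0
    include_indirect: bool = False
    include_incidentaloma: bool = False

    def __post_init__(self) -> None:
        if self.treat_threshold not in ("ge1", "ge100"):
            raise ValueError("treat_threshold must be 'ge1' or 'ge100'")
        if self.outcome not in ("chd", "cvd"):
            raise ValueError("outcome must be 'chd' or 'cvd'")
        if self.valuation not in ("events", "qalys"):
            raise ValueError("valuation must be 'events' or 'qalys'")
        if self.horizon not in (5, 10):
            raise ValueError("horizon must be 5 or 10")
        if self.rate_multiplier <= 0:
            raise ValueError("rate_multiplier must be positive")

    @property
    def cac_strategy(self) -> str:
        return "cac_ge1" if self.treat_threshold == "ge1" else "cac_ge100"

    @property
    def strategy_names(self) -> tuple[str, str, str]:
        return ("atp3", "treat_all", self.cac_strategy)

    def parameter_overrides(self) -> dict[str, float]:
        return {"cost_cac_test": self.cac_cost, "cost_statin_annual": self.statin_cost}

    def cost_flags(self) -> economics.CostFlags:
        return economics.CostFlags(self.include_indirect, self.include_incidentaloma)


def _prepare_cohort(
    spec: ScenarioSpec,
    ps: ParameterSet,
    n_patients: int,
    seed_or_rng,
    table: JointClassificationTable = REFERENCE_COUNTS,
    exact: bool | None = None,
    age_model: Mapping | None = None,
) -> CohortTable:
    rng = seed_or_rng if isinstance(seed_or_rng, np.random.Generator) else np.random.default_rng(seed_or_rng)
    if exact is None:
        exact = n_patients == table.total
    cohort = generate_cohort(n_patients, table=table, age_model=age_model, rng=rng, exact=exact)
    rates = ps.event_rates(spec.outcome, spec.horizon)
    return assign_event_hazards(cohort, rates, spec.outcome,
                                multiplier=spec.rate_multiplier, horizon=spec.horizon)


def evaluate_strategies(
    spec: ScenarioSpec,
    cohort: CohortTable | None = None,
    ps: ParameterSet | None = None,
    seed: int = 0,
    n_patients: int | None = None,
    mode: str = "expected_value",
    crn: CommonRandomNumbers | None = None,
    life_table: LifeTable | None = None,
    options: EngineOptions | None = None,
    age_model: Mapping | None = None,
) -> dict[str, StrategyOutcome]:
    """Run ATP III, treat-all and the scenario's CAC strategy on one cohort."""
    if ps is None:
        ps = build_parameter_set(spec.parameter_overrides())
    else:
        ps = ps.with_overrides(spec.parameter_overrides())
    if life_table is None:
        life_table = load_life_table()
    rng = np.random.default_rng(seed)
    if cohort is None:
        cohort = _prepare_cohort(spec, ps, n_patients or REFERENCE_COUNTS.total, rng, age_model=age_model)
    else:
        rates = ps.event_rates(spec.outcome, spec.horizon)
        cohort = assign_event_hazards(cohort, rates, spec.outcome,
                                      multiplier=spec.rate_multiplier, horizon=spec.horizon)
    if mode == "microsimulation" and crn is None:
        crn = CommonRandomNumbers.draw(len(cohort), spec.horizon, rng)

    flags = spec.cost_flags()
    out: dict[str, StrategyOutcome] = {}
    for name in spec.strategy_names:
        sspec = StrategySpec.from_name(name)
        assignment = assign_treatment(
            cohort, sspec, ps,
            adherence_uniforms=crn.adherence if crn is not None else None,
            rng=np.random.default_rng(seed + 1) if crn is None else None,
        )
        out[name] = run_cohort(
            cohort, assignment, ps, spec.horizon, outcome_type=spec.outcome,
            mode=mode, crn=crn, life_table=life_table, options=options, cost_flags=flags,
        )
    return out


# ---------------------------------------------------------------------------
# Probabilistic sensitivity analysis
# ---------------------------------------------------------------------------


@dataclass
class PSAResult:
    """Per-simulation costs and effects for each strategy, plus summaries."""

    spec: ScenarioSpec
    table: pd.DataFrame  # sim, strategy, cost, qalys, events_per_1000, effect
    n_sims: int
    n_patients: int

    def means(self) -> pd.DataFrame:
        return self.table.groupby("strategy")[["cost", "qalys", "events_per_1000", "effect"]].mean()

    def mean_cost_effect(self) -> dict[str, economics.CostEffect]:
        m = self.means()
        return {
            s: economics.CostEffect(float(m.loc[s, "cost"]), float(m.loc[s, "effect"]))
            for s in m.index
        }

    def decision(self, threshold: float = economics.DEFAULT_WTP_THRESHOLD) -> str:
        ce = self.mean_cost_effect()
        key = {self.spec.cac_strategy: "cac"}
        return economics.decision_label({key.get(k, k): v for k, v in ce.items()},
                                        threshold=threshold)

    def ceac(self, wtp_grid: Sequence[float]) -> economics.CEACCurve:
        return economics.ceac(self.table, wtp_grid)


def run_psa(
    spec: ScenarioSpec,
    n_sims: int = 1000,
    n_patients: int = 2000,
    seed: int = 0,
    table: JointClassificationTable = REFERENCE_COUNTS,
    age_model: Mapping | None = None,
    base_ps: ParameterSet | None = None,
    life_table: LifeTable | None = None,
    options: EngineOptions | None = None,
) -> PSAResult:
    """Second-order Monte Carlo: each simulation draws one parameter set and
    one cohort, then microsimulates all three strategies with common random
    numbers."""
    if n_sims <= 0 or n_patients <= 0:
        raise ValueError("n_sims and n_patients must be positive")
    if base_ps is None:
        base_ps = build_parameter_set(spec.parameter_overrides())
    else:
        base_ps = base_ps.with_overrides(spec.parameter_overrides())
    if life_table is None:
        life_table = load_life_table()

    rows = []
    root = np.random.SeedSequence(seed)
    for sim, child in enumerate(root.spawn(n_sims)):
        rng = np.random.default_rng(child)
        ps_i = base_ps.sample(rng)
        cohort = _prepare_cohort(spec, ps_i, n_patients, rng, table=table,
                                 exact=False, age_model=age_model)
        crn = CommonRandomNumbers.draw(n_patients, spec.horizon, rng)
        outs = evaluate_strategies(
            spec, cohort=cohort, ps=ps_i, mode="microsimulation", crn=crn,
            life_table=life_table, options=options,
        )
        for name, o in outs.items():
            rows.append(
                {
                    "sim": sim,
                    "strategy": name,
                    "cost": o.cost_per_patient,
                    "qalys": o.qalys_per_patient,
                    "events_per_1000": o.events_per_1000,
                    "effect": o.effect(spec.valuation),
                }
            )
    return PSAResult(spec, pd.DataFrame(rows), n_sims, n_patients)


# ---------------------------------------------------------------------------
# Scenario grid
# ---------------------------------------------------------------------------

def table_grid_specs() -> dict[int, ScenarioSpec]:
    """The 52 published scenario rows (1-36 base-case rates, 37-52 doubled)."""

    def s(**kw) -> ScenarioSpec:
        return ScenarioSpec(**kw)

    specs: dict[int, ScenarioSpec] = {}
    # rows 1-18: CHD; 19-36: CVD (same layout)
    layout = [
        dict(cac_cost=100, statin_cost=180, horizon=5, treat_threshold="ge1", valuation="events"),
        dict(cac_cost=100, statin_cost=180, horizon=5, treat_threshold="ge1", valuation="qalys"),
        dict(cac_cost=100, statin_cost=180, horizon=5, treat_threshold="ge100", valuation="events"),
        dict(cac_cost=100, statin_cost=180, horizon=5, treat_threshold="ge100", valuation="qalys"),
        dict(cac_cost=100, statin_cost=180, horizon=10, treat_threshold="ge1", valuation="events"),
        dict(cac_cost=100, statin_cost=180, horizon=10, treat_threshold="ge1", valuation="qalys"),
        dict(cac_cost=100, statin_cost=180, horizon=10, treat_threshold="ge100", valuation="events"),
        dict(cac_cost=100, statin_cost=180, horizon=10, treat_threshold="ge100", valuation="qalys"),
        dict(cac_cost=100, statin_cost=50, horizon=5, treat_threshold="ge1", valuation="events"),
        dict(cac_cost=100, statin_cost=50, horizon=5, treat_threshold="ge1", valuation="qalys"),
        dict(cac_cost=100, statin_cost=1000, horizon=5, treat_threshold="ge1", valuation="qalys"),
        dict(cac_cost=100, statin_cost=1000, horizon=5, treat_threshold="ge100", valuation="qalys"),
        dict(cac_cost=75, statin_cost=180, horizon=5, treat_threshold="ge1", valuation="qalys"),
        dict(cac_cost=75, statin_cost=180, horizon=5, treat_threshold="ge100", valuation="qalys"),
        dict(cac_cost=150, statin_cost=180, horizon=5, treat_threshold="ge1", valuation="qalys"),
        dict(cac_cost=150, statin_cost=180, horizon=5, treat_threshold="ge100", valuation="qalys"),
        dict(cac_cost=250, statin_cost=180, horizon=5, treat_threshold="ge1", valuation="qalys"),
        dict(cac_cost=100, statin_cost=180, horizon=5, treat_threshold="ge1", valuation="qalys",
             include_indirect=True, include_incidentaloma=True),
    ]
    for i, kw in enumerate(layout, start=1):
        specs[i] = s(outcome="chd", **kw)
        specs[i + 18] = s(outcome="cvd", **kw)
    # rows 37-52: doubled event rates, eight per outcome
    doubled = [
        dict(horizon=5, treat_threshold="ge1", valuation="events"),
        dict(horizon=5, treat_threshold="ge1", valuation="qalys"),
        dict(horizon=5, treat_threshold="ge100", valuation="events"),
        dict(horizon=5, treat_threshold="ge100", valuation="qalys"),
        dict(horizon=10, treat_threshold="ge1", valuation="events"),
        dict(horizon=10, treat_threshold="ge1", valuation="qalys"),
        dict(horizon=10, treat_threshold="ge100", valuation="events"),
        dict(horizon=10, treat_threshold="ge100", valuation="qalys"),
    ]
    for i, kw in enumerate(doubled):
        specs[37 + i] = s(outcome="chd", rate_multiplier=2.0, **kw)
        specs[45 + i] = s(outcome="cvd", rate_multiplier=2.0, **kw)
    return specs


def run_scenario_grid(
    specs: Mapping[int, ScenarioSpec] | Iterable[ScenarioSpec],
    seed: int = 0,
    n_patients: int | None = None,
    threshold: float = economics.DEFAULT_WTP_THRESHOLD,
    age_model: Mapping | None = None,
) -> pd.DataFrame:
    """Evaluate every scenario with the expected-value engine and label it.

    One cohort (exact cell counts by default) is generated per seed and reused
    across scenarios so that rows differ only in their scenario settings.
    """
    if not isinstance(specs, Mapping):
        specs = {i + 1: s for i, s in enumerate(specs)}
    if not specs:
        return pd.DataFrame(
            columns=["scenario", "cac_cost", "statin_cost", "horizon", "treat_threshold",
                     "outcome", "valuation", "rate_multiplier", "decision"]
        )
    life_table = load_life_table()
    n = n_patients or REFERENCE_COUNTS.total
    cohort = generate_cohort(n, table=REFERENCE_COUNTS, age_model=age_model,
                             seed=seed, exact=(n == REFERENCE_COUNTS.total))
    rows = []
    for key, spec in specs.items():
        outs = evaluate_strategies(spec, cohort=cohort, seed=seed, life_table=life_table)
        ce = {("cac" if k.startswith("cac_") else k): economics.CostEffect(
            o.cost_per_patient, o.effect(spec.valuation)) for k, o in outs.items()}
        row = {
            "scenario": key,
            "cac_cost": spec.cac_cost,
            "statin_cost": spec.statin_cost,
            "horizon": spec.horizon,
            "treat_threshold": spec.treat_threshold,
            "outcome": spec.outcome,
            "valuation": spec.valuation,
            "rate_multiplier": spec.rate_multiplier,
            "decision": economics.decision_label(ce, threshold=threshold),
        }
        for k, o in outs.items():
            short = "cac" if k.startswith("cac_") else k
            row[f"cost_{short}"] = o.cost_per_patient
            row[f"effect_{short}"] = o.effect(spec.valuation)
            row[f"events_{short}"] = o.events_per_1000
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Break-even CAC cost
# ---------------------------------------------------------------------------


class NoBreakevenError(RuntimeError):
    """The incremental cost does not change sign over the bracketing bounds."""


def find_breakeven_cac_cost(
    spec: ScenarioSpec | None = None,
    bounds: tuple[float, float] = (0.0, 500.0),
    tol: float = 1.0,
    seed: int = 0,
    n_patients: int | None = None,
    age_model: Mapping | None = None,
) -> float:
    """CAC test cost at which the CAC strategy's total discounted cost equals
    ATP III's (the cost-saving boundary), found by bisection on the
    expected-value incremental cost."""
    spec = spec or ScenarioSpec(outcome="cvd", valuation="qalys")
    life_table = load_life_table()
    n = n_patients or REFERENCE_COUNTS.total
    cohort = generate_cohort(n, table=REFERENCE_COUNTS, age_model=age_model,
                             seed=seed, exact=(n == REFERENCE_COUNTS.total))

    def delta_cost(c: float) -> float:
        outs = evaluate_strategies(replace(spec, cac_cost=float(c)), cohort=cohort,
                                   seed=seed, life_table=life_table)
        return outs[spec.cac_strategy].cost_per_patient - outs["atp3"].cost_per_patient

    lo, hi = bounds
    f_lo, f_hi = delta_cost(lo), delta_cost(hi)
    if f_lo > 0 or f_hi < 0:
        raise NoBreakevenError(
            f"incremental cost has no sign change on [{lo}, {hi}] "
            f"(f(lo)={f_lo:.2f}, f(hi)={f_hi:.2f})"
        )
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if delta_cost(mid) <= 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)
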