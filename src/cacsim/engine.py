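"""Annual-cycle Markov engine: first CHD/CVD events, survival and QALY accrual.

Each patient occupies one of the states healthy, post-event (years 1, 2, and
later), or one of four absorbing death states (fatal first event, other-cause
death, fatal severe statin reaction, radiation-induced cancer death).  The
model runs for 5 or 10 one-year cycles; the absorbing outcome of interest is
the *first* CHD or CVD event, so post-event survivors face only background
mortality and no further counted events.

Competing risks within a cycle are resolved without an ordering assumption:
each annual probability is converted to a constant hazard (-ln(1-p)), hazards
are summed, the total transition probability is 1-exp(-sum), and the cause is
allocated proportionally to the hazards.

QALYs accrue per cycle from the age-interpolated healthy utility times
multiplicative decrements (statin disutility, statin adverse events), with a
post-event decrement that tapers linearly over two years: the event year
carries the full multiplier m, the next year (1+m)/2, and later years 1.
Costs are accumulated in an undiscounted per-cycle ledger by category and
discounted by the economics module; QALYs (and, by default, event counts) are
discounted at 3% per year, with cycle payoffs treated as end-of-year flows
(factor 1.03^-(k+1); the annuity-due convention is available via
``EngineOptions.discount_timing``).

Two evaluation modes share the same parameterization:

* ``expected_value`` -- exact state-occupancy propagation per patient, with
  recommended patients split into adherent/non-adherent branches (weights =
  the adherence probability).  Deterministic given the cohort.
* ``microsimulation`` -- individual trajectories from per-patient uniform
  streams, designed for common random numbers across strategies.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import economics
from .cohort import CohortTable
from .parameters import (
    LifeTable,
    ParameterSet,
    case_fatality,
    healthy_utility,
    load_life_table,
    productivity_cost,
)
from .strategies import INTENSITY_INTENSIVE, TreatmentAssignment

__all__ = [
    "HEALTH_STATES",
    "EngineOptions",
    "CommonRandomNumbers",
    "StrategyOutcome",
    "annual_transition",
    "qaly_cycle_value",
    "run_cohort",
]

HEALTH_STATES = (
    "healthy",
    "post_event_year1",
    "post_event_year2",
    "post_event_later",
    "dead_event",
    "dead_other",
    "dead_statin_ae",
    "dead_radiation",
)

_DEAD = {"dead_event", "dead_other", "dead_statin_ae", "dead_radiation"}


@dataclass(frozen=True)
class EngineOptions:
    """Numerical/structural switches (defaults are the base case)."""

    discount_events: bool = True  # report events on the same discounted basis as costs/QALYs
    discount_timing: str = "end"  # 'end': cycle payoffs at year end, (1+r)^-(k+1); 'start': (1+r)^-k
    half_cycle_correction: bool = False  # not applied by default (documented limitation)
    nonadherent_incur_costs: bool = False  # never-initiator reading of non-adherence
    mild_ae_annual: bool = False  # False: transient decrement in the initiation year only
    horizon_override: bool = False  # allow horizons outside {5, 10}


@dataclass
class CommonRandomNumbers:
    """Per-patient uniform streams shared across strategies within one simulation."""

    adherence: np.ndarray  # (n,)
    transition: np.ndarray  # (n, horizon) healthy-state transition / post-state mortality
    allocation: np.ndarray  # (n, horizon) cause allocation
    fatal: np.ndarray  # (n, horizon) case-fatality draw
    mild_ae: np.ndarray  # (n,)
    severe_ae: np.ndarray  # (n, horizon) non-fatal severe reaction

    @classmethod
    def draw(cls, n: int, horizon: int, rng: np.random.Generator) -> "CommonRandomNumbers":
        return cls(
            adherence=rng.uniform(size=n),
            transition=rng.uniform(size=(n, horizon)),
            allocation=rng.uniform(size=(n, horizon)),
            fatal=rng.uniform(size=(n, horizon)),
            mild_ae=rng.uniform(size=n),
            severe_ae=rng.uniform(size=(n, horizon)),
        )


@dataclass
class StrategyOutcome:
    """Per-strategy totals for one cohort run."""

    strategy: str
    n: int
    horizon: int
    outcome_type: str
    mode: str
    events_per_1000: float  # on the configured (default: discounted) basis
    events_fatal_per_1000: float
    events_nonfatal_per_1000: float
    events_per_1000_undiscounted: float
    discounted_qalys: float  # cohort total
    discounted_cost: float  # cohort total, per the cost flags used
    ledger: pd.DataFrame  # per-cycle undiscounted costs by category
    trace: pd.DataFrame  # per-cycle state occupancy and accruals
    cost_flags: "economics.CostFlags"

    @property
    def cost_per_patient(self) -> float:
        return self.discounted_cost / self.n

    @property
    def qalys_per_patient(self) -> float:
        return self.discounted_qalys / self.n

    @property
    def qalys_per_1000(self) -> float:
        return 1000.0 * self.qalys_per_patient

    def effect(self, valuation: str) -> float:
        """Per-patient effect on the 'higher is better' scale used for ICERs:
        discounted QALYs, or minus (first events per patient)."""
        if valuation == "qalys":
            return self.qalys_per_patient
        if valuation == "events":
            return -self.events_per_1000 / 1000.0
        raise ValueError("valuation must be 'events' or 'qalys'")


# ---------------------------------------------------------------------------
# Single-cycle primitives (reference implementations; the cohort runners use
# the same arithmetic vectorized)
# ---------------------------------------------------------------------------

def _hazard(p: np.ndarray | float) -> np.ndarray | float:
    return -np.log1p(-np.asarray(p, dtype=float))


def _radiation_death_prob(ps: ParameterSet) -> float:
    """Annual excess probability of a fatal radiation-induced cancer after a
    CAC scan: lifetime risk spread uniformly over the latency window, times
    the 1-year case fatality."""
    return (
        ps["radiation_lifetime_risk"]
        / ps["radiation_latency_years"]
        * ps["radiation_case_fatality"]
    )


def annual_transition(
    state: str,
    annual_event_risk: float,
    effective_rr: float,
    ps: ParameterSet,
    attained_age: float,
    rng: np.random.Generator,
    life_table: LifeTable | None = None,
    outcome_type: str = "cvd",
    on_statin: bool | None = None,
    cac_tested: bool = False,
) -> str:
    """Advance a single patient one cycle and return the next state.

    From ``healthy`` the competing risks are the first event (fatal with the
    age-specific case fatality), other-cause death, a fatal severe statin
    reaction (on-statin only) and radiation-induced cancer death (CAC-tested
    only).  Post-event survivors face only other-cause death; dead states are
    absorbing.
    """
    if state in _DEAD:
        return state
    if life_table is None:
        life_table = load_life_table()
    if on_statin is None:
        on_statin = effective_rr < 1.0
    qx = float(life_table.qx_at(attained_age))

    if state != "healthy":
        if rng.uniform() < qx:
            return "dead_other"
        return {"post_event_year1": "post_event_year2"}.get(state, "post_event_later")

    p_event = min(annual_event_risk * effective_rr, 1.0)
    r = np.array(
        [
            _hazard(p_event),
            _hazard(qx),
            _hazard(ps["p_severe_ae"] * ps["p_death_severe_ae"]) if on_statin else 0.0,
            _hazard(_radiation_death_prob(ps)) if cac_tested else 0.0,
        ]
    )
    total = r.sum()
    if not np.isfinite(total):
        raise ValueError("combined single-cycle probabilities are degenerate")
    p_any = -np.expm1(-total)
    if rng.uniform() >= p_any:
        return "healthy"
    cause = rng.choice(4, p=r / total)
    if cause == 0:
        cf = float(case_fatality(ps, outcome_type, np.array([attained_age]))[0])
        return "dead_event" if rng.uniform() < cf else "post_event_year1"
    return ("dead_other", "dead_statin_ae", "dead_radiation")[cause - 1]


def qaly_cycle_value(
    attained_age: float,
    state: str,
    ps: ParameterSet,
    outcome_type: str = "cvd",
    on_statin: bool = False,
    mild_ae: bool = False,
    severe_ae_year: bool = False,
) -> float:
    """Utility-years accrued in one cycle (pre-discount) for a given state.

    Ages are clamped to the 50-90 interpolation anchors.
    """
    if state in _DEAD:
        return 0.0
    u = float(healthy_utility(ps, np.array([attained_age]))[0])
    if state == "healthy":
        if on_statin:
            u *= ps["util_statin"]
            if mild_ae:
                u *= ps["util_mild_ae"]
            if severe_ae_year:
                u *= ps["util_severe_ae"]
        return u
    m = ps[f"util_event_{outcome_type}"]
    if state == "post_event_year1":
        return u * m
    if state == "post_event_year2":
        return u * (1.0 + m) / 2.0
    return u  # post_event_later


# ---------------------------------------------------------------------------
# Cohort runners
# ---------------------------------------------------------------------------

def run_cohort(
    cohort: CohortTable,
    assignment: TreatmentAssignment,
    ps: ParameterSet,
    horizon: int,
    outcome_type: str | None = None,
    mode: str = "expected_value",
    seed: int | None = None,
    crn: CommonRandomNumbers | None = None,
    life_table: LifeTable | None = None,
    options: EngineOptions | None = None,
    cost_flags: "economics.CostFlags | None" = None,
) -> StrategyOutcome:
    """Run one strategy over the horizon and return its totals.

    ``outcome_type`` defaults to the cohort's; hazards must already be
    assigned for that outcome.  In microsimulation mode the adherence and
    trajectory draws come from ``crn`` if given (common random numbers),
    otherwise from ``seed``.
    """
    options = options or EngineOptions()
    if horizon not in (5, 10) and not options.horizon_override:
        raise ValueError("horizon must be 5 or 10 years (set horizon_override to relax)")
    outcome_type = outcome_type or cohort.outcome_type
    if outcome_type not in ("chd", "cvd"):
        raise ValueError("outcome_type must be 'chd' or 'cvd'")
    if life_table is None:
        life_table = load_life_table()
    cost_flags = cost_flags or economics.CostFlags()

    if mode == "expected_value":
        out = _run_expected(cohort, assignment, ps, horizon, outcome_type,
                            life_table, options)
    elif mode == "microsimulation":
        if crn is None:
            crn = CommonRandomNumbers.draw(len(cohort), horizon, np.random.default_rng(seed))
        out = _run_microsim(cohort, assignment, ps, horizon, outcome_type,
                            life_table, options, crn)
    else:
        raise ValueError("mode must be 'expected_value' or 'microsimulation'")

    out.mode = mode
    out.cost_flags = cost_flags
    out.discounted_cost = economics.accrue_costs(
        out.ledger, cost_flags, discount_rate=ps["discount_rate"],
        timing=options.discount_timing,
    )
    disc = _discount_factors(ps, horizon, options)
    out.trace["cost_disc"] = (
        economics.cycle_costs(out.ledger, cost_flags).to_numpy() * disc
    )
    return out


def _discount_factors(ps: ParameterSet, horizon: int, options: EngineOptions) -> np.ndarray:
    if options.discount_timing not in ("end", "start"):
        raise ValueError("discount_timing must be 'end' or 'start'")
    offset = 1 if options.discount_timing == "end" else 0
    return (1.0 + ps["discount_rate"]) ** -(np.arange(horizon) + offset)


def _utility_multiplier_expected(ps: ParameterSet, with_mild: bool) -> float:
    """Expected annual utility multiplier while on a statin (disutility of use
    times the expectation over the adverse-event branches).  The mild-AE
    decrement enters only in cycles where it applies (by default the
    initiation year, when the transient complication occurs)."""
    p_mild, p_sev = ps["p_mild_ae"], ps["p_severe_ae"]
    mult = ps["util_statin"] * (1.0 - p_sev + p_sev * ps["util_severe_ae"])
    if with_mild:
        mult *= 1.0 - p_mild + p_mild * ps["util_mild_ae"]
    return mult


def _empty_ledger(horizon: int) -> pd.DataFrame:
    return pd.DataFrame(
        0.0, index=pd.RangeIndex(horizon, name="cycle"), columns=list(economics.COST_CATEGORIES)
    )


def _finalize(
    strategy: str,
    n: int,
    horizon: int,
    outcome_type: str,
    ps: ParameterSet,
    options: EngineOptions,
    trace_rows: list[dict],
    ledger: pd.DataFrame,
    events_k: np.ndarray,
    events_fatal_k: np.ndarray,
    qalys_k: np.ndarray,
) -> StrategyOutcome:
    disc = _discount_factors(ps, horizon, options)
    ev_basis = disc if options.discount_events else np.ones(horizon)
    events = float(events_k @ ev_basis)
    events_fatal = float(events_fatal_k @ ev_basis)
    trace = pd.DataFrame(trace_rows)
    trace["qalys_disc"] = qalys_k * disc
    return StrategyOutcome(
        strategy=strategy,
        n=n,
        horizon=horizon,
        outcome_type=outcome_type,
        mode="",
        events_per_1000=1000.0 * events / n,
        events_fatal_per_1000=1000.0 * events_fatal / n,
        events_nonfatal_per_1000=1000.0 * (events - events_fatal) / n,
        events_per_1000_undiscounted=1000.0 * float(events_k.sum()) / n,
        discounted_qalys=float(qalys_k @ disc),
        discounted_cost=np.nan,
        ledger=ledger,
        trace=trace,
        cost_flags=economics.CostFlags(),
    )


def _run_expected(cohort, assignment, ps, horizon, outcome_type, life_table, options):
    n = len(cohort)
    rec = assignment.recommended
    adh_p = assignment.adherence_prob
    rr_int = assignment.intensity_rr

    # branch expansion: an untreated replica for everyone, plus an on-statin
    # replica (weight = adherence probability) for each recommended patient
    w_untreated = np.where(rec, 1.0 - adh_p, 1.0)
    age0 = np.concatenate([cohort.ages, cohort.ages[rec]])
    risk = np.concatenate([cohort.risks, cohort.risks[rec]])
    w = np.concatenate([w_untreated, adh_p[rec]])
    on_statin = np.concatenate([np.zeros(n, dtype=bool), np.ones(int(rec.sum()), dtype=bool)])
    rr = np.where(on_statin, np.concatenate([np.ones(n), rr_int[rec]]), 1.0)
    # drop zero-weight rows (e.g. adherence 0 or 1)
    keep = w > 0
    age0, risk, w, on_statin, rr = age0[keep], risk[keep], w[keep], on_statin[keep], rr[keep]

    cac_tested = assignment.strategy.cac_tested
    p_sev = ps["p_severe_ae"]
    r_sae = _hazard(p_sev * ps["p_death_severe_ae"])
    r_rad = _hazard(_radiation_death_prob(ps)) if cac_tested else 0.0
    m_evt = ps[f"util_event_{outcome_type}"]
    statin_cost = ps["cost_statin_annual"]

    h = w.copy()
    p1 = np.zeros_like(w)
    p2 = np.zeros_like(w)
    pl = np.zeros_like(w)
    dead = {k: 0.0 for k in ("dead_event", "dead_other", "dead_statin_ae", "dead_radiation")}

    ledger = _empty_ledger(horizon)
    if cac_tested:
        ledger.loc[0, "cac_test"] = n * ps["cost_cac_test"]
        ledger.loc[0, "cac_time"] = n * ps["cost_cac_time"]
        ledger.loc[0, "incidentaloma"] = n * ps["incidentaloma_fraction"] * ps["cost_incidentaloma"]
    initiators = float(w[on_statin].sum())
    ledger.loc[0, "ae_mild"] = initiators * ps["p_mild_ae"] * ps["cost_mild_ae"]
    if options.nonadherent_incur_costs:
        # alternative reading: non-adherent recommended patients fill
        # prescriptions (costs and AEs) without benefit
        extra = float((w_untreated * rec)[rec].sum()) if n else 0.0
        ledger.loc[0, "ae_mild"] += extra * ps["p_mild_ae"] * ps["cost_mild_ae"]

    events_k = np.zeros(horizon)
    events_fatal_k = np.zeros(horizon)
    qalys_k = np.zeros(horizon)
    trace_rows = []

    pays_statin = on_statin.copy()
    if options.nonadherent_incur_costs:
        pays_statin = pays_statin | np.concatenate(
            [rec, np.zeros(int(rec.sum()), dtype=bool)]
        )[keep]

    for k in range(horizon):
        age_k = age0 + k
        qx = life_table.qx_at(age_k)
        p_event = np.clip(risk * rr, 0.0, 1.0)
        r_ev = _hazard(p_event)
        r_ox = _hazard(qx)
        r3 = np.where(on_statin, r_sae, 0.0)
        total = r_ev + r_ox + r3 + r_rad
        if np.any(~np.isfinite(total)):
            raise ValueError("combined single-cycle probabilities are degenerate")
        p_any = -np.expm1(-total)
        with np.errstate(invalid="ignore", divide="ignore"):
            inv = np.where(total > 0, 1.0 / np.where(total > 0, total, 1.0), 0.0)
        trans = h * p_any
        ev = trans * r_ev * inv
        cf = case_fatality(ps, outcome_type, age_k)
        fatal = ev * cf
        nonfatal = ev - fatal
        d_other_h = trans * r_ox * inv
        d_sae = trans * r3 * inv
        d_rad = trans * r_rad * inv

        h_start = h
        h = h - trans
        p1_d, p2_d, pl_d = p1 * qx, p2 * qx, pl * qx
        pl_new = pl - pl_d + p2 - p2_d
        p2_new = p1 - p1_d
        p1_new = nonfatal
        dead["dead_event"] += float(fatal.sum())
        dead["dead_other"] += float(d_other_h.sum() + p1_d.sum() + p2_d.sum() + pl_d.sum())
        dead["dead_statin_ae"] += float(d_sae.sum())
        dead["dead_radiation"] += float(d_rad.sum())
        p1, p2, pl = p1_new, p2_new, pl_new

        u = healthy_utility(ps, age_k)
        u_statin = _utility_multiplier_expected(ps, with_mild=(k == 0 or options.mild_ae_annual))
        u_h = u * np.where(on_statin, u_statin, 1.0)
        qalys_k[k] = float(
            (h * u_h).sum() + (p1 * u * m_evt).sum() + (p2 * u * (1 + m_evt) / 2).sum() + (pl * u).sum()
        )

        statin_years = float((h_start * pays_statin).sum())
        ledger.loc[k, "statin"] += statin_years * statin_cost
        ledger.loc[k, "ae_severe"] += statin_years * p_sev * ps["cost_severe_ae"]
        ledger.loc[k, "event_fatal"] += float(fatal.sum()) * ps[f"cost_event_fatal_{outcome_type}"]
        ledger.loc[k, "event_nonfatal"] += (
            float(nonfatal.sum()) * ps[f"cost_event_nonfatal_{outcome_type}"]
        )
        ledger.loc[k, "productivity"] += float((ev * productivity_cost(ps, outcome_type, age_k)).sum())

        events_k[k] = float(ev.sum())
        events_fatal_k[k] = float(fatal.sum())
        trace_rows.append(
            {
                "cycle": k,
                "healthy": float(h.sum()),
                "post_event_year1": float(p1.sum()),
                "post_event_year2": float(p2.sum()),
                "post_event_later": float(pl.sum()),
                **dead,
                "events": events_k[k],
                "events_fatal": events_fatal_k[k],
            }
        )

    return _finalize(
        assignment.strategy.name, n, horizon, outcome_type, ps, options,
        trace_rows, ledger, events_k, events_fatal_k, qalys_k,
    )


def _run_microsim(cohort, assignment, ps, horizon, outcome_type, life_table, options, crn):
    n = len(cohort)
    age0 = cohort.ages
    risk = cohort.risks
    rec = assignment.recommended
    adh_p = assignment.adherence_prob
    adherent = rec & (crn.adherence < adh_p)
    rr_int = assignment.intensity_rr

    cac_tested = assignment.strategy.cac_tested
    p_sev = ps["p_severe_ae"]
    p_sae_death = p_sev * ps["p_death_severe_ae"]
    p_sev_nonfatal = p_sev * (1.0 - ps["p_death_severe_ae"])
    r_rad = _hazard(_radiation_death_prob(ps)) if cac_tested else 0.0
    m_evt = ps[f"util_event_{outcome_type}"]
    statin_cost = ps["cost_statin_annual"]

    on_statin = adherent.copy()  # may switch off after a severe reaction
    pays_statin_base = adherent | (rec if options.nonadherent_incur_costs else False)
    mild = on_statin & (crn.mild_ae < ps["p_mild_ae"])
    initiators = pays_statin_base if options.nonadherent_incur_costs else adherent
    mild_payers = initiators & (crn.mild_ae < ps["p_mild_ae"])

    # state: 0 healthy, 1..3 post-event (year1, year2, later), 4..7 dead
    state = np.zeros(n, dtype=int)
    S_P1, S_P2, S_PL, S_DEV, S_DOTH, S_DSAE, S_DRAD = 1, 2, 3, 4, 5, 6, 7

    ledger = _empty_ledger(horizon)
    if cac_tested:
        ledger.loc[0, "cac_test"] = n * ps["cost_cac_test"]
        ledger.loc[0, "cac_time"] = n * ps["cost_cac_time"]
        ledger.loc[0, "incidentaloma"] = n * ps["incidentaloma_fraction"] * ps["cost_incidentaloma"]
    ledger.loc[0, "ae_mild"] = float(mild_payers.sum()) * ps["cost_mild_ae"]

    events_k = np.zeros(horizon)
    events_fatal_k = np.zeros(horizon)
    qalys_k = np.zeros(horizon)
    trace_rows = []

    for k in range(horizon):
        age_k = age0 + k
        qx = life_table.qx_at(age_k)
        healthy = state == 0

        rr = np.where(on_statin, rr_int, 1.0)
        p_event = np.clip(risk * rr, 0.0, 1.0)
        r_ev = _hazard(p_event)
        r_ox = _hazard(qx)
        r3 = np.where(on_statin, _hazard(p_sae_death), 0.0)
        total = r_ev + r_ox + r3 + r_rad
        p_any = -np.expm1(-total)

        statin_active = healthy & on_statin
        statin_payers = healthy & (pays_statin_base if options.nonadherent_incur_costs else on_statin)
        ledger.loc[k, "statin"] += float(statin_payers.sum()) * statin_cost

        # non-fatal severe reaction: cost + utility hit this year, then stop
        severe_year = statin_active & (crn.severe_ae[:, k] < p_sev_nonfatal)
        ledger.loc[k, "ae_severe"] += float(severe_year.sum()) * ps["cost_severe_ae"]

        trans = healthy & (crn.transition[:, k] < p_any)
        with np.errstate(invalid="ignore", divide="ignore"):
            share_ev = np.where(total > 0, r_ev / np.where(total > 0, total, 1.0), 0.0)
            share_ox = np.where(total > 0, r_ox / np.where(total > 0, total, 1.0), 0.0)
            share_sae = np.where(total > 0, r3 / np.where(total > 0, total, 1.0), 0.0)
        u_alloc = crn.allocation[:, k]
        is_event = trans & (u_alloc < share_ev)
        is_oth = trans & ~is_event & (u_alloc < share_ev + share_ox)
        is_sae = trans & ~is_event & ~is_oth & (u_alloc < share_ev + share_ox + share_sae)
        is_rad = trans & ~is_event & ~is_oth & ~is_sae

        cf = case_fatality(ps, outcome_type, age_k)
        fatal = is_event & (crn.fatal[:, k] < cf)
        nonfatal = is_event & ~fatal

        # post-event background mortality (reuses the transition stream; a
        # patient is either healthy or post-event in a given cycle)
        post = (state >= S_P1) & (state <= S_PL)
        post_dies = post & (crn.transition[:, k] < qx)

        new_state = state.copy()
        new_state[post & ~post_dies & (state == S_P1)] = S_P2
        new_state[post & ~post_dies & ((state == S_P2) | (state == S_PL))] = S_PL
        new_state[post_dies] = S_DOTH
        new_state[nonfatal] = S_P1
        new_state[fatal] = S_DEV
        new_state[is_oth] = S_DOTH
        new_state[is_sae] = S_DSAE
        new_state[is_rad] = S_DRAD
        state = new_state

        n_fatal = int(fatal.sum())
        n_nonfatal = int(nonfatal.sum())
        ledger.loc[k, "event_fatal"] += n_fatal * ps[f"cost_event_fatal_{outcome_type}"]
        ledger.loc[k, "event_nonfatal"] += n_nonfatal * ps[f"cost_event_nonfatal_{outcome_type}"]
        ledger.loc[k, "productivity"] += float(
            productivity_cost(ps, outcome_type, age_k)[is_event].sum()
        )

        u = healthy_utility(ps, age_k)
        u_cycle = np.zeros(n)
        still_healthy = state == 0
        mult = np.ones(n)
        mult[statin_active] = ps["util_statin"]
        if k == 0 or options.mild_ae_annual:
            mult[statin_active & mild] *= ps["util_mild_ae"]
        mult[severe_year] *= ps["util_severe_ae"]
        u_cycle[still_healthy] = (u * mult)[still_healthy]
        u_cycle[state == S_P1] = (u * m_evt)[state == S_P1]
        u_cycle[state == S_P2] = (u * (1 + m_evt) / 2)[state == S_P2]
        u_cycle[state == S_PL] = u[state == S_PL]
        qalys_k[k] = float(u_cycle.sum())

        on_statin = on_statin & ~severe_year  # discontinue after severe reaction

        events_k[k] = n_fatal + n_nonfatal
        events_fatal_k[k] = n_fatal
        trace_rows.append(
            {
                "cycle": k,
                "healthy": int((state == 0).sum()),
                "post_event_year1": int((state == S_P1).sum()),
                "post_event_year2": int((state == S_P2).sum()),
                "post_event_later": int((state == S_PL).sum()),
                "dead_event": int((state == S_DEV).sum()),
                "dead_other": int((state == S_DOTH).sum()),
                "dead_statin_ae": int((state == S_DSAE).sum()),
                "dead_radiation": int((state == S_DRAD).sum()),
                "events": events_k[k],
                "events_fatal": events_fatal_k[k],
            }
        )

    return _finalize(
        assignment.strategy.name, n, horizon, outcome_type, ps, options,
        trace_rows, ledger, events_k, events_fatal_k, qalys_k,
    )
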