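"""Markov engine: closed forms, conservation, mode equivalence, monotonicity."""

import numpy as np
import pytest

from cacsim.cohort import assign_event_hazards, generate_cohort
from cacsim.engine import (
    CommonRandomNumbers,
    EngineOptions,
    annual_transition,
    qaly_cycle_value,
    run_cohort,
)
from cacsim.parameters import LifeTable, case_fatality
from cacsim.strategies import StrategySpec, assign_treatment

from conftest import single_patient_cohort

_STATES = [
    "healthy", "post_event_year1", "post_event_year2", "post_event_later",
    "dead_event", "dead_other", "dead_statin_ae", "dead_radiation",
]


def _run_single(ps, life_table, *, age=60.0, risk=0.0, strategy="atp3",
                horizon=5, options=None, ps_overrides=None, outcome="cvd"):
    cohort = single_patient_cohort(age=age, risk=risk)
    if ps_overrides:
        ps = ps.with_overrides(ps_overrides)
    asg = assign_treatment(cohort, StrategySpec.from_name(strategy), ps, seed=0)
    return run_cohort(cohort, asg, ps, horizon, outcome, life_table=life_table,
                      options=options)


class TestSingleCycle:
    def test_dead_states_are_absorbing(self, ps, zero_mortality):
        rng = np.random.default_rng(0)
        for state in ("dead_event", "dead_other", "dead_statin_ae", "dead_radiation"):
            assert annual_transition(state, 0.5, 1.0, ps, 60, rng, zero_mortality) == state

    def test_zero_hazards_keep_healthy(self, ps, zero_mortality):
        ps0 = ps.with_overrides({"p_severe_ae": 0.0, "radiation_lifetime_risk": 0.0})
        rng = np.random.default_rng(1)
        for _ in range(50):
            assert annual_transition("healthy", 0.0, 1.0, ps0, 60, rng, zero_mortality) == "healthy"

    def test_post_event_progression(self, ps, zero_mortality):
        rng = np.random.default_rng(2)
        assert annual_transition("post_event_year1", 0.0, 1.0, ps, 60, rng, zero_mortality) == "post_event_year2"
        assert annual_transition("post_event_year2", 0.0, 1.0, ps, 60, rng, zero_mortality) == "post_event_later"
        assert annual_transition("post_event_later", 0.0, 1.0, ps, 60, rng, zero_mortality) == "post_event_later"


class TestClosedForms:
    def test_five_cycle_cumulative_event_probability(self, ps, zero_mortality):
        """With only the event hazard active, the engine reproduces
        1 - (1-p)^5 exactly."""
        p = 0.01920450
        ps0 = ps.with_overrides(
            {"p_severe_ae": 0.0, "radiation_lifetime_risk": 0.0, "adherence_no_cac": 0.0}
        )
        out = _run_single(ps0, zero_mortality, age=55.0, risk=p)
        expected = 1.0 - (1.0 - p) ** 5
        assert out.events_per_1000_undiscounted / 1000.0 == pytest.approx(expected, abs=1e-12)

    def test_discounted_qalys_zero_hazard(self, ps, zero_mortality):
        """Age-60 untreated survivor: sum of age-interpolated utilities times
        the 3% discount factors (annuity-due convention)."""
        untreated = {"adherence_no_cac": 0.0}
        opts = EngineOptions(discount_timing="start")
        out = _run_single(ps, zero_mortality, age=60.0, risk=0.0, options=opts,
                          ps_overrides=untreated)
        u = [0.82, 0.817, 0.814, 0.811, 0.808]  # anchors 0.82@60, 0.79@70
        expected = sum(ui * 1.03**-k for k, ui in enumerate(u))
        assert out.discounted_qalys == pytest.approx(expected, abs=1e-9)
        # end-of-cycle timing is the same sum shifted one period
        out_end = _run_single(ps, zero_mortality, age=60.0, risk=0.0,
                              ps_overrides=untreated)
        assert out_end.discounted_qalys == pytest.approx(expected / 1.03, abs=1e-9)

    def test_statin_cost_geometric_sum(self, ps, zero_mortality):
        """Five on-statin years at $180 discounted at 3%: 180 * sum(1.03^-k)."""
        ps1 = ps.with_overrides({"adherence_no_cac": 1.0, "p_severe_ae": 0.0})
        out = _run_single(ps1, zero_mortality, risk=0.0, strategy="atp3")
        statin = out.ledger["statin"].to_numpy()
        discounted = float(statin @ 1.03 ** -np.arange(5))
        assert discounted == pytest.approx(180 * sum(1.03**-k for k in range(5)), abs=1e-6)
        assert discounted == pytest.approx(849.08, abs=0.01)

    def test_fatal_event_stops_qaly_accrual(self, ps, zero_mortality):
        """A certain, always-fatal event in cycle 0 leaves zero QALYs."""
        ps1 = ps.with_overrides(
            {"cf_cvd_lt65": 1.0, "cf_cvd_ge65": 1.0, "adherence_no_cac": 0.0}
        )
        out = _run_single(ps1, zero_mortality, risk=np.nextafter(1.0, 0.0))
        assert out.discounted_qalys == pytest.approx(0.0, abs=1e-9)
        assert out.events_per_1000_undiscounted == pytest.approx(1000.0, abs=1e-6)

    def test_untreated_never_event_patient_costs_nothing(self, ps, zero_mortality):
        out = _run_single(ps, zero_mortality, risk=0.0, strategy="atp3",
                          ps_overrides={"adherence_no_cac": 0.0})
        assert out.discounted_cost == 0.0


class TestQalyCycleValue:
    def test_healthy_utility_anchor(self, ps):
        assert qaly_cycle_value(60.0, "healthy", ps) == pytest.approx(0.82)

    def test_dead_is_zero(self, ps):
        assert qaly_cycle_value(60.0, "dead_event", ps) == 0.0

    def test_post_event_taper(self, ps):
        y1 = qaly_cycle_value(60.0, "post_event_year1", ps, outcome_type="chd")
        y2 = qaly_cycle_value(60.0, "post_event_year2", ps, outcome_type="chd")
        later = qaly_cycle_value(60.0, "post_event_later", ps, outcome_type="chd")
        assert y1 == pytest.approx(0.82 * 0.8351)  # 0.684782
        assert y2 == pytest.approx(0.82 * (1 + 0.8351) / 2)  # 0.752391
        assert later == pytest.approx(0.82)

    def test_utility_clamped_outside_anchor_range(self, ps):
        assert qaly_cycle_value(45.0, "healthy", ps) == pytest.approx(0.84)
        assert qaly_cycle_value(95.0, "healthy", ps) == pytest.approx(0.68)

    def test_statin_multipliers(self, ps):
        base = qaly_cycle_value(60.0, "healthy", ps, on_statin=True)
        assert base == pytest.approx(0.82 * 0.99616)
        with_ae = qaly_cycle_value(60.0, "healthy", ps, on_statin=True,
                                   mild_ae=True, severe_ae_year=True)
        assert with_ae == pytest.approx(0.82 * 0.99616 * 0.9941 * 0.9553)


class TestCohortRuns:
    def test_occupancy_conservation_both_modes(self, exact_cohort, ps, life_table):
        asg = assign_treatment(exact_cohort, StrategySpec.from_name("cac_ge1"), ps, seed=0)
        for mode in ("expected_value", "microsimulation"):
            out = run_cohort(exact_cohort, asg, ps, 5, "cvd", mode=mode, seed=1,
                             life_table=life_table)
            occ = out.trace[_STATES].sum(axis=1).to_numpy()
            assert np.allclose(occ, len(exact_cohort), atol=1e-8)

    def test_fatal_plus_nonfatal_equals_total(self, exact_cohort, ps, life_table):
        asg = assign_treatment(exact_cohort, StrategySpec.from_name("atp3"), ps, seed=0)
        out = run_cohort(exact_cohort, asg, ps, 5, "cvd", life_table=life_table)
        assert out.events_fatal_per_1000 + out.events_nonfatal_per_1000 == pytest.approx(
            out.events_per_1000
        )

    def test_microsim_converges_to_expected_value(self, ps, life_table):
        n = 100_000
        cohort = generate_cohort(n, seed=7)
        cohort = assign_event_hazards(cohort, ps.event_rates("cvd", 5), "cvd")
        rng = np.random.default_rng(11)
        crn = CommonRandomNumbers.draw(n, 5, rng)
        asg = assign_treatment(cohort, StrategySpec.from_name("cac_ge1"), ps,
                               adherence_uniforms=crn.adherence)
        ev = run_cohort(cohort, asg, ps, 5, "cvd", life_table=life_table)
        mc = run_cohort(cohort, asg, ps, 5, "cvd", mode="microsimulation", crn=crn,
                        life_table=life_table)
        p = ev.events_per_1000_undiscounted / 1000.0
        se = 1000.0 * np.sqrt(p * (1 - p) / n)
        assert abs(mc.events_per_1000_undiscounted - ev.events_per_1000_undiscounted) < 3 * se
        assert mc.qalys_per_patient == pytest.approx(ev.qalys_per_patient, rel=2e-3)

    def test_events_monotone_in_rr_and_adherence(self, exact_cohort, ps, life_table):
        def events(overrides):
            ps_i = ps.with_overrides(overrides)
            asg = assign_treatment(exact_cohort, StrategySpec.from_name("atp3"), ps_i, seed=0)
            return run_cohort(exact_cohort, asg, ps_i, 5, "cvd", life_table=life_table).events_per_1000

        by_rr = [events({"rr_moderate": r}) for r in (0.4, 0.65, 1.0)]
        assert by_rr[0] < by_rr[1] < by_rr[2]
        by_adh = [events({"adherence_no_cac": a}) for a in (0.2, 0.55, 0.9)]
        assert by_adh[0] > by_adh[1] > by_adh[2]

    def test_discounting_monotone_in_rate(self, exact_cohort, ps, life_table):
        def run(rate):
            ps_i = ps.with_overrides({"discount_rate": rate})
            asg = assign_treatment(exact_cohort, StrategySpec.from_name("cac_ge1"), ps_i, seed=0)
            return run_cohort(exact_cohort, asg, ps_i, 5, "cvd", life_table=life_table)

        lo, hi = run(0.03), run(0.06)
        assert hi.discounted_qalys < lo.discounted_qalys
        assert hi.discounted_cost < lo.discounted_cost

    def test_microsim_seed_reproducibility(self, exact_cohort, ps, life_table):
        asg = assign_treatment(exact_cohort, StrategySpec.from_name("treat_all"), ps, seed=0)

        def run(seed):
            out = run_cohort(exact_cohort, asg, ps, 5, "cvd", mode="microsimulation",
                             seed=seed, life_table=life_table)
            return (out.events_per_1000, out.discounted_qalys, out.discounted_cost)

        assert run(5) == run(5)
        assert run(5) != run(6)

    def test_case_fatality_uses_attained_age(self, ps):
        assert case_fatality(ps, "chd", np.array([64.0]))[0] == 0.10000
        assert case_fatality(ps, "chd", np.array([65.0]))[0] == 0.15714

    def test_invalid_horizon_rejected(self, exact_cohort, ps, life_table):
        asg = assign_treatment(exact_cohort, StrategySpec.from_name("atp3"), ps, seed=0)
        with pytest.raises(ValueError):
            run_cohort(exact_cohort, asg, ps, 7, "cvd", life_table=life_table)
        out = run_cohort(exact_cohort, asg, ps, 3, "cvd", life_table=life_table,
                         options=EngineOptions(horizon_override=True))
        assert out.horizon == 3

    def test_null_calibration_recovers_stratum_rates(self, ps, life_table, zero_mortality):
        """Untreated cohort: per-stratum 5-year cumulative event fractions
        equal 1-(1-rate)^5 when background mortality is switched off."""
        cohort = generate_cohort(1619, seed=2, exact=True)
        cohort = assign_event_hazards(cohort, ps.event_rates("cvd", 5), "cvd")
        ps0 = ps.with_overrides({"adherence_no_cac": 0.0, "p_severe_ae": 0.0})
        asg = assign_treatment(cohort, StrategySpec.from_name("atp3"), ps0, seed=0)
        out = run_cohort(cohort, asg, ps0, 5, "cvd", life_table=zero_mortality)
        rates = ps.event_rates("cvd", 5)
        counts = {s: int((cohort.strata == i).sum()) for i, s in enumerate(("zero", "low", "high"))}
        expected = sum(counts[s] * (1 - (1 - r) ** 5) for s, r in rates.items())
        assert out.events_per_1000_undiscounted / 1000.0 * len(cohort) == pytest.approx(
            expected, abs=1e-8
        )
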