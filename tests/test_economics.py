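"""Cost accrual, ICER/dominance classification, decision labels and CEACs."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cacsim.economics import (
    COST_CATEGORIES,
    CEACCurve,
    CostEffect,
    CostFlags,
    accrue_costs,
    ceac,
    compare_strategies,
    decision_label,
)


def _ledger(horizon=5, seed=0):
    rng = np.random.default_rng(seed)
    return pd.DataFrame(
        rng.uniform(0, 100, size=(horizon, len(COST_CATEGORIES))), columns=list(COST_CATEGORIES)
    )


class TestAccrual:
    def test_base_flags_exclude_indirect_and_incidentaloma(self):
        led = _ledger()
        base = accrue_costs(led, CostFlags())
        with_all = accrue_costs(led, CostFlags(True, True))
        extra = led[["productivity", "cac_time", "incidentaloma"]].sum(axis=1).to_numpy()
        disc = 1.03 ** -(np.arange(5) + 1)
        assert with_all - base == pytest.approx(float(extra @ disc))

    def test_removing_a_component_never_increases_cost(self):
        led = _ledger()
        for a, b in itertools.product([False, True], repeat=2):
            assert accrue_costs(led, CostFlags(a, b)) <= accrue_costs(led, CostFlags(True, True))

    def test_discount_timing(self):
        led = pd.DataFrame(0.0, index=range(5), columns=list(COST_CATEGORIES))
        led["statin"] = 180.0
        start = accrue_costs(led, CostFlags(), timing="start")
        end = accrue_costs(led, CostFlags(), timing="end")
        assert start == pytest.approx(180 * sum(1.03**-k for k in range(5)))
        assert end == pytest.approx(start / 1.03)

    def test_unknown_category_rejected(self):
        led = _ledger().rename(columns={"statin": "lipitor"})
        with pytest.raises(ValueError):
            accrue_costs(led, CostFlags())


class TestCompare:
    def test_dominant_by_definition(self):
        r = compare_strategies(CostEffect(90, 1.5), CostEffect(100, 1.0))
        assert r.classification == "dominant" and r.icer is None
        assert r.delta_cost == -10 and r.delta_effect == 0.5

    def test_icer_below_threshold_is_cost_effective(self):
        r = compare_strategies(CostEffect(1000, 0.1), CostEffect(0, 0.0))
        assert r.icer == pytest.approx(10_000)
        assert r.classification == "cost_effective_at_threshold"

    def test_icer_above_threshold_is_rejected(self):
        r = compare_strategies(CostEffect(6000, 0.1), CostEffect(0, 0.0))
        assert r.icer == pytest.approx(60_000)
        assert r.classification == "not_cost_effective"

    @given(
        c1=st.floats(-1e6, 1e6), e1=st.floats(-100, 100),
        c2=st.floats(-1e6, 1e6), e2=st.floats(-100, 100),
    )
    @settings(max_examples=200, deadline=None)
    def test_antisymmetry(self, c1, e1, c2, e2):
        ab = compare_strategies(CostEffect(c1, e1), CostEffect(c2, e2))
        ba = compare_strategies(CostEffect(c2, e2), CostEffect(c1, e1))
        assert ab.delta_cost == -ba.delta_cost
        assert ab.delta_effect == -ba.delta_effect
        if ab.classification == "dominant":
            assert ba.classification == "dominated"
        if ab.classification == "dominated":
            assert ba.classification == "dominant"


class TestDecisionLabel:
    def test_cac_dominates_both(self):
        label = decision_label(
            {"atp3": CostEffect(100, 1.0), "treat_all": CostEffect(120, 1.1), "cac": CostEffect(80, 1.2)}
        )
        assert label == "CAC Dominates Both"

    def test_status_quo_when_alternatives_too_costly(self):
        label = decision_label(
            {"atp3": CostEffect(100, 1.0), "treat_all": CostEffect(100_000, 1.5),
             "cac": CostEffect(90_000, 1.4)}
        )
        assert label == "ATP III (Status Quo)"

    def test_treat_all_dominates_atp3_only(self):
        # treat-all cheaper and most effective; CAC cheaper still but less effective
        label = decision_label(
            {"atp3": CostEffect(100, 1.0), "treat_all": CostEffect(90, 1.3), "cac": CostEffect(70, 1.2)}
        )
        assert label == "Treat All Dominates ATP III"

    def test_cost_effective_label_carries_icer(self):
        label = decision_label(
            {"atp3": CostEffect(0, 0.0), "treat_all": CostEffect(400, 0.1), "cac": CostEffect(900, 0.05)}
        )
        assert label == "Treat All Cost-Effective; ICER = $4,000"

    def test_missing_comparator_rejected(self):
        with pytest.raises(ValueError):
            decision_label({"treat_all": CostEffect(1, 1), "cac": CostEffect(2, 2)})


def _psa_frame(costs, effects):
    rows = []
    for sim, (cs_, es_) in enumerate(zip(costs, effects)):
        for s, c, e in zip(("a", "b", "c"), cs_, es_):
            rows.append({"sim": sim, "strategy": s, "cost": c, "effect": e})
    return pd.DataFrame(rows)


class TestCEAC:
    def test_matches_brute_force_on_hand_written_sims(self):
        costs = [(10, 20, 30), (25, 5, 30), (30, 20, 10)]
        effects = [(1.0, 2.0, 3.0), (1.0, 1.0, 2.0), (3.0, 2.0, 1.0)]
        grid = [0.0, 5.0, 20.0]
        curve = ceac(_psa_frame(costs, effects), grid)
        for wtp in grid:
            for j, s in enumerate(("a", "b", "c")):
                wins = 0.0
                for cs_, es_ in zip(costs, effects):
                    nmb = [wtp * e - c for c, e in zip(cs_, es_)]
                    best = max(nmb)
                    winners = [i for i, v in enumerate(nmb) if v == best]
                    if j in winners:
                        wins += 1.0 / len(winners)
                assert curve.acceptance_at(wtp, s) == pytest.approx(wins / len(costs))

    def test_acceptance_sums_to_one_everywhere(self):
        rng = np.random.default_rng(3)
        costs = rng.uniform(0, 1000, size=(40, 3))
        effects = rng.uniform(0, 5, size=(40, 3))
        grid = np.linspace(0, 100_000, 11)
        curve = ceac(_psa_frame(costs, effects), grid)
        sums = curve.table.groupby("wtp")["acceptance"].sum()
        assert np.allclose(sums.to_numpy(), 1.0, atol=1e-12)

    def test_single_strategy_always_accepted(self):
        df = pd.DataFrame(
            {"sim": [0, 1], "strategy": "only", "cost": [10.0, 20.0], "effect": [1.0, 2.0]}
        )
        curve = ceac(df, [0.0, 50_000.0])
        assert np.all(curve.table["acceptance"] == 1.0)

    def test_cheapest_strategy_wins_at_zero_wtp(self):
        rng = np.random.default_rng(4)
        costs = np.column_stack([rng.uniform(0, 10, 20), rng.uniform(20, 30, 20), rng.uniform(40, 50, 20)])
        effects = rng.uniform(0, 5, size=(20, 3))
        curve = ceac(_psa_frame(costs, effects), [0.0])
        assert curve.acceptance_at(0.0, "a") == 1.0

    def test_equal_costs_decided_by_effects(self):
        costs = np.full((10, 3), 100.0)
        effects = np.column_stack([np.full(10, 1.0), np.full(10, 3.0), np.full(10, 2.0)])
        curve = ceac(_psa_frame(costs, effects), [10_000.0])
        assert curve.acceptance_at(10_000.0, "b") == 1.0

    def test_empty_results_rejected(self):
        with pytest.raises(ValueError):
            ceac(pd.DataFrame(columns=["sim", "strategy", "cost", "effect"]), [0.0])
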