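"""Cost accrual, incremental comparisons (ICER / dominance), decision labels,
and cost-effectiveness acceptability curves.

All monetary amounts are 2011 USD.  The base case includes the direct costs
of CAC testing, statins and events; productivity costs, the CAC time cost and
the incidentaloma re-scan penalty are included only when the corresponding
flags are set.  Pairwise decisions follow the published rule: a strategy
dominates if it is both less costly and more effective; otherwise an
alternative with a positive ICER at or below the willingness-to-pay threshold
(default $50,000 per unit of effect) is favored over the status quo.
Acceptability curves use the standard max-net-monetary-benefit rule among all
mutually exclusive strategies, with ties split equally.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "COST_CATEGORIES",
    "CostFlags",
    "CostEffect",
    "ComparisonResult",
    "CEACCurve",
    "accrue_costs",
    "cycle_costs",
    "compare_strategies",
    "ceac",
    "decision_label",
    "DEFAULT_WTP_THRESHOLD",
]

COST_CATEGORIES = (
    "cac_test",
    "statin",
    "event_nonfatal",
    "event_fatal",
    "ae_mild",
    "ae_severe",
    "incidentaloma",
    "productivity",
    "cac_time",
)

_BASE_CATEGORIES = ("cac_test", "statin", "event_nonfatal", "event_fatal", "ae_mild", "ae_severe")
_INDIRECT_CATEGORIES = ("productivity", "cac_time")

DEFAULT_WTP_THRESHOLD = 50_000.0


@dataclass(frozen=True)
class CostFlags:
    """Which optional cost components to include."""

    include_indirect: bool = False
    include_incidentaloma: bool = False

    def categories(self) -> tuple[str, ...]:
        cats = list(_BASE_CATEGORIES)
        if self.include_indirect:
            cats += list(_INDIRECT_CATEGORIES)
        if self.include_incidentaloma:
            cats.append("incidentaloma")
        return tuple(cats)


def cycle_costs(ledger: pd.DataFrame, flags: CostFlags) -> pd.Series:
    """Undiscounted per-cycle total over the selected categories."""
    unknown = set(ledger.columns) - set(COST_CATEGORIES)
    if unknown:
        raise ValueError(f"unknown ledger categories: {sorted(unknown)}")
    return ledger[list(flags.categories())].sum(axis=1)


def accrue_costs(
    ledger: pd.DataFrame,
    flags: CostFlags | None = None,
    discount_rate: float = 0.03,
    timing: str = "end",
) -> float:
    """Total discounted cost of a per-cycle ledger.

    ``timing='end'`` (default) discounts cycle k by (1+r)^-(k+1), i.e. cycle
    payoffs fall at the end of the year; ``'start'`` uses (1+r)^-k with the
    first cycle undiscounted.
    """
    if timing not in ("end", "start"):
        raise ValueError("timing must be 'end' or 'start'")
    flags = flags or CostFlags()
    per_cycle = cycle_costs(ledger, flags).to_numpy()
    offset = 1 if timing == "end" else 0
    disc = (1.0 + discount_rate) ** -(np.arange(len(per_cycle)) + offset)
    return float(per_cycle @ disc)


# ---------------------------------------------------------------------------
# Incremental comparisons
# ---------------------------------------------------------------------------


class CostEffect(NamedTuple):
    """A (cost, effect) pair on a 'higher effect is better' scale."""

    cost: float
    effect: float


def _as_cost_effect(x, valuation: str | None) -> CostEffect:
    if isinstance(x, CostEffect):
        return x
    if hasattr(x, "effect") and hasattr(x, "cost_per_patient"):  # StrategyOutcome
        if valuation is None:
            raise ValueError("valuation required when comparing StrategyOutcomes")
        return CostEffect(x.cost_per_patient, x.effect(valuation))
    cost, effect = x
    return CostEffect(float(cost), float(effect))


@dataclass(frozen=True)
class ComparisonResult:
    """Incremental economics of an alternative ``a`` versus comparator ``b``."""

    delta_cost: float
    delta_effect: float
    icer: float | None  # undefined when one strategy dominates
    classification: str  # dominant | dominated | cost_effective_at_threshold | not_cost_effective
    threshold_used: float


def compare_strategies(
    a,
    b,
    valuation: str | None = None,
    threshold: float = DEFAULT_WTP_THRESHOLD,
) -> ComparisonResult:
    """Pairwise incremental comparison (a minus b).

    ``a``/``b`` may be StrategyOutcomes (with ``valuation`` of ``events`` or
    ``qalys``) or plain (cost, effect) pairs.  ``dominant`` means a is cheaper
    and more effective; the ICER is reported only when both deltas share a
    sign, and the threshold decision uses the standard quadrant rules.
    """
    ca, cb = _as_cost_effect(a, valuation), _as_cost_effect(b, valuation)
    dc = ca.cost - cb.cost
    de = ca.effect - cb.effect
    if dc < 0 and de > 0:
        return ComparisonResult(dc, de, None, "dominant", threshold)
    if dc > 0 and de < 0:
        return ComparisonResult(dc, de, None, "dominated", threshold)
    if de == 0:
        cls = "cost_effective_at_threshold" if dc <= 0 else "not_cost_effective"
        return ComparisonResult(dc, de, None, cls, threshold)
    icer = dc / de
    if dc >= 0 and de > 0:  # more costly, more effective: accept if ICER <= threshold
        cls = "cost_effective_at_threshold" if icer <= threshold else "not_cost_effective"
    else:  # cheaper and less effective: accept if savings per unit lost >= threshold
        cls = "cost_effective_at_threshold" if icer >= threshold else "not_cost_effective"
    return ComparisonResult(dc, de, icer, cls, threshold)


# ---------------------------------------------------------------------------
# Decision labels (three-strategy vocabulary)
# ---------------------------------------------------------------------------

_DISPLAY = {"atp3": "ATP III", "treat_all": "Treat All", "cac": "CAC",
            "cac_ge1": "CAC", "cac_ge100": "CAC"}


def decision_label(
    outcomes: Mapping[str, object],
    valuation: str | None = None,
    threshold: float = DEFAULT_WTP_THRESHOLD,
) -> str:
    """Summarize the three-way comparison in the published vocabulary.

    ``outcomes`` maps strategy keys (must include ``atp3`` plus ``treat_all``
    and one CAC strategy) to StrategyOutcomes or (cost, effect) pairs.
    Alternatives are first screened pairwise against the status quo: a
    candidate either dominates ATP III or buys its extra effect at an ICER at
    or below the threshold (symmetrically, gives up effect at a saving per
    unit above it).  The favored strategy is the most effective candidate;
    the label reports whether it dominates both alternatives, dominates
    ATP III, or is cost-effective with its ICER vs ATP III.  With no
    acceptable candidate ATP III remains the status quo.
    """
    ce = {k: _as_cost_effect(v, valuation) for k, v in outcomes.items()}
    if "atp3" not in ce:
        raise ValueError("outcomes must include the 'atp3' comparator")
    candidates = [
        k
        for k in ce
        if k != "atp3"
        and compare_strategies(ce[k], ce["atp3"], threshold=threshold).classification
        in ("dominant", "cost_effective_at_threshold")
    ]
    if not candidates:
        return "ATP III (Status Quo)"
    # most effective acceptable alternative; cheaper one wins effect ties
    favored = max(candidates, key=lambda k: (ce[k].effect, -ce[k].cost))

    name = _DISPLAY.get(favored, favored)
    others = [k for k in ce if k != favored]
    dominates = {
        k: compare_strategies(ce[favored], ce[k], threshold=threshold).classification
        == "dominant"
        for k in others
    }
    if all(dominates.values()):
        return f"{name} Dominates Both"
    if dominates.get("atp3", False):
        return f"{name} Dominates ATP III"
    vs_atp3 = compare_strategies(ce[favored], ce["atp3"], threshold=threshold)
    if vs_atp3.classification == "cost_effective_at_threshold" and vs_atp3.icer is not None:
        return f"{name} Cost-Effective; ICER = ${vs_atp3.icer:,.0f}"
    if vs_atp3.classification == "cost_effective_at_threshold":
        return f"{name} Cost-Effective"
    return "ATP III (Status Quo)"


# ---------------------------------------------------------------------------
# Cost-effectiveness acceptability curves
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CEACCurve:
    """Acceptance probability by willingness-to-pay threshold and strategy."""

    table: pd.DataFrame  # columns: wtp, strategy, acceptance

    def acceptance_at(self, wtp: float, strategy: str) -> float:
        t = self.table
        row = t[(t["wtp"] == wtp) & (t["strategy"] == strategy)]
        if row.empty:
            raise KeyError(f"no CEAC entry for wtp={wtp}, strategy={strategy!r}")
        return float(row["acceptance"].iloc[0])


def ceac(
    results: pd.DataFrame,
    wtp_grid: Sequence[float],
    cost_col: str = "cost",
    effect_col: str = "effect",
) -> CEACCurve:
    """Acceptability curves from per-simulation strategy results.

    ``results`` is long-format with columns sim, strategy, ``cost_col`` and
    ``effect_col``.  At each threshold the accepted strategy of a simulation
    maximizes net monetary benefit; ties are split equally.
    """
    if results.empty:
        raise ValueError("empty PSA results")
    strategies = sorted(results["strategy"].unique())
    wide_c = results.pivot(index="sim", columns="strategy", values=cost_col)[strategies]
    wide_e = results.pivot(index="sim", columns="strategy", values=effect_col)[strategies]
    if wide_c.isna().any().any():
        raise ValueError("every simulation must contain every strategy")
    C = wide_c.to_numpy()
    E = wide_e.to_numpy()
    n_sims = C.shape[0]
    rows = []
    for wtp in wtp_grid:
        nmb = wtp * E - C
        best = nmb.max(axis=1, keepdims=True)
        winners = np.isclose(nmb, best, rtol=0.0, atol=1e-9)
        share = winners / winners.sum(axis=1, keepdims=True)
        acc = share.sum(axis=0) / n_sims
        for s, a in zip(strategies, acc):
            rows.append({"wtp": float(wtp), "strategy": s, "acceptance": float(a)})
    return CEACCurve(pd.DataFrame(rows))
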