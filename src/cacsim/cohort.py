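"""Synthetic intermediate-risk cohorts and CAC reclassification summaries.

The simulated population emulates an intermediate-risk (10-year Framingham
CHD risk 6-20%) statin-naive sample cross-classified by ATP III statin
eligibility and coronary artery calcium (CAC) stratum.  The published joint
counts (n = 1,619) are bundled as :data:`REFERENCE_COUNTS`.  Ages are drawn from a
configurable model (default: truncated normal on [45, 84]); age is assumed
independent of CAC stratum and eligibility, a documented simplification.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import IntEnum
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "CACStratum",
    "JointClassificationTable",
    "CohortTable",
    "ReclassificationSummary",
    "REFERENCE_COUNTS",
    "DEFAULT_AGE_MODEL",
    "reclassification_summary",
    "generate_cohort",
    "assign_event_hazards",
    "write_cohort",
    "read_cohort",
]


class CACStratum(IntEnum):
    """CAC score stratum; ordered ZERO < LOW < HIGH."""

    ZERO = 0  # CAC = 0
    LOW = 1  # 1 <= CAC < 100
    HIGH = 2  # CAC >= 100


STRATUM_NAMES = {CACStratum.ZERO: "zero", CACStratum.LOW: "low", CACStratum.HIGH: "high"}
_NAME_TO_STRATUM = {v: k for k, v in STRATUM_NAMES.items()}


@dataclass(frozen=True)
class JointClassificationTable:
    """2x3 joint counts: rows = (ATP III statin-eligible, not eligible),
    columns = CAC strata in (zero, low, high) order."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=int)
        if counts.shape != (2, 3):
            raise ValueError("counts must be a 2x3 array (eligibility x stratum)")
        if np.any(counts < 0):
            raise ValueError("cell counts must be non-negative")
        object.__setattr__(self, "counts", counts)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def proportions(self) -> np.ndarray:
        if self.total == 0:
            raise ZeroDivisionError("table total is zero; proportions undefined")
        return self.counts / self.total

    def eligible_total(self) -> int:
        return int(self.counts[0].sum())

    def stratum_total(self, stratum: CACStratum) -> int:
        return int(self.counts[:, int(stratum)].sum())


#: Published joint classification (ATP III eligibility x CAC stratum) of the
#: n=1,619 intermediate-risk study sample.
REFERENCE_COUNTS = JointClassificationTable(
    np.array(
        [
            [226, 196, 193],  # statin-eligible by ATP III: CAC=0, 1-99, >=100
            [454, 294, 256],  # not eligible
        ]
    )
)


@dataclass(frozen=True)
class ReclassificationSummary:
    """Reclassification of statin eligibility when CAC (at a treatment
    threshold) overrides ATP III, as percentages of the whole population."""

    threshold: CACStratum
    upward_pct: float  # not ATP III-eligible but at/above the CAC threshold
    downward_pct: float  # ATP III-eligible but below the CAC threshold
    net_pct: float  # upward - downward (computed pre-rounding)

    def rounded(self) -> tuple[float, float, float]:
        return (round(self.upward_pct, 1), round(self.downward_pct, 1), round(self.net_pct, 1))


def reclassification_summary(
    table: JointClassificationTable, threshold: CACStratum
) -> ReclassificationSummary:
    """Percent of the population reclassified upward/downward by a CAC-based
    treatment rule (treat CAC >= 1 for ``threshold=LOW``, treat CAC >= 100 for
    ``threshold=HIGH``) relative to ATP III eligibility."""
    if threshold == CACStratum.ZERO:
        raise ValueError("treatment threshold must be LOW (>=1) or HIGH (>=100)")
    total = table.total
    if total == 0:
        raise ZeroDivisionError("table total is zero; percentages undefined")
    above = np.arange(3) >= int(threshold)
    upward = table.counts[1, above].sum()
    downward = table.counts[0, ~above].sum()
    up = 100.0 * upward / total
    down = 100.0 * downward / total
    return ReclassificationSummary(threshold, up, down, up - down)


# ---------------------------------------------------------------------------
# Cohort generation
# ---------------------------------------------------------------------------

DEFAULT_AGE_MODEL: dict = {
    "kind": "truncnorm",
    "mean": 65.0,
    "sd": 8.0,
    "low": 45.0,
    "high": 84.0,
}


@dataclass
class CohortTable:
    """An ordered collection of simulated patients.

    ``records`` columns: id, age, atp3_eligible (bool), cac_stratum (int),
    annual_event_risk.  ``outcome_type``/``horizon`` record which risk column
    the hazards were assigned from; ``rate_multiplier`` scales them.
    """

    records: pd.DataFrame
    outcome_type: str | None = None
    horizon: int | None = None
    rate_multiplier: float = 1.0

    def __post_init__(self) -> None:
        required = {"id", "age", "atp3_eligible", "cac_stratum", "annual_event_risk"}
        missing = required - set(self.records.columns)
        if missing:
            raise ValueError(f"cohort records missing columns: {sorted(missing)}")

    def __len__(self) -> int:
        return len(self.records)

    @property
    def ages(self) -> np.ndarray:
        return self.records["age"].to_numpy(dtype=float)

    @property
    def strata(self) -> np.ndarray:
        return self.records["cac_stratum"].to_numpy(dtype=int)

    @property
    def eligible(self) -> np.ndarray:
        return self.records["atp3_eligible"].to_numpy(dtype=bool)

    @property
    def risks(self) -> np.ndarray:
        return self.records["annual_event_risk"].to_numpy(dtype=float)

    def cell_counts(self) -> np.ndarray:
        """Observed 2x3 (eligibility x stratum) counts."""
        out = np.zeros((2, 3), dtype=int)
        for row, elig in enumerate((True, False)):
            mask = self.eligible == elig
            for s in CACStratum:
                out[row, int(s)] = int(np.sum(mask & (self.strata == int(s))))
        return out


def _draw_ages(n: int, model: Mapping, rng: np.random.Generator) -> np.ndarray:
    kind = model.get("kind", "truncnorm")
    if kind == "fixed":
        age = float(model["age"])
        if not (45.0 <= age <= 84.0):
            raise ValueError("fixed age must lie in [45, 84]")
        return np.full(n, age)
    if kind == "truncnorm":
        from scipy.stats import truncnorm

        mean, sd = float(model["mean"]), float(model["sd"])
        lo, hi = float(model.get("low", 45.0)), float(model.get("high", 84.0))
        if sd <= 0 or hi <= lo:
            raise ValueError("malformed age model: need sd > 0 and high > low")
        a, b = (lo - mean) / sd, (hi - mean) / sd
        return truncnorm.rvs(a, b, loc=mean, scale=sd, size=n, random_state=rng)
    if kind == "uniform":
        lo, hi = float(model.get("low", 45.0)), float(model.get("high", 84.0))
        return rng.uniform(lo, hi, size=n)
    raise ValueError(f"unknown age model kind {kind!r}")


def generate_cohort(
    n: int,
    table: JointClassificationTable = REFERENCE_COUNTS,
    age_model: Mapping | None = None,
    seed: int | None = None,
    exact: bool = False,
    rng: np.random.Generator | None = None,
) -> CohortTable:
    """Generate ``n`` patients whose (eligibility x stratum) frequencies follow
    the joint table.

    In ``exact`` mode ``n`` must equal the table total and every cell count is
    reproduced exactly; otherwise cells are drawn multinomially from the cell
    proportions.  Ages are drawn independently from ``age_model``.
    """
    if n <= 0:
        raise ValueError("cohort size must be positive")
    if rng is None:
        rng = np.random.default_rng(seed)
    if age_model is None:
        age_model = DEFAULT_AGE_MODEL

    if exact:
        if n != table.total:
            raise ValueError(
                f"exact mode requires n == table total ({table.total}), got {n}"
            )
        cells = table.counts
    else:
        cells = rng.multinomial(n, table.proportions.ravel()).reshape(2, 3)

    elig_col, strat_col = [], []
    for row, elig in enumerate((True, False)):
        for s in CACStratum:
            k = int(cells[row, int(s)])
            elig_col.extend([elig] * k)
            strat_col.extend([int(s)] * k)

    records = pd.DataFrame(
        {
            "id": np.arange(n),
            "age": _draw_ages(n, age_model, rng),
            "atp3_eligible": np.asarray(elig_col, dtype=bool),
            "cac_stratum": np.asarray(strat_col, dtype=int),
            "annual_event_risk": np.zeros(n),
        }
    )
    return CohortTable(records)


def assign_event_hazards(
    cohort: CohortTable,
    rates: Mapping,
    outcome_type: str,
    multiplier: float = 1.0,
    horizon: int | None = None,
) -> CohortTable:
    """Set each record's annual first-event risk to ``multiplier`` times its
    stratum rate (capped below 1).

    ``rates`` maps strata (CACStratum or their names) to annual risks, e.g.
    ``ParameterSet.event_rates(outcome, horizon)``.
    """
    if multiplier < 0:
        raise ValueError("rate multiplier must be non-negative")
    lookup: dict[int, float] = {}
    for key, val in rates.items():
        if isinstance(key, str):
            key = _NAME_TO_STRATUM[key]
        lookup[int(key)] = float(val)
    missing = [STRATUM_NAMES[s] for s in CACStratum if int(s) not in lookup]
    if missing:
        raise KeyError(f"missing stratum rate(s): {missing}")

    strata = cohort.strata
    risks = np.array([lookup[s] for s in strata]) * multiplier
    if np.any(risks >= 1.0):
        risks = np.clip(risks, 0.0, np.nextafter(1.0, 0.0))
    records = cohort.records.copy()
    records["annual_event_risk"] = risks
    return CohortTable(records, outcome_type=outcome_type, horizon=horizon,
                       rate_multiplier=multiplier)


# ---------------------------------------------------------------------------
# Delimited-text export/import
# ---------------------------------------------------------------------------

def write_cohort(cohort: CohortTable, path) -> None:
    cohort.records.to_csv(path, sep="\t", index=False)


def read_cohort(path, outcome_type: str | None = None, horizon: int | None = None,
                rate_multiplier: float = 1.0) -> CohortTable:
    records = pd.read_csv(path, sep="\t")
    records["atp3_eligible"] = records["atp3_eligible"].astype(bool)
    return CohortTable(records, outcome_type=outcome_type, horizon=horizon,
                       rate_multiplier=rate_multiplier)
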