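"""Treatment strategies: who is advised a statin, at what intensity, and the
effective relative risk once adherence is accounted for.

Four strategies are compared on the same cohort:

* ``atp3``      -- statins for ATP III-eligible patients (moderate intensity),
  adherence 55% (no CAC scan).
* ``treat_all`` -- statins for everyone (moderate), adherence 55%.
* ``cac_ge1``   -- scan everyone; moderate statins for 1<=CAC<100, intensive
  for CAC>=100, none for CAC=0; adherence 65%.
* ``cac_ge100`` -- scan everyone; intensive statins for CAC>=100 only;
  adherence 65%.

In the CAC strategies the scan result overrides ATP III eligibility (an
ATP III-eligible patient with CAC=0 is not treated).  Adherence is drawn once
per patient and fixed over the horizon; non-adherent patients are modelled as
never-initiators (no benefit, cost, disutility, or statin adverse events;
configurable in the engine).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import CACStratum, CohortTable
from .parameters import ParameterSet

__all__ = [
    "STRATEGY_NAMES",
    "StrategySpec",
    "TreatmentAssignment",
    "assign_treatment",
    "effective_rr",
]

STRATEGY_NAMES = ("atp3", "treat_all", "cac_ge1", "cac_ge100")

INTENSITY_NONE = "none"
INTENSITY_MODERATE = "moderate"
INTENSITY_INTENSIVE = "intensive"


@dataclass(frozen=True)
class StrategySpec:
    name: str
    cac_tested: bool
    adherence_key: str

    def __post_init__(self) -> None:
        if self.name not in STRATEGY_NAMES:
            raise ValueError(f"unknown strategy {self.name!r}; choose from {STRATEGY_NAMES}")
        is_cac = self.name.startswith("cac_")
        if self.cac_tested != is_cac:
            raise ValueError("cac_tested must be true exactly for the CAC strategies")

    @classmethod
    def from_name(cls, name: str) -> "StrategySpec":
        is_cac = name.startswith("cac_")
        return cls(name, is_cac, "adherence_cac" if is_cac else "adherence_no_cac")


@dataclass
class TreatmentAssignment:
    """Per-patient treatment recommendation under one strategy.

    ``table`` columns: recommended (bool), intensity, adherence_prob,
    adherent (bool; one Bernoulli draw per recommended patient), effective_rr
    (the realized relative risk: 1 unless recommended and adherent).
    """

    strategy: StrategySpec
    table: pd.DataFrame

    @property
    def recommended(self) -> np.ndarray:
        return self.table["recommended"].to_numpy(dtype=bool)

    @property
    def adherent(self) -> np.ndarray:
        return self.table["adherent"].to_numpy(dtype=bool)

    @property
    def adherence_prob(self) -> np.ndarray:
        return self.table["adherence_prob"].to_numpy(dtype=float)

    @property
    def intensity(self) -> np.ndarray:
        return self.table["intensity"].to_numpy()

    @property
    def intensity_rr(self) -> np.ndarray:
        return self.table["intensity_rr"].to_numpy(dtype=float)

    @property
    def realized_rr(self) -> np.ndarray:
        return self.table["effective_rr"].to_numpy(dtype=float)

    def n_recommended(self) -> int:
        return int(self.recommended.sum())


def _recommendation(cohort: CohortTable, spec: StrategySpec):
    strata = cohort.strata
    if spec.name == "atp3":
        recommended = cohort.eligible.copy()
        intensive = np.zeros(len(cohort), dtype=bool)
    elif spec.name == "treat_all":
        recommended = np.ones(len(cohort), dtype=bool)
        intensive = np.zeros(len(cohort), dtype=bool)
    elif spec.name == "cac_ge1":
        recommended = strata >= int(CACStratum.LOW)
        intensive = strata == int(CACStratum.HIGH)
    else:  # cac_ge100
        recommended = strata == int(CACStratum.HIGH)
        intensive = recommended.copy()
    return recommended, intensive


def assign_treatment(
    cohort: CohortTable,
    spec: StrategySpec,
    ps: ParameterSet,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    adherence_uniforms: np.ndarray | None = None,
) -> TreatmentAssignment:
    """Map each patient to a recommendation, intensity and adherence draw.

    ``adherence_uniforms`` (one U(0,1) per patient) supports common random
    numbers across strategies: a patient adherent at 55% is then also adherent
    at 65%.  Otherwise draws come from ``rng``/``seed``.
    """
    recommended, intensive = _recommendation(cohort, spec)
    n = len(cohort)

    adh_p = float(ps[spec.adherence_key])
    if adherence_uniforms is None:
        if rng is None:
            rng = np.random.default_rng(seed)
        adherence_uniforms = rng.uniform(size=n)
    adherent = recommended & (np.asarray(adherence_uniforms) < adh_p)

    rr_mod = float(ps["rr_moderate"])
    rr_int = float(ps["rr_intensive"])
    intensity = np.where(
        recommended, np.where(intensive, INTENSITY_INTENSIVE, INTENSITY_MODERATE), INTENSITY_NONE
    )
    intensity_rr = np.where(recommended, np.where(intensive, rr_int, rr_mod), 1.0)
    eff = np.where(adherent, intensity_rr, 1.0)

    table = pd.DataFrame(
        {
            "recommended": recommended,
            "intensity": intensity,
            "adherence_prob": np.where(recommended, adh_p, 0.0),
            "adherent": adherent,
            "intensity_rr": intensity_rr,
            "effective_rr": eff,
        }
    )
    return TreatmentAssignment(spec, table)


def effective_rr(recommended, adherent, intensity, ps: ParameterSet):
    """Relative risk actually experienced: the intensity-specific RR when
    recommended and adherent, else 1 (vectorized)."""
    recommended = np.asarray(recommended, dtype=bool)
    adherent = np.asarray(adherent, dtype=bool)
    intensity = np.asarray(intensity)
    rr = np.where(intensity == INTENSITY_INTENSIVE, ps["rr_intensive"], ps["rr_moderate"])
    out = np.where(recommended & adherent, rr, 1.0)
    return out if out.ndim else float(out)
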