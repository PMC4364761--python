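"""Model parameter registry, sampling distributions, and the background life table.

Every quantity used by the simulation lives here as a named :class:`Parameter`
carrying a base-case point value and, where second-order uncertainty is
modelled, a :class:`DistributionSpec` for probabilistic sensitivity analysis.
Utilities and the radiation-risk constants are held fixed (no distribution).

Annual event risks are keyed ``rate_{outcome}_{stratum}_{horizon}y`` where
``outcome`` is ``chd``/``cvd``, ``stratum`` is ``zero``/``low``/``high``
(CAC = 0, 1<=CAC<100, CAC>=100) and ``horizon`` is 5 or 10: the 5-year
analyses use average annual rates over five years of follow-up, the 10-year
analyses the ten-year-based rates.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np

__all__ = [
    "DistributionSpec",
    "Parameter",
    "ParameterSet",
    "LifeTable",
    "build_parameter_set",
    "sample_parameter_set",
    "load_life_table",
]


# ---------------------------------------------------------------------------
# Distributions
# ---------------------------------------------------------------------------

_FAMILIES = ("point", "beta", "gamma", "triangular")


@dataclass(frozen=True)
class DistributionSpec:
    """A sampling distribution for one parameter.

    families and their args:

    * ``point``      -- (value,)
    * ``beta``       -- (alpha, beta)
    * ``gamma``      -- (shape, scale); use :meth:`gamma_mean_sd` to build
      from a mean and standard deviation (shape = (m/s)^2, scale = s^2/m)
    * ``triangular`` -- (min, mode, max)
    """

    family: str
    args: tuple

    def __post_init__(self) -> None:
        if self.family not in _FAMILIES:
            raise ValueError(f"unknown distribution family {self.family!r}")
        a = self.args
        if self.family == "beta":
            if len(a) != 2 or a[0] <= 0 or a[1] <= 0:
                raise ValueError(f"beta requires alpha, beta > 0, got {a}")
        elif self.family == "gamma":
            if len(a) != 2 or a[0] <= 0 or a[1] <= 0:
                raise ValueError(f"gamma requires shape, scale > 0, got {a}")
        elif self.family == "triangular":
            if len(a) != 3 or not (a[0] <= a[1] <= a[2]):
                raise ValueError(f"triangular requires min <= mode <= max, got {a}")
        elif len(a) != 1:
            raise ValueError("point requires a single value")

    # -- constructors -------------------------------------------------------
    @classmethod
    def point(cls, value: float) -> "DistributionSpec":
        return cls("point", (float(value),))

    @classmethod
    def beta(cls, alpha: float, beta: float) -> "DistributionSpec":
        return cls("beta", (float(alpha), float(beta)))

    @classmethod
    def beta_mean_ess(cls, mean: float, ess: float) -> "DistributionSpec":
        """Beta with a given mean and effective sample size alpha + beta."""
        if not 0.0 < mean < 1.0:
            raise ValueError("mean must lie in (0, 1)")
        return cls.beta(mean * ess, (1.0 - mean) * ess)

    @classmethod
    def gamma_mean_sd(cls, mean: float, sd: float) -> "DistributionSpec":
        if mean <= 0 or sd <= 0:
            raise ValueError("gamma mean and sd must be positive")
        return cls("gamma", ((mean / sd) ** 2, sd**2 / mean))

    @classmethod
    def gamma_shape_scale(cls, shape: float, scale: float) -> "DistributionSpec":
        return cls("gamma", (float(shape), float(scale)))

    @classmethod
    def triangular(cls, lo: float, mode: float, hi: float) -> "DistributionSpec":
        return cls("triangular", (float(lo), float(mode), float(hi)))

    @classmethod
    def triangular_pm20(cls, mean: float) -> "DistributionSpec":
        """Triangular spanning +/-20% around the mean, mode at the mean."""
        return cls.triangular(0.8 * mean, mean, 1.2 * mean)

    # -- behaviour ----------------------------------------------------------
    def mean(self) -> float:
        a = self.args
        if self.family == "point":
            return a[0]
        if self.family == "beta":
            return a[0] / (a[0] + a[1])
        if self.family == "gamma":
            return a[0] * a[1]
        return (a[0] + a[1] + a[2]) / 3.0

    def sample(self, rng: np.random.Generator) -> float:
        a = self.args
        if self.family == "point":
            return a[0]
        if self.family == "beta":
            return float(rng.beta(a[0], a[1]))
        if self.family == "gamma":
            return float(rng.gamma(a[0], a[1]))
        return float(rng.triangular(a[0], a[1], a[2]))


@dataclass(frozen=True)
class Parameter:
    name: str
    value: float
    dist: DistributionSpec | None = None  # None => held fixed in PSA


# ---------------------------------------------------------------------------
# Parameter set
# ---------------------------------------------------------------------------

STRATA = ("zero", "low", "high")
OUTCOMES = ("chd", "cvd")
HORIZONS = (5, 10)

# per-stratum annual first-event risks; (5-year basis, 10-year basis)
_EVENT_RATES = {
    ("cvd", "zero"): (0.00406206, 0.00413593),
    ("cvd", "low"): (0.01086766, 0.01115809),
    ("cvd", "high"): (0.01920450, 0.02060006),
    ("chd", "zero"): (0.00201915, 0.00212544),
    ("chd", "low"): (0.00839575, 0.00756866),
    ("chd", "high"): (0.01676953, 0.01639898),
}

UTILITY_AGES = (50.0, 60.0, 70.0, 80.0, 90.0)
UTILITY_VALUES = (0.84, 0.82, 0.79, 0.74, 0.68)

PRODUCTIVITY_AGES = (40.0, 50.0, 60.0, 70.0, 80.0)
PRODUCTIVITY_CHD = (6500.0, 5100.0, 1900.0, 500.0, 200.0)
PRODUCTIVITY_CVD = (7900.0, 6200.0, 2300.0, 600.0, 200.0)


class ParameterSet:
    """An immutable mapping of named parameters with point values and PSA distributions."""

    def __init__(self, params: Iterable[Parameter]):
        self._params: dict[str, Parameter] = {p.name: p for p in params}

    # mapping-ish surface
    def __getitem__(self, name: str) -> float:
        return self._params[name].value

    def __contains__(self, name: str) -> bool:
        return name in self._params

    def __iter__(self):
        return iter(self._params)

    def __len__(self) -> int:
        return len(self._params)

    def names(self) -> list[str]:
        return list(self._params)

    def parameter(self, name: str) -> Parameter:
        return self._params[name]

    def value(self, name: str) -> float:
        return self._params[name].value

    def event_rate(self, outcome: str, stratum: str, horizon: int) -> float:
        return self[f"rate_{outcome}_{stratum}_{horizon}y"]

    def event_rates(self, outcome: str, horizon: int) -> dict[str, float]:
        return {s: self.event_rate(outcome, s, horizon) for s in STRATA}

    def with_overrides(self, overrides: Mapping[str, float]) -> "ParameterSet":
        unknown = sorted(set(overrides) - set(self._params))
        if unknown:
            raise KeyError(
                f"unknown parameter(s) {unknown}; valid names: {sorted(self._params)}"
            )
        out = dict(self._params)
        for name, value in overrides.items():
            old = out[name]
            dist = old.dist
            # keep the relative PSA spread coherent with the new point value
            # for the +/-20% triangular cost parameters
            if name in ("cost_cac_test", "cost_statin_annual"):
                dist = DistributionSpec.triangular_pm20(float(value))
            out[name] = Parameter(name, float(value), dist)
        return ParameterSet(out.values())

    def sample(self, rng: np.random.Generator) -> "ParameterSet":
        """One PSA draw: parameters with a distribution are replaced by a sample,
        fixed parameters keep their point value. Draw order is the (stable)
        registry order, so a given generator state maps to one sampled set."""
        sampled = []
        for p in self._params.values():
            if p.dist is None:
                sampled.append(p)
            else:
                sampled.append(Parameter(p.name, p.dist.sample(rng), None))
        return ParameterSet(sampled)

    def to_frame(self):
        import pandas as pd

        rows = []
        for p in self._params.values():
            rows.append(
                {
                    "name": p.name,
                    "value": p.value,
                    "family": p.dist.family if p.dist else "fixed",
                    "args": ",".join(f"{a:g}" for a in p.dist.args) if p.dist else "",
                }
            )
        return pd.DataFrame(rows)


def build_parameter_set(
    overrides: Mapping[str, float] | None = None,
    event_rate_ess: float = 5000.0,
) -> ParameterSet:
    """Assemble the base-case parameter registry.

    ``event_rate_ess`` sets the effective sample size (alpha + beta) of the
    beta distributions attached to the per-stratum annual event risks, whose
    variance is otherwise unidentified from the published point rates.
    """
    tri = DistributionSpec.triangular
    params: list[Parameter] = []

    for (outcome, stratum), (r5, r10) in _EVENT_RATES.items():
        for horizon, rate in ((5, r5), (10, r10)):
            params.append(
                Parameter(
                    f"rate_{outcome}_{stratum}_{horizon}y",
                    rate,
                    DistributionSpec.beta_mean_ess(rate, event_rate_ess),
                )
            )

    params += [
        Parameter("rr_moderate", 0.65, tri(0.55, 0.65, 0.75)),
        Parameter("rr_intensive", 0.55, tri(0.45, 0.55, 0.65)),
        Parameter("cf_chd_lt65", 0.10000, DistributionSpec.beta(17, 153)),
        Parameter("cf_chd_ge65", 0.15714, DistributionSpec.beta(22, 118)),
        Parameter("cf_cvd_lt65", 0.10260, DistributionSpec.beta(16, 140)),
        Parameter("cf_cvd_ge65", 0.16265, DistributionSpec.beta(23, 118)),
        Parameter("p_mild_ae", 0.18, DistributionSpec.beta(252, 1148)),
        # 1 : 18,000 person-years, treated as an annual probability
        Parameter("p_severe_ae", 1.0 / 18000.0, DistributionSpec.beta(5.6, 99994)),
        Parameter("p_death_severe_ae", 0.09, DistributionSpec.beta(7.2, 73)),
        Parameter("adherence_no_cac", 0.55, tri(0.40, 0.55, 1.00)),
        Parameter("adherence_cac", 0.65, tri(0.50, 0.65, 1.00)),
        Parameter("radiation_lifetime_risk", 0.00002, None),
        Parameter("radiation_case_fatality", 0.65, None),
        Parameter("radiation_latency_years", 25.0, None),
        # direct medical costs, 2011 USD
        Parameter("cost_event_nonfatal_chd", 64400.0, DistributionSpec.gamma_mean_sd(64400, 32200)),
        Parameter("cost_event_fatal_chd", 49000.0, DistributionSpec.gamma_mean_sd(49000, 24500)),
        Parameter("cost_event_nonfatal_cvd", 55700.0, DistributionSpec.gamma_mean_sd(55700, 27850)),
        Parameter("cost_event_fatal_cvd", 43500.0, DistributionSpec.gamma_mean_sd(43500, 21750)),
        Parameter("cost_cac_test", 100.0, DistributionSpec.triangular_pm20(100.0)),
        Parameter("cost_statin_annual", 180.0, DistributionSpec.triangular_pm20(180.0)),
        Parameter("cost_mild_ae", 180.0, DistributionSpec.gamma_mean_sd(180, 30)),
        Parameter("cost_severe_ae", 6500.0, DistributionSpec.gamma_mean_sd(6500, 3250)),
        Parameter("cost_incidentaloma", 250.0, DistributionSpec.gamma_mean_sd(250, 125)),
        Parameter("incidentaloma_fraction", 0.08, None),
        # 1 hour at the median >=55 wage; shape kept at the published 1.056
        Parameter("cost_cac_time", 15.20, DistributionSpec.gamma_shape_scale(1.056, 15.20 / 1.056)),
        # QALY multipliers (fixed in PSA except where a distribution is given)
        Parameter("util_statin", 0.99616, tri(0.99232, 0.99616, 1.000)),
        Parameter("util_mild_ae", 0.9941, tri(0.9890, 0.9941, 0.9986)),
        Parameter("util_severe_ae", 0.9553, tri(0.9233, 0.9553, 0.9808)),
        Parameter("util_event_chd", 0.8351, DistributionSpec.beta(102, 20)),
        Parameter("util_event_cvd", 0.8272, DistributionSpec.beta(180, 38)),
        Parameter("discount_rate", 0.03, None),
    ]
    # age-anchored healthy utilities, fixed in PSA
    for age, u in zip(UTILITY_AGES, UTILITY_VALUES):
        params.append(Parameter(f"utility_age_{int(age)}", u, None))
    # productivity costs, sd = 50% of mean
    for age, c in zip(PRODUCTIVITY_AGES, PRODUCTIVITY_CHD):
        params.append(
            Parameter(f"prod_chd_age_{int(age)}", c, DistributionSpec.gamma_mean_sd(c, 0.5 * c))
        )
    for age, c in zip(PRODUCTIVITY_AGES, PRODUCTIVITY_CVD):
        params.append(
            Parameter(f"prod_cvd_age_{int(age)}", c, DistributionSpec.gamma_mean_sd(c, 0.5 * c))
        )

    ps = ParameterSet(params)
    if overrides:
        ps = ps.with_overrides(overrides)
    return ps


def sample_parameter_set(
    ps: ParameterSet,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> ParameterSet:
    """Draw one sampled parameter set (reproducible given the seed)."""
    if rng is None:
        rng = np.random.default_rng(seed)
    return ps.sample(rng)


# -- derived helpers used by the engine -------------------------------------

def healthy_utility(ps: ParameterSet, ages: np.ndarray) -> np.ndarray:
    """Age-specific healthy utility, linearly interpolated between the anchors
    and clamped outside 50-90."""
    vals = [ps[f"utility_age_{int(a)}"] for a in UTILITY_AGES]
    return np.interp(np.asarray(ages, dtype=float), UTILITY_AGES, vals)


def productivity_cost(ps: ParameterSet, outcome: str, ages: np.ndarray) -> np.ndarray:
    """Age-interpolated productivity cost of a first event (event year)."""
    vals = [ps[f"prod_{outcome}_age_{int(a)}"] for a in PRODUCTIVITY_AGES]
    return np.interp(np.asarray(ages, dtype=float), PRODUCTIVITY_AGES, vals)


def case_fatality(ps: ParameterSet, outcome: str, ages: np.ndarray) -> np.ndarray:
    """Age-dependent case fatality of a first event (threshold at attained age 65)."""
    lt = ps[f"cf_{outcome}_lt65"]
    ge = ps[f"cf_{outcome}_ge65"]
    return np.where(np.asarray(ages, dtype=float) < 65.0, lt, ge)


# ---------------------------------------------------------------------------
# Life table
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LifeTable:
    """Annual all-cause mortality probabilities by single year of age."""

    ages: np.ndarray
    qx: np.ndarray
    source: str = ""

    def __post_init__(self) -> None:
        ages = np.asarray(self.ages, dtype=int)
        qx = np.asarray(self.qx, dtype=float)
        if ages.shape != qx.shape or ages.ndim != 1 or ages.size == 0:
            raise ValueError("life table requires matching 1-d age and qx arrays")
        order = np.argsort(ages)
        ages, qx = ages[order], qx[order]
        if np.any(np.diff(ages) != 1):
            missing = int(ages[np.flatnonzero(np.diff(ages) != 1)[0]]) + 1
            raise ValueError(f"life table ages must be contiguous (gap after age {missing - 1})")
        if np.any((qx < 0) | (qx > 1)):
            raise ValueError("life table probabilities must lie in [0, 1]")
        object.__setattr__(self, "ages", ages)
        object.__setattr__(self, "qx", qx)

    def qx_at(self, ages) -> np.ndarray:
        """qx looked up by (integer) age, clamped to the table's range."""
        idx = np.clip(np.asarray(ages, dtype=int) - self.ages[0], 0, self.ages.size - 1)
        return self.qx[idx]

    @classmethod
    def zero_mortality(cls, lo: int = 30, hi: int = 110) -> "LifeTable":
        """All-zero table, for closed-form checks."""
        ages = np.arange(lo, hi + 1)
        return cls(ages, np.zeros_like(ages, dtype=float), source="zero")


def load_life_table(path=None) -> LifeTable:
    """Load a two-column (age, qx) delimited life table; default: bundled fixture."""
    if path is None:
        ref = importlib.resources.files("cacsim.data") / "us_life_table_2011_synthetic.tsv"
        with importlib.resources.as_file(ref) as p:
            return load_life_table(p)
    ages, qx = [], []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#") or line.lower().startswith("age"):
                continue
            a, q = line.split()
            ages.append(int(a))
            qx.append(float(q))
    return LifeTable(np.asarray(ages), np.asarray(qx), source=str(path))
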