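"""Synthetic worlds for the illness-death model and the data they produce.

A :class:`Scenario` bundles the incidence rate, the mortality of the
disease-free ``m0`` and an age-specific mortality rate ratio ``R(a)`` (so
``m1 = R * m0``) together with a calendar ``time_origin``.  Rate surfaces
internally measure time as years since the origin; every public method here
takes calendar years and converts.

Two ready-made scenarios are provided:

* :func:`dementia_scenario` — Gompertz–Makeham background mortality with a
  1 %/year secular decline and a rate ratio falling log-linearly from 3 at
  age 60 to 1.5 at age 95, emulating dementia in European women.  The default
  incidence, exp(−16 + 0.15·a), is a configurable stand-in in the literature's
  order of magnitude (≈1.9/1000 person-years at 65, ≈18/1000 at 80), not a
  surveyed rate.
* :func:`diabetes_like_scenario` — a type-2-diabetes-like world over ages
  50–90 with a tunable rate-ratio pair (R(50), R(90)) and an initial
  prevalence cross-section, used to exercise the Bayesian estimator.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .rates import (
    ExponentialRate,
    GompertzMakehamMortality,
    LogLinearRateRatio,
    RateSurface,
)

__all__ = [
    "PrevalenceCrossSection",
    "Scenario",
    "dementia_scenario",
    "diabetes_like_scenario",
    "sample_observed_prevalence",
]


@dataclass(frozen=True)
class PrevalenceCrossSection:
    """Age-specific prevalence surveyed at a single calendar time.

    Parameters
    ----------
    calendar_time : float
        Decimal calendar year of the survey.
    ages : array-like
        Strictly increasing exact ages in years (band midpoints for grouped
        data).
    prevalence : array-like
        Prevalence in [0, 1], aligned to ``ages``.
    group_sizes : array-like, optional
        Number of people n_j per age group, aligned to ``ages``; required by
        the Bayesian likelihood, optional otherwise.
    """

    calendar_time: float
    ages: np.ndarray
    prevalence: np.ndarray
    group_sizes: Optional[np.ndarray] = None

    def __post_init__(self):
        ages = np.asarray(self.ages, dtype=float)
        prev = np.asarray(self.prevalence, dtype=float)
        object.__setattr__(self, "ages", ages)
        object.__setattr__(self, "prevalence", prev)
        if ages.ndim != 1 or prev.shape != ages.shape:
            raise ValueError("ages and prevalence must be 1-D arrays of equal length")
        if ages.size == 0:
            raise ValueError("cross-section must contain at least one age")
        if np.any(np.diff(ages) <= 0):
            raise ValueError("ages must be strictly increasing")
        bad = np.where((prev < 0) | (prev > 1))[0]
        if bad.size:
            j = int(bad[0])
            raise ValueError(f"prevalence {prev[j]} at age {ages[j]} outside [0, 1]")
        if self.group_sizes is not None:
            n = np.asarray(self.group_sizes, dtype=float)
            object.__setattr__(self, "group_sizes", n)
            if n.shape != ages.shape:
                raise ValueError("group_sizes must align with ages")
            if np.any(n <= 0):
                j = int(np.argmax(n <= 0))
                raise ValueError(f"group size {n[j]} at age {ages[j]} must be positive")

    def interpolate(self, age):
        """Linear interpolation of prevalence in age; refuses to extrapolate."""
        a = np.asarray(age, dtype=float)
        if np.any(a < self.ages[0]) or np.any(a > self.ages[-1]):
            raise ValueError(
                f"age {age} outside the surveyed range [{self.ages[0]}, {self.ages[-1]}]"
            )
        out = np.interp(a, self.ages, self.prevalence)
        return out if np.ndim(age) else float(out)

    def covers(self, age: float) -> bool:
        return self.ages[0] <= age <= self.ages[-1]

    def with_group_sizes(self, n) -> "PrevalenceCrossSection":
        n = np.broadcast_to(np.asarray(n, dtype=float), self.ages.shape).copy()
        return dataclasses.replace(self, group_sizes=n)


@dataclass(frozen=True)
class Scenario:
    """A synthetic chronic-disease world: incidence, m0 and rate ratio.

    ``incidence`` and ``m0`` are :class:`~exmort.rates.RateSurface` objects in
    offset time (years since ``time_origin``); ``ratio`` maps age to the
    mortality rate ratio R(a) = m1/m0.  Remission is structurally absent.
    """

    incidence: RateSurface
    m0: RateSurface
    ratio: LogLinearRateRatio
    time_origin: float = 2000.0

    def offset(self, t_calendar):
        """Convert calendar years to the scenario's internal time frame."""
        return np.asarray(t_calendar, dtype=float) - self.time_origin if np.ndim(
            t_calendar
        ) else t_calendar - self.time_origin

    def incidence_at(self, t_calendar, a):
        return self.incidence.evaluate(self.offset(t_calendar), a)

    def m0_at(self, t_calendar, a):
        return self.m0.evaluate(self.offset(t_calendar), a)

    def ratio_at(self, a):
        return self.ratio(a)

    def m1_at(self, t_calendar, a):
        return self.ratio(a) * self.m0_at(t_calendar, a)

    def excess_at(self, t_calendar, a):
        """Excess mortality Δm = m1 − m0 = (R − 1) m0."""
        return (self.ratio(a) - 1.0) * self.m0_at(t_calendar, a)

    # -- configuration round trip -------------------------------------------------

    def to_config(self) -> dict:
        """Serialize to a plain dict (YAML-friendly); parametric surfaces only."""
        if not isinstance(self.incidence, ExponentialRate):
            raise TypeError("only ExponentialRate incidence is serializable")
        if not isinstance(self.m0, GompertzMakehamMortality):
            raise TypeError("only GompertzMakehamMortality m0 is serializable")
        return {
            "time_origin": float(self.time_origin),
            "incidence": {
                "intercept": self.incidence.intercept,
                "age_slope": self.incidence.age_slope,
            },
            "m0": {
                "intercept": self.m0.intercept,
                "age_slope": self.m0.age_slope,
                "annual_trend_factor": self.m0.annual_trend_factor,
            },
            "ratio": {
                "age_low": self.ratio.age_low,
                "ratio_low": self.ratio.ratio_low,
                "age_high": self.ratio.age_high,
                "ratio_high": self.ratio.ratio_high,
            },
        }

    @classmethod
    def from_config(cls, config: dict) -> "Scenario":
        known = {"time_origin", "incidence", "m0", "ratio"}
        extra = set(config) - known
        if extra:
            raise ValueError(f"unknown scenario config keys: {sorted(extra)}")
        missing = known - set(config)
        if missing:
            raise ValueError(f"missing scenario config keys: {sorted(missing)}")
        return cls(
            incidence=ExponentialRate(**config["incidence"]),
            m0=GompertzMakehamMortality(**config["m0"]),
            ratio=LogLinearRateRatio(**config["ratio"]),
            time_origin=float(config["time_origin"]),
        )


def dementia_scenario(incidence_override: Optional[RateSurface] = None) -> Scenario:
    """The dementia simulation world centred at calendar year 2000.

    Background mortality m0(t, a) = exp(−10.7 + 0.1 a + t ln 0.99), t in years
    since 2000; rate ratio log-linear from R(60) = 3 to R(95) = 1.5; default
    incidence i(a) = exp(−16 + 0.15 a) unless overridden.
    """
    return Scenario(
        incidence=incidence_override
        if incidence_override is not None
        else ExponentialRate(intercept=-16.0, age_slope=0.15),
        m0=GompertzMakehamMortality(intercept=-10.7, age_slope=0.1, annual_trend_factor=0.99),
        ratio=LogLinearRateRatio(age_low=60.0, ratio_low=3.0, age_high=95.0, ratio_high=1.5),
        time_origin=2000.0,
    )


#: Age at which ``seed_prevalence_level`` pins the initial prevalence.
_DIABETES_REFERENCE_AGE = 70.0


def diabetes_like_scenario(
    r50: float,
    r90: float,
    seed_prevalence_level: float = 0.15,
    *,
    initial_year: float = 2009.0,
    ages: Optional[np.ndarray] = None,
    settings=None,
):
    """A diabetes-like world plus its initial prevalence cross-section.

    The rate ratio is log-linear with anchors (50, ``r50``) and (90, ``r90``);
    the anchors must lie inside the supports [2, 9] and [1, 2] used by the
    Bayesian priors.  Background mortality is Gompertz–Makeham around 2012 and
    incidence rises exponentially with age (doubling roughly every 10 years);
    its overall scale is calibrated deterministically (Brent root finding on
    the forward-solved prevalence) so that the initial cross-section has
    prevalence ``seed_prevalence_level`` at age 70.

    Returns
    -------
    (Scenario, PrevalenceCrossSection)
        The scenario and the exact (noise-free) initial prevalence at
        ``initial_year`` on ``ages`` (default 50…90 in 1-year steps).
    """
    from scipy.optimize import brentq

    from .forward import SolverSettings, cross_section, odds_at

    if not 2.0 <= r50 <= 9.0:
        raise ValueError(f"r50={r50} outside the admissible range [2, 9]")
    if not 1.0 <= r90 <= 2.0:
        raise ValueError(f"r90={r90} outside the admissible range [1, 2]")
    if not 0.01 <= seed_prevalence_level <= 0.35:
        raise ValueError("seed_prevalence_level must lie in [0.01, 0.35]")
    settings = settings or SolverSettings()
    if ages is None:
        ages = np.arange(50.0, 90.0 + 0.5, 1.0)

    ratio = LogLinearRateRatio(50.0, r50, 90.0, r90)
    m0 = GompertzMakehamMortality(intercept=-10.7, age_slope=0.1, annual_trend_factor=0.99)

    def build(log_scale: float) -> Scenario:
        inc = ExponentialRate(
            intercept=log_scale - 0.07 * _DIABETES_REFERENCE_AGE, age_slope=0.07
        )
        return Scenario(incidence=inc, m0=m0, ratio=ratio, time_origin=2012.0)

    def gap(log_scale: float) -> float:
        theta = odds_at(build(log_scale), initial_year, _DIABETES_REFERENCE_AGE, settings)
        return theta / (1.0 + theta) - seed_prevalence_level

    # prevalence at the reference age is monotone in the incidence scale
    log_scale = brentq(gap, math.log(1e-5), math.log(0.5), xtol=1e-12, rtol=8.9e-16)
    scenario = build(log_scale)
    initial = cross_section(scenario, initial_year, ages, settings, method="odds")
    return scenario, initial


def sample_observed_prevalence(
    cs: PrevalenceCrossSection, group_sizes, seed: int
) -> PrevalenceCrossSection:
    """Binomial sampling noise: per age j draw Binomial(n_j, p_j)/n_j.

    A test utility emulating survey sampling; the analytic pipelines consume
    exact prevalences.
    """
    if group_sizes is None:
        raise ValueError("group_sizes are required for sampling")
    n = np.broadcast_to(np.asarray(group_sizes), cs.ages.shape)
    if np.any(n <= 0) or not np.allclose(n, np.round(n)):
        raise ValueError("group_sizes must be positive integers")
    n = np.round(n).astype(np.int64)
    rng = np.random.default_rng(seed)
    draws = rng.binomial(n, cs.prevalence)
    return PrevalenceCrossSection(
        calendar_time=cs.calendar_time,
        ages=cs.ages.copy(),
        prevalence=draws / n,
        group_sizes=n.astype(float),
    )
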