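"""Transition-rate surfaces for the illness-death model.

The illness-death model for a chronic disease has three states — *Healthy*,
*Ill*, *Dead* — and, because remission is structurally absent, three
transition rates: the incidence rate ``i``, the mortality of the disease-free
``m0`` and the mortality of the diseased ``m1``.  All rates are per
person-year and may depend on time ``t`` and age ``a``.

A rate surface is anything with an ``evaluate(t, a)`` method returning a
non-negative rate.  The time argument is expressed in the frame the surface
was built in; surfaces attached to a :class:`~exmort.scenario.Scenario` use
years since the scenario's ``time_origin``, and the scenario converts from
calendar years at its public interface.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Protocol, runtime_checkable

import numpy as np

__all__ = [
    "RateSurface",
    "ConstantRate",
    "ExponentialRate",
    "GompertzMakehamMortality",
    "LogLinearRateRatio",
    "TabulatedRate",
]


@runtime_checkable
class RateSurface(Protocol):
    """Contract for a rate surface: ``evaluate(t, a) -> rate`` (per person-year)."""

    def evaluate(self, t, a):  # pragma: no cover - protocol signature
        ...


@dataclass(frozen=True)
class ConstantRate:
    """A rate that is the same at every time and age."""

    value: float

    def __post_init__(self):
        if self.value < 0:
            raise ValueError(f"rate must be non-negative, got {self.value}")

    def evaluate(self, t, a):
        return self.value + np.zeros_like(np.asarray(a, dtype=float)) if np.ndim(a) else self.value

    __call__ = evaluate


@dataclass(frozen=True)
class ExponentialRate:
    """Time-constant rate with log-linear age dependence, exp(intercept + age_slope * a)."""

    intercept: float
    age_slope: float

    def evaluate(self, t, a):
        return np.exp(self.intercept + self.age_slope * np.asarray(a, dtype=float)) if np.ndim(a) else math.exp(
            self.intercept + self.age_slope * a
        )

    __call__ = evaluate


@dataclass(frozen=True)
class GompertzMakehamMortality:
    """Gompertz–Makeham-type mortality with a multiplicative annual calendar trend.

    ``evaluate(t, a) = exp(intercept + age_slope * a + t * ln(annual_trend_factor))``

    with ``t`` in years since the reference origin.  ``annual_trend_factor``
    below 1 encodes secularly declining mortality (e.g. 0.99 is a 1 % decline
    per calendar year).
    """

    intercept: float = -10.7
    age_slope: float = 0.1
    annual_trend_factor: float = 0.99

    def __post_init__(self):
        if self.annual_trend_factor <= 0:
            raise ValueError("annual_trend_factor must be positive")

    def evaluate(self, t, a):
        z = self.intercept + self.age_slope * np.asarray(a, dtype=float) + np.asarray(
            t, dtype=float
        ) * math.log(self.annual_trend_factor)
        return np.exp(z) if np.ndim(z) else math.exp(z)

    __call__ = evaluate


@dataclass(frozen=True)
class LogLinearRateRatio:
    """Mortality rate ratio R(a) whose logarithm is affine in age.

    Anchored so that ``evaluate(age_low) == ratio_low`` and
    ``evaluate(age_high) == ratio_high`` exactly:

        log R(a) = log(ratio_low)
                 + [log(ratio_high) - log(ratio_low)] * (a - age_low) / (age_high - age_low)

    Evaluation outside the anchor range extrapolates the same line.
    """

    age_low: float
    ratio_low: float
    age_high: float
    ratio_high: float

    def __post_init__(self):
        if self.age_high == self.age_low:
            raise ValueError("anchor ages must differ")
        if self.ratio_low <= 0 or self.ratio_high <= 0:
            raise ValueError("anchor ratios must be positive")

    @property
    def log_slope(self) -> float:
        return (math.log(self.ratio_high) - math.log(self.ratio_low)) / (self.age_high - self.age_low)

    def evaluate(self, a):
        z = math.log(self.ratio_low) + self.log_slope * (np.asarray(a, dtype=float) - self.age_low)
        return np.exp(z) if np.ndim(z) else math.exp(z)

    __call__ = evaluate


class TabulatedRate:
    """Age-specific rate given on a grid, piecewise-linearly interpolated in age.

    Time-constant by construction: ``evaluate(t, a)`` ignores ``t``.  Ages
    outside the tabulated range raise rather than extrapolate.
    """

    def __init__(self, ages, rates):
        ages = np.asarray(ages, dtype=float)
        rates = np.asarray(rates, dtype=float)
        if ages.ndim != 1 or ages.shape != rates.shape:
            raise ValueError("ages and rates must be 1-D arrays of equal length")
        if ages.size < 2:
            raise ValueError("need at least two grid points")
        if np.any(np.diff(ages) <= 0):
            raise ValueError("ages must be strictly increasing")
        if np.any(rates < 0):
            j = int(np.argmax(rates < 0))
            raise ValueError(f"negative rate {rates[j]} at age {ages[j]}")
        self.ages = ages
        self.rates = rates

    def evaluate(self, t, a):
        a_arr = np.asarray(a, dtype=float)
        if np.any(a_arr < self.ages[0]) or np.any(a_arr > self.ages[-1]):
            raise ValueError(
                f"age {a} outside tabulated range [{self.ages[0]}, {self.ages[-1]}]"
            )
        out = np.interp(a_arr, self.ages, self.rates)
        return out if np.ndim(a) else float(out)

    __call__ = evaluate

    def __repr__(self):  # pragma: no cover - cosmetic
        return f"TabulatedRate(ages=[{self.ages[0]}..{self.ages[-1]}], n={self.ages.size})"
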