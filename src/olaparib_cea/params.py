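"""Model parameters: recurrence schedules and the full strategy configuration.

Base-case values reproduce the published model inputs for adjuvant olaparib
in gBRCA1/2-mutated, high-risk early breast cancer: costs in 2021 US
dollars, utilities on the usual 0-1 scale, times in months, ages in years.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np

from .survival import HazardRatio, apply_hazard_ratio, prob_to_rate

__all__ = [
    "RecurrenceSchedule",
    "ModelParams",
    "BASE_HAZARD_RATIO",
    "PLACEBO_DDFS_TARGETS",
    "PLACEBO_OS_TARGETS",
    "OLAPARIB_DDFS_TARGETS",
    "OLAPARIB_OS_TARGETS",
]

# Trial survival targets (fractions) at months 12/24/36/48.
OLAPARIB_DDFS_TARGETS: Mapping[int, float] = {12: 0.944, 24: 0.906, 36: 0.880, 48: 0.865}
PLACEBO_DDFS_TARGETS: Mapping[int, float] = {12: 0.903, 24: 0.840, 36: 0.810, 48: 0.791}
OLAPARIB_OS_TARGETS: Mapping[int, float] = {12: 0.980, 24: 0.950, 36: 0.928, 48: 0.898}
PLACEBO_OS_TARGETS: Mapping[int, float] = {12: 0.969, 24: 0.928, 36: 0.891, 48: 0.864}

BASE_HAZARD_RATIO = HazardRatio(point=0.61, ci_low=0.48, ci_high=0.77)


@dataclass(frozen=True)
class RecurrenceSchedule:
    """Monthly metastatic-recurrence rates by model year.

    Years 1-4 carry individually calibrated monthly rates; beyond the trial
    window the schedule falls back to fixed annual recurrence probabilities
    for triple-negative-like disease (years 5-9, then years >= 10), which by
    assumption carry no treatment effect.
    """

    monthly_rates_years1to4: tuple[float, float, float, float]
    annual_prob_years5to9: float = 0.0156
    annual_prob_years10plus: float = 0.0078

    def __post_init__(self) -> None:
        if len(self.monthly_rates_years1to4) != 4:
            raise ValueError("need exactly 4 year-specific monthly rates")
        if any(r < 0 or not np.isfinite(r) for r in self.monthly_rates_years1to4):
            raise ValueError(f"rates must be >= 0, got {self.monthly_rates_years1to4}")
        for p in (self.annual_prob_years5to9, self.annual_prob_years10plus):
            if not 0 <= p < 1:
                raise ValueError(f"annual probability must be in [0, 1), got {p}")

    @property
    def monthly_rate_years5to9(self) -> float:
        return prob_to_rate(self.annual_prob_years5to9, 12.0)

    @property
    def monthly_rate_years10plus(self) -> float:
        return prob_to_rate(self.annual_prob_years10plus, 12.0)

    def monthly_rate(self, month: int) -> float:
        """Recurrence rate in force during 1-based model month ``month``."""
        if month < 1:
            raise ValueError(f"month must be >= 1, got {month}")
        year = (month - 1) // 12 + 1
        if year <= 4:
            return self.monthly_rates_years1to4[year - 1]
        if year <= 9:
            return self.monthly_rate_years5to9
        return self.monthly_rate_years10plus

    def monthly_rates(self, n_months: int) -> np.ndarray:
        """Vector of rates for months 1..n_months."""
        years = np.arange(n_months) // 12 + 1
        out = np.where(
            years <= 9, self.monthly_rate_years5to9, self.monthly_rate_years10plus
        )
        for y, r in enumerate(self.monthly_rates_years1to4, start=1):
            out = np.where(years == y, r, out)
        return out.astype(float)

    def with_hazard_ratio(self, hr: float) -> "RecurrenceSchedule":
        """Scale the trial-window (years 1-4) rates by a hazard ratio.

        Post-trial rates are shared between arms and are left untouched.
        """
        scaled = tuple(apply_hazard_ratio(r, hr) for r in self.monthly_rates_years1to4)
        return replace(self, monthly_rates_years1to4=scaled)


def treated_schedule_from_placebo(
    placebo: RecurrenceSchedule, hr: HazardRatio | float
) -> RecurrenceSchedule:
    """Treated-arm schedule implied by the placebo schedule and a hazard ratio."""
    point = hr.point if isinstance(hr, HazardRatio) else float(hr)
    return placebo.with_hazard_ratio(point)


@dataclass(frozen=True)
class ModelParams:
    """Full configuration for one strategy of the cohort model.

    Defaults are the published base case: a 42-year-old cohort entering in
    the no-recurrence state after definitive local therapy, with costs from
    the 2021 Medicare fee schedule and literature, and 3% annual discounting
    of all outcomes.
    """

    label: str = "no olaparib"
    olaparib: bool = False
    starting_age: float = 42.0
    monthly_drug_cost: float = 14_523.0
    oncologist_visit_cost: float = 867.0
    imaging_cost: float = 540.0  # diagnostic mammogram + breast MRI
    monthly_metastatic_cost: float = 23_599.0
    utility_no_recurrence: float = 0.98
    utility_metastatic: float = 0.55
    olaparib_utility_multiplier: float = 0.90
    hazard_ratio: HazardRatio = BASE_HAZARD_RATIO
    schedule: RecurrenceSchedule = field(
        default_factory=lambda: RecurrenceSchedule((0.0, 0.0, 0.0, 0.0))
    )
    monthly_metastatic_death_rate: float = 0.052
    annual_discount_rate: float = 0.03
    imaging_fraction: float = 0.535  # share of the cohort with >= 1 breast
    treatment_duration_months: int = 12
    max_age: float = 110.0

    def __post_init__(self) -> None:
        for name in ("utility_no_recurrence", "utility_metastatic", "olaparib_utility_multiplier"):
            u = getattr(self, name)
            if not 0 <= u <= 1:
                raise ValueError(f"{name} must be in [0, 1], got {u}")
        for name in (
            "monthly_drug_cost",
            "oncologist_visit_cost",
            "imaging_cost",
            "monthly_metastatic_cost",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.annual_discount_rate < 0:
            raise ValueError("discount rate must be >= 0")
        if not 0 <= self.imaging_fraction <= 1:
            raise ValueError("imaging_fraction must be in [0, 1]")
        if self.treatment_duration_months <= 0:
            raise ValueError("treatment_duration_months must be > 0")
        if self.monthly_metastatic_death_rate < 0:
            raise ValueError("monthly_metastatic_death_rate must be >= 0")
        if self.max_age <= self.starting_age:
            raise ValueError("max_age must exceed starting_age")

    @property
    def horizon_months(self) -> int:
        return int(round((self.max_age - self.starting_age) * 12))

    def with_(self, **changes) -> "ModelParams":
        """Return a copy with the given fields replaced."""
        return replace(self, **changes)
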