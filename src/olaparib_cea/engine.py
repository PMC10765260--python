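"""Four-state Markov cohort engine with 1-month cycles.

States: no recurrence, metastatic recurrence, death from breast cancer,
death from other causes.  The whole cohort starts in no recurrence; distant
recurrence and background (other-cause) mortality compete for exits from
the no-recurrence state, and breast-cancer death (constant monthly rate
calibrated to a 13.3-month median survival) competes with background
mortality in the metastatic state.  Breast-cancer death is reachable only
from the metastatic state.

The recursion for state occupancy under piecewise-constant monthly hazards
has a closed form (cumulative products of stay probabilities and cumulative
sums of inflows), so a lifetime run is a handful of vector operations; the
probabilistic sensitivity analysis leans on this.

Rewards accrue on the state occupied during a cycle, with transitions
applied at cycle end and no half-cycle correction; with monthly cycles the
correction would change lifetime totals by well under one percent.  The
accrual of month ``m`` is discounted by ``(1 + d)^-(m/12)``.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .lifetable import LifeTable
from .params import ModelParams
from .survival import competing_risk_probs

__all__ = [
    "HealthState",
    "CohortTrace",
    "cycle_transition_row",
    "run_cohort",
    "model_ddfs",
    "model_os",
]


class HealthState(enum.IntEnum):
    NO_RECURRENCE = 0
    METASTATIC = 1
    DEATH_BREAST_CANCER = 2
    DEATH_OTHER = 3


def cycle_transition_row(
    state: HealthState,
    month: int,
    age: float,
    p: ModelParams,
    lt: LifeTable,
) -> np.ndarray:
    """One row of the transition matrix in force during ``month``.

    Probabilities are ordered as :class:`HealthState`; each row sums to 1.
    """
    if month < 1:
        raise ValueError(f"month must be >= 1, got {month}")
    row = np.zeros(4)
    h_bg = -math.log1p(-min(lt.annual_prob(age), 1 - 1e-12)) / 12.0
    if state == HealthState.NO_RECURRENCE:
        r_rec = p.schedule.monthly_rate(month)
        p_rec, p_bg = competing_risk_probs([r_rec, h_bg], 1.0)
        row[HealthState.METASTATIC] = p_rec
        row[HealthState.DEATH_OTHER] = p_bg
        row[HealthState.NO_RECURRENCE] = 1.0 - p_rec - p_bg
    elif state == HealthState.METASTATIC:
        p_bc, p_bg = competing_risk_probs(
            [p.monthly_metastatic_death_rate, h_bg], 1.0
        )
        row[HealthState.DEATH_BREAST_CANCER] = p_bc
        row[HealthState.DEATH_OTHER] = p_bg
        row[HealthState.METASTATIC] = 1.0 - p_bc - p_bg
    elif state in (HealthState.DEATH_BREAST_CANCER, HealthState.DEATH_OTHER):
        row[state] = 1.0
    else:
        raise ValueError(f"unknown state {state!r}")
    return row


def _event_months(olaparib: bool, n_months: int) -> tuple[np.ndarray, np.ndarray]:
    """(visit, imaging) indicator vectors for months 1..n_months.

    Surveillance schedule: with adjuvant olaparib, monthly oncologist visits
    during the 12 treatment months, 6-monthly visits through month 72 (five
    years after completing systemic therapy), annual visits thereafter.
    Without olaparib, 6-monthly visits through month 60, annual thereafter.
    Surveillance imaging (diagnostic mammogram + breast MRI) is annual in
    both arms for the fraction of the cohort with at least one breast.
    """
    months = np.arange(1, n_months + 1)
    if olaparib:
        visits = (
            (months <= 12)
            | ((months > 12) & (months <= 72) & (months % 6 == 0))
            | ((months > 72) & (months % 12 == 0))
        )
    else:
        visits = ((months <= 60) & (months % 6 == 0)) | (
            (months > 60) & (months % 12 == 0)
        )
    imaging = months % 12 == 0
    return visits.astype(float), imaging.astype(float)


@dataclass
class CohortTrace:
    """State occupancy and reward accrual of one strategy over time.

    Occupancy arrays are indexed by elapsed months 0..T (``no_recurrence[t]``
    is the fraction of the cohort distant-recurrence-free and alive at month
    ``t``); per-cycle reward arrays have length T, entry ``m-1`` holding the
    accrual of month ``m``.
    """

    params: ModelParams
    no_recurrence: np.ndarray
    metastatic: np.ndarray
    death_breast_cancer: np.ndarray
    death_other: np.ndarray
    cycle_cost: np.ndarray
    cycle_life_years: np.ndarray
    cycle_qalys: np.ndarray
    cycle_cost_discounted: np.ndarray
    cycle_life_years_discounted: np.ndarray
    cycle_qalys_discounted: np.ndarray

    @property
    def n_cycles(self) -> int:
        return self.cycle_cost.size

    @property
    def total_cost(self) -> float:
        return float(self.cycle_cost_discounted.sum())

    @property
    def total_life_years(self) -> float:
        return float(self.cycle_life_years_discounted.sum())

    @property
    def total_qalys(self) -> float:
        return float(self.cycle_qalys_discounted.sum())

    @property
    def total_cost_undiscounted(self) -> float:
        return float(self.cycle_cost.sum())

    @property
    def total_life_years_undiscounted(self) -> float:
        return float(self.cycle_life_years.sum())

    @property
    def total_qalys_undiscounted(self) -> float:
        return float(self.cycle_qalys.sum())

    def occupancy(self, t: int) -> np.ndarray:
        return np.array(
            [
                self.no_recurrence[t],
                self.metastatic[t],
                self.death_breast_cancer[t],
                self.death_other[t],
            ]
        )

    def ddfs(self, month: int) -> float:
        """Distant disease-free survival: alive and recurrence-free at ``month``."""
        self._check_month(month)
        return float(self.no_recurrence[month])

    def os(self, month: int) -> float:
        """Overall survival at ``month`` (metastatic occupants are alive)."""
        self._check_month(month)
        return float(
            1.0 - self.death_breast_cancer[month] - self.death_other[month]
        )

    def _check_month(self, month: int) -> None:
        if not 0 <= month <= self.n_cycles:
            raise ValueError(
                f"month {month} outside trace (0..{self.n_cycles})"
            )

    def to_frame(self) -> pd.DataFrame:
        t = np.arange(self.n_cycles + 1)
        df = pd.DataFrame(
            {
                "month": t,
                "age": self.params.starting_age + t / 12.0,
                "no_recurrence": self.no_recurrence,
                "metastatic": self.metastatic,
                "death_breast_cancer": self.death_breast_cancer,
                "death_other": self.death_other,
            }
        )
        for name, arr in [
            ("cycle_cost_discounted", self.cycle_cost_discounted),
            ("cycle_life_years_discounted", self.cycle_life_years_discounted),
            ("cycle_qalys_discounted", self.cycle_qalys_discounted),
        ]:
            df[name] = np.concatenate([[0.0], arr])
        return df


def run_cohort(
    p: ModelParams, lt: LifeTable, horizon_months: int | None = None
) -> CohortTrace:
    """Simulate the cohort from the starting age to the model horizon.

    The horizon defaults to age ``p.max_age``; the life table must cover it.
    """
    T = p.horizon_months if horizon_months is None else int(horizon_months)
    if T < 1:
        raise ValueError(f"horizon must be >= 1 month, got {T}")

    h_bg = lt.monthly_rates(p.starting_age, T)  # background death rate, months 1..T
    r_rec = p.schedule.monthly_rates(T)  # recurrence rate, months 1..T
    d_bc = p.monthly_metastatic_death_rate

    # --- no recurrence: pure decrement -----------------------------------
    exit_nr = r_rec + h_bg
    stay_nr = np.exp(-exit_nr)
    n = np.empty(T + 1)
    n[0] = 1.0
    np.cumprod(stay_nr, out=n[1:])
    with np.errstate(invalid="ignore"):
        frac_rec = np.where(exit_nr > 0, r_rec / np.where(exit_nr > 0, exit_nr, 1.0), 0.0)
    p_any_nr = -np.expm1(-exit_nr)
    inflow_met = n[:-1] * frac_rec * p_any_nr  # arrivals in metastatic at month m
    to_death_other_nr = n[:-1] * (1.0 - frac_rec) * p_any_nr

    # --- metastatic: decrement plus inflow --------------------------------
    exit_met = d_bc + h_bg
    stay_met = np.exp(-exit_met)
    P = np.cumprod(stay_met)  # P[m-1] = prod of stay_met over months 1..m
    # met[t] = sum_{u<=t} inflow_u * prod_{v=u+1..t} stay_v = P_t * cumsum(inflow/P);
    # arrivals of month t join at its end and first face exit during month t+1
    met = np.empty(T + 1)
    met[0] = 0.0
    z = np.where(P > 0, inflow_met / np.where(P > 0, P, 1.0), 0.0)
    met[1:] = P * np.cumsum(z)

    with np.errstate(invalid="ignore"):
        frac_bc = np.where(exit_met > 0, d_bc / np.where(exit_met > 0, exit_met, 1.0), 0.0)
    p_any_met = -np.expm1(-exit_met)
    met_during = met[:-1]
    to_death_bc = met_during * frac_bc * p_any_met
    to_death_other_met = met_during * (1.0 - frac_bc) * p_any_met

    death_bc = np.concatenate([[0.0], np.cumsum(to_death_bc)])
    death_other = np.concatenate(
        [[0.0], np.cumsum(to_death_other_nr + to_death_other_met)]
    )

    # --- rewards ----------------------------------------------------------
    months = np.arange(1, T + 1)
    disc = (1.0 + p.annual_discount_rate) ** (-months / 12.0)
    n_during = n[:-1]

    on_drug = (months <= p.treatment_duration_months) if p.olaparib else np.zeros(T, bool)
    u_nr = np.full(T, p.utility_no_recurrence)
    if p.olaparib:
        u_nr[on_drug] *= p.olaparib_utility_multiplier

    alive = n_during + met_during
    ly = alive / 12.0
    qaly = (n_during * u_nr + met_during * p.utility_metastatic) / 12.0

    visits, imaging = _event_months(p.olaparib, T)
    cost = (
        n_during
        * (
            (p.monthly_drug_cost if p.olaparib else 0.0) * on_drug
            + p.oncologist_visit_cost * visits
            + p.imaging_cost * p.imaging_fraction * imaging
        )
        + met_during * p.monthly_metastatic_cost
    )

    return CohortTrace(
        params=p,
        no_recurrence=n,
        metastatic=met,
        death_breast_cancer=death_bc,
        death_other=death_other,
        cycle_cost=cost,
        cycle_life_years=ly,
        cycle_qalys=qaly,
        cycle_cost_discounted=cost * disc,
        cycle_life_years_discounted=ly * disc,
        cycle_qalys_discounted=qaly * disc,
    )


def model_ddfs(trace: CohortTrace, month: int) -> float:
    """Model distant disease-free survival at ``month``."""
    return trace.ddfs(month)


def model_os(trace: CohortTrace, month: int) -> float:
    """Model overall survival at ``month``."""
    return trace.os(month)
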