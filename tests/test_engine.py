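"""Cohort-engine behaviour: transition rows, occupancy dynamics, rewards.

The vectorized engine is cross-checked against a deliberately naive
month-by-month matrix iteration written independently in this file.
"""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from olaparib_cea import (
    HealthState,
    LifeTable,
    ModelParams,
    RecurrenceSchedule,
    cycle_transition_row,
    model_ddfs,
    model_os,
    run_cohort,
)

SCHED = RecurrenceSchedule((0.008, 0.006, 0.003, 0.002))


# ---------------------------------------------------------------------------
# transition rows


def test_death_states_are_absorbing(base_params, bundled_lt):
    for state in (HealthState.DEATH_BREAST_CANCER, HealthState.DEATH_OTHER):
        row = cycle_transition_row(state, 5, 42.0, base_params, bundled_lt)
        expected = np.zeros(4)
        expected[state] = 1.0
        assert np.array_equal(row, expected)


def test_no_recurrence_stays_put_without_hazards(zero_lt):
    p = ModelParams(schedule=RecurrenceSchedule((0, 0, 0, 0), 0.0, 0.0))
    row = cycle_transition_row(HealthState.NO_RECURRENCE, 1, 42.0, p, zero_lt)
    assert row[HealthState.NO_RECURRENCE] == 1.0


def test_metastatic_death_probability_closed_form(zero_lt, base_params):
    row = cycle_transition_row(HealthState.METASTATIC, 1, 42.0, base_params, zero_lt)
    assert row[HealthState.DEATH_BREAST_CANCER] == pytest.approx(
        1 - math.exp(-0.052), rel=1e-12
    )
    assert row[HealthState.DEATH_OTHER] == 0.0


@pytest.mark.parametrize("state", list(HealthState))
@pytest.mark.parametrize("month", [1, 13, 60, 200])
def test_rows_sum_to_one(state, month, bundled_lt):
    p = ModelParams(schedule=SCHED)
    row = cycle_transition_row(state, month, 42 + (month - 1) / 12, p, bundled_lt)
    assert row.sum() == pytest.approx(1.0, abs=1e-12)
    assert np.all(row >= 0)


# ---------------------------------------------------------------------------
# independent oracle: naive matrix iteration


def _naive_trace(p: ModelParams, lt: LifeTable, T: int):
    """Month-by-month 4-state iteration from first principles."""
    occ = np.zeros((T + 1, 4))
    occ[0, 0] = 1.0
    ly = qaly = 0.0
    for m in range(1, T + 1):
        age = p.starting_age + (m - 1) / 12.0
        q = lt.annual_prob(age)
        h = -math.log(1 - q) / 12.0 if q < 1 else math.inf
        year = (m - 1) // 12 + 1
        if year <= 4:
            r = p.schedule.monthly_rates_years1to4[year - 1]
        elif year <= 9:
            r = -math.log(1 - p.schedule.annual_prob_years5to9) / 12.0
        else:
            r = -math.log(1 - p.schedule.annual_prob_years10plus) / 12.0
        M = np.zeros((4, 4))
        tot = r + h
        p_any = 1 - math.exp(-tot)
        M[0, 1] = r / tot * p_any if tot > 0 else 0.0
        M[0, 3] = h / tot * p_any if tot > 0 else 0.0
        M[0, 0] = 1 - M[0, 1] - M[0, 3]
        tot_m = p.monthly_metastatic_death_rate + h
        p_any_m = 1 - math.exp(-tot_m)
        M[1, 2] = (
            p.monthly_metastatic_death_rate / tot_m * p_any_m if tot_m > 0 else 0.0
        )
        M[1, 3] = h / tot_m * p_any_m if tot_m > 0 else 0.0
        M[1, 1] = 1 - M[1, 2] - M[1, 3]
        M[2, 2] = M[3, 3] = 1.0
        disc = (1 + p.annual_discount_rate) ** (-m / 12.0)
        u = p.utility_no_recurrence
        if p.olaparib and m <= p.treatment_duration_months:
            u *= p.olaparib_utility_multiplier
        ly += (occ[m - 1, 0] + occ[m - 1, 1]) / 12 * disc
        qaly += (occ[m - 1, 0] * u + occ[m - 1, 1] * p.utility_metastatic) / 12 * disc
        occ[m] = occ[m - 1] @ M
    return occ, ly, qaly


@pytest.mark.parametrize("olaparib", [False, True])
def test_vectorized_engine_matches_naive_iteration(olaparib, gompertz_lt):
    p = ModelParams(olaparib=olaparib, schedule=SCHED, starting_age=45.0)
    T = 150
    trace = run_cohort(p, gompertz_lt, horizon_months=T)
    occ, ly, qaly = _naive_trace(p, gompertz_lt, T)
    got = np.column_stack(
        [trace.no_recurrence, trace.metastatic,
         trace.death_breast_cancer, trace.death_other]
    )
    assert np.allclose(got, occ, atol=1e-12)
    assert trace.total_life_years == pytest.approx(ly, rel=1e-10)
    assert trace.total_qalys == pytest.approx(qaly, rel=1e-10)


# ---------------------------------------------------------------------------
# closed-form reward checks


def test_zero_hazard_cohort_accrues_exact_person_time(zero_lt):
    p = ModelParams(
        schedule=RecurrenceSchedule((0, 0, 0, 0), 0.0, 0.0),
        utility_no_recurrence=1.0,
        annual_discount_rate=0.0,
    )
    trace = run_cohort(p, zero_lt, horizon_months=120)
    assert trace.total_life_years == pytest.approx(10.0, abs=1e-9)
    assert trace.total_qalys == pytest.approx(10.0, abs=1e-9)


def test_metastatic_survival_median_at_fourteen_months_in_state(zero_lt):
    # force the whole cohort into the metastatic state during month 1 and
    # read off the geometric survival implied by the 0.052 monthly rate:
    # the alive fraction first drops below one-half 14 months after entry
    p = ModelParams(
        schedule=RecurrenceSchedule((1e9, 0, 0, 0), 0.0, 0.0),
        annual_discount_rate=0.0,
    )
    trace = run_cohort(p, zero_lt, horizon_months=40)
    alive = trace.no_recurrence + trace.metastatic
    entry = 1  # cohort sits in METASTATIC from month 1 on
    months_in_state = next(
        k for k in range(1, 40 - entry) if alive[entry + k] <= 0.5
    )
    assert months_in_state == 14
    # ... consistent with the 13.3-month continuous median
    assert math.log(2) / 0.052 == pytest.approx(13.3, abs=0.05)


def test_cost_schedule_hand_computed_first_year(zero_lt):
    sched = RecurrenceSchedule((0, 0, 0, 0), 0.0, 0.0)
    olap = ModelParams(
        label="olaparib", olaparib=True, schedule=sched, annual_discount_rate=0.0
    )
    trace = run_cohort(olap, zero_lt, horizon_months=12)
    # 12 months drug + monthly visits, one annual imaging round at 53.5%
    expected = 12 * (14_523 + 867) + 0.535 * 540
    assert trace.total_cost == pytest.approx(expected, rel=1e-12)
    assert trace.total_qalys == pytest.approx(0.98 * 0.9, rel=1e-12)

    no_olap = ModelParams(schedule=sched, annual_discount_rate=0.0)
    trace = run_cohort(no_olap, zero_lt, horizon_months=12)
    # visits at months 6 and 12 plus the annual imaging round
    assert trace.total_cost == pytest.approx(2 * 867 + 0.535 * 540, rel=1e-12)
    assert trace.total_qalys == pytest.approx(0.98, rel=1e-12)


# ---------------------------------------------------------------------------
# invariants


@settings(max_examples=25, deadline=None, derandomize=True)
@given(
    r1=st.floats(0, 0.05), r2=st.floats(0, 0.05),
    r3=st.floats(0, 0.05), r4=st.floats(0, 0.05),
    d=st.floats(0.001, 0.3),
)
def test_mass_conservation_under_random_parameters(r1, r2, r3, r4, d, gompertz_lt):
    p = ModelParams(
        schedule=RecurrenceSchedule((r1, r2, r3, r4)),
        monthly_metastatic_death_rate=d,
    )
    trace = run_cohort(p, gompertz_lt, horizon_months=300)
    total = (
        trace.no_recurrence + trace.metastatic
        + trace.death_breast_cancer + trace.death_other
    )
    assert np.allclose(total, 1.0, atol=1e-9)


def test_null_intervention_strategies_coincide(bundled_lt):
    shared = dict(
        schedule=SCHED,
        monthly_drug_cost=0.0,
        olaparib_utility_multiplier=1.0,
        oncologist_visit_cost=0.0,  # removes the arm-specific visit pattern
    )
    a = run_cohort(ModelParams(olaparib=True, **shared), bundled_lt)
    b = run_cohort(ModelParams(olaparib=False, **shared), bundled_lt)
    assert a.total_cost == pytest.approx(b.total_cost, abs=1e-9)
    assert a.total_qalys == pytest.approx(b.total_qalys, abs=1e-9)
    assert a.total_life_years == pytest.approx(b.total_life_years, abs=1e-9)


def test_discounting_reduces_totals(bundled_lt):
    p0 = ModelParams(schedule=SCHED, annual_discount_rate=0.0)
    p3 = ModelParams(schedule=SCHED, annual_discount_rate=0.03)
    t0, t3 = run_cohort(p0, bundled_lt), run_cohort(p3, bundled_lt)
    assert t0.total_qalys > t3.total_qalys
    assert t0.total_cost > t3.total_cost
    # and discounted never exceeds undiscounted within one run
    assert t3.total_cost <= t3.total_cost_undiscounted
    assert t3.total_qalys <= t3.total_qalys_undiscounted


def test_higher_metastatic_mortality_lowers_life_years(bundled_lt):
    lys = [
        run_cohort(
            ModelParams(schedule=SCHED, monthly_metastatic_death_rate=d), bundled_lt
        ).total_life_years
        for d in (0.03, 0.052, 0.08, 0.15)
    ]
    assert all(a > b for a, b in zip(lys, lys[1:]))


def test_survival_curves_monotone_and_ordered(calibrated_pair, bundled_lt):
    for params in (calibrated_pair.no_olaparib, calibrated_pair.olaparib):
        trace = run_cohort(params, bundled_lt)
        ddfs = trace.no_recurrence
        os_curve = 1 - trace.death_breast_cancer - trace.death_other
        assert np.all(np.diff(ddfs) <= 1e-15)
        assert np.all(np.diff(os_curve) <= 1e-15)
        assert np.all(os_curve >= ddfs - 1e-15)


def test_trace_accessors(calibrated_pair, bundled_lt):
    trace = run_cohort(calibrated_pair.no_olaparib, bundled_lt)
    assert model_ddfs(trace, 0) == 1.0
    assert model_os(trace, 0) == 1.0
    with pytest.raises(ValueError):
        model_ddfs(trace, trace.n_cycles + 1)
    df = trace.to_frame()
    assert {"month", "age", "no_recurrence", "metastatic"} <= set(df.columns)
    assert len(df) == trace.n_cycles + 1
    assert df["cycle_cost_discounted"].sum() == pytest.approx(trace.total_cost)


def test_horizon_requires_life_table_coverage(base_params):
    short = LifeTable(ages=np.arange(40, 81), annual_death_probs=np.full(41, 0.01))
    with pytest.raises(ValueError):
        run_cohort(base_params.with_(schedule=SCHED), short)
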