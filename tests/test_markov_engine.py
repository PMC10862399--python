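"""Cohort engine: conservation, closed forms, superposition, accrual."""

import numpy as np
import pandas as pd
import pytest

from trdburden.cost_utility_inputs import StateInputs
from trdburden.incidence_scenarios import IncidencePlan
from trdburden.markov_engine import (
    EngineError,
    ScenarioConfig,
    accrue_outcomes,
    cagr,
    run_closed_cohort,
    run_open_cohort,
    summarise,
)
from trdburden.states import (
    N_STATES,
    N_SUBGROUPS,
    STATE_INDEX,
    SUBGROUPS,
    State,
    TRANSITIONS,
)
from trdburden.survival_transitions import FixedProbs, assemble_schedule


def _schedules(values=None, cycles=10):
    fits = {tr: FixedProbs(tr, 0.0) for tr in TRANSITIONS}
    if values:
        fits.update({tr: FixedProbs(tr, v) for tr, v in values.items()})
    return {g: assemble_schedule(fits, g, cycles=cycles) for g in SUBGROUPS}


def _inputs(cost=1000.0, psy=200.0, u_ntrd=0.8):
    ca = np.zeros((N_SUBGROUPS, N_STATES))
    cp = np.zeros((N_SUBGROUPS, N_STATES))
    for s in (State.NTRD, State.TRD, State.NTRD_COMORBID, State.TRD_COMORBID):
        ca[:, STATE_INDEX[s]] = cost
        cp[:, STATE_INDEX[s]] = psy
    utility = np.array([u_ntrd, 0.6, 0.664, 0.498, 0.85, 0.0])
    return StateInputs(cost_allcause=ca, cost_psychiatric=cp, utility=utility)


def _entrants(total=1000.0, subgroup=None):
    e = np.zeros(N_SUBGROUPS)
    if subgroup is None:
        e[:] = total / N_SUBGROUPS
    else:
        e[subgroup] = total
    return e


class TestClosedCohort:
    def test_identity_schedule_everyone_stays(self):
        trace = run_closed_cohort(_schedules(), _inputs(), _entrants(500.0))
        assert np.allclose(trace.occupancy[:, :, STATE_INDEX[State.NTRD]].sum(axis=1), 500.0)
        assert trace.deaths.sum() == 0.0

    def test_geometric_death_accumulation_exact(self):
        p = 0.07
        n = 2500.0
        sched = _schedules({(State.NTRD, State.DEATH): p})
        trace = run_closed_cohort(sched, _inputs(), _entrants(n, subgroup=4))
        for t in range(1, 11):
            expected = n * (1 - (1 - p) ** t)
            got = trace.occupancy[t, :, STATE_INDEX[State.DEATH]].sum()
            assert abs(got - expected) < 1e-9

    def test_homogeneity_in_entrants(self, base_case):
        e = base_case.entrants()
        t1 = run_closed_cohort(base_case.schedules, base_case.state_inputs, e)
        t2 = run_closed_cohort(base_case.schedules, base_case.state_inputs, 1.25 * e)
        for outcome in ("cost_allcause", "cost_psychiatric", "life_years", "qalys"):
            np.testing.assert_allclose(
                t2.annual(outcome), 1.25 * t1.annual(outcome), rtol=1e-12
            )
        np.testing.assert_allclose(t2.deaths, 1.25 * t1.deaths, rtol=1e-12)

    def test_conservation_of_occupancy(self, base_case):
        e = base_case.entrants()
        trace = run_closed_cohort(base_case.schedules, base_case.state_inputs, e)
        totals = trace.occupancy.sum(axis=(1, 2))
        assert np.allclose(totals, e.sum(), atol=1e-9)

    def test_cumulative_outcomes_monotone(self, base_case):
        trace = run_closed_cohort(
            base_case.schedules, base_case.state_inputs, base_case.entrants()
        )
        for outcome in ("cost_allcause", "cost_psychiatric"):
            assert (trace.annual(outcome) >= 0).all()
        assert (np.cumsum(trace.annual("deaths")) >= 0).all()
        assert (np.diff(np.cumsum(trace.annual("deaths"))) >= -1e-12).all()

    def test_discounting_reduces_costs(self, base_case):
        e = base_case.entrants()
        t0 = run_closed_cohort(base_case.schedules, base_case.state_inputs, e)
        td = run_closed_cohort(
            base_case.schedules,
            base_case.state_inputs,
            e,
            ScenarioConfig(mode="closed", discount_rate=0.025),
        )
        assert td.cumulative("cost_allcause") < t0.cumulative("cost_allcause")
        # first cycle is undiscounted by convention
        assert abs(td.annual("cost_allcause")[0] - t0.annual("cost_allcause")[0]) < 1e-9

    def test_qalys_bounded_by_life_years(self, base_case):
        trace = run_closed_cohort(
            base_case.schedules, base_case.state_inputs, base_case.entrants()
        )
        assert trace.cumulative("qalys") <= trace.cumulative("life_years") + 1e-9

    def test_subgroup_mismatch_raises(self):
        sched = _schedules()
        del sched[SUBGROUPS[0]]
        with pytest.raises(EngineError, match=SUBGROUPS[0].age_band):
            run_closed_cohort(sched, _inputs(), _entrants())


class TestAccrual:
    def test_discount_example(self):
        occ = np.zeros((N_SUBGROUPS, N_STATES))
        occ[0, STATE_INDEX[State.NTRD]] = 1.0
        si = _inputs(cost=100.0, psy=0.0)
        out = accrue_outcomes(occ, si, cycle=2, discount_rate=0.025)
        assert abs(out["cost_allcause"].sum() - 100.0 / 1.025) < 1e-9
        assert abs(out["cost_allcause"].sum() - 97.56) < 0.005

    def test_death_state_accrues_nothing(self):
        occ = np.zeros((N_SUBGROUPS, N_STATES))
        occ[:, STATE_INDEX[State.DEATH]] = 10.0
        out = accrue_outcomes(occ, _inputs(), cycle=1)
        assert out["cost_allcause"].sum() == 0.0
        assert out["life_years"].sum() == 0.0
        assert out["qalys"].sum() == 0.0

    def test_low_intensity_counts_in_life_years_not_costs(self):
        occ = np.zeros((N_SUBGROUPS, N_STATES))
        occ[:, STATE_INDEX[State.LOW_INTENSITY]] = 1.0
        out = accrue_outcomes(occ, _inputs(), cycle=1)
        assert out["cost_allcause"].sum() == 0.0
        assert out["life_years"].sum() == N_SUBGROUPS
        assert abs(out["qalys"].sum() - 0.85 * N_SUBGROUPS) < 1e-12

    def test_negative_occupancy_rejected(self):
        occ = np.full((N_SUBGROUPS, N_STATES), -1.0)
        with pytest.raises(EngineError, match="negative"):
            accrue_outcomes(occ, _inputs(), cycle=1)


def _plan(entries: dict[int, float]) -> IncidencePlan:
    years = range(min(entries), max(entries) + 1)
    table = pd.DataFrame(
        {g.label: [entries.get(y, 0.0) / N_SUBGROUPS for y in years] for g in SUBGROUPS},
        index=pd.Index(years, name="year"),
    )
    return IncidencePlan(table=table)


class TestOpenCohort:
    def test_single_entry_year_equals_shifted_closed_run(self, base_case):
        plan = _plan({2020: 1600.0, 2029: 0.0})  # zero-entry years extend the calendar
        otrace = run_open_cohort(base_case.schedules, base_case.state_inputs, plan)
        ctrace = run_closed_cohort(
            base_case.schedules, base_case.state_inputs, _entrants(1600.0)
        )
        np.testing.assert_allclose(
            otrace.annual("cost_allcause"), ctrace.annual("cost_allcause"), atol=1e-9
        )
        np.testing.assert_allclose(otrace.deaths, ctrace.deaths, atol=1e-9)

    def test_superposition_of_two_entry_years(self, base_case):
        plan = _plan({2020: 1000.0, 2022: 500.0, 2031: 0.0})
        otrace = run_open_cohort(base_case.schedules, base_case.state_inputs, plan)
        c1 = run_closed_cohort(base_case.schedules, base_case.state_inputs, _entrants(1000.0))
        c2 = run_closed_cohort(base_case.schedules, base_case.state_inputs, _entrants(500.0))
        open_costs = otrace.annual("cost_allcause")  # calendar years 2020..2031
        expected = np.zeros(12)
        expected[:10] += c1.annual("cost_allcause")
        expected[2:12] += c2.annual("cost_allcause")
        np.testing.assert_allclose(open_costs, expected, atol=1e-9)

    def test_constant_entrants_reach_steady_state(self, base_case):
        plan = _plan({y: 1000.0 for y in range(2014, 2034)})
        otrace = run_open_cohort(base_case.schedules, base_case.state_inputs, plan)
        costs = otrace.annual("cost_allcause")
        # once 10 cohorts are in the system the calendar outputs stabilise
        assert abs(costs[-1] - costs[-2]) < 1e-6 * costs[-1]
        assert abs(costs[10] - costs[-1]) < 1e-6 * costs[-1]

    def test_plan_gap_is_rejected(self):
        years = [2014, 2016]
        table = pd.DataFrame(
            {g.label: [1.0, 1.0] for g in SUBGROUPS}, index=pd.Index(years, name="year")
        )
        with pytest.raises(Exception, match="contiguous"):
            IncidencePlan(table=table)


class TestSummaries:
    def test_case_fatality_from_printed_pair(self):
        # headline check: 899 deaths among 9,147 entrants ~ 9.8%
        assert abs(100.0 * 899 / 9147 - 9.83) < 0.005

    def test_cagr_constant_series_is_zero(self):
        assert cagr(np.full(10, 5.0)) == 0.0

    def test_cagr_closed_form(self):
        series = np.zeros(10)
        series[0], series[-1] = 39.5, 24.5
        got = cagr(series)
        assert abs(got - ((24.5 / 39.5) ** (1 / 9) - 1)) < 1e-12
        assert abs(got - (-0.0517)) < 0.0005

    def test_cagr_zero_start_raises(self):
        with pytest.raises(EngineError, match="CAGR"):
            cagr(np.array([0.0, 1.0]))

    def test_summary_consistent_with_trace(self, base_case):
        trace = run_closed_cohort(
            base_case.schedules, base_case.state_inputs, base_case.entrants()
        )
        summ = summarise(trace)
        assert abs(summ["cumulative_deaths"] - trace.deaths.sum()) < 1e-9
        assert abs(
            summ["cumulative_cost_allcause"] - trace.cumulative("cost_allcause")
        ) < 1e-6
        sub = summ["subgroups"]
        assert len(sub) == 16
        assert abs(sub["cost_allcause"].sum() - summ["cumulative_cost_allcause"]) < 1e-6
        # per-patient-year burden uses life-years as denominator
        row = sub.iloc[0]
        assert abs(row.cost_allcause_per_py - row.cost_allcause / row.life_years) < 1e-9
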