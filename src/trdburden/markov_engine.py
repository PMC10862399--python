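"""Six-state time-inhomogeneous Markov cohort engine.

The engine propagates expected state occupancy through yearly cycles with
per-subgroup, per-cycle transition matrices and accrues costs (all-cause and
psychiatric), incident deaths, life-years and QALYs.

Accrual conventions (all switchable where noted):

* state membership for accrual is measured at cycle start; transitions
  apply at cycle end; no half-cycle correction by default;
* patients dying within a cycle accrue no cost and no fraction of a
  life-year for that cycle (a half-cycle option exists but is off);
* life-years include the low-intensity state (alive recovery proxy);
  "active" counts exclude low-intensity and death;
* discounting divides cycle-t amounts by (1 + r)^(t-1); the first cycle is
  undiscounted and main results use r = 0.

Closed mode follows one incident cohort for the whole horizon.  Open mode
introduces an incident cohort per calendar year; each cohort is simulated
for at most 10 cycles, and a cohort entering year Y contributes its cycle-1
outcomes to calendar year Y, so the calendar view superposes shifted closed
cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .cost_utility_inputs import StateInputs
from .incidence_scenarios import IncidencePlan
from .states import (
    ALIVE_STATES,
    COMORBID_FAMILY,
    N_STATES,
    N_SUBGROUPS,
    STATE_INDEX,
    STATE_ORDER,
    SUBGROUPS,
    State,
    Subgroup,
    TRD_FAMILY,
)
from .survival_transitions import TransitionSchedule

_ALIVE_MASK = np.array([s in ALIVE_STATES for s in STATE_ORDER], dtype=float)
_TRD_MASK = np.array([s in TRD_FAMILY for s in STATE_ORDER], dtype=float)
_COMORBID_MASK = np.array([s in COMORBID_FAMILY for s in STATE_ORDER], dtype=float)
_DEATH = STATE_INDEX[State.DEATH]
_NTRD = STATE_INDEX[State.NTRD]


class EngineError(RuntimeError):
    pass


@dataclass
class ScenarioConfig:
    mode: str = "closed"
    horizon_cycles: int = 10
    discount_rate: float = 0.0
    half_cycle: bool = False

    def __post_init__(self) -> None:
        if self.mode not in ("closed", "open"):
            raise EngineError(f"unknown mode {self.mode!r}")
        if self.horizon_cycles < 1:
            raise EngineError("horizon must be >= 1 cycle")
        if self.discount_rate < 0:
            raise EngineError("discount rate must be >= 0")


def _schedule_array(
    schedules: Mapping[Subgroup, TransitionSchedule], cycles: int
) -> np.ndarray:
    """(16, cycles, 6, 6) stack of per-subgroup transition matrices."""
    arr = np.empty((N_SUBGROUPS, cycles, N_STATES, N_STATES))
    for gi, g in enumerate(SUBGROUPS):
        if g not in schedules:
            raise EngineError(f"missing transition schedule for subgroup {g.label}")
        sched = schedules[g]
        if sched.cycles < cycles:
            raise EngineError(
                f"schedule for {g.label} covers {sched.cycles} < {cycles} cycles"
            )
        arr[gi] = sched.probs[:cycles]
    return arr


@dataclass
class CohortTrace:
    """Per-cycle occupancy and accrued outcomes for one scenario run.

    ``occupancy[t]`` is expected persons per (subgroup, state) at the start
    of cycle t+1 (``occupancy[0]`` is the initial distribution); per-state
    accrual arrays have shape (cycles, 16, 6) so attribution splits can be
    formed after the fact.  In open mode the cycle axis is calendar years
    and ``years`` is populated.
    """

    occupancy: np.ndarray
    cost_allcause: np.ndarray
    cost_psychiatric: np.ndarray
    life_years: np.ndarray
    qalys: np.ndarray
    deaths: np.ndarray  # incident deaths per (cycle, subgroup)
    entrants: np.ndarray  # (16,) total entrants over the run
    discount_rate: float = 0.0
    years: list[int] | None = None

    @property
    def n_cycles(self) -> int:
        return self.cost_allcause.shape[0]

    # -- aggregations --------------------------------------------------------------
    def annual(self, outcome: str, split: str = "all") -> np.ndarray:
        """Per-cycle totals of one outcome, optionally restricted to the TRD
        or comorbid state families."""
        arr = getattr(self, outcome)
        if outcome == "deaths":
            return arr.sum(axis=1)
        mask = {"all": None, "trd": _TRD_MASK, "comorbid": _COMORBID_MASK}[split]
        if mask is None:
            return arr.sum(axis=(1, 2))
        return (arr * mask).sum(axis=(1, 2))

    def cumulative(self, outcome: str, split: str = "all") -> float:
        return float(self.annual(outcome, split).sum())

    def by_subgroup(self, outcome: str) -> np.ndarray:
        arr = getattr(self, outcome)
        if outcome == "deaths":
            return arr.sum(axis=0)
        return arr.sum(axis=(0, 2))

    def active_share(self) -> np.ndarray:
        """Share of entrants occupying TRD or comorbid states at each cycle start."""
        occ = self.occupancy[:-1]  # cycle starts
        union = occ[:, :, STATE_INDEX[State.TRD]] + occ[:, :, STATE_INDEX[State.NTRD_COMORBID]] + occ[
            :, :, STATE_INDEX[State.TRD_COMORBID]
        ]
        total = occ.sum(axis=(1, 2))
        return union.sum(axis=1) / np.maximum(total, 1e-300)

    def to_frame(self) -> pd.DataFrame:
        """Tidy occupancy export: year/cycle, subgroup, state, occupancy."""
        rows = []
        for t in range(self.occupancy.shape[0]):
            label = self.years[t] if self.years and t < len(self.years) else t
            for gi, g in enumerate(SUBGROUPS):
                for s in STATE_ORDER:
                    rows.append(
                        {
                            "cycle": label,
                            "subgroup": g.label,
                            "state": s.value,
                            "occupancy": self.occupancy[t, gi, STATE_INDEX[s]],
                        }
                    )
        return pd.DataFrame(rows)


def accrue_outcomes(
    occupancy_row: np.ndarray,
    state_inputs: StateInputs,
    cycle: int,
    discount_rate: float = 0.0,
) -> dict[str, np.ndarray]:
    """Outcome accrual for one cycle from a (16, 6) start-of-cycle occupancy.

    Returns per-(subgroup, state) arrays for costs, life-years and QALYs,
    discounted by (1 + r)^(cycle - 1).
    """
    occ = np.asarray(occupancy_row, dtype=float)
    if (occ < -1e-9).any():
        raise EngineError("negative occupancy passed to accrual")
    disc = (1.0 + discount_rate) ** (cycle - 1)
    return {
        "cost_allcause": occ * state_inputs.cost_allcause / disc,
        "cost_psychiatric": occ * state_inputs.cost_psychiatric / disc,
        "life_years": occ * _ALIVE_MASK / disc,
        "qalys": occ * state_inputs.utility / disc,
    }


def run_closed_cohort(
    schedules: Mapping[Subgroup, TransitionSchedule],
    state_inputs: StateInputs,
    entrants: np.ndarray | Mapping[Subgroup, float],
    config: ScenarioConfig | None = None,
) -> CohortTrace:
    """Deterministic closed-cohort run: one entry cohort, full horizon.

    ``entrants`` gives expected patients per subgroup; everyone starts in
    the NTRD state.
    """
    config = config or ScenarioConfig(mode="closed")
    cycles = config.horizon_cycles
    if isinstance(entrants, Mapping):
        entrants = np.array([float(entrants.get(g, 0.0)) for g in SUBGROUPS])
    entrants = np.asarray(entrants, dtype=float)
    if entrants.shape != (N_SUBGROUPS,):
        raise EngineError(f"entrants must have shape ({N_SUBGROUPS},)")
    if (entrants < 0).any():
        raise EngineError("entrants must be non-negative")
    state_inputs.validate()
    P = _schedule_array(schedules, cycles)

    occupancy = np.zeros((cycles + 1, N_SUBGROUPS, N_STATES))
    occupancy[0, :, _NTRD] = entrants
    shape = (cycles, N_SUBGROUPS, N_STATES)
    acc = {
        "cost_allcause": np.zeros(shape),
        "cost_psychiatric": np.zeros(shape),
        "life_years": np.zeros(shape),
        "qalys": np.zeros(shape),
    }
    deaths = np.zeros((cycles, N_SUBGROUPS))
    for t in range(1, cycles + 1):
        start = occupancy[t - 1]
        cyc = accrue_outcomes(start, state_inputs, t, config.discount_rate)
        end = np.einsum("gs,gst->gt", start, P[:, t - 1])
        if config.half_cycle:
            # pro-rate within-cycle exits to absorbing states at half weight
            mid = 0.5 * (start + end)
            cyc = accrue_outcomes(mid, state_inputs, t, config.discount_rate)
        for key in acc:
            acc[key][t - 1] = cyc[key]
        occupancy[t] = end
        deaths[t - 1] = end[:, _DEATH] - start[:, _DEATH]

    return CohortTrace(
        occupancy=occupancy,
        deaths=deaths,
        entrants=entrants.copy(),
        discount_rate=config.discount_rate,
        **acc,
    )


def run_open_cohort(
    schedules: Mapping[Subgroup, TransitionSchedule],
    state_inputs: StateInputs,
    plan: IncidencePlan,
    config: ScenarioConfig | None = None,
) -> CohortTrace:
    """Open-cohort run: one incident cohort per plan year, each followed for
    at most ``horizon_cycles`` cycles; outputs are calendar-year totals.

    Implemented as a calendar loop over an age-structured occupancy (cohort
    age 1..horizon), which is equivalent to superposing shifted closed
    cohorts.
    """
    config = config or ScenarioConfig(mode="open")
    cycles = config.horizon_cycles
    years = plan.years
    if not years:
        raise EngineError("incidence plan is empty")
    P = _schedule_array(schedules, cycles)
    state_inputs.validate()

    # occupancy by cohort age at the start of the current calendar year
    occ_age = np.zeros((cycles, N_SUBGROUPS, N_STATES))
    n_years = len(years)
    occupancy = np.zeros((n_years + 1, N_SUBGROUPS, N_STATES))
    shape = (n_years, N_SUBGROUPS, N_STATES)
    acc = {
        "cost_allcause": np.zeros(shape),
        "cost_psychiatric": np.zeros(shape),
        "life_years": np.zeros(shape),
        "qalys": np.zeros(shape),
    }
    deaths = np.zeros((n_years, N_SUBGROUPS))
    total_entrants = np.zeros(N_SUBGROUPS)

    for yi, year in enumerate(years):
        entry = plan.entrants(year)
        total_entrants += entry
        occ_age[0] = 0.0
        occ_age[0, :, _NTRD] = entry
        occupancy[yi] = occ_age.sum(axis=0)
        disc_cycle = yi + 1  # discount anchored at the first plan year
        rate = config.discount_rate
        for age in range(cycles):
            cyc = accrue_outcomes(occ_age[age], state_inputs, disc_cycle, rate)
            for key in acc:
                acc[key][yi] += cyc[key]
        # transition every cohort one cycle; deaths incident this calendar year
        before_death = occ_age[:, :, _DEATH].sum(axis=0)
        new_age = np.zeros_like(occ_age)
        for age in range(cycles - 1):
            new_age[age + 1] = np.einsum("gs,gst->gt", occ_age[age], P[:, age])
        # the oldest cohort (age == cycles) leaves the model after its last cycle
        oldest_end = np.einsum("gs,gst->gt", occ_age[cycles - 1], P[:, cycles - 1])
        deaths[yi] = (
            new_age[:, :, _DEATH].sum(axis=0) + oldest_end[:, _DEATH] - before_death
        )
        occ_age = new_age
    occupancy[n_years] = occ_age.sum(axis=0)

    return CohortTrace(
        occupancy=occupancy,
        deaths=deaths,
        entrants=total_entrants,
        discount_rate=config.discount_rate,
        years=years,
        **acc,
    )


# -- headline statistics -----------------------------------------------------------


def cagr(series: np.ndarray) -> float:
    """Compound annual growth rate across an annual series."""
    series = np.asarray(series, dtype=float)
    if len(series) < 2:
        raise EngineError("CAGR needs at least two values")
    if series[0] == 0:
        raise EngineError("CAGR undefined: first value is 0")
    return float((series[-1] / series[0]) ** (1.0 / (len(series) - 1)) - 1.0)


def summarise(trace: CohortTrace, entrants_total: float | None = None) -> dict:
    """Cumulative totals, case fatality, CAGRs and per-subgroup burdens."""
    if entrants_total is None:
        entrants_total = float(trace.entrants.sum())
    cum_deaths = float(trace.deaths.sum())
    annual_all = trace.annual("cost_allcause")
    annual_psy = trace.annual("cost_psychiatric")
    out = {
        "entrants": entrants_total,
        "cumulative_cost_allcause": trace.cumulative("cost_allcause"),
        "cumulative_cost_psychiatric": trace.cumulative("cost_psychiatric"),
        "cumulative_deaths": cum_deaths,
        "life_years": trace.cumulative("life_years"),
        "qalys": trace.cumulative("qalys"),
        "life_years_trd": trace.cumulative("life_years", "trd"),
        "qalys_trd": trace.cumulative("qalys", "trd"),
        "life_years_comorbid": trace.cumulative("life_years", "comorbid"),
        "qalys_comorbid": trace.cumulative("qalys", "comorbid"),
        "case_fatality_pct": 100.0 * cum_deaths / entrants_total if entrants_total else np.nan,
        "cagr_cost_allcause": cagr(annual_all),
        "cagr_cost_psychiatric": cagr(annual_psy),
        "cost_share_trd_pct": 100.0
        * trace.cumulative("cost_allcause", "trd")
        / max(trace.cumulative("cost_allcause"), 1e-300),
        "cost_share_comorbid_pct": 100.0
        * trace.cumulative("cost_allcause", "comorbid")
        / max(trace.cumulative("cost_allcause"), 1e-300),
        "psychiatric_share_pct": 100.0
        * trace.cumulative("cost_psychiatric")
        / max(trace.cumulative("cost_allcause"), 1e-300),
    }
    # per-subgroup cumulative and per-patient-year burdens
    rows = []
    ly_g = trace.by_subgroup("life_years")
    for gi, g in enumerate(SUBGROUPS):
        ly = ly_g[gi]
        cum_cost = trace.by_subgroup("cost_allcause")[gi]
        cum_psy = trace.by_subgroup("cost_psychiatric")[gi]
        dg = trace.by_subgroup("deaths")[gi]
        rows.append(
            {
                "subgroup": g.label,
                "entrants": trace.entrants[gi],
                "cost_allcause": cum_cost,
                "cost_psychiatric": cum_psy,
                "deaths": dg,
                "life_years": ly,
                "cost_allcause_per_py": cum_cost / ly if ly > 0 else np.nan,
                "cost_psychiatric_per_py": cum_psy / ly if ly > 0 else np.nan,
                "deaths_per_100py": 100.0 * dg / ly if ly > 0 else np.nan,
            }
        )
    out["subgroups"] = pd.DataFrame(rows)
    return out
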