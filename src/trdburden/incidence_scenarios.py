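"""Projection of annual newly diagnosed patients, 2014-2032.

New-patient counts are obtained by multiplying mean age-specific annual
incidence (held constant, estimated from a 2014-2018 observation window) by
official population projections per five-year age group, then apportioning
to the 16 subgroups using the reference cohort's sex and history mix within
each age band.

Two scenario levers modify a baseline plan:

* open-cohort plans always carry the historical +33% uplift on 2019-2022
  entry years (social unrest and pandemic years);
* the optional pandemic scenario adds extra 2023 cases, either uniformly
  (+25%) or through a youth-weighted age-specific profile calibrated to the
  same aggregate effect.

The packaged population projection, incidence rates and uplift profile are
synthetic fixtures (reverse-engineered from printed aggregate figures), not
observed data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources
from typing import Mapping

import numpy as np
import pandas as pd

from .states import AGE_BANDS, SUBGROUPS

PLAN_YEARS: tuple[int, int] = (2014, 2032)  # 19 incident cohorts

AGE_GROUPS: tuple[str, ...] = (
    "10-14", "15-19", "20-24",
    "25-29", "30-34", "35-39",
    "40-44", "45-49", "50-54", "55-59", "60-64",
    "65-69", "70-74", "75-79", "80-84", "85+",
)

#: Five-year age groups mapped onto model age bands (the 40-44 group is
#: assigned to the 41-65 band; the one-year overlap is a documented
#: approximation of the band boundary).
AGE_GROUP_TO_BAND: dict[str, str] = {
    **{g: "10-24" for g in AGE_GROUPS[:3]},
    **{g: "25-40" for g in AGE_GROUPS[3:6]},
    **{g: "41-65" for g in AGE_GROUPS[6:11]},
    **{g: ">65" for g in AGE_GROUPS[11:]},
}


class IncidenceError(ValueError):
    pass


@dataclass
class PopulationProjection:
    """Projected population per calendar year and five-year age group."""

    table: pd.DataFrame  # year, age_group, population

    def __post_init__(self) -> None:
        if (self.table["population"] < 0).any():
            raise IncidenceError("population values must be non-negative")

    def population(self, year: int) -> pd.Series:
        sel = self.table[self.table["year"] == year]
        if sel.empty:
            raise IncidenceError(f"no population projection for year {year}")
        pop = sel.set_index("age_group")["population"]
        missing = set(AGE_GROUPS) - set(pop.index)
        if missing:
            raise IncidenceError(f"population for {year} missing age groups {sorted(missing)}")
        return pop.reindex(list(AGE_GROUPS))


def load_population_projection() -> PopulationProjection:
    """Packaged synthetic population projection (2014-2032, ages >= 10)."""
    with resources.files("trdburden.data").joinpath(
        "population_projection_synthetic.csv"
    ).open() as fh:
        return PopulationProjection(pd.read_csv(fh))


def load_incidence_rates() -> dict[str, float]:
    """Packaged synthetic age-specific incidence (per person-year)."""
    doc = json.loads(
        resources.files("trdburden.data")
        .joinpath("incidence_rates_synthetic.json")
        .read_text()
    )
    return {g: float(r) for g, r in doc["rates"].items()}


def load_pandemic_uplift() -> dict:
    doc = json.loads(
        resources.files("trdburden.data")
        .joinpath("pandemic_uplift_synthetic.json")
        .read_text()
    )
    return doc


def default_sex_history_mix() -> dict[str, dict[tuple[str, bool], float]]:
    """Reference-cohort sex x history mix within each age band."""
    from .synthetic_cohort import default_subgroup_mix

    mix = default_subgroup_mix()
    out: dict[str, dict[tuple[str, bool], float]] = {}
    for band in AGE_BANDS:
        total = sum(p for g, p in mix.items() if g.age_band == band)
        out[band] = {
            (g.sex, g.history): p / total for g, p in mix.items() if g.age_band == band
        }
    return out


def project_new_patients(
    rates: Mapping[str, float],
    population: PopulationProjection,
    year: int,
    sex_history_mix: Mapping[str, Mapping[tuple[str, bool], float]] | None = None,
    age_uplift: Mapping[str, float] | None = None,
) -> pd.Series:
    """Expected newly diagnosed patients by subgroup for one calendar year.

    Counts per age group are rate x population (optionally scaled by an
    age-specific uplift), summed into age bands and apportioned to sex and
    history strata by the reference mix.  Deterministic.
    """
    missing = set(AGE_GROUPS) - set(rates)
    if missing:
        raise IncidenceError(f"incidence rates missing age groups {sorted(missing)}")
    pop = population.population(year)
    mix = sex_history_mix or default_sex_history_mix()
    band_totals = {band: 0.0 for band in AGE_BANDS}
    for g in AGE_GROUPS:
        uplift = 1.0 if age_uplift is None else float(age_uplift[g])
        band_totals[AGE_GROUP_TO_BAND[g]] += rates[g] * pop[g] * uplift
    values = {}
    for sub in SUBGROUPS:
        values[sub.label] = band_totals[sub.age_band] * mix[sub.age_band][(sub.sex, sub.history)]
    return pd.Series(values, name=year)


@dataclass
class IncidencePlan:
    """Annual entrants by subgroup over contiguous calendar years."""

    table: pd.DataFrame  # index: year; columns: subgroup labels
    scenario: str = "baseline"

    def __post_init__(self) -> None:
        years = self.table.index.to_numpy()
        if len(years) and not np.array_equal(years, np.arange(years[0], years[-1] + 1)):
            raise IncidenceError("plan years must be contiguous")
        if (self.table.to_numpy() < 0).any():
            raise IncidenceError("entrant counts must be non-negative")

    @property
    def years(self) -> list[int]:
        return [int(y) for y in self.table.index]

    def total(self, year: int | None = None) -> float:
        if year is None:
            return float(self.table.to_numpy().sum())
        if year not in self.table.index:
            raise IncidenceError(f"plan has no entry year {year}")
        return float(self.table.loc[year].sum())

    def entrants(self, year: int) -> np.ndarray:
        """(16,) expected entrants by subgroup for one entry year."""
        if year not in self.table.index:
            raise IncidenceError(f"plan has no entry year {year}")
        return self.table.loc[year].reindex([g.label for g in SUBGROUPS]).to_numpy(dtype=float)

    def to_csv(self, path) -> None:
        self.table.rename_axis("year").to_csv(path)


def build_incidence_plan(
    rates: Mapping[str, float] | None = None,
    population: PopulationProjection | None = None,
    years: tuple[int, int] = PLAN_YEARS,
    sex_history_mix=None,
) -> IncidencePlan:
    """Baseline plan: constant incidence applied to the population projection."""
    rates = rates or load_incidence_rates()
    population = population or load_population_projection()
    rows = [
        project_new_patients(rates, population, year, sex_history_mix)
        for year in range(years[0], years[1] + 1)
    ]
    table = pd.DataFrame(rows)
    table.index = pd.Index(range(years[0], years[1] + 1), name="year")
    return IncidencePlan(table=table, scenario="baseline")


_SCENARIOS = ("baseline", "pandemic")
_PROFILES = ("age_specific", "uniform")


def apply_pandemic_uplift(
    plan: IncidencePlan,
    scenario: str,
    mode: str = "closed",
    profile: str = "age_specific",
    rates: Mapping[str, float] | None = None,
    population: PopulationProjection | None = None,
    sex_history_mix=None,
) -> IncidencePlan:
    """Scenario adjustment of a baseline plan.

    Open-cohort plans (both scenarios) multiply 2019-2022 entrants by 1.33.
    The pandemic scenario additionally replaces 2023 entrants: uniformly
    (+25%) or via the age-specific calibrated profile.  ``baseline`` with
    ``mode='closed'`` returns the plan unchanged.
    """
    if scenario not in _SCENARIOS:
        raise IncidenceError(f"unknown scenario {scenario!r}; expected {_SCENARIOS}")
    if mode not in ("closed", "open"):
        raise IncidenceError(f"unknown mode {mode!r}")
    if profile not in _PROFILES:
        raise IncidenceError(f"unknown uplift profile {profile!r}")
    uplift_doc = load_pandemic_uplift()
    table = plan.table.copy()

    if mode == "open":
        factor = float(uplift_doc["uplift_2019_2022"])
        for year in range(2019, 2023):
            if year in table.index:
                table.loc[year] *= factor

    if scenario == "pandemic":
        if 2023 not in table.index:
            raise IncidenceError("plan has no 2023 entry year to uplift")
        if profile == "uniform":
            table.loc[2023] *= float(uplift_doc["uniform_2023"])
        else:
            rates = rates or load_incidence_rates()
            population = population or load_population_projection()
            table.loc[2023] = project_new_patients(
                rates,
                population,
                2023,
                sex_history_mix,
                age_uplift=uplift_doc["profile_2023"],
            )
    label = f"{mode}_{scenario}"
    return IncidencePlan(table=table, scenario=label)
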