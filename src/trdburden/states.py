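"""Health states, patient subgroups and covariate coding.

The model follows newly diagnosed depression through six mutually exclusive
health states:

* ``NTRD`` — non-treatment-resistant depression, the initial state for every
  patient.
* ``TRD`` — treatment-resistant depression (failure of two adequate
  antidepressant regimens, confirmed by a third).
* ``NTRD-comorbid`` / ``TRD-comorbid`` — new-onset somatic or psychiatric
  comorbidity occurring before vs after TRD onset.  Splitting the comorbidity
  state around TRD relaxes the memoryless assumption of the cohort model.
* ``low-intensity`` — absorbing alive state proxying recovery (no further
  depression-related records).
* ``death`` — absorbing all-cause death.

Patients are stratified into 16 subgroups by four age bands at diagnosis,
sex, and presence of baseline medical history.  Covariates enter regression
models through a fixed dummy coding with reference level
(female, 41-65, no history).
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np


class State(str, Enum):
    NTRD = "NTRD"
    TRD = "TRD"
    NTRD_COMORBID = "NTRD-comorbid"
    TRD_COMORBID = "TRD-comorbid"
    LOW_INTENSITY = "low-intensity"
    DEATH = "death"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


STATE_ORDER: tuple[State, ...] = (
    State.NTRD,
    State.TRD,
    State.NTRD_COMORBID,
    State.TRD_COMORBID,
    State.LOW_INTENSITY,
    State.DEATH,
)
STATE_INDEX: dict[State, int] = {s: i for i, s in enumerate(STATE_ORDER)}
N_STATES = len(STATE_ORDER)

ACTIVE_STATES: tuple[State, ...] = (
    State.NTRD,
    State.TRD,
    State.NTRD_COMORBID,
    State.TRD_COMORBID,
)
ABSORBING_STATES: tuple[State, ...] = (State.LOW_INTENSITY, State.DEATH)
ALIVE_STATES: tuple[State, ...] = ACTIVE_STATES + (State.LOW_INTENSITY,)

#: States counted in the "TRD states" attribution split.
TRD_FAMILY: tuple[State, ...] = (State.TRD, State.TRD_COMORBID)
#: States counted in the "new-onset comorbidities" attribution split.
COMORBID_FAMILY: tuple[State, ...] = (State.NTRD_COMORBID, State.TRD_COMORBID)

AGE_BANDS: tuple[str, ...] = ("10-24", "25-40", "41-65", ">65")
SEXES: tuple[str, ...] = ("female", "male")


@dataclass(frozen=True, order=True)
class Subgroup:
    """One of the 16 age-band x sex x baseline-history strata."""

    age_band: str
    sex: str
    history: bool

    def __post_init__(self) -> None:
        if self.age_band not in AGE_BANDS:
            raise ValueError(f"unknown age band {self.age_band!r}")
        if self.sex not in SEXES:
            raise ValueError(f"unknown sex {self.sex!r}")

    @property
    def label(self) -> str:
        hist = "history" if self.history else "no-history"
        return f"{self.sex}|{self.age_band}|{hist}"

    @classmethod
    def from_label(cls, label: str) -> "Subgroup":
        sex, band, hist = label.split("|")
        return cls(band, sex, hist == "history")


SUBGROUPS: tuple[Subgroup, ...] = tuple(
    Subgroup(band, sex, hist)
    for band in AGE_BANDS
    for sex in SEXES
    for hist in (False, True)
)
N_SUBGROUPS = len(SUBGROUPS)
SUBGROUP_INDEX: dict[Subgroup, int] = {g: i for i, g in enumerate(SUBGROUPS)}

#: Dummy coding used by every regression model in the package.
COVARIATE_NAMES: tuple[str, ...] = (
    "age_10_24",
    "age_25_40",
    "age_gt_65",
    "male",
    "history",
)
N_COVARIATES = len(COVARIATE_NAMES)


def covariate_vector(subgroup: Subgroup) -> np.ndarray:
    """Dummy covariate vector for a subgroup (reference female/41-65/no history)."""
    return np.array(
        [
            float(subgroup.age_band == "10-24"),
            float(subgroup.age_band == "25-40"),
            float(subgroup.age_band == ">65"),
            float(subgroup.sex == "male"),
            float(subgroup.history),
        ]
    )


#: (16, 5) matrix of covariate vectors in subgroup order.
COVARIATE_MATRIX: np.ndarray = np.stack([covariate_vector(g) for g in SUBGROUPS])

Transition = tuple[State, State]

#: Permitted transitions of the model graph (besides the implicit stay
#: probability).  Low-intensity and death are absorbing.
TRANSITIONS: tuple[Transition, ...] = (
    (State.NTRD, State.TRD),
    (State.NTRD, State.NTRD_COMORBID),
    (State.NTRD, State.LOW_INTENSITY),
    (State.NTRD, State.DEATH),
    (State.TRD, State.TRD_COMORBID),
    (State.TRD, State.LOW_INTENSITY),
    (State.TRD, State.DEATH),
    (State.NTRD_COMORBID, State.LOW_INTENSITY),
    (State.NTRD_COMORBID, State.DEATH),
    (State.TRD_COMORBID, State.LOW_INTENSITY),
    (State.TRD_COMORBID, State.DEATH),
)

#: Configurable extra edge, off by default: comorbid NTRD patients who later
#: become treatment resistant.
OPTIONAL_TRANSITION: Transition = (State.NTRD_COMORBID, State.TRD_COMORBID)


def permitted_transitions(include_comorbid_to_trd: bool = False) -> tuple[Transition, ...]:
    if include_comorbid_to_trd:
        return TRANSITIONS + (OPTIONAL_TRANSITION,)
    return TRANSITIONS


def transitions_from(state: State, include_comorbid_to_trd: bool = False) -> tuple[Transition, ...]:
    return tuple(
        t for t in permitted_transitions(include_comorbid_to_trd) if t[0] == state
    )
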