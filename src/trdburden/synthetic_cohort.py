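"""Synthetic patient-level cohort generator.

Real territory-wide EMR extracts behind burden models of this kind cannot be
shared, so the estimation stages of this package run on synthetic records
that reproduce the statistical structure those stages assume:

* 16 subgroups (age band x sex x baseline medical history) drawn from a
  configurable mix;
* multi-state disease paths simulated by competing cause-specific
  event-time draws (independent latent times, earliest realised), with
  accelerated-failure-time covariate effects;
* a declining crude annual probability of developing treatment resistance,
  matching the pattern reported for real incident cohorts (roughly
  6.2%, 4.4% and 3.0% over the first three years under the default
  calibration);
* negative-binomially distributed annual service-use counts (outpatient
  visits, emergency attendances, inpatient bed-days; psychiatric counts a
  subset of all-cause counts);
* administrative censoring at the end of a calendar cut-off year, giving
  4-7 years of follow-up for diagnosis years 2014-2016.

Everyone starts in the NTRD state at diagnosis (time 0).  Entry times into
later states are generated directly; no prescription-sequence logic is
simulated.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from ._families import FAMILY_ORDER, get_family
from .states import (
    ACTIVE_STATES,
    AGE_BANDS,
    COVARIATE_MATRIX,
    N_COVARIATES,
    N_SUBGROUPS,
    SUBGROUP_INDEX,
    SUBGROUPS,
    State,
    Subgroup,
    Transition,
    permitted_transitions,
)

SETTINGS: tuple[str, ...] = ("outpatient", "emergency", "inpatient")

_COUNT_COLUMNS = tuple(
    f"{setting}_{scope}" for setting in SETTINGS for scope in ("allcause", "psychiatric")
)


class ConfigurationError(ValueError):
    """Raised when a generator configuration violates its invariants."""


@dataclass(frozen=True)
class HazardSpec:
    """Cause-specific baseline hazard plus AFT covariate effects.

    ``params`` are on the natural scale of the family (e.g. ``scale``/
    ``shape`` for Weibull, ``a``/``b`` for Gompertz).  ``beta`` are log
    time-ratios for (age 10-24, age 25-40, age >65, male, history); a
    positive coefficient prolongs event-free time.
    """

    family: str
    params: Mapping[str, float]
    beta: tuple[float, ...] = (0.0,) * N_COVARIATES

    def transformed_params(self) -> np.ndarray:
        fam = get_family(self.family)
        p = dict(self.params)
        out = []
        for name in fam.param_names:
            if name.startswith("log_"):
                value = p[name[4:]]
                if value <= 0:
                    raise ConfigurationError(
                        f"hazard parameter {name[4:]!r} must be > 0, got {value}"
                    )
                out.append(np.log(value))
            else:
                out.append(p[name])
        return np.asarray(out, dtype=float)

    def validate(self) -> None:
        if self.family not in FAMILY_ORDER:
            raise ConfigurationError(f"unknown hazard family {self.family!r}")
        if len(self.beta) != N_COVARIATES:
            raise ConfigurationError(
                f"beta must have {N_COVARIATES} entries, got {len(self.beta)}"
            )
        self.transformed_params()  # positivity checks


@dataclass(frozen=True)
class ServiceUseSpec:
    """Negative-binomial annual service use for one state x setting.

    All-cause counts are generated as psychiatric + non-psychiatric draws so
    the psychiatric scope is a subset by construction.  ``dispersion`` is the
    NB2 theta: variance = mu + mu^2 / theta.
    """

    mean_psychiatric: float
    mean_other: float
    dispersion: float

    def validate(self) -> None:
        if self.mean_psychiatric < 0 or self.mean_other < 0:
            raise ConfigurationError("service-use means must be non-negative")
        if self.dispersion <= 0:
            raise ConfigurationError(
                f"dispersion must be > 0, got {self.dispersion}"
            )


@dataclass
class GeneratorConfig:
    n_patients: int
    subgroup_mix: dict[Subgroup, float]
    hazards: dict[Transition, HazardSpec]
    service_use: dict[tuple[State, str], ServiceUseSpec]
    #: log-scale covariate effects on service-use means (shared across settings)
    count_covariate_effects: tuple[float, ...] = (0.0,) * N_COVARIATES
    diagnosis_years: tuple[int, int] = (2014, 2016)
    censor_year: int = 2020
    include_comorbid_to_trd: bool = False
    seed: int = 0

    def validate(self) -> None:
        if self.n_patients <= 0:
            raise ConfigurationError(f"n_patients must be positive, got {self.n_patients}")
        mix = np.array([self.subgroup_mix.get(g, 0.0) for g in SUBGROUPS])
        if (mix < 0).any():
            raise ConfigurationError("subgroup_mix entries must be non-negative")
        if abs(mix.sum() - 1.0) > 1e-9:
            raise ConfigurationError(
                f"subgroup_mix must sum to 1 within 1e-9, got {mix.sum():.12f}"
            )
        required = permitted_transitions(self.include_comorbid_to_trd)
        for tr in self.hazards:
            if tr not in required:
                raise ConfigurationError(f"hazard given for non-permitted transition {tr}")
        for tr in required:
            if tr not in self.hazards:
                raise ConfigurationError(f"missing hazard for transition {tr}")
            self.hazards[tr].validate()
        for state in ACTIVE_STATES:
            for setting in SETTINGS:
                key = (state, setting)
                if key not in self.service_use:
                    raise ConfigurationError(f"missing service_use spec for {key}")
                self.service_use[key].validate()
        if len(self.count_covariate_effects) != N_COVARIATES:
            raise ConfigurationError("count_covariate_effects must have 5 entries")
        y0, y1 = self.diagnosis_years
        if y1 < y0 or self.censor_year < y1:
            raise ConfigurationError("censor_year must be >= last diagnosis year")

    def mix_array(self) -> np.ndarray:
        return np.array([self.subgroup_mix.get(g, 0.0) for g in SUBGROUPS])

    # -- JSON sidecar -------------------------------------------------------------
    def to_json(self) -> str:
        doc = {
            "n_patients": self.n_patients,
            "subgroup_mix": {g.label: p for g, p in self.subgroup_mix.items()},
            "hazards": {
                f"{a.value}->{b.value}": {
                    "family": h.family,
                    "params": dict(h.params),
                    "beta": list(h.beta),
                }
                for (a, b), h in self.hazards.items()
            },
            "service_use": {
                f"{state.value}|{setting}": dataclasses.asdict(spec)
                for (state, setting), spec in self.service_use.items()
            },
            "count_covariate_effects": list(self.count_covariate_effects),
            "diagnosis_years": list(self.diagnosis_years),
            "censor_year": self.censor_year,
            "include_comorbid_to_trd": self.include_comorbid_to_trd,
            "seed": self.seed,
        }
        return json.dumps(doc, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "GeneratorConfig":
        doc = json.loads(text)
        hazards = {}
        for key, h in doc["hazards"].items():
            a, b = key.split("->")
            hazards[(State(a), State(b))] = HazardSpec(
                h["family"], h["params"], tuple(h["beta"])
            )
        service = {}
        for key, s in doc["service_use"].items():
            state, setting = key.split("|")
            service[(State(state), setting)] = ServiceUseSpec(**s)
        return cls(
            n_patients=doc["n_patients"],
            subgroup_mix={
                Subgroup.from_label(lbl): p for lbl, p in doc["subgroup_mix"].items()
            },
            hazards=hazards,
            service_use=service,
            count_covariate_effects=tuple(doc["count_covariate_effects"]),
            diagnosis_years=tuple(doc["diagnosis_years"]),
            censor_year=doc["censor_year"],
            include_comorbid_to_trd=doc["include_comorbid_to_trd"],
            seed=doc["seed"],
        )


@dataclass
class Cohort:
    """Patient-level records in tidy long format.

    ``patients``: one row per patient (covariates, diagnosis time, censoring).
    ``events``: one row per state entry, including NTRD at time 0.
    ``counts``: one row per active patient-year with service-use counts by
    setting and scope plus the fraction of the year at risk (``exposure``).
    """

    patients: pd.DataFrame
    events: pd.DataFrame
    counts: pd.DataFrame
    config: GeneratorConfig | None = None

    @property
    def n_patients(self) -> int:
        return len(self.patients)

    def subgroup_counts(self) -> pd.Series:
        return self.patients["subgroup"].value_counts().reindex(
            [g.label for g in SUBGROUPS], fill_value=0
        )


def _draw_latent_times(
    rng: np.random.Generator,
    spec: HazardSpec,
    X: np.ndarray,
) -> np.ndarray:
    """Latent event times under an AFT hazard for each row of X."""
    fam = get_family(spec.family)
    params = spec.transformed_params()
    u = rng.uniform(size=len(X))
    t0 = fam.isf(u, params)
    eta = X @ np.asarray(spec.beta, dtype=float)
    return t0 * np.exp(eta)


def _competing_stage(
    rng: np.random.Generator,
    config: GeneratorConfig,
    from_state: State,
    X: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, list[State]]:
    """Sojourn time and cause index of the first exit from ``from_state``.

    Returns (time, cause_index, causes); cause_index -1 where no latent time
    is finite (the subject would stay forever absent censoring).
    """
    causes = [b for (a, b) in permitted_transitions(config.include_comorbid_to_trd) if a == from_state]
    times = np.stack(
        [_draw_latent_times(rng, config.hazards[(from_state, c)], X) for c in causes],
        axis=1,
    )
    order = np.argsort(times, axis=1)
    first = order[:, 0]
    tmin = times[np.arange(len(X)), first]
    first = np.where(np.isfinite(tmin), first, -1)
    return tmin, first, causes


def generate_cohort(config: GeneratorConfig) -> Cohort:
    """Generate ``config.n_patients`` synthetic patient records.

    Deterministic given ``config.seed``; sub-streams for subgroup assignment,
    event times and service counts are derived from one seed sequence so
    regenerating one stage leaves the others unchanged.
    """
    config.validate()
    root = np.random.SeedSequence(config.seed)
    rng_subgroup, rng_diag, rng_events, rng_counts = (
        np.random.default_rng(s) for s in root.spawn(4)
    )
    n = config.n_patients

    subgroup_idx = rng_subgroup.choice(N_SUBGROUPS, size=n, p=config.mix_array())
    X = COVARIATE_MATRIX[subgroup_idx]

    y0, y1 = config.diagnosis_years
    diag_time = rng_diag.uniform(float(y0), float(y1) + 1.0, size=n)
    censor_time = (config.censor_year + 1.0) - diag_time  # years since diagnosis

    patients = pd.DataFrame(
        {
            "patient_id": np.arange(n),
            "subgroup": [SUBGROUPS[i].label for i in subgroup_idx],
            "age_band": [SUBGROUPS[i].age_band for i in subgroup_idx],
            "sex": [SUBGROUPS[i].sex for i in subgroup_idx],
            "history": [bool(SUBGROUPS[i].history) for i in subgroup_idx],
            "diagnosis_year": np.floor(diag_time).astype(int),
            "diagnosis_time": diag_time,
            "censor_time": censor_time,
        }
    )

    # -- multi-state event cascade -------------------------------------------------
    event_pid: list[np.ndarray] = [np.arange(n)]
    event_state: list[np.ndarray] = [np.full(n, State.NTRD.value, dtype=object)]
    event_time: list[np.ndarray] = [np.zeros(n)]

    def run_stage(pid: np.ndarray, entry: np.ndarray, from_state: State) -> None:
        """Simulate the first exit from ``from_state`` for the given patients."""
        if len(pid) == 0:
            return
        soj, cause_idx, causes = _competing_stage(rng_events, config, from_state, X[pid])
        exit_time = entry + soj
        realised = (cause_idx >= 0) & (exit_time < censor_time[pid])
        for ci, cause in enumerate(causes):
            sel = realised & (cause_idx == ci)
            if not sel.any():
                continue
            event_pid.append(pid[sel])
            event_state.append(np.full(sel.sum(), cause.value, dtype=object))
            event_time.append(exit_time[sel])
            if cause in ACTIVE_STATES:
                run_stage(pid[sel], exit_time[sel], cause)

    run_stage(np.arange(n), np.zeros(n), State.NTRD)

    events = pd.DataFrame(
        {
            "patient_id": np.concatenate(event_pid),
            "state": np.concatenate(event_state),
            "entry_time": np.concatenate(event_time),
        }
    ).sort_values(["patient_id", "entry_time"], kind="mergesort", ignore_index=True)

    counts = _generate_counts(rng_counts, config, patients, events, X)
    return Cohort(patients=patients, events=events, counts=counts, config=config)


def _state_timeline(events: pd.DataFrame, n: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per patient: entry times into TRD / comorbid / absorbing (inf if never)."""
    trd_entry = np.full(n, np.inf)
    comorbid_entry = np.full(n, np.inf)
    absorb_entry = np.full(n, np.inf)
    state_entry: dict[str, np.ndarray] = {}
    for state in State:
        sel = events[events["state"] == state.value]
        arr = np.full(n, np.inf)
        arr[sel["patient_id"].to_numpy()] = sel["entry_time"].to_numpy()
        state_entry[state.value] = arr
    trd_entry = np.minimum(state_entry[State.TRD.value], state_entry[State.TRD_COMORBID.value])
    comorbid_entry = np.minimum(
        state_entry[State.NTRD_COMORBID.value], state_entry[State.TRD_COMORBID.value]
    )
    absorb_entry = np.minimum(
        state_entry[State.LOW_INTENSITY.value], state_entry[State.DEATH.value]
    )
    return trd_entry, comorbid_entry, absorb_entry


def _entry_time_matrix(events: pd.DataFrame, n: int) -> np.ndarray:
    """(n, 6) matrix of state entry times in STATE_ORDER, inf where never entered."""
    from .states import STATE_INDEX, STATE_ORDER

    mat = np.full((n, len(STATE_ORDER)), np.inf)
    pid = events["patient_id"].to_numpy()
    st = events["state"].map({s.value: i for s, i in STATE_INDEX.items()}).to_numpy()
    mat[pid, st] = events["entry_time"].to_numpy()
    return mat


def _states_at(entry_mat: np.ndarray, time: float) -> np.ndarray:
    """State value occupied by each patient at ``time`` (last state entered)."""
    from .states import STATE_ORDER

    masked = np.where(entry_mat <= time, entry_mat, -np.inf)
    idx = np.argmax(masked, axis=1)  # each state entered at most once
    values = np.array([s.value for s in STATE_ORDER], dtype=object)
    return values[idx]


def _generate_counts(
    rng: np.random.Generator,
    config: GeneratorConfig,
    patients: pd.DataFrame,
    events: pd.DataFrame,
    X: np.ndarray,
) -> pd.DataFrame:
    n = len(patients)
    censor = patients["censor_time"].to_numpy()
    _, _, absorb_entry = _state_timeline(events, n)
    end_active = np.minimum(censor, absorb_entry)

    entry_mat = _entry_time_matrix(events, n)
    max_years = int(np.ceil(np.max(end_active))) if n else 0
    rows_pid: list[np.ndarray] = []
    rows_year: list[np.ndarray] = []
    rows_exposure: list[np.ndarray] = []
    rows_state: list[np.ndarray] = []
    for year in range(1, max_years + 1):
        start = float(year - 1)
        at_risk = end_active > start
        if not at_risk.any():
            break
        pid = np.flatnonzero(at_risk)
        exposure = np.minimum(end_active[pid] - start, 1.0)
        state = _states_at(entry_mat[pid], start)
        rows_pid.append(pid)
        rows_year.append(np.full(len(pid), year))
        rows_exposure.append(exposure)
        rows_state.append(state)

    if not rows_pid:
        return _empty_counts()

    pid = np.concatenate(rows_pid)
    year = np.concatenate(rows_year)
    exposure = np.concatenate(rows_exposure)
    state = np.concatenate(rows_state)

    cov_mult = np.exp(X[pid] @ np.asarray(config.count_covariate_effects))
    data = {
        "patient_id": pid,
        "year": year,
        "state": state,
        "exposure": exposure,
    }
    for setting in SETTINGS:
        psy = np.zeros(len(pid), dtype=np.int64)
        other = np.zeros(len(pid), dtype=np.int64)
        for st in ACTIVE_STATES:
            sel = state == st.value
            if not sel.any():
                continue
            spec = config.service_use[(st, setting)]
            for target, mean in ((psy, spec.mean_psychiatric), (other, spec.mean_other)):
                mu = mean * cov_mult[sel] * exposure[sel]
                # gamma-Poisson mixture: NB2 with variance mu + mu^2/theta
                lam = rng.gamma(shape=spec.dispersion, scale=mu / spec.dispersion)
                target[sel] = rng.poisson(lam)
        data[f"{setting}_psychiatric"] = psy
        data[f"{setting}_allcause"] = psy + other
    counts = pd.DataFrame(data)
    order = ["patient_id", "year", "state", "exposure"] + [
        f"{s}_{scope}" for s in SETTINGS for scope in ("allcause", "psychiatric")
    ]
    return counts[order].sort_values(["patient_id", "year"], ignore_index=True)


def _empty_counts() -> pd.DataFrame:
    cols = ["patient_id", "year", "state", "exposure"] + [
        f"{s}_{scope}" for s in SETTINGS for scope in ("allcause", "psychiatric")
    ]
    return pd.DataFrame({c: pd.Series(dtype=float) for c in cols})


# -- crude transition probabilities (validation view) ------------------------------


def crude_transition_probabilities(
    cohort: Cohort, transition: Transition = (State.NTRD, State.TRD), years: int = 3
) -> np.ndarray:
    """Observed annual probability of ``transition`` over the first ``years``.

    For year t, the risk set is patients still in the source state at t-1
    with administrative follow-up through year t; the numerator is first
    exits into the target state during (t-1, t].
    """
    from_state, to_state = transition
    n = cohort.n_patients
    events = cohort.events
    censor = cohort.patients["censor_time"].to_numpy()

    not_from = events[events["state"] != from_state.value]
    exit_time = np.full(n, np.inf)
    exit_state = np.empty(n, dtype=object)
    first = not_from.groupby("patient_id").first()
    exit_time[first.index.to_numpy()] = first["entry_time"].to_numpy()
    exit_state[first.index.to_numpy()] = first["state"].to_numpy()
    if from_state is not State.NTRD:
        raise NotImplementedError("crude probabilities are reported for NTRD exits")

    probs = np.empty(years)
    for year in range(1, years + 1):
        at_risk = (exit_time > year - 1) & (censor >= year)
        hits = at_risk & (exit_time <= year) & (exit_state == to_state.value)
        probs[year - 1] = hits.sum() / max(at_risk.sum(), 1)
    return probs


def cumulative_state_counts(cohort: Cohort, state: State, by_time: float) -> int:
    """Number of patients who have entered ``state`` by ``by_time`` years."""
    ev = cohort.events
    sel = (ev["state"] == state.value) & (ev["entry_time"] <= by_time)
    return int(sel.sum())


# -- on-disk format ----------------------------------------------------------------


def write_cohort(cohort: Cohort, path: str | Path) -> Path:
    """Write a cohort as tab-delimited long-format text plus a JSON sidecar."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    cohort.patients.to_csv(path / "patients.tsv", sep="\t", index=False)
    cohort.events.to_csv(path / "events.tsv", sep="\t", index=False)
    cohort.counts.to_csv(path / "counts.tsv", sep="\t", index=False)
    if cohort.config is not None:
        (path / "config.json").write_text(cohort.config.to_json())
    return path


class CohortParseError(ValueError):
    pass


def _read_tsv(path: Path, dtypes: dict[str, object]) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep="\t", dtype=dtypes, float_precision="round_trip")
    except (ValueError, pd.errors.ParserError) as exc:
        raise CohortParseError(f"{path.name}: {exc}") from exc
    missing = set(dtypes) - set(df.columns)
    if missing:
        raise CohortParseError(f"{path.name}: missing columns {sorted(missing)} (line 1)")
    return df


def read_cohort(path: str | Path) -> Cohort:
    path = Path(path)
    patients = _read_tsv(
        path / "patients.tsv",
        {
            "patient_id": np.int64,
            "subgroup": str,
            "age_band": str,
            "sex": str,
            "history": bool,
            "diagnosis_year": np.int64,
            "diagnosis_time": float,
            "censor_time": float,
        },
    )
    events = _read_tsv(
        path / "events.tsv", {"patient_id": np.int64, "state": str, "entry_time": float}
    )
    counts_dtypes: dict[str, object] = {
        "patient_id": np.int64,
        "year": np.int64,
        "state": str,
        "exposure": float,
    }
    for setting in SETTINGS:
        counts_dtypes[f"{setting}_allcause"] = np.int64
        counts_dtypes[f"{setting}_psychiatric"] = np.int64
    counts_path = path / "counts.tsv"
    counts = _read_tsv(counts_path, counts_dtypes)
    if counts.empty:
        counts = counts.astype({k: v for k, v in counts_dtypes.items()})
    config = None
    cfg_path = path / "config.json"
    if cfg_path.exists():
        config = GeneratorConfig.from_json(cfg_path.read_text())
    return Cohort(patients=patients, events=events, counts=counts, config=config)


def validate_cohort(cohort: Cohort) -> None:
    """Check the record-level invariants; raise AssertionError on violation."""
    ev = cohort.events
    for pid, grp in ev.groupby("patient_id"):
        times = grp["entry_time"].to_numpy()
        states = grp["state"].to_numpy()
        assert states[0] == State.NTRD.value and times[0] == 0.0
        assert (np.diff(times) > 0).all(), f"non-increasing entry times for {pid}"
        absorbing = np.isin(states, [State.LOW_INTENSITY.value, State.DEATH.value])
        if absorbing.any():
            assert absorbing.sum() == 1 and absorbing[-1], (
                f"absorbing state does not terminate events for {pid}"
            )
    censor = cohort.patients.set_index("patient_id")["censor_time"]
    assert (ev["entry_time"].to_numpy() <= censor.loc[ev["patient_id"]].to_numpy()).all()
    count_cols = [c for c in cohort.counts.columns if c.endswith(("allcause", "psychiatric"))]
    assert (cohort.counts[count_cols].to_numpy() >= 0).all()


# -- default (calibrated) configuration --------------------------------------------

#: AFT log time-ratios on death transitions: age and history shorten, being
#: in the youngest band prolongs, survival time.
_DEATH_BETA = (0.9, 0.4, -1.6, -0.25, -0.45)

#: Default marginal composition approximating a 2014-2016 reference incident
#: cohort: mostly women, mostly diagnosed at ages 41-65, mostly without
#: baseline medical history.
_AGE_SHARES = {"10-24": 0.106, "25-40": 0.200, "41-65": 0.556, ">65": 0.138}
_FEMALE_SHARE = 0.75
_HISTORY_SHARE = 0.28


def default_subgroup_mix() -> dict[Subgroup, float]:
    mix = {}
    for g in SUBGROUPS:
        p = _AGE_SHARES[g.age_band]
        p *= _FEMALE_SHARE if g.sex == "female" else 1.0 - _FEMALE_SHARE
        p *= _HISTORY_SHARE if g.history else 1.0 - _HISTORY_SHARE
        mix[g] = p
    return mix


def alternative_2018_mix() -> dict[Subgroup, float]:
    """Demographic-shift check: the 10-24 share raised to 17.0%, other age
    bands rescaled proportionally; sex/history margins unchanged."""
    shares = dict(_AGE_SHARES)
    rest = 1.0 - 0.17
    base_rest = 1.0 - shares["10-24"]
    shares = {
        band: (0.17 if band == "10-24" else share * rest / base_rest)
        for band, share in shares.items()
    }
    mix = {}
    for g in SUBGROUPS:
        p = shares[g.age_band]
        p *= _FEMALE_SHARE if g.sex == "female" else 1.0 - _FEMALE_SHARE
        p *= _HISTORY_SHARE if g.history else 1.0 - _HISTORY_SHARE
        mix[g] = p
    return mix


def default_hazards() -> dict[Transition, HazardSpec]:
    """Calibrated cause-specific hazards.

    The NTRD->TRD hazard is Gompertz with negative shape so the crude annual
    TRD probability declines geometrically (about 6.2%, 4.4%, 3.0% over
    years 1-3 at the default mix); other transitions are exponential.  Death
    hazards carry strong age effects in AFT form.
    """
    exp = lambda rate, beta=(0.0,) * N_COVARIATES: HazardSpec(  # noqa: E731
        "exponential", {"scale": 1.0 / rate}, beta
    )
    return {
        (State.NTRD, State.TRD): HazardSpec(
            "gompertz", {"a": 0.082029, "b": -0.367279}
        ),
        (State.NTRD, State.NTRD_COMORBID): exp(0.045),
        (State.NTRD, State.LOW_INTENSITY): exp(0.085),
        (State.NTRD, State.DEATH): exp(0.0068, _DEATH_BETA),
        (State.TRD, State.TRD_COMORBID): exp(0.055),
        (State.TRD, State.LOW_INTENSITY): exp(0.055),
        (State.TRD, State.DEATH): exp(0.011, _DEATH_BETA),
        (State.NTRD_COMORBID, State.LOW_INTENSITY): exp(0.060),
        (State.NTRD_COMORBID, State.DEATH): exp(0.022, _DEATH_BETA),
        (State.TRD_COMORBID, State.LOW_INTENSITY): exp(0.045),
        (State.TRD_COMORBID, State.DEATH): exp(0.028, _DEATH_BETA),
    }


def default_service_use() -> dict[tuple[State, str], ServiceUseSpec]:
    """Annual service-use means per state and setting (reference subgroup).

    Chosen so that per-state annual costs sit in the low thousands of US$
    for NTRD and around US$10^4 for comorbid states in high-use subgroups,
    with psychiatric care roughly a fifth of all-cause cost overall.
    """
    return {
        (State.NTRD, "outpatient"): ServiceUseSpec(2.2, 6.8, 1.2),
        (State.NTRD, "emergency"): ServiceUseSpec(0.08, 0.50, 1.2),
        (State.NTRD, "inpatient"): ServiceUseSpec(0.35, 2.65, 1.2),
        (State.TRD, "outpatient"): ServiceUseSpec(7.0, 8.0, 1.2),
        (State.TRD, "emergency"): ServiceUseSpec(0.25, 0.70, 1.2),
        (State.TRD, "inpatient"): ServiceUseSpec(2.0, 4.0, 1.2),
        (State.NTRD_COMORBID, "outpatient"): ServiceUseSpec(3.5, 14.0, 1.2),
        (State.NTRD_COMORBID, "emergency"): ServiceUseSpec(0.12, 1.30, 1.2),
        (State.NTRD_COMORBID, "inpatient"): ServiceUseSpec(0.8, 8.0, 1.2),
        (State.TRD_COMORBID, "outpatient"): ServiceUseSpec(8.0, 14.0, 1.2),
        (State.TRD_COMORBID, "emergency"): ServiceUseSpec(0.30, 1.60, 1.2),
        (State.TRD_COMORBID, "inpatient"): ServiceUseSpec(2.5, 9.0, 1.2),
    }


#: log-scale service-use multipliers: older and history-positive patients use
#: substantially more care; men slightly more than women.
_DEFAULT_COUNT_EFFECTS = (-0.10, -0.05, 0.60, 0.05, 0.25)


def default_generator_config(n_patients: int = 25_190, seed: int = 0) -> GeneratorConfig:
    """The study-condition configuration used throughout the package."""
    return GeneratorConfig(
        n_patients=n_patients,
        subgroup_mix=default_subgroup_mix(),
        hazards=default_hazards(),
        service_use=default_service_use(),
        count_covariate_effects=_DEFAULT_COUNT_EFFECTS,
        diagnosis_years=(2014, 2016),
        censor_year=2020,
        seed=seed,
    )
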