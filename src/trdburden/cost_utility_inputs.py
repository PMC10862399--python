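"""Per-state annual costs from service-use counts, and state utility weights.

Annual costs of care are derived in two steps: negative-binomial regression
of patient-year service counts (one model per setting and cause scope,
adjusted for age band, sex, baseline medical history and time-varying TRD /
comorbidity status with a log person-time offset), then multiplication of
the predicted mean annual counts by service-specific unit costs.  Costs are
expressed in 2023 US dollars.

Utility weights live on [0, 1].  Comorbid states take a fixed proportional
decrement (default 17%) off their non-comorbid counterparts; the death
state has utility zero and the low-intensity (recovery proxy) state takes
its value from configuration.  Low-intensity and death states accrue zero
cost: care in those states is by definition not depression related.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .states import (
    ACTIVE_STATES,
    COVARIATE_MATRIX,
    COVARIATE_NAMES,
    N_STATES,
    N_SUBGROUPS,
    STATE_INDEX,
    STATE_ORDER,
    SUBGROUP_INDEX,
    SUBGROUPS,
    State,
    Subgroup,
)
from .synthetic_cohort import SETTINGS, Cohort

SCOPES: tuple[str, ...] = ("allcause", "psychiatric")

#: (TRD flag, comorbid flag) indicator profile of each cost-accruing state.
STATE_FLAGS: dict[State, tuple[float, float]] = {
    State.NTRD: (0.0, 0.0),
    State.TRD: (1.0, 0.0),
    State.NTRD_COMORBID: (0.0, 1.0),
    State.TRD_COMORBID: (1.0, 1.0),
}


class CostInputError(ValueError):
    pass


@dataclass(frozen=True)
class UnitCostTable:
    """Unit costs per service contact in 2023 US$ (HK$ at 7.85 per US$)."""

    outpatient: float
    emergency: float
    inpatient: float

    def __post_init__(self) -> None:
        for setting in SETTINGS:
            if getattr(self, setting) <= 0:
                raise CostInputError(f"unit cost for {setting} must be positive")

    def __getitem__(self, setting: str) -> float:
        return float(getattr(self, setting))

    def to_json(self) -> str:
        return json.dumps(
            {s: getattr(self, s) for s in SETTINGS}, indent=2, sort_keys=True
        )

    @classmethod
    def from_json(cls, text: str) -> "UnitCostTable":
        return cls(**json.loads(text))


def default_unit_costs() -> UnitCostTable:
    """Synthetic stand-in for 2023 non-subsidised public hospital charges,
    rounded to US$ at 7.85 HK$/US$."""
    return UnitCostTable(outpatient=152.0, emergency=157.0, inpatient=650.0)


# -- patient-year table and NB fitting --------------------------------------------


def patient_year_table(cohort: Cohort) -> pd.DataFrame:
    """Patient-year count rows joined with covariates and state flags."""
    counts = cohort.counts
    if counts.empty:
        raise CostInputError("cohort has no patient-year count rows")
    pat = cohort.patients.set_index("patient_id")
    tab = counts.merge(
        pat[["subgroup"]], left_on="patient_id", right_index=True, how="left"
    )
    gi = tab["subgroup"].map(lambda s: SUBGROUP_INDEX[Subgroup.from_label(s)]).to_numpy()
    X = COVARIATE_MATRIX[gi]
    for k, name in enumerate(COVARIATE_NAMES):
        tab[name] = X[:, k]
    flags = tab["state"].map(
        {s.value: STATE_FLAGS[s] for s in ACTIVE_STATES}
    )
    tab["trd"] = flags.map(lambda f: f[0])
    tab["comorbid"] = flags.map(lambda f: f[1])
    return tab


_MODEL_COLUMNS = list(COVARIATE_NAMES) + ["trd", "comorbid", "trd_comorbid"]


@dataclass
class NBCountFit:
    """A fitted negative-binomial annual count model for one setting/scope.

    NB2 parameterisation: variance = mu + alpha * mu^2 (theta = 1/alpha).
    The state effect is saturated (TRD, comorbid and their interaction) so
    predictions at the four indicator profiles recover state-specific means.
    """

    setting: str
    scope: str
    params: pd.Series
    params_se: pd.Series
    alpha: float
    converged: bool
    loglik: float
    dropped_columns: tuple[str, ...] = ()

    @property
    def dispersion(self) -> float:
        """theta with variance = mu + mu^2/theta."""
        return 1.0 / self.alpha if self.alpha > 0 else np.inf

    def conf_int(self, name: str, level: float = 0.95) -> tuple[float, float]:
        from scipy import stats as _st

        z = _st.norm.ppf(0.5 + level / 2.0)
        m, s = float(self.params[name]), float(self.params_se[name])
        return m - z * s, m + z * s

    def predict_mean(self, state: State, subgroup: Subgroup) -> float:
        """Predicted mean annual count for one state x subgroup profile."""
        if state not in STATE_FLAGS:
            raise CostInputError(f"state {state} does not accrue service use")
        trd, com = STATE_FLAGS[state]
        profile = dict(
            zip(
                ["const", *COVARIATE_NAMES, "trd", "comorbid", "trd_comorbid"],
                [1.0, *COVARIATE_MATRIX[SUBGROUP_INDEX[subgroup]], trd, com, trd * com],
            )
        )
        x = np.array([profile[name] for name in self.params.index])
        return float(np.exp(x @ self.params.to_numpy()))


def _polish_mean_coefficients(
    y: np.ndarray,
    X: np.ndarray,
    offset: np.ndarray,
    beta: np.ndarray,
    alpha: float,
    tol: float = 1e-12,
    max_iter: int = 50,
) -> np.ndarray:
    """Newton refinement of the NB2 mean coefficients at fixed dispersion.

    The profile likelihood in the mean coefficients is well conditioned even
    when alpha sits at its Poisson-limit boundary, where joint quasi-Newton
    steps stall; solving the mean score exactly restores identities such as
    'intercept-only fitted mean equals the sample mean'.
    """
    beta = beta.copy()
    for _ in range(max_iter):
        mu = np.exp(X @ beta + offset)
        w = (y - mu) / (1.0 + alpha * mu)
        grad = X.T @ w
        if np.max(np.abs(grad)) < tol * max(1.0, float(np.sum(y))):
            break
        info = (X * (mu / (1.0 + alpha * mu))[:, None]).T @ X
        try:
            step = np.linalg.solve(info, grad)
        except np.linalg.LinAlgError:  # pragma: no cover
            break
        beta += np.clip(step, -1.0, 1.0)
    return beta


def fit_nb_count_model(
    cohort_or_table: Cohort | pd.DataFrame, setting: str, scope: str = "allcause"
) -> NBCountFit:
    """Fit the NB regression for one service setting and cause scope.

    Raises ``CostInputError`` when the outcome is all zeros (a zero-cost
    override is then appropriate) and ``CostInputError`` with the iteration
    trace when the optimiser fails.
    """
    if setting not in SETTINGS:
        raise CostInputError(f"unknown setting {setting!r}")
    if scope not in SCOPES:
        raise CostInputError(f"unknown scope {scope!r}")
    tab = (
        patient_year_table(cohort_or_table)
        if isinstance(cohort_or_table, Cohort)
        else cohort_or_table
    )
    y = tab[f"{setting}_{scope}"].to_numpy(dtype=float)
    if np.all(y == 0):
        raise CostInputError(
            f"all {setting}/{scope} counts are zero; use a zero-cost override"
        )
    tab = tab.assign(trd_comorbid=tab["trd"] * tab["comorbid"])
    exog = sm.add_constant(tab[_MODEL_COLUMNS], has_constant="add")
    # zero-variance regressors (e.g. a cohort that never reaches a state)
    # are absorbed into the intercept
    dropped = tuple(
        c for c in exog.columns if c != "const" and exog[c].nunique() == 1
    )
    exog = exog.drop(columns=list(dropped))
    offset = np.log(np.clip(tab["exposure"].to_numpy(dtype=float), 1e-12, None))
    model = sm.NegativeBinomial(y, exog, offset=offset)
    with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
        try:
            res = model.fit(disp=False, maxiter=300)
        except Exception as exc:  # pragma: no cover - statsmodels internals
            raise CostInputError(f"NB fit failed for {setting}/{scope}: {exc}") from exc
    if not res.mle_retvals.get("converged", False):
        raise CostInputError(
            f"NB fit did not converge for {setting}/{scope}: {res.mle_retvals}"
        )
    params = res.params.drop("alpha")
    params[:] = _polish_mean_coefficients(
        y, exog.to_numpy(dtype=float), offset, params.to_numpy(), float(res.params["alpha"])
    )
    return NBCountFit(
        setting=setting,
        scope=scope,
        params=params,
        params_se=res.bse.drop("alpha"),
        alpha=float(res.params["alpha"]),
        converged=True,
        loglik=float(res.llf),
        dropped_columns=dropped,
    )


def predict_state_means(fits: Mapping[tuple[str, str], NBCountFit]) -> pd.DataFrame:
    """Mean annual counts for every state x subgroup x setting x scope."""
    rows = []
    for state in ACTIVE_STATES:
        for g in SUBGROUPS:
            for setting in SETTINGS:
                for scope in SCOPES:
                    fit = fits.get((setting, scope))
                    if fit is None:
                        raise CostInputError(f"missing count model for {(setting, scope)}")
                    rows.append(
                        {
                            "state": state.value,
                            "subgroup": g.label,
                            "setting": setting,
                            "scope": scope,
                            "mean_count": fit.predict_mean(state, g),
                        }
                    )
    return pd.DataFrame(rows)


def counts_to_costs(
    mean_counts: pd.DataFrame, unit_costs: UnitCostTable
) -> pd.DataFrame:
    """Annual cost per state x subgroup: sum over settings of count x unit cost.

    ``mean_counts`` must provide every active state x subgroup x setting for
    both scopes; a missing combination raises an error naming it.
    """
    required_states = [s.value for s in ACTIVE_STATES]
    idx = mean_counts.set_index(["state", "subgroup", "setting", "scope"])["mean_count"]
    rows = []
    for state in required_states:
        for g in SUBGROUPS:
            cost = {"allcause": 0.0, "psychiatric": 0.0}
            for setting in SETTINGS:
                for scope in SCOPES:
                    key = (state, g.label, setting, scope)
                    if key not in idx.index:
                        raise CostInputError(
                            f"missing mean count for state={state}, "
                            f"subgroup={g.label}, setting={setting}, scope={scope}"
                        )
                    cost[scope] += float(idx.loc[key]) * unit_costs[setting]
            rows.append(
                {
                    "state": state,
                    "subgroup": g.label,
                    "cost_allcause": cost["allcause"],
                    "cost_psychiatric": cost["psychiatric"],
                }
            )
    # absorbing states accrue nothing by definition
    for state in (State.LOW_INTENSITY, State.DEATH):
        for g in SUBGROUPS:
            rows.append(
                {
                    "state": state.value,
                    "subgroup": g.label,
                    "cost_allcause": 0.0,
                    "cost_psychiatric": 0.0,
                }
            )
    return pd.DataFrame(rows)


# -- utilities ---------------------------------------------------------------------


def default_base_utilities() -> dict[State, float]:
    """Fixture placeholder utilities (not literature values): NTRD 0.80,
    TRD 0.60, low-intensity 0.85."""
    return {State.NTRD: 0.80, State.TRD: 0.60, State.LOW_INTENSITY: 0.85}


def apply_utility_decrement(
    base: Mapping[State, float], decrement: float = 0.17
) -> dict[State, float]:
    """Complete the utility set from non-comorbid base values.

    Comorbid-state utilities are (1 - decrement) times their non-comorbid
    counterparts; death has utility 0.
    """
    if not 0.0 <= decrement < 1.0:
        raise CostInputError(f"decrement must be in [0, 1), got {decrement}")
    for state in (State.NTRD, State.TRD, State.LOW_INTENSITY):
        u = base.get(state)
        if u is None or not 0.0 < u <= 1.0:
            raise CostInputError(f"base utility for {state} must be in (0, 1]")
    return {
        State.NTRD: float(base[State.NTRD]),
        State.TRD: float(base[State.TRD]),
        State.NTRD_COMORBID: (1.0 - decrement) * float(base[State.NTRD]),
        State.TRD_COMORBID: (1.0 - decrement) * float(base[State.TRD]),
        State.LOW_INTENSITY: float(base[State.LOW_INTENSITY]),
        State.DEATH: 0.0,
    }


# -- assembled state inputs --------------------------------------------------------


@dataclass
class StateInputs:
    """Per-state x subgroup annual costs and utilities as dense arrays.

    ``cost_allcause`` and ``cost_psychiatric`` have shape (16, 6) in
    (SUBGROUPS, STATE_ORDER); ``utility`` has shape (6,).
    """

    cost_allcause: np.ndarray
    cost_psychiatric: np.ndarray
    utility: np.ndarray

    def validate(self) -> None:
        if (self.cost_psychiatric > self.cost_allcause + 1e-9).any():
            raise CostInputError("psychiatric cost exceeds all-cause cost")
        for s in (State.LOW_INTENSITY, State.DEATH):
            i = STATE_INDEX[s]
            if self.cost_allcause[:, i].any() or self.cost_psychiatric[:, i].any():
                raise CostInputError(f"absorbing state {s} must have zero cost")
        if self.utility[STATE_INDEX[State.DEATH]] != 0.0:
            raise CostInputError("death utility must be 0")
        if (self.utility < 0).any() or (self.utility > 1).any():
            raise CostInputError("utilities must lie in [0, 1]")

    @classmethod
    def from_frames(
        cls, costs: pd.DataFrame, utilities: Mapping[State, float]
    ) -> "StateInputs":
        ca = np.zeros((N_SUBGROUPS, N_STATES))
        cp = np.zeros((N_SUBGROUPS, N_STATES))
        idx = costs.set_index(["subgroup", "state"])
        for gi, g in enumerate(SUBGROUPS):
            for s in STATE_ORDER:
                key = (g.label, s.value)
                if key in idx.index:
                    ca[gi, STATE_INDEX[s]] = idx.loc[key, "cost_allcause"]
                    cp[gi, STATE_INDEX[s]] = idx.loc[key, "cost_psychiatric"]
        u = np.array([utilities[s] for s in STATE_ORDER])
        out = cls(cost_allcause=ca, cost_psychiatric=cp, utility=u)
        out.validate()
        return out

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for gi, g in enumerate(SUBGROUPS):
            for s in STATE_ORDER:
                i = STATE_INDEX[s]
                rows.append(
                    {
                        "state": s.value,
                        "subgroup": g.label,
                        "cost_allcause": self.cost_allcause[gi, i],
                        "cost_psychiatric": self.cost_psychiatric[gi, i],
                        "utility": self.utility[i],
                    }
                )
        return pd.DataFrame(rows)

    def write_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def derive_state_inputs(
    cohort: Cohort,
    unit_costs: UnitCostTable | None = None,
    base_utilities: Mapping[State, float] | None = None,
    decrement: float = 0.17,
) -> StateInputs:
    """Full derivation: NB count models -> predicted means -> costs -> inputs."""
    unit_costs = unit_costs or default_unit_costs()
    base_utilities = base_utilities or default_base_utilities()
    table = patient_year_table(cohort)
    fits = {
        (setting, scope): fit_nb_count_model(table, setting, scope)
        for setting in SETTINGS
        for scope in SCOPES
    }
    means = predict_state_means(fits)
    costs = counts_to_costs(means, unit_costs)
    utilities = apply_utility_decrement(base_utilities, decrement)
    return StateInputs.from_frames(costs, utilities)
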