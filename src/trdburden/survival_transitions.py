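"""Parametric survival estimation and cycle-wise transition probabilities.

Every permitted transition of the state graph is treated as a cause-specific
time-to-event outcome: the clock starts at entry into the source state,
competing transitions and the administrative cut-off are right-censoring.
Five families (exponential, Weibull, lognormal, log-logistic, Gompertz) are
fitted by maximum likelihood with covariate adjustment for age band, sex and
baseline medical history in accelerated-failure-time form, and the best
family is selected by AIC (BIC and a Kaplan-Meier deviation statistic are
recorded alongside).

A fitted survival function S is converted to the conditional probability of
the event during yearly cycle t via q(t) = 1 - S(t)/S(t-1), and per-source
probabilities are assembled into row-stochastic cycle matrices.  Two
combination rules are available for competing exits from the same state:

* ``cause_specific`` — each cause keeps its net q(t) and the stay
  probability is the complement, with proportional rescaling if the naive
  sum exceeds one.  This mirrors common cohort-model practice.
* ``competing`` — exact crude probabilities obtained by integrating each
  cause-specific hazard against the all-cause survival over the cycle,
  which is self-consistent with competing-risks data generation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import optimize

from ._families import FAMILY_ORDER, Family, get_family
from .states import (
    ABSORBING_STATES,
    ACTIVE_STATES,
    COVARIATE_MATRIX,
    N_COVARIATES,
    N_STATES,
    STATE_INDEX,
    STATE_ORDER,
    SUBGROUP_INDEX,
    State,
    Subgroup,
    Transition,
    covariate_vector,
    permitted_transitions,
)
from .synthetic_cohort import Cohort

logger = logging.getLogger(__name__)

_GAUSS_NODES, _GAUSS_WEIGHTS = np.polynomial.legendre.leggauss(48)


class EstimationError(RuntimeError):
    pass


class ZeroEventsError(EstimationError):
    """No events observed; use a zero-probability override for this edge."""


@dataclass
class SurvivalFit:
    """A fitted parametric time-to-event model for one transition.

    ``params`` are the baseline family parameters on their transformed
    (unconstrained) scale; ``beta`` are AFT log time-ratios for
    (age 10-24, age 25-40, age >65, male, history).
    """

    transition: Transition
    family: str
    params: np.ndarray
    beta: np.ndarray
    loglik: float
    n_events: int
    n_at_risk: int
    converged: bool = True
    grad_norm: float = np.nan
    params_se: np.ndarray | None = None
    km_deviation: float = np.nan

    @property
    def n_free_params(self) -> int:
        return len(self.params) + len(self.beta)

    @property
    def aic(self) -> float:
        return 2.0 * self.n_free_params - 2.0 * self.loglik

    @property
    def bic(self) -> float:
        return self.n_free_params * np.log(self.n_at_risk) - 2.0 * self.loglik

    def _family(self) -> Family:
        return get_family(self.family)

    def eta(self, subgroup: Subgroup | None) -> float:
        if subgroup is None or len(self.beta) == 0:
            return 0.0
        return float(covariate_vector(subgroup) @ self.beta)

    def sf(self, t, subgroup: Subgroup | None = None) -> np.ndarray:
        """Covariate-adjusted survival function S(t | subgroup)."""
        t = np.asarray(t, dtype=float)
        u = t * np.exp(-self.eta(subgroup))
        return np.exp(self._family().log_sf(u, self.params))

    def hazard(self, t, subgroup: Subgroup | None = None) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        eta = self.eta(subgroup)
        u = t * np.exp(-eta)
        return np.exp(self._family().log_hazard(u, self.params) - eta)

    def natural_params(self) -> dict[str, float]:
        return self._family().natural(self.params)


@dataclass
class FixedProbs:
    """Constant per-cycle probability stand-in (zero-event overrides, tests)."""

    transition: Transition
    value: float = 0.0

    def cycle_probs(self, subgroup: Subgroup | None = None, cycles: int = 10) -> np.ndarray:
        return np.full(cycles, self.value)


# -- likelihood -------------------------------------------------------------------


def _neg_loglik(
    theta: np.ndarray,
    family: Family,
    t: np.ndarray,
    events: np.ndarray,
    X: np.ndarray | None,
) -> float:
    k = family.n_params
    bp = theta[:k]
    if X is not None:
        eta = X @ theta[k:]
        u = t * np.exp(-eta)
    else:
        eta = 0.0
        u = t
    with np.errstate(over="ignore", invalid="ignore"):
        ls = family.log_sf(u, bp)
        lh = family.log_hazard(u, bp)
        ll = np.sum(ls) + np.sum(lh[events]) - (np.sum(eta[events]) if X is not None else 0.0)
    if not np.isfinite(ll):
        return 1e12
    return -float(ll)


def _numeric_hessian(fun, theta: np.ndarray, eps: float = 1e-4) -> np.ndarray:
    p = len(theta)
    hess = np.empty((p, p))
    f0 = fun(theta)
    for i in range(p):
        for j in range(i, p):
            ei = np.zeros(p)
            ej = np.zeros(p)
            ei[i] = eps
            ej[j] = eps
            fpp = fun(theta + ei + ej)
            fpm = fun(theta + ei - ej)
            fmp = fun(theta - ei + ej)
            fmm = fun(theta - ei - ej)
            hess[i, j] = hess[j, i] = (fpp - fpm - fmp + fmm) / (4.0 * eps**2)
    return hess


def transition_data(
    cohort: Cohort, transition: Transition
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Durations, event indicators and covariates for one transition.

    Time origin is entry into the source state (clock reset); exits to any
    other state and administrative censoring are treated as right-censoring.
    """
    from_state, to_state = transition
    events = cohort.events
    n = cohort.n_patients

    entry = np.full(n, np.inf)
    sel = events[events["state"] == from_state.value]
    entry[sel["patient_id"].to_numpy()] = sel["entry_time"].to_numpy()
    in_state = np.isfinite(entry)

    # first exit out of the source state after entry
    exit_time = np.full(n, np.inf)
    exit_state = np.empty(n, dtype=object)
    later = events[
        np.isfinite(entry[events["patient_id"].to_numpy()])
        & (events["entry_time"].to_numpy() > entry[events["patient_id"].to_numpy()])
    ]
    first = later.groupby("patient_id").first()
    exit_time[first.index.to_numpy()] = first["entry_time"].to_numpy()
    exit_state[first.index.to_numpy()] = first["state"].to_numpy()

    censor = cohort.patients["censor_time"].to_numpy()
    pid = np.flatnonzero(in_state)
    end = np.minimum(exit_time[pid], censor[pid])
    durations = end - entry[pid]
    is_event = (exit_time[pid] <= censor[pid]) & (exit_state[pid] == to_state.value)
    X = COVARIATE_MATRIX[
        cohort.patients["subgroup"].map(lambda s: SUBGROUP_INDEX[Subgroup.from_label(s)]).to_numpy()[pid]
    ]
    keep = durations > 1e-9
    return durations[keep], is_event[keep].astype(bool), X[keep]


def fit_parametric_survival(
    cohort_or_data: Cohort | tuple[np.ndarray, np.ndarray, np.ndarray | None],
    transition: Transition,
    family: str,
    covariates: bool = True,
    compute_se: bool = True,
) -> SurvivalFit:
    """Maximum-likelihood fit of one family to one transition.

    Accepts either a cohort (durations are derived from its event table) or a
    pre-built ``(durations, events, X)`` triple.  Raises ``ZeroEventsError``
    when no events are observed, and ``EstimationError`` (carrying the final
    gradient norm) when the optimiser fails to converge.
    """
    if isinstance(cohort_or_data, Cohort):
        t, ev, X = transition_data(cohort_or_data, transition)
    else:
        t, ev, X = cohort_or_data
        t = np.asarray(t, dtype=float)
        ev = np.asarray(ev, dtype=bool)
    if not covariates:
        X = None
    if len(t) == 0:
        raise EstimationError(f"no subjects at risk for transition {transition}")
    n_events = int(ev.sum())
    if n_events == 0:
        raise ZeroEventsError(
            f"no events for transition {transition}; "
            "use a zero-probability override (FixedProbs) for this edge"
        )

    fam = get_family(family)
    theta0 = fam.init_params(t, ev)
    if X is not None:
        theta0 = np.concatenate([theta0, np.zeros(X.shape[1])])

    fun = lambda th: _neg_loglik(th, fam, t, ev, X)  # noqa: E731
    best = None
    for start in (theta0, theta0 + 0.3, theta0 - 0.3):
        res = optimize.minimize(fun, start, method="BFGS", options={"maxiter": 500, "gtol": 1e-6})
        if best is None or res.fun < best.fun:
            best = res
        if res.success:
            break
    res = best
    grad_norm = float(np.max(np.abs(res.jac)))
    # BFGS can report failure on precision loss at an excellent optimum;
    # accept when the scaled gradient is small.
    converged = bool(res.success) or grad_norm < 1e-3 * max(1.0, abs(res.fun))
    if not converged:
        raise EstimationError(
            f"optimiser did not converge for {transition} [{family}]: "
            f"final gradient norm {grad_norm:.3e}"
        )

    k = fam.n_params
    se = None
    if compute_se:
        hess = _numeric_hessian(fun, res.x)
        try:
            cov = np.linalg.inv(hess)
            diag = np.diag(cov)
            se = np.sqrt(np.where(diag > 0, diag, np.nan))
        except np.linalg.LinAlgError:  # pragma: no cover
            se = None

    fit = SurvivalFit(
        transition=transition,
        family=family,
        params=res.x[:k],
        beta=res.x[k:] if X is not None else np.zeros(0),
        loglik=-float(res.fun),
        n_events=n_events,
        n_at_risk=len(t),
        converged=converged,
        grad_norm=grad_norm,
        params_se=se,
    )
    fit.km_deviation = _km_deviation(fit, t, ev)
    return fit


def _km_deviation(fit: SurvivalFit, t: np.ndarray, ev: np.ndarray) -> float:
    """Max absolute gap between the fitted marginal survival and Kaplan-Meier.

    An automated stand-in for visual curve inspection; computed at event
    times against the covariate-averaged fitted survival.
    """
    if not ev.any():
        return np.nan
    order = np.argsort(t)
    ts, es = t[order], ev[order]
    n = len(ts)
    at_risk = n - np.arange(n)
    km = np.cumprod(1.0 - es / at_risk)
    event_times = ts[es]
    km_at_events = km[es]
    fitted = np.exp(fit._family().log_sf(event_times, fit.params))
    return float(np.max(np.abs(fitted - km_at_events)))


def fit_all_families(
    cohort_or_data, transition: Transition, covariates: bool = True, compute_se: bool = False
) -> dict[str, SurvivalFit]:
    fits = {}
    if isinstance(cohort_or_data, Cohort):
        cohort_or_data = transition_data(cohort_or_data, transition)
    for family in FAMILY_ORDER:
        fits[family] = fit_parametric_survival(
            cohort_or_data, transition, family, covariates=covariates, compute_se=compute_se
        )
    return fits


def select_best_family(fits: Mapping[str, SurvivalFit] | Sequence[SurvivalFit]) -> SurvivalFit:
    """Best-fitting family by lowest AIC, ties broken by fixed family order.

    Requires all five families.  When AIC and BIC disagree on the winner the
    AIC choice stands and the disagreement is logged.
    """
    if not isinstance(fits, Mapping):
        fits = {f.family: f for f in fits}
    missing = [f for f in FAMILY_ORDER if f not in fits]
    if missing:
        raise EstimationError(f"missing fits for families: {missing}")
    by_aic = min(FAMILY_ORDER, key=lambda f: (fits[f].aic, FAMILY_ORDER.index(f)))
    by_bic = min(FAMILY_ORDER, key=lambda f: (fits[f].bic, FAMILY_ORDER.index(f)))
    if by_aic != by_bic:
        logger.info(
            "AIC/BIC disagree for %s: AIC selects %s, BIC selects %s; keeping AIC choice",
            fits[by_aic].transition,
            by_aic,
            by_bic,
        )
    return fits[by_aic]


# -- survival -> cycle probabilities ----------------------------------------------


def survival_to_cycle_probs(
    fit: SurvivalFit, subgroup: Subgroup | None = None, cycles: int = 10
) -> np.ndarray:
    """Conditional event probability per yearly cycle, q(t) = 1 - S(t)/S(t-1).

    q(t) is the probability of the event during cycle t given event-free at
    t-1.  For the exponential family this is constant at 1 - exp(-lambda).
    """
    grid = np.arange(cycles + 1, dtype=float)
    s = fit.sf(grid, subgroup)
    if np.any(s[:-1] <= 0.0):
        raise EstimationError(
            f"survival support exhausted before cycle {cycles} for {fit.transition}"
        )
    q = 1.0 - s[1:] / s[:-1]
    return np.clip(q, 0.0, 1.0)


# attach for duck-typed use alongside FixedProbs
def _fit_cycle_probs(self: SurvivalFit, subgroup=None, cycles: int = 10) -> np.ndarray:
    return survival_to_cycle_probs(self, subgroup, cycles)


SurvivalFit.cycle_probs = _fit_cycle_probs  # type: ignore[attr-defined]


@dataclass
class TransitionSchedule:
    """Per-subgroup cycle-indexed transition matrices.

    ``probs`` has shape (cycles, 6, 6) in STATE_ORDER; every row sums to one
    and absorbing states are identity rows.
    """

    subgroup: Subgroup
    probs: np.ndarray
    rescaled_cycles: tuple[int, ...] = ()

    @property
    def cycles(self) -> int:
        return self.probs.shape[0]

    def validate(self, atol: float = 1e-12) -> None:
        if np.any(self.probs < -atol) or np.any(self.probs > 1 + atol):
            raise ValueError("transition probabilities outside [0, 1]")
        rowsums = self.probs.sum(axis=2)
        if not np.allclose(rowsums, 1.0, atol=atol):
            raise ValueError(f"rows do not sum to 1 (max dev {np.abs(rowsums-1).max():.2e})")
        for s in ABSORBING_STATES:
            i = STATE_INDEX[s]
            if not np.allclose(self.probs[:, i, i], 1.0, atol=atol):
                raise ValueError(f"absorbing state {s} is not identity")


def _crude_cycle_probs(
    fits: Mapping[Transition, object],
    causes: Sequence[Transition],
    subgroup: Subgroup | None,
    cycles: int,
) -> np.ndarray:
    """Crude per-cycle probabilities by integrating each cause's hazard
    against the all-cause survival (48-point Gauss-Legendre per cycle)."""
    out = np.zeros((cycles, len(causes)))
    hazard_fits = []
    for tr in causes:
        fit = fits[tr]
        if isinstance(fit, FixedProbs):
            if fit.value != 0.0:
                raise EstimationError(
                    "competing combination requires hazard-bearing fits; "
                    f"got nonzero FixedProbs for {tr}"
                )
            hazard_fits.append(None)
        else:
            hazard_fits.append(fit)

    def total_log_sf(t: np.ndarray) -> np.ndarray:
        acc = np.zeros_like(t)
        for fit in hazard_fits:
            if fit is not None:
                acc += np.log(np.maximum(fit.sf(t, subgroup), 1e-300))
        return acc

    for t in range(1, cycles + 1):
        a, b = float(t - 1), float(t)
        nodes = 0.5 * (b - a) * _GAUSS_NODES + 0.5 * (a + b)
        w = 0.5 * (b - a) * _GAUSS_WEIGHTS
        s_tot = np.exp(total_log_sf(nodes))
        s_start = np.exp(total_log_sf(np.array([a])))[0]
        if s_start <= 0.0:
            raise EstimationError(f"support exhausted at cycle {t}")
        for ci, fit in enumerate(hazard_fits):
            if fit is None:
                continue
            h = fit.hazard(nodes, subgroup)
            out[t - 1, ci] = np.sum(w * h * s_tot) / s_start
    return out


def assemble_schedule(
    fits: Mapping[Transition, object],
    subgroup: Subgroup,
    cycles: int = 10,
    mode: str = "cause_specific",
    include_comorbid_to_trd: bool = False,
) -> TransitionSchedule:
    """Build the cycle-indexed 6x6 transition matrices for one subgroup.

    ``fits`` maps each permitted transition to a SurvivalFit or FixedProbs
    (zero override).  In ``cause_specific`` mode each cause keeps its net
    q(t) with proportional rescaling when competing probabilities sum above
    one; in ``competing`` mode crude probabilities are derived by hazard
    integration and can never sum above one.
    """
    if mode not in ("cause_specific", "competing"):
        raise ValueError(f"unknown combination mode {mode!r}")
    required = permitted_transitions(include_comorbid_to_trd)
    missing = [tr for tr in required if tr not in fits]
    if missing:
        raise EstimationError(f"missing fits for transitions: {missing}")

    probs = np.zeros((cycles, N_STATES, N_STATES))
    rescaled: list[int] = []
    for s in ABSORBING_STATES:
        probs[:, STATE_INDEX[s], STATE_INDEX[s]] = 1.0

    for from_state in ACTIVE_STATES:
        causes = [tr for tr in required if tr[0] == from_state]
        i = STATE_INDEX[from_state]
        if mode == "competing":
            q = _crude_cycle_probs(fits, causes, subgroup, cycles)
        else:
            q = np.stack(
                [np.asarray(fits[tr].cycle_probs(subgroup, cycles)) for tr in causes],
                axis=1,
            )
        total = q.sum(axis=1)
        over = total > 1.0
        if over.any():
            which = np.flatnonzero(over)
            logger.warning(
                "competing probabilities from %s exceed 1 at cycles %s for %s; "
                "rescaling proportionally (check inputs)",
                from_state,
                (which + 1).tolist(),
                subgroup.label,
            )
            q[over] = q[over] / total[over, None]
            total = np.minimum(total, 1.0)
            rescaled.extend((which + 1).tolist())
        for ci, tr in enumerate(causes):
            probs[:, i, STATE_INDEX[tr[1]]] = q[:, ci]
        probs[:, i, i] = 1.0 - total

    schedule = TransitionSchedule(subgroup=subgroup, probs=probs, rescaled_cycles=tuple(sorted(set(rescaled))))
    schedule.validate(atol=1e-9)
    return schedule


def schedule_to_frame(schedule: TransitionSchedule) -> "pd.DataFrame":
    """Tidy export: subgroup, cycle, from, to, prob."""
    import pandas as pd

    rows = []
    for t in range(schedule.cycles):
        for i, a in enumerate(STATE_ORDER):
            for j, b in enumerate(STATE_ORDER):
                rows.append(
                    {
                        "subgroup": schedule.subgroup.label,
                        "cycle": t + 1,
                        "from": a.value,
                        "to": b.value,
                        "prob": schedule.probs[t, i, j],
                    }
                )
    return pd.DataFrame(rows)


def validate_mape(modelled: Sequence[float], observed: Sequence[float]) -> float:
    """Mean absolute percentage error of modelled vs observed values."""
    modelled = np.asarray(modelled, dtype=float)
    observed = np.asarray(observed, dtype=float)
    if modelled.shape != observed.shape:
        raise ValueError("modelled and observed must have equal length")
    if np.any(observed == 0):
        raise ValueError("observed contains 0; percentage error undefined")
    return float(np.mean(np.abs(modelled - observed) / np.abs(observed)) * 100.0)
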