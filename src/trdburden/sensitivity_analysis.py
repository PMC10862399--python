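"""Deterministic (one-way) and probabilistic sensitivity analyses.

A ``ParameterRegistry`` lists every varied input with its base value,
lower/upper bounds (95% CI when available, else a 20% variation) and a PSA
distribution.  Deterministic analysis reruns the model at each parameter's
bounds with everything else at base and orders parameters by outcome swing
(tornado order).  Probabilistic analysis draws all parameters jointly
(1000 Monte-Carlo iterations by default) from their assigned distributions:
beta for probabilities and utilities (moment matched), gamma for costs,
normal truncated at zero for entrant counts.

Perturbations act on derived model inputs — per-cycle transition
probability vectors (re-complementing the stay probability, with
proportional rescaling if a row would exceed one), per-state cost and
utility levels, and the entrant count — not on the underlying survival
coefficients.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .cost_utility_inputs import StateInputs
from .markov_engine import ScenarioConfig, run_closed_cohort
from .states import (
    ACTIVE_STATES,
    N_STATES,
    STATE_INDEX,
    SUBGROUPS,
    State,
    Subgroup,
    Transition,
)
from .survival_transitions import TransitionSchedule

OUTCOMES = ("cost_allcause_cum", "cost_psychiatric_cum", "deaths_cum", "qalys_cum")


class SensitivityError(ValueError):
    pass


@dataclass(frozen=True)
class Parameter:
    """One registry entry.

    ``target`` identifies what the parameter scales:
    ``("entrants", None)``, ``("transition", (from, to))``,
    ``("cost", state)`` or ``("utility", state)``.  ``value`` semantics are
    the natural level of the quantity (cycle-1 probability, annual cost,
    utility, entrant count); model application rescales the corresponding
    derived input by value/base.
    """

    name: str
    target: tuple[str, object]
    base: float
    low: float
    high: float
    distribution: str = "auto"

    def __post_init__(self) -> None:
        if not self.low <= self.base <= self.high:
            raise SensitivityError(
                f"{self.name}: bounds must satisfy low <= base <= high "
                f"({self.low}, {self.base}, {self.high})"
            )

    @property
    def kind(self) -> str:
        return self.target[0]

    def resolved_distribution(self) -> str:
        if self.distribution != "auto":
            return self.distribution
        return {
            "transition": "beta",
            "utility": "beta",
            "cost": "gamma",
            "entrants": "truncnorm",
        }[self.kind]

    def sample(self, rng: np.random.Generator) -> float:
        """One PSA draw; degenerate bounds return the base exactly."""
        if self.high == self.low:
            return self.base
        sd = (self.high - self.low) / 3.92  # bounds read as a 95% interval
        dist = self.resolved_distribution()
        m = self.base
        if dist == "beta":
            if not 0.0 < m < 1.0:
                raise SensitivityError(
                    f"{self.name}: beta distribution needs base in (0,1), got {m}"
                )
            v = min(sd**2, 0.9 * m * (1.0 - m))
            nu = m * (1.0 - m) / v - 1.0
            a, b = m * nu, (1.0 - m) * nu
            if a <= 0 or b <= 0:
                raise SensitivityError(f"{self.name}: invalid beta shapes ({a}, {b})")
            return float(rng.beta(a, b))
        if dist == "gamma":
            if m <= 0:
                raise SensitivityError(f"{self.name}: gamma needs positive base")
            shape = (m / sd) ** 2
            scale = sd**2 / m
            return float(rng.gamma(shape, scale))
        if dist == "truncnorm":
            a = (0.0 - m) / sd
            return float(stats.truncnorm.rvs(a, np.inf, loc=m, scale=sd, random_state=rng))
        raise SensitivityError(f"{self.name}: unknown distribution {dist!r}")


@dataclass
class ParameterRegistry:
    parameters: list[Parameter]

    def __iter__(self):
        return iter(self.parameters)

    def __len__(self) -> int:
        return len(self.parameters)

    def names(self) -> list[str]:
        return [p.name for p in self.parameters]

    def get(self, name: str) -> Parameter:
        for p in self.parameters:
            if p.name == name:
                return p
        raise KeyError(name)


# -- model bundle and runner -------------------------------------------------------


@dataclass
class ModelBundle:
    """Everything a closed-cohort base case needs, pre-derived."""

    schedules: Mapping[Subgroup, TransitionSchedule]
    state_inputs: StateInputs
    entrants: np.ndarray  # (16,)
    config: ScenarioConfig = field(default_factory=lambda: ScenarioConfig(mode="closed"))


def _perturb_schedules(
    schedules: Mapping[Subgroup, TransitionSchedule],
    multipliers: Mapping[Transition, float],
) -> tuple[dict[Subgroup, TransitionSchedule], bool]:
    """Scale per-cycle probabilities of chosen edges; re-complement stay.

    Returns the new schedules and whether any row needed proportional
    rescaling to remain a probability row.
    """
    rescaled = False
    out: dict[Subgroup, TransitionSchedule] = {}
    for g, sched in schedules.items():
        probs = sched.probs.copy()
        for (a, b), mult in multipliers.items():
            i, j = STATE_INDEX[a], STATE_INDEX[b]
            scaled = probs[:, i, j] * mult
            if (scaled > 1.0).any():
                rescaled = True  # row normalisation below restores a valid row
            probs[:, i, j] = np.maximum(scaled, 0.0)
        for s in ACTIVE_STATES:
            i = STATE_INDEX[s]
            off = probs[:, i, :].sum(axis=1) - probs[:, i, i]
            over = off > 1.0
            if over.any():
                rescaled = True
                mask = np.ones(N_STATES, dtype=bool)
                mask[i] = False
                probs[np.ix_(over.nonzero()[0], [i], mask.nonzero()[0])] /= off[
                    over, None, None
                ]
                off = np.minimum(off, 1.0)
            probs[:, i, i] = 1.0 - off
        out[g] = TransitionSchedule(subgroup=g, probs=probs)
    return out, rescaled


def make_runner(bundle: ModelBundle) -> Callable[[Mapping[str, float], ParameterRegistry], dict]:
    """Closed-cohort model runner mapping parameter values to outcomes.

    Values are interpreted relative to each parameter's base: derived inputs
    are rescaled by value/base.  The entrant parameter scales all subgroups
    proportionally.
    """

    base_cost_all = bundle.state_inputs.cost_allcause
    base_cost_psy = bundle.state_inputs.cost_psychiatric
    base_utility = bundle.state_inputs.utility
    base_entrants = bundle.entrants

    def run(values: Mapping[str, float], registry: ParameterRegistry) -> dict:
        trans_mult: dict[Transition, float] = {}
        cost_mult = np.ones(N_STATES)
        util = base_utility.copy()
        entrant_scale = 1.0
        rescale_flag = False
        for p in registry:
            v = float(values.get(p.name, p.base))
            if p.base == 0:
                if v != 0:
                    raise SensitivityError(f"{p.name}: cannot rescale a zero base")
                continue
            ratio = v / p.base
            if p.kind == "entrants":
                entrant_scale = ratio
            elif p.kind == "transition":
                trans_mult[p.target[1]] = ratio
            elif p.kind == "cost":
                cost_mult[STATE_INDEX[p.target[1]]] = ratio
            elif p.kind == "utility":
                i = STATE_INDEX[p.target[1]]
                util[i] = min(base_utility[i] * ratio, 1.0)
            else:
                raise SensitivityError(f"unknown parameter kind {p.kind!r}")

        schedules = bundle.schedules
        if trans_mult:
            schedules, rescale_flag = _perturb_schedules(bundle.schedules, trans_mult)
        inputs = StateInputs(
            cost_allcause=base_cost_all * cost_mult,
            cost_psychiatric=base_cost_psy * cost_mult,
            utility=util,
        )
        trace = run_closed_cohort(
            schedules, inputs, base_entrants * entrant_scale, bundle.config
        )
        return {
            "cost_allcause_cum": trace.cumulative("cost_allcause"),
            "cost_psychiatric_cum": trace.cumulative("cost_psychiatric"),
            "deaths_cum": float(trace.deaths.sum()),
            "qalys_cum": trace.cumulative("qalys"),
            "rescaled": rescale_flag,
        }

    return run


def default_registry(
    bundle: ModelBundle, variation: float = 0.20
) -> ParameterRegistry:
    """Registry over entrants, every transition, state costs and utilities,
    each with a +/-20% variation around base (the no-CI convention)."""
    from .states import permitted_transitions

    params: list[Parameter] = []
    total_entrants = float(bundle.entrants.sum())
    params.append(
        Parameter(
            "entrants",
            ("entrants", None),
            total_entrants,
            (1 - variation) * total_entrants,
            (1 + variation) * total_entrants,
        )
    )
    weights = bundle.entrants / max(total_entrants, 1e-300)
    for tr in permitted_transitions():
        i, j = STATE_INDEX[tr[0]], STATE_INDEX[tr[1]]
        # entrant-weighted cycle-1 probability as the natural base level
        q1 = float(
            sum(
                w * bundle.schedules[g].probs[0, i, j]
                for w, g in zip(weights, SUBGROUPS)
            )
        )
        if q1 <= 0:
            continue
        params.append(
            Parameter(
                f"p_{tr[0].value}_to_{tr[1].value}",
                ("transition", tr),
                q1,
                (1 - variation) * q1,
                min((1 + variation) * q1, 1.0),
            )
        )
    for s in ACTIVE_STATES:
        i = STATE_INDEX[s]
        base_cost = float(bundle.state_inputs.cost_allcause[:, i] @ weights)
        if base_cost <= 0:
            continue
        params.append(
            Parameter(
                f"cost_{s.value}",
                ("cost", s),
                base_cost,
                (1 - variation) * base_cost,
                (1 + variation) * base_cost,
            )
        )
    for s in (State.NTRD, State.TRD, State.NTRD_COMORBID, State.TRD_COMORBID, State.LOW_INTENSITY):
        u = float(bundle.state_inputs.utility[STATE_INDEX[s]])
        if u <= 0:
            continue
        params.append(
            Parameter(
                f"utility_{s.value}",
                ("utility", s),
                u,
                (1 - variation) * u,
                min((1 + variation) * u, 1.0),
            )
        )
    return ParameterRegistry(params)


# -- DSA ---------------------------------------------------------------------------


@dataclass
class DsaResult:
    table: pd.DataFrame  # parameter, low, high, outcome_low, outcome_high, swing
    outcome: str
    base_outcome: float

    def tornado_order(self) -> list[str]:
        return self.table["parameter"].tolist()


def run_dsa(
    registry: ParameterRegistry,
    runner: Callable,
    outcome: str = "cost_allcause_cum",
) -> DsaResult:
    """One-way DSA: two runs per parameter at its bounds, others at base."""
    if outcome not in OUTCOMES:
        raise SensitivityError(f"unknown outcome {outcome!r}")
    base = runner({}, registry)
    rows = []
    for p in registry:
        lo = runner({p.name: p.low}, registry)
        hi = runner({p.name: p.high}, registry)
        rows.append(
            {
                "parameter": p.name,
                "low": p.low,
                "high": p.high,
                "outcome_low": lo[outcome],
                "outcome_high": hi[outcome],
                "swing": hi[outcome] - lo[outcome],
                "rescaled": bool(lo.get("rescaled") or hi.get("rescaled")),
            }
        )
    table = (
        pd.DataFrame(rows)
        .assign(abs_swing=lambda d: d["swing"].abs())
        .sort_values(["abs_swing", "parameter"], ascending=[False, True], kind="mergesort")
        .drop(columns="abs_swing")
        .reset_index(drop=True)
    )
    return DsaResult(table=table, outcome=outcome, base_outcome=base[outcome])


# -- PSA ---------------------------------------------------------------------------


@dataclass
class PsaResult:
    draws: pd.DataFrame  # iteration x parameter values
    outcomes: pd.DataFrame  # iteration x outcomes
    seed: int

    def summary(self) -> dict[str, dict[str, float]]:
        return {
            col: {
                "mean": float(self.outcomes[col].mean()),
                "sd": float(self.outcomes[col].std(ddof=1)),
            }
            for col in self.outcomes.columns
        }


def run_psa(
    registry: ParameterRegistry,
    runner: Callable,
    n_iter: int = 1000,
    seed: int = 0,
) -> PsaResult:
    """Joint Monte-Carlo PSA: ``n_iter`` draws over all parameters.

    One seeded generator and the registry's fixed parameter order make the
    result reproducible: identical seeds give identical outputs.
    """
    if n_iter < 1:
        raise SensitivityError("n_iter must be >= 1")
    rng = np.random.default_rng(seed)
    draw_rows = []
    outcome_rows = []
    for it in range(n_iter):
        values = {p.name: p.sample(rng) for p in registry}
        res = runner(values, registry)
        draw_rows.append(values)
        outcome_rows.append({k: res[k] for k in OUTCOMES})
    return PsaResult(
        draws=pd.DataFrame(draw_rows),
        outcomes=pd.DataFrame(outcome_rows),
        seed=seed,
    )
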