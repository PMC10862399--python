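"""Parametric time-to-event family primitives.

Each family exposes the baseline log-survival, log-hazard, and inverse
survival function on a transformed (unconstrained) parameter vector, so that
the same code serves maximum-likelihood fitting, cycle-probability
derivation, and event-time simulation.  Positivity-constrained parameters
are carried on the log scale.

Covariates enter in accelerated-failure-time (AFT) form at the call sites:
with linear predictor eta = x'beta, the subject-specific survival is
S(t | x) = S0(t * exp(-eta)), i.e. exp(eta) is a time ratio (eta > 0
prolongs event-free time).  Time acceleration is well defined for all five
families, including Gompertz, for which no proportional-hazards-free
reparameterisation is shared with the other families.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

_TINY = 1e-300


class Family:
    """Baseline distribution interface; subclasses define the five families."""

    name: str = ""
    #: names of the transformed baseline parameters
    param_names: tuple[str, ...] = ()

    @property
    def n_params(self) -> int:
        return len(self.param_names)

    # -- transformed-parameter API ------------------------------------------------
    def log_sf(self, t: np.ndarray, params: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def log_hazard(self, t: np.ndarray, params: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def isf(self, u: np.ndarray, params: np.ndarray) -> np.ndarray:
        """Time t with S0(t) = u; returns inf where the event never occurs."""
        raise NotImplementedError

    def init_params(self, t: np.ndarray, events: np.ndarray) -> np.ndarray:
        """Moment-style starting values for the optimiser."""
        raise NotImplementedError

    # -- natural-scale helpers ----------------------------------------------------
    def natural(self, params: np.ndarray) -> dict[str, float]:
        """Transformed parameters mapped to their natural scale."""
        raise NotImplementedError


def _rate_guess(t: np.ndarray, events: np.ndarray) -> float:
    total_time = float(np.sum(t))
    n_events = max(float(np.sum(events)), 1.0)
    return n_events / max(total_time, _TINY)


class Exponential(Family):
    name = "exponential"
    param_names = ("log_scale",)

    def log_sf(self, t, params):
        return -t / np.exp(params[0])

    def log_hazard(self, t, params):
        return np.full_like(np.asarray(t, dtype=float), -params[0])

    def isf(self, u, params):
        return -np.exp(params[0]) * np.log(u)

    def init_params(self, t, events):
        return np.array([-np.log(_rate_guess(t, events))])

    def natural(self, params):
        return {"scale": float(np.exp(params[0]))}


class Weibull(Family):
    name = "weibull"
    param_names = ("log_scale", "log_shape")

    def log_sf(self, t, params):
        scale, shape = np.exp(params[0]), np.exp(params[1])
        return -((np.maximum(t, _TINY) / scale) ** shape)

    def log_hazard(self, t, params):
        log_scale, log_shape = params[0], params[1]
        shape = np.exp(log_shape)
        return (
            log_shape
            - log_scale
            + (shape - 1.0) * (np.log(np.maximum(t, _TINY)) - log_scale)
        )

    def isf(self, u, params):
        scale, shape = np.exp(params[0]), np.exp(params[1])
        return scale * (-np.log(u)) ** (1.0 / shape)

    def init_params(self, t, events):
        return np.array([-np.log(_rate_guess(t, events)), 0.0])

    def natural(self, params):
        return {"scale": float(np.exp(params[0])), "shape": float(np.exp(params[1]))}


class LogNormal(Family):
    name = "lognormal"
    param_names = ("mu", "log_sigma")

    def log_sf(self, t, params):
        mu, sigma = params[0], np.exp(params[1])
        z = (np.log(np.maximum(t, _TINY)) - mu) / sigma
        return stats.norm.logsf(z)

    def log_hazard(self, t, params):
        mu, sigma = params[0], np.exp(params[1])
        tt = np.maximum(t, _TINY)
        z = (np.log(tt) - mu) / sigma
        log_pdf = stats.norm.logpdf(z) - np.log(sigma) - np.log(tt)
        return log_pdf - stats.norm.logsf(z)

    def isf(self, u, params):
        mu, sigma = params[0], np.exp(params[1])
        return np.exp(mu + sigma * stats.norm.isf(u))

    def init_params(self, t, events):
        ev = events.astype(bool)
        if ev.any():
            logs = np.log(np.maximum(t[ev], _TINY))
            mu = float(np.mean(logs))
            sigma = float(np.std(logs)) or 1.0
        else:  # pragma: no cover - guarded upstream
            mu, sigma = 0.0, 1.0
        return np.array([mu, np.log(sigma)])

    def natural(self, params):
        return {"mu": float(params[0]), "sigma": float(np.exp(params[1]))}


class LogLogistic(Family):
    name = "loglogistic"
    param_names = ("log_scale", "log_shape")

    def log_sf(self, t, params):
        scale, shape = np.exp(params[0]), np.exp(params[1])
        x = shape * (np.log(np.maximum(t, _TINY)) - np.log(scale))
        return -np.logaddexp(0.0, x)

    def log_hazard(self, t, params):
        log_scale, log_shape = params[0], params[1]
        shape = np.exp(log_shape)
        tt = np.maximum(t, _TINY)
        x = shape * (np.log(tt) - log_scale)
        # h(t) = (shape/scale)(t/scale)^(shape-1) * S(t)
        return (
            log_shape
            - log_scale
            + (shape - 1.0) * (np.log(tt) - log_scale)
            - np.logaddexp(0.0, x)
        )

    def isf(self, u, params):
        scale, shape = np.exp(params[0]), np.exp(params[1])
        return scale * (1.0 / u - 1.0) ** (1.0 / shape)

    def init_params(self, t, events):
        ev = events.astype(bool)
        if ev.any():
            med = float(np.median(t[ev]))
        else:  # pragma: no cover
            med = 1.0
        return np.array([np.log(max(med, _TINY)), 0.0])

    def natural(self, params):
        return {"scale": float(np.exp(params[0])), "shape": float(np.exp(params[1]))}


class Gompertz(Family):
    """Gompertz hazard h(t) = a * exp(b t); b < 0 gives a defective
    distribution (a long-term event-free fraction), which is the natural
    shape for transition risks that fade as patients stabilise."""

    name = "gompertz"
    param_names = ("log_a", "b")

    @staticmethod
    def _cum_hazard(t, a, b):
        bt = b * t
        small = np.abs(bt) < 1e-8
        with np.errstate(over="ignore", invalid="ignore"):
            full = a / np.where(small, 1.0, b) * np.expm1(bt)
        # second-order series around b = 0
        series = a * t * (1.0 + bt / 2.0)
        return np.where(small, series, full)

    def log_sf(self, t, params):
        a, b = np.exp(params[0]), params[1]
        return -self._cum_hazard(np.asarray(t, dtype=float), a, b)

    def log_hazard(self, t, params):
        return params[0] + params[1] * np.asarray(t, dtype=float)

    def isf(self, u, params):
        a, b = np.exp(params[0]), params[1]
        h = -np.log(u)
        if abs(b) < 1e-12:
            return h / a
        arg = 1.0 + b * h / a
        with np.errstate(invalid="ignore", divide="ignore"):
            t = np.log(arg) / b
        return np.where(arg > 0.0, t, np.inf)

    def init_params(self, t, events):
        return np.array([np.log(_rate_guess(t, events)), -0.05])

    def natural(self, params):
        return {"a": float(np.exp(params[0])), "b": float(params[1])}


FAMILIES: dict[str, Family] = {
    f.name: f for f in (Exponential(), Weibull(), LogNormal(), LogLogistic(), Gompertz())
}

#: Fixed order used for deterministic tie-breaking in model selection.
FAMILY_ORDER: tuple[str, ...] = (
    "exponential",
    "weibull",
    "lognormal",
    "loglogistic",
    "gompertz",
)


def get_family(name: str) -> Family:
    try:
        return FAMILIES[name]
    except KeyError:
        raise ValueError(
            f"unknown survival family {name!r}; expected one of {FAMILY_ORDER}"
        ) from None
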