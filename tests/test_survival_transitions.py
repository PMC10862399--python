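"""Survival fitting, model selection and cycle-probability conversion."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import integrate

from trdburden._families import FAMILY_ORDER, get_family
from trdburden.states import SUBGROUPS, State, TRANSITIONS
from trdburden.survival_transitions import (
    EstimationError,
    FixedProbs,
    SurvivalFit,
    ZeroEventsError,
    assemble_schedule,
    fit_parametric_survival,
    select_best_family,
    survival_to_cycle_probs,
    validate_mape,
)

TR = (State.NTRD, State.TRD)


def _sim(family, params, n, seed, censor=7.0):
    rng = np.random.default_rng(seed)
    fam = get_family(family)
    t0 = fam.isf(rng.uniform(size=n), np.asarray(params, dtype=float))
    t = np.minimum(t0, censor)
    ev = t0 <= censor
    return t, ev, None


def _make_fit(family, params, transition=TR):
    return SurvivalFit(
        transition=transition,
        family=family,
        params=np.asarray(params, dtype=float),
        beta=np.zeros(0),
        loglik=0.0,
        n_events=1,
        n_at_risk=1,
    )


class TestFitting:
    def test_exponential_mle_matches_closed_form(self):
        lam = 0.10
        t, ev, _ = _sim("exponential", [np.log(1 / lam)], 10_000, 1)
        fit = fit_parametric_survival((t, ev, None), TR, "exponential", covariates=False)
        lam_hat_closed = ev.sum() / t.sum()
        lam_hat = 1.0 / np.exp(fit.params[0])
        assert abs(lam_hat - lam_hat_closed) / lam_hat_closed < 1e-4
        # truth inside the 95% CI on the log-scale parameter
        z = abs(fit.params[0] - np.log(1 / lam)) / fit.params_se[0]
        assert z < 1.96

    def test_all_censored_raises_zero_events(self):
        t = np.full(50, 2.0)
        ev = np.zeros(50, dtype=bool)
        with pytest.raises(ZeroEventsError, match="zero-probability"):
            fit_parametric_survival((t, ev, None), TR, "exponential", covariates=False)

    def test_aic_bic_identities(self):
        t, ev, _ = _sim("weibull", [0.5, np.log(0.8)], 2000, 3)
        for family in FAMILY_ORDER:
            fit = fit_parametric_survival((t, ev, None), TR, family, covariates=False)
            k = fit.n_free_params
            assert abs(fit.aic - (2 * k - 2 * fit.loglik)) < 1e-9
            assert abs(fit.bic - (k * np.log(fit.n_at_risk) - 2 * fit.loglik)) < 1e-9

    def test_weibull_truth_recovered_by_aic_and_bic(self):
        # Weibull with decreasing hazard (shape 0.7)
        t, ev, _ = _sim("weibull", [np.log(8.0), np.log(0.7)], 10_000, 4)
        fits = {
            fam: fit_parametric_survival((t, ev, None), TR, fam, covariates=False)
            for fam in FAMILY_ORDER
        }
        assert min(fits, key=lambda f: fits[f].aic) == "weibull"
        assert min(fits, key=lambda f: fits[f].bic) == "weibull"
        assert select_best_family(fits).family == "weibull"

    def test_aft_covariate_fit_cross_checked_against_lifelines(self):
        lifelines = pytest.importorskip("lifelines")
        import pandas as pd

        rng = np.random.default_rng(8)
        n = 6000
        x = (rng.random(n) < 0.4).astype(float)
        scale, shape, beta = 6.0, 0.8, 0.5
        t0 = scale * np.exp(beta * x) * (-np.log(rng.uniform(size=n))) ** (1 / shape)
        t = np.minimum(t0, 7.0)
        ev = t0 <= 7.0
        X = np.column_stack([x, np.zeros((n, 4))])  # first covariate slot only
        fit = fit_parametric_survival((t, ev, X), TR, "weibull", compute_se=False)

        df = pd.DataFrame({"t": t, "e": ev.astype(int), "x": x})
        aft = lifelines.WeibullAFTFitter().fit(df, duration_col="t", event_col="e")
        ll_scale = float(aft.params_[("lambda_", "Intercept")])
        ll_beta = float(aft.params_[("lambda_", "x")])
        assert abs(fit.params[0] - ll_scale) < 2e-2
        assert abs(fit.beta[0] - ll_beta) < 2e-2


class TestModelSelection:
    def _fits_with_aics(self, aics):
        fits = {}
        for fam, target_aic in zip(FAMILY_ORDER, aics):
            fit = _make_fit(fam, [0.0] if fam == "exponential" else [0.0, 0.0])
            fit.loglik = fit.n_free_params - target_aic / 2.0
            fit.n_at_risk = 100
            fits[fam] = fit
        return fits

    def test_lowest_aic_wins(self):
        fits = self._fits_with_aics([100, 90, 95, 99, 98])
        assert select_best_family(fits).family == FAMILY_ORDER[1]

    def test_exact_tie_broken_by_family_order(self):
        fits = self._fits_with_aics([90, 95, 96, 97, 98])
        # force an exact AIC tie between exponential and weibull
        fits["weibull"].loglik = fits["weibull"].n_free_params - 45.0
        assert fits["weibull"].aic == fits["exponential"].aic
        assert select_best_family(fits).family == "exponential"

    def test_missing_family_raises_with_names(self):
        fits = self._fits_with_aics([1, 2, 3, 4, 5])
        del fits["gompertz"]
        with pytest.raises(EstimationError, match="gompertz"):
            select_best_family(fits)


PARAM_GRID = [
    ("exponential", [np.log(1 / 0.08)]),
    ("weibull", [np.log(9.0), np.log(0.7)]),
    ("weibull", [np.log(4.0), np.log(1.3)]),
    ("lognormal", [2.0, np.log(0.9)]),
    ("loglogistic", [np.log(7.0), np.log(1.4)]),
    ("gompertz", [np.log(0.08), -0.35]),
    ("gompertz", [np.log(0.02), 0.10]),
]


class TestCycleProbs:
    def test_exponential_constant_probability(self):
        lam = 0.0513
        fit = _make_fit("exponential", [np.log(1 / lam)])
        q = survival_to_cycle_probs(fit, None, cycles=10)
        assert np.allclose(q, 1 - np.exp(-lam), atol=1e-12)
        assert abs(q[0] - 0.0500) < 1e-4

    def test_weibull_declining_sequence(self):
        # scale chosen so S(1) = 0.938, i.e. q(1) = 6.2%
        shape = 0.7
        scale = (-np.log(0.938)) ** (-1 / shape)
        fit = _make_fit("weibull", [np.log(scale), np.log(shape)])
        q = survival_to_cycle_probs(fit, None, cycles=3)
        assert abs(q[0] - 0.062) < 1e-12
        assert q[0] > q[1] > q[2]

    @pytest.mark.parametrize("family,params", PARAM_GRID)
    def test_matches_hazard_quadrature_oracle(self, family, params):
        fit = _make_fit(family, params)
        for subgroup in (None, SUBGROUPS[0]):
            q = survival_to_cycle_probs(fit, subgroup, cycles=10)
            for t in range(1, 11):
                H, _ = integrate.quad(
                    lambda u: float(fit.hazard(u, subgroup)),
                    t - 1,
                    t,
                    epsabs=1e-13,
                    epsrel=1e-13,
                    limit=200,
                )
                assert abs(q[t - 1] - (1.0 - np.exp(-H))) < 1e-9

    def test_support_exhaustion_raises(self):
        # lognormal with tiny sigma: survival numerically zero long before cycle 10
        fit = _make_fit("lognormal", [0.0, np.log(1e-3)])
        with pytest.raises(EstimationError, match="support"):
            survival_to_cycle_probs(fit, None, cycles=10)


def _fixed_fit_map(values):
    fits = {tr: FixedProbs(tr, 0.0) for tr in TRANSITIONS}
    fits.update({tr: FixedProbs(tr, v) for tr, v in values.items()})
    return fits


class TestAssembleSchedule:
    def test_all_zero_gives_identity_matrices(self):
        sched = assemble_schedule(_fixed_fit_map({}), SUBGROUPS[0])
        assert np.allclose(sched.probs, np.eye(6)[None], atol=0)

    def test_complement_rule(self):
        values = {
            (State.NTRD, State.TRD): 0.06,
            (State.NTRD, State.NTRD_COMORBID): 0.05,
            (State.NTRD, State.LOW_INTENSITY): 0.10,
            (State.NTRD, State.DEATH): 0.02,
        }
        sched = assemble_schedule(_fixed_fit_map(values), SUBGROUPS[0])
        assert abs(sched.probs[0, 0, 0] - 0.77) < 1e-12
        assert np.allclose(sched.probs.sum(axis=2), 1.0, atol=1e-12)

    def test_oversum_rescales_proportionally_and_is_flagged(self):
        values = {
            (State.NTRD, State.TRD): 0.8,
            (State.NTRD, State.LOW_INTENSITY): 0.6,
        }
        sched = assemble_schedule(_fixed_fit_map(values), SUBGROUPS[0])
        row = sched.probs[0, 0]
        assert sched.rescaled_cycles
        assert abs(row.sum() - 1.0) < 1e-12
        assert abs(row[1] / row[4] - 0.8 / 0.6) < 1e-12  # relative risks preserved

    def test_missing_transition_names_edge(self):
        fits = _fixed_fit_map({})
        del fits[(State.TRD, State.DEATH)]
        with pytest.raises(EstimationError, match="TRD"):
            assemble_schedule(fits, SUBGROUPS[0])

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(
        st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=11, max_size=11)
    )
    def test_rows_sum_to_one_for_random_probabilities(self, qs):
        values = dict(zip(TRANSITIONS, qs))
        sched = assemble_schedule(_fixed_fit_map(values), SUBGROUPS[3])
        assert np.allclose(sched.probs.sum(axis=2), 1.0, atol=1e-12)
        assert (sched.probs >= -1e-15).all() and (sched.probs <= 1 + 1e-15).all()

    def test_competing_mode_matches_monte_carlo_oracle(self):
        lam = 0.4
        fits = _fixed_fit_map({})
        exp_fit = lambda tr: _make_fit("exponential", [np.log(1 / lam)], tr)  # noqa: E731
        fits[(State.NTRD, State.LOW_INTENSITY)] = exp_fit((State.NTRD, State.LOW_INTENSITY))
        fits[(State.NTRD, State.DEATH)] = exp_fit((State.NTRD, State.DEATH))
        sched = assemble_schedule(fits, SUBGROUPS[0], mode="competing")

        n = 1_000_000
        rng = np.random.default_rng(77)
        t1 = rng.exponential(1 / lam, n)
        t2 = rng.exponential(1 / lam, n)
        p_low = np.mean((t1 < t2) & (t1 <= 1.0))
        se = np.sqrt(p_low * (1 - p_low) / n)
        assert abs(sched.probs[0, 0, 4] - p_low) < 3 * se
        # closed form for two competing exponentials
        analytic = 0.5 * (1 - np.exp(-2 * lam))
        assert abs(sched.probs[0, 0, 4] - analytic) < 1e-9
        assert abs(sched.probs[0, 0, 5] - analytic) < 1e-9


class TestMape:
    def test_exact_match_is_zero(self):
        assert validate_mape([1.0, 2.0], [1.0, 2.0]) == 0.0

    def test_symmetric_example(self):
        assert abs(validate_mape([110, 90], [100, 100]) - 10.0) < 1e-12

    def test_zero_observed_raises(self):
        with pytest.raises(ValueError, match="undefined"):
            validate_mape([1.0], [0.0])

    def test_length_mismatch_raises(self):
        with pytest.raises(ValueError, match="equal length"):
            validate_mape([1.0], [1.0, 2.0])
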