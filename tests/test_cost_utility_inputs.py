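"""Negative-binomial count models, cost aggregation and utilities."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from trdburden.cost_utility_inputs import (
    CostInputError,
    UnitCostTable,
    apply_utility_decrement,
    counts_to_costs,
    default_base_utilities,
    fit_nb_count_model,
)
from trdburden.states import COVARIATE_NAMES, SUBGROUPS, State


def _table(n, rng, mean=4.0, theta=1.5, covariate_effects=None, poisson=False):
    """Synthetic patient-year count table with randomised covariates."""
    tab = pd.DataFrame(
        {name: (rng.random(n) < 0.4).astype(float) for name in COVARIATE_NAMES}
    )
    tab["trd"] = (rng.random(n) < 0.15).astype(float)
    tab["comorbid"] = (rng.random(n) < 0.2).astype(float)
    tab["exposure"] = 1.0
    eta = np.zeros(n)
    if covariate_effects:
        for name, b in covariate_effects.items():
            eta += b * tab[name].to_numpy()
    mu = mean * np.exp(eta)
    if poisson:
        y = rng.poisson(mu)
    else:
        y = rng.poisson(rng.gamma(theta, mu / theta))
    tab["outpatient_allcause"] = y
    return tab


class TestNbCountModel:
    def test_parameter_recovery_mean_and_dispersion(self, rng):
        tab = _table(20_000, rng, mean=4.0, theta=1.5, covariate_effects={"trd": 0.4})
        fit = fit_nb_count_model(tab, "outpatient", "allcause")
        lo, hi = fit.conf_int("const")
        assert lo < np.log(4.0) < hi
        lo, hi = fit.conf_int("trd")
        assert lo < 0.4 < hi
        assert abs(fit.dispersion - 1.5) < 0.15

    def test_poisson_limit_mean_equals_sample_mean(self, rng):
        n = 5000
        tab = pd.DataFrame({name: np.zeros(n) for name in COVARIATE_NAMES})
        tab["trd"] = 0.0
        tab["comorbid"] = 0.0
        tab["exposure"] = 1.0
        tab["outpatient_allcause"] = rng.poisson(4.0, n)
        fit = fit_nb_count_model(tab, "outpatient", "allcause")
        assert abs(np.exp(fit.params["const"]) - tab["outpatient_allcause"].mean()) < 1e-6

    def test_doubling_counts_doubles_predictions(self, rng):
        tab = _table(8000, rng, mean=3.0)
        doubled = tab.assign(outpatient_allcause=2 * tab["outpatient_allcause"])
        f1 = fit_nb_count_model(tab, "outpatient", "allcause")
        f2 = fit_nb_count_model(doubled, "outpatient", "allcause")
        g = SUBGROUPS[0]
        for state in (State.NTRD, State.TRD):
            ratio = f2.predict_mean(state, g) / f1.predict_mean(state, g)
            assert abs(ratio - 2.0) < 1e-2

    def test_all_zero_counts_recommends_override(self, rng):
        tab = _table(100, rng)
        tab["outpatient_allcause"] = 0
        with pytest.raises(CostInputError, match="zero-cost override"):
            fit_nb_count_model(tab, "outpatient", "allcause")

    def test_exposure_offset_scales_counts(self, rng):
        # halving exposure with the same counts doubles the fitted rate
        tab = _table(8000, rng, mean=3.0)
        half = tab.assign(exposure=0.5)
        f1 = fit_nb_count_model(tab, "outpatient", "allcause")
        f2 = fit_nb_count_model(half, "outpatient", "allcause")
        ratio = f2.predict_mean(State.NTRD, SUBGROUPS[0]) / f1.predict_mean(
            State.NTRD, SUBGROUPS[0]
        )
        assert abs(ratio - 2.0) < 1e-6


def _mean_counts_frame(values):
    """values: {(state, setting): (all, psy)}; constant across subgroups."""
    rows = []
    for state in (State.NTRD, State.TRD, State.NTRD_COMORBID, State.TRD_COMORBID):
        for g in SUBGROUPS:
            for setting in ("outpatient", "emergency", "inpatient"):
                allc, psy = values.get((state, setting), (0.0, 0.0))
                rows.append(
                    dict(state=state.value, subgroup=g.label, setting=setting,
                         scope="allcause", mean_count=allc)
                )
                rows.append(
                    dict(state=state.value, subgroup=g.label, setting=setting,
                         scope="psychiatric", mean_count=psy)
                )
    return pd.DataFrame(rows)


class TestCountsToCosts:
    UNIT = UnitCostTable(outpatient=100.0, emergency=180.0, inpatient=700.0)

    def test_arithmetic_contract(self):
        frame = _mean_counts_frame(
            {
                (State.NTRD, "outpatient"): (2.0, 0.0),
                (State.NTRD, "emergency"): (0.0, 0.0),
                (State.NTRD, "inpatient"): (1.0, 0.0),
            }
        )
        costs = counts_to_costs(frame, self.UNIT)
        row = costs[(costs.state == "NTRD") & (costs.subgroup == SUBGROUPS[0].label)]
        assert float(row.cost_allcause.iloc[0]) == 2 * 100 + 0 + 1 * 700 == 900

    def test_zero_counts_zero_cost(self):
        costs = counts_to_costs(_mean_counts_frame({}), self.UNIT)
        assert (costs.cost_allcause == 0).all() and (costs.cost_psychiatric == 0).all()

    def test_absorbing_states_present_with_zero_cost(self):
        costs = counts_to_costs(_mean_counts_frame({}), self.UNIT)
        for state in ("low-intensity", "death"):
            sel = costs[costs.state == state]
            assert len(sel) == len(SUBGROUPS)
            assert (sel.cost_allcause == 0).all()

    def test_missing_setting_names_combination(self):
        frame = _mean_counts_frame({})
        frame = frame[~((frame.setting == "emergency") & (frame.state == "TRD"))]
        with pytest.raises(CostInputError, match="TRD.*emergency|emergency"):
            counts_to_costs(frame, self.UNIT)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        counts=st.lists(st.floats(0, 50), min_size=3, max_size=3),
        scale=st.floats(0.1, 10),
    )
    def test_linear_in_counts_and_unit_costs(self, counts, scale):
        base = _mean_counts_frame(
            {
                (State.NTRD, "outpatient"): (counts[0], 0),
                (State.NTRD, "emergency"): (counts[1], 0),
                (State.NTRD, "inpatient"): (counts[2], 0),
            }
        )
        unit2 = UnitCostTable(100.0 * scale, 180.0 * scale, 700.0 * scale)
        c1 = counts_to_costs(base, self.UNIT)
        c2 = counts_to_costs(base.assign(mean_count=base.mean_count * 2), self.UNIT)
        c3 = counts_to_costs(base, unit2)
        np.testing.assert_allclose(c2.cost_allcause, 2 * c1.cost_allcause, rtol=1e-12)
        np.testing.assert_allclose(c3.cost_allcause, scale * c1.cost_allcause, rtol=1e-12)


class TestUtilities:
    def test_seventeen_percent_decrement(self):
        u = apply_utility_decrement({State.NTRD: 0.80, State.TRD: 0.60, State.LOW_INTENSITY: 0.85})
        assert abs(u[State.NTRD_COMORBID] - 0.664) < 1e-12
        assert abs(u[State.TRD_COMORBID] - 0.498) < 1e-12
        assert u[State.DEATH] == 0.0

    def test_zero_decrement_is_identity(self):
        base = default_base_utilities()
        u = apply_utility_decrement(base, 0.0)
        assert u[State.NTRD_COMORBID] == base[State.NTRD]
        assert u[State.TRD_COMORBID] == base[State.TRD]

    @pytest.mark.parametrize("bad", [-0.1, 1.0, 1.5])
    def test_invalid_decrement_rejected(self, bad):
        with pytest.raises(CostInputError, match="decrement"):
            apply_utility_decrement(default_base_utilities(), bad)

    def test_invalid_base_utility_rejected(self):
        with pytest.raises(CostInputError):
            apply_utility_decrement({State.NTRD: 0.0, State.TRD: 0.6, State.LOW_INTENSITY: 0.85})


class TestDerivedStateInputs:
    def test_psychiatric_never_exceeds_allcause(self, base_case):
        si = base_case.state_inputs
        assert (si.cost_psychiatric <= si.cost_allcause + 1e-9).all()

    def test_comorbid_states_cost_more_than_ntrd(self, base_case):
        from trdburden.states import STATE_INDEX

        si = base_case.state_inputs
        ntrd = si.cost_allcause[:, STATE_INDEX[State.NTRD]]
        com = si.cost_allcause[:, STATE_INDEX[State.NTRD_COMORBID]]
        assert (com > ntrd).all()

    def test_high_use_subgroup_comorbid_cost_in_ten_thousands(self, base_case):
        from trdburden.states import STATE_INDEX, SUBGROUP_INDEX, Subgroup

        si = base_case.state_inputs
        g = SUBGROUP_INDEX[Subgroup(">65", "male", True)]
        cost = si.cost_allcause[g, STATE_INDEX[State.NTRD_COMORBID]]
        assert 1e4 < cost < 1e5
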