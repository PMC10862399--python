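"""Derive per-state annual costs and utilities from patient-year records.

Negative-binomial regressions (per service setting and cause scope) predict
mean annual counts at each state x subgroup profile; multiplying by unit
costs gives annual costs of care.  Comorbid-state utilities take a 17%
decrement off their non-comorbid counterparts.
"""

from trdburden import (
    apply_utility_decrement,
    default_generator_config,
    derive_state_inputs,
    generate_cohort,
)
from trdburden.cost_utility_inputs import default_base_utilities, default_unit_costs
from trdburden.states import STATE_INDEX, STATE_ORDER, SUBGROUP_INDEX, Subgroup

cohort = generate_cohort(default_generator_config(n_patients=10_000, seed=42))
inputs = derive_state_inputs(cohort, default_unit_costs())

print("annual cost of care (US$ 2023 per patient-year), reference subgroup"
      " (female, 41-65, no history):")
ref = SUBGROUP_INDEX[Subgroup("41-65", "female", False)]
for state in STATE_ORDER:
    i = STATE_INDEX[state]
    print(
        f"  {state.value:15s} all-cause {inputs.cost_allcause[ref, i]:9.0f}"
        f"   psychiatric {inputs.cost_psychiatric[ref, i]:8.0f}"
    )

hi = SUBGROUP_INDEX[Subgroup(">65", "male", True)]
print(
    f"\nhighest-use subgroup (male, >65, history), comorbid state all-cause cost: "
    f"US${inputs.cost_allcause[hi, STATE_INDEX[STATE_ORDER[2]]]:,.0f} per patient-year"
)

utilities = apply_utility_decrement(default_base_utilities(), decrement=0.17)
print("\nutility weights (QALY per life-year):")
for state, u in utilities.items():
    print(f"  {state.value:15s} {u:.3f}")
print("Costs in the absorbing states are zero by definition; death has utility 0.")
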