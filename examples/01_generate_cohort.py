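"""Generate a synthetic incident-depression cohort and inspect its structure.

The generator emulates a territory-wide EMR extract: 16 demographic
subgroups, competing cause-specific event times through the six-state
disease course, negative-binomial service-use counts, and administrative
censoring after 4-7 years of follow-up.
"""

import numpy as np

from trdburden import (
    crude_transition_probabilities,
    default_generator_config,
    generate_cohort,
)

config = default_generator_config(n_patients=10_000, seed=42)
cohort = generate_cohort(config)

print(f"patients: {cohort.n_patients}")
print(f"state-entry events: {len(cohort.events)}")
print(f"patient-year count rows: {len(cohort.counts)}")
print("\nstate entries (everyone starts in NTRD):")
print(cohort.events["state"].value_counts().to_string())

crude = crude_transition_probabilities(cohort) * 100
print(
    f"\ncrude annual probability of developing treatment resistance, years 1-3: "
    f"{np.round(crude, 2)} %"
)
print(
    "The declining sequence mirrors real incident cohorts: patients who stay "
    "non-resistant become increasingly likely to remain stable."
)
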