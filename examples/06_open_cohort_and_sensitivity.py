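"""Open-cohort scenario plus deterministic and probabilistic sensitivity.

The open cohort introduces one incident cohort per calendar year (19 in
total); each is followed for at most 10 cycles, so a calendar year
aggregates patients diagnosed in the previous decade.  DSA varies one
parameter at a time to its bounds; PSA draws all parameters jointly.
"""

import numpy as np

from trdburden import build_base_case, default_registry, make_runner, run_dsa, run_psa
from trdburden.pipeline import run_open

base = build_base_case(seed=42, n_patients=8_000)

otrace, osumm = run_open(base)
print(f"open cohort, 19 entry years: {osumm['entrants']:,.0f} total entrants")
costs = otrace.annual("cost_allcause") / 1e6
years = otrace.years
print("annual all-cause cost for prevalent cases, 2023-2032 (US$M):")
print("  " + "  ".join(f"{y}:{c:.0f}" for y, c in zip(years[9:], costs[9:])))

bundle = base.bundle()
registry = default_registry(bundle)  # +/-20% variation on every input
runner = make_runner(bundle)

dsa = run_dsa(registry, runner)
print("\ntornado (top 5 drivers of cumulative all-cause cost):")
for _, row in dsa.table.head(5).iterrows():
    print(f"  {row.parameter:28s} swing US${row.swing/1e6:8.1f} M")
print("Entrant count dominates: a given percentage change in new patients"
      "\ntranslates one-for-one into cost change.")

psa = run_psa(registry, runner, n_iter=1000, seed=7)
summ = psa.summary()["cost_allcause_cum"]
print(f"\nPSA (1000 Monte-Carlo iterations): cumulative all-cause cost "
      f"US${summ['mean']/1e6:.1f} M (SD {summ['sd']/1e6:.1f} M)")
print(f"base case: US${dsa.base_outcome/1e6:.1f} M — the PSA mean sits close to it "
      "because the model is near-linear in its inputs.")
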