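# Methods

This note documents the model implemented by `trdburden`, its assumptions,
the parameters that matter, and the design choices made where the design
was genuinely open. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Model structure

A cohort Markov model with six mutually exclusive health states — NTRD
(non-treatment-resistant depression, the initial state), TRD,
NTRD-comorbid, TRD-comorbid, low-intensity service user (an absorbing alive
state proxying recovery), and all-cause death (absorbing) — advanced in
one-year cycles over a 10-cycle horizon. Splitting the comorbidity state
into pre-TRD and post-TRD variants relaxes the memoryless assumption:
transition intensities and costs may differ by disease stage even though
the chain itself carries no memory.

Permitted edges: NTRD → {TRD, NTRD-comorbid, low-intensity, death},
TRD → {TRD-comorbid, low-intensity, death},
NTRD-comorbid → {low-intensity, death},
TRD-comorbid → {low-intensity, death}, plus the stay probability as
complement on every row. An optional NTRD-comorbid → TRD-comorbid edge
exists behind a flag and is off by default: whether comorbid non-resistant
patients should be allowed to acquire treatment resistance is a genuine
structural ambiguity, and the conservative default keeps the comorbid
branch terminal.

Patients are stratified into 16 subgroups (four age bands at diagnosis ×
sex × baseline medical history). Each subgroup gets its own schedule of
per-cycle 6×6 transition matrices and its own state costs.

## Time-varying transition probabilities

For every edge, a cause-specific parametric time-to-event model is fitted
by maximum likelihood, treating competing transitions and the
administrative cut-off as right-censoring. Five families are fitted —
exponential, Weibull, lognormal, log-logistic, Gompertz — and the fit with
the lowest AIC is selected (exact ties break by a fixed family order:
exponential first). BIC is computed alongside and any AIC/BIC disagreement
is logged; a Kaplan–Meier deviation statistic (maximum absolute gap between
the fitted baseline survival and the KM estimate at event times) is
recorded per fit as an automated stand-in for visual curve inspection.

Covariates (age-band dummies, male, history; reference female/41–65/no
history) enter in accelerated-failure-time form for all five families:
S(t|x) = S₀(t·e^(−x'β)). AFT was chosen because lognormal and log-logistic
have no proportional-hazards representation, and time acceleration is well
defined even for Gompertz; β is therefore uniformly a log time-ratio.

Cycle probabilities derive from the fitted survival function as
q(t) = 1 − S(t)/S(t−1), the conditional probability of the event during
cycle t given event-free status at t−1. For the exponential family this is
constant, 1 − e^(−λ); for declining-hazard families it falls cycle on
cycle.

Two conventions deserve explicit statement:

* **Clock.** Survival clocks reset at entry into the source state, but a
  cohort Markov model cannot carry sojourn time without tunnel states, so
  the engine indexes every schedule by cycle since diagnosis. For NTRD
  exits the two clocks coincide (everyone starts in NTRD at time 0); for
  post-TRD and post-comorbid transitions the model-time cycle index is used
  as the time argument. With near-constant post-entry hazards — the default
  study conditions — the approximation is mild; it is visible in the
  internal validation described below.
* **Competing-risk combination.** The default combination of cause-specific
  q(t) values from one source state is summation, with the stay probability
  as complement and proportional rescaling (loudly logged) in the
  pathological case where the sum exceeds one. An alternative exact mode
  ("competing") integrates each cause's hazard against the all-cause
  survival by 48-point Gauss–Legendre quadrature per cycle, yielding crude
  probabilities that can never sum above one; it exists for oracle testing
  and for users who prefer strict competing-risks semantics. The default
  was kept at the conventional summation because, against the synthetic
  study conditions, it validates better: the slight overstatement of each
  net q(t) compensates the discrete model's inability to make two jumps in
  one cycle.

**Internal validation.** Modelled cumulative deaths and low-intensity
entries at cycle 4 (the latest cycle fully covered by every record's
follow-up) are compared with the empirical counts in the estimation
records; the mean absolute percentage error is the validation statistic.
The acceptance suite requires it below 5% at the full cohort size.

## Costs and utilities

Annual service counts (outpatient visits, emergency attendances, inpatient
bed-days; all-cause and psychiatric scopes) are modelled per setting and
scope with NB2 negative-binomial regression (variance μ + μ²/θ) on
patient-year rows, adjusted for the matched covariates plus time-varying
TRD and comorbidity indicators and their interaction, with a log
person-time offset. The interaction term saturates the four active states
so that predictions at the four indicator profiles recover state-specific
means; costs are predicted at covariate profiles (one per state ×
subgroup), not by summing individual predictions — the profile approach
keeps the state-cost table well defined for states a subgroup rarely
visits. After the statsmodels fit, the mean coefficients are polished by a
Newton solve of the mean score at fixed dispersion; this restores exact
moment identities (an intercept-only fitted mean equals the sample mean)
that joint quasi-Newton optimisation loses when the dispersion estimate
sits at its Poisson-limit boundary.

Annual cost = Σ over settings (predicted mean count × unit cost). Unit
costs are 2023 US$ (HK$ at 7.85/US$); the packaged defaults (outpatient
152, emergency 157, bed-day 650) are synthetic stand-ins for public
non-subsidised charges. Low-intensity and death states accrue zero cost by
definition — care in those states is not depression-related — and the
psychiatric scope can never exceed all-cause because psychiatric counts are
a subset.

Utilities default to placeholder values u(NTRD)=0.80, u(TRD)=0.60,
u(low-intensity)=0.85 — deliberately labelled non-literature fixtures;
study-specific values slot in through configuration. Comorbid states take a
17% proportional decrement off their non-comorbid counterparts; death has
utility 0.

## Incidence and scenarios

Annual newly diagnosed patients are projected as mean age-specific
incidence (held constant) × the population projection per five-year age
group, apportioned to subgroups by the reference cohort's sex/history mix
within each age band. The packaged population, rate and uplift tables are
synthetic fixtures reverse-engineered from aggregate figures (the 2023
baseline reproduces 9,147 entrants at 15.0 per 10,000; group populations
are flat within bands and the 40–44 group is assigned to the 41–65 band —
a documented one-year overlap at the band boundary).

Scenario levers: open-cohort plans always multiply 2019–2022 entry years by
1.33 (the social-unrest and pandemic spike is historical record, so it
belongs to both open variants); the pandemic scenario additionally uplifts
2023, either uniformly (+25%, giving 11,433.75) or through a youth-weighted
age-specific profile calibrated once so 2023 entrants total 11,397. With
these fixtures the open plan totals 182,499 entrants (pandemic 184,749)
over 19 cohorts with 8,397–11,705 per year.

## Cohort engine

Expected occupancy propagates as occ(t) = occ(t−1)·P(t) per subgroup.
Accrual conventions: state membership measured at cycle start, transitions
applied at cycle end, no half-cycle correction by default (a half-cycle
option exists but is off — it averages start and end occupancy); deaths
within a cycle accrue no cost and no fraction of a life-year; life-years
include the low-intensity state while "active" counts exclude it;
discounting divides cycle-t amounts by (1+r)^(t−1) with r=0 for main
results and 2.5% available.

The open cohort is an age-structured calendar loop: each entry year injects
its cohort at age 1, every cohort is advanced through its own cycle
schedule for at most 10 cycles and then leaves the model, and a cohort
entering year Y contributes its cycle-1 outcomes to calendar year Y. This
construction is exactly the superposition of shifted closed-cohort runs,
which the test suite asserts to 1e-9.

Headline statistics: case fatality = cumulative deaths / entrants; CAGR =
(V_last/V_first)^(1/(n−1)) − 1 on annual series; per-patient-year subgroup
burdens divide cumulative burden by the subgroup's life-years (not person
counts). Quality-of-life reduction for an attribution group is
(1 − QALY/LY)×100 over that group's states.

## Sensitivity analyses

The parameter registry covers the entrant count, every transition (its
cycle-1 probability as the natural level; perturbation rescales the whole
per-cycle vector and re-complements the stay probability, with row
renormalisation flagged if a row would exceed one), per-state annual cost
levels and state utilities. Bounds default to ±20% where no CI is supplied.
DSA reruns the model at each parameter's bounds with everything else at
base and orders parameters by absolute outcome swing. PSA draws all
parameters jointly — beta for probabilities and utilities (moment-matched
to base and the bound-implied SD), gamma for costs, normal truncated at
zero for entrants, a conventional assignment rather than a data-derived one
— from one seeded generator in fixed registry order, 1000 iterations by
default, reporting outcome means and SDs. Perturbations act on derived
inputs, not on survival coefficients: the DSA parameters are the
probabilities themselves.

## Synthetic study conditions

The generator's defaults define the study conditions and are fixed:

* 25,190 patients diagnosed uniformly over 2014–2016, censored at end-2020
  (4–7 years of follow-up).
* Subgroup mix from independent margins: age bands 10.6 / 20.0 / 55.6 /
  13.8%, 75% female, 28% with baseline history (an alternative mix with the
  10–24 share at 17.0% supports the demographic-shift check).
* NTRD→TRD hazard: Gompertz a=0.082029, b=−0.367279. A negative-shape
  Gompertz declines near-geometrically, which is the only two-parameter
  shape among the five families able to reproduce the printed crude annual
  sequence 6.2/4.4/3.0% comfortably inside ±0.5 pp — a Weibull's
  conditional-probability ratios are tied to a single exponent and cannot
  hit all three years except at the band edges. The parameters were
  calibrated once, semi-analytically (hazard integration against the
  competing exits), before any downstream result was inspected.
* Other transitions exponential with rates 0.0068–0.085; death hazards
  carry strong AFT age effects (the >65 band dies ~5× faster at baseline)
  plus male and history effects, so covariate adjustment is genuinely
  load-bearing.
* Service-use means per state × setting with NB dispersion θ=1.2 and
  log-scale covariate multipliers (older, male, history-positive patients
  use more care), chosen so NTRD all-cause cost sits in the low thousands
  of US$ per patient-year, comorbid states are 2.5–3.5× dearer, the
  psychiatric share lands near one fifth overall, and the highest-use
  subgroup's comorbid-state cost reaches the US$10⁴ range.
* One global seed; per-stage sub-streams (subgroup assignment, event times,
  service counts) spawned from one seed sequence, so the generation is
  vectorised yet byte-reproducible and partially regenerable.

What the generator does **not** emulate: diagnostic coding noise,
prescription-sequence ascertainment of TRD (entry times are generated
directly; real TRD is observed with delay through regimen failures),
within-subgroup heterogeneity beyond the five covariates, seasonal or
calendar-time trends in hazards, and correlation between a patient's
service use and their subsequent transitions. Passing tests therefore
demonstrate the correctness of the estimation and projection machinery
under a faithful data-generating process, not the clinical accuracy of any
particular parameter value taken from real records.

## Numerical choices

* Survival likelihoods are maximised with BFGS from moment-based starts
  (two perturbed restarts on failure); convergence requires the reported
  success flag or a scaled gradient norm below 1e-3, else an error carries
  the final gradient norm. Standard errors come from the inverse of a
  central-difference Hessian.
* Positivity-constrained parameters are optimised on the log scale; the
  Gompertz cumulative hazard uses expm1 with a series fallback for |bt| <
  1e-8.
* Cycle-probability support exhaustion (S(t−1) = 0 before the horizon)
  raises rather than silently clipping.
* Zero-event transitions raise a dedicated error instructing a
  zero-probability override; the pipeline substitutes the override and logs
  it.
* Proportional rescaling of competing probabilities preserves relative
  cause-specific risk and is logged as a warning, since needing it signals
  implausible inputs.
* Problem sizes in the acceptance suite: 25,190-patient generation and
  estimation, 50 replicates × 5 families at n=10,000 for coverage (≥85%
  of 95% CIs covering truth), n=20,000 patient-years for count-model
  recovery, 10⁶ draws for the competing-risks Monte-Carlo oracle, 1000 PSA
  iterations.

## Known limitations

* The cycle-index clock for post-TRD transitions understates early
  post-entry risk for non-constant hazards; tunnel states would remove the
  approximation at the cost of a much larger state space.
* The discrete chain allows one transition per cycle; paths with two
  events inside a year are truncated, which the default combination mode
  partially offsets (see above).
* Costs for recovered (low-intensity) patients are zero by definition;
  background healthcare costs of recovered patients are out of scope.
* Suicide-specific mortality, productivity losses and any societal-
  perspective costs are not modelled.
* PSA distribution assignments are conventions, not estimates from data.
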