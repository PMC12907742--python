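# Methods

## Model structure and assumptions

The engine is a population-level cohort Markov model: occupancy of five
mutually exclusive states (cognitively unimpaired; MCI due to AD; mild,
moderate and severe AD dementia) per 5-year age band and sex, advanced in
annual cycles from 2020 to 2040. It assumes the Markov properties of the
class: memorylessness (flows depend only on current occupancy),
time-homogeneity (transition probabilities constant over calendar time), and
exhaustive, non-overlapping states. "Yearly rates" are treated directly as
annual transition probabilities applied once per cycle — not as instantaneous
hazards converted through exponentials — matching the spreadsheet-style
annual-cycle models this package reimplements; correspondingly, validation
checks that each state's outgoing probabilities sum to ≤ 1, and no half-cycle
correction is applied.

Backward transitions (moderate→mild, severe→moderate) are included to absorb
stage-misclassification noise in the source estimates; they are not claims of
clinical improvement.

### Cycle order

The order of operations within a cycle is fixed for reproducibility
(the underlying class of models does not prescribe one):

1. simultaneous probability flows between disease states, including
   per-state mortality, from start-of-cycle occupancy;
2. age-specific onset (unimpaired → MCI), the only age-varying rate;
3. cohort ageing: 1/5 of each band's survivors advance one band per year
   (standard banded-cohort approximation; the open 100+ band retains);
4. the unimpaired count is recomputed as the national projection minus all
   disease states.

Step 4 makes background demography implicit: births, migration and
non-disease mortality never need their own rates because the projection is
authoritative for total population, while disease states carry explicit
mortality. The cost of this design is that inconsistent inputs (disease
occupancy exceeding a projection cell) are possible; the engine then clamps
the residual at zero and logs a warning rather than failing, since the run
remains informative and the warning pinpoints the offending cell. The
packaged parameter set produces no clamps over the full horizon.

Initialization splits each cell of the base-year projection by prevalence:
AD dementia prevalence × population, divided across severities by the
age-group split; MCI prevalence × population; unimpaired as residual. The
printed severity splits are rounded percentages whose rows sum to
99.99–100.01%; they are renormalised at application so that state occupancy
sums exactly to the projection (validation allows 1e-3 slack on the raw
rows). Because prevalence-based initialization is generally not the
stationary distribution of the transition dynamics, the first few projected
years show a re-equilibration transient under the placeholder transitions;
this is expected and disappears when calibrated transitions are supplied.

## Parameters

Published values shipped in the reference set (2019 GBP, undiscounted,
constant per-person costs over time):

* AD dementia prevalence by band and sex, MCI prevalence and age-specific
  MCI incidence (all-sex; applied identically to both sexes as no sex split
  is published), for bands from 30–34 up; bands below 30 carry zero disease.
* Severity splits by coarse age group (35–64, 65–74, 75–84, 85+), mapped to
  5-year bands by containment; 30–34 uses the youngest group.
* Stage cost ratios (health 0.5548/1.4829/1.7597, social
  0.4261/1.7049/1.7622 for mild/moderate/severe), applied to the
  all-severity AD HCRU cost per band and the all-severity AD social-care
  cost by sex (£12,526 male / £12,480 female); 48% of the dementia
  population is assumed to use formal social care (the multiplier applies to
  AD-specific social care only).
* General-population HCRU by band and sex; general social care £200.26
  (18–64) and £499.89 (65+) — bands 0–19 are costed £0 social care (the
  15–19 band straddles age 18 and is treated as under-18), and bands under
  30 £0 healthcare, since no values are published below 30. Absolute cost
  totals are therefore scoped to ages 30+; every offset against baseline is
  unaffected because under-30 cells are disease-free and identical across
  scenarios.
* Visit prices £33 (primary care) and £465 (NHS memory-clinic/specialist);
  optional annual DMT price (secondary analysis: £1,200 / £11,100 /
  £21,000).
* MCI due to AD is costed at general-population rates: the stage cost ratios
  cover only dementia severities and no AD-specific MCI cost is available.

**Placeholder transition probabilities.** No numeric inter-state transition
probabilities are published; they are mandatory user inputs. The shipped
defaults (MCI→mild 0.15, mild→moderate 0.25, moderate→severe 0.30,
moderate→mild 0.03, severe→moderate 0.02; annual mortality 0.08 / 0.12 /
0.18 / 0.35 for MCI / mild / moderate / severe) are **illustrative**, chosen
for clinical plausibility (stage-mortality ratios of roughly 1.5×) and so
that disease occupancy stays comfortably inside the projection in every cell
(no residual clamping). They are flagged `placeholder` in the provenance log.
Under these defaults the reference baseline lands close to published UK
figures — ~0.9% AD dementia prevalence in 2020 and ~1.8M people eligible for
treatment — without being calibrated to them.

## DMT scenario engine

Efficacy acts as a multiplier `(1 − e × f)` on the two forward edges out of
the treatment-eligible states (MCI→mild, mild→moderate), where `f` is the
treated fraction of the eligible pool in the cycle's starting year. This
blended scaling is algebraically identical to splitting the pool into a
fully-treated fraction `f` with probability `p(1 − e)` and an untreated
remainder, so no individual tracking is needed; people transitioning
backward into mild AD remain covered through the same fraction (memoryless
treatment). Mortality, backward edges and moderate→severe are untouched —
people with moderate/severe AD are not eligible.

Uptake ramps linearly from 0 at the schedule start to its maximum at the
ramp end (0→58% high, 0→25% low, over 2025–2034 in the presets), then stays
flat. The presets take the ramp's literal wording — uptake is exactly 0 in
the 2025 launch year — although the original analysis evidently used a
nonzero first-year value (it reports ~147k people treated in 2025); the
schedule type makes the first-year value configurable, and pre-launch years
are always identical to baseline. New starters are
`max(0, treated(y) − treated(y−1))`: a simple incremental definition that
does not model replacement of leavers, slightly understating initiation
visits when eligibility declines (a conservative choice affecting only
initiation-visit costs). Follow-up visits are charged in the initiation year
on top of the initiation specialist visit.

The per-treated-patient saving is reported as `−annual offset / treated(y)`
per year; cumulative person-year denominators can be formed from the
treatment series directly, since the published headline's denominator
convention is ambiguous.

## Synthetic population generator

The generator emulates the *shape* of an official national projection, not
its values: bands 0–4 … 100+, both sexes, annual tables. The age pyramid is
a stationary-population density — proportional to the survival function of a
logistic lifespan distribution `S(a) = 1/(1 + exp((a − L)/s))` with `L` tied
to the configured median age (L ≈ 2 × median) and `s` (default 6 years)
setting the old-age decline; the open band's weight is the integral of `S`
over [100, ∞). Defaults: 67M people in 2020, +0.35%/year growth, median age
40, ageing drift +0.2 years of longevity per calendar year, mild female tilt
at high ages, and a seeded ±2% per-band lognormal jitter (fixed across
years). These produce a 65+ share rising from ~19.5% to ~23% over
2020–2040 and ~1.3% aged 90+, in the range of UK demography. What it does
*not* emulate: cohort-specific birth waves, migration shocks, or sex-specific
mortality detail — so passing tests demonstrate correct model mechanics on
realistic demographic structure, not calibrated UK forecasts.

`random_model` draws whole parameter sets for property-based testing as
multiplicative perturbations (0.6–1.4×) of the reference regime, with
Dirichlet severity splits and broad-uniform costs. Two regime constraints
are enforced by construction: (1) stage mortalities share a common jitter so
their ordering and plausible spacing survive; (2) each candidate is
projected once and the rare draw that would clamp the residual is
deterministically redrawn from a derived seed. The first constraint reflects
a genuine regime-dependence worth knowing about: if the moderate-vs-mild
mortality gap is made implausibly large, slowing progression keeps people
alive in mild AD long enough that prevalence can *rise* with efficacy — the
directional claim "more efficacy, fewer prevalent cases" is a property of
clinically plausible parameterizations, not of the model class.

## Numerical choices

* Conservation (states sum to the projection per cell) is exact to
  < 1e-6 persons in every projected year; the vectorised cycle is tested to
  1e-9 persons against an independent edge-by-edge ledger oracle.
* The care-model identity — majority-specialist minus majority-primary
  equals £864 (= 2 × (465 − 33)) per treated person-year, initiation visits
  cancelling — is exact on the follow-up cost stream; on multi-billion-pound
  summed totals it holds to ~1e-9 relative (float resolution of differencing
  £1e11 aggregates).
* Config round-trips (save → load) preserve values to 1e-12.
* Cost totals additively decompose (health + social + follow-up + drug) and
  cumulative series are running sums to 1e-6.
* CSV/JSON outputs are byte-reproducible given config and seed.

## Known limitations

* Transition probabilities are placeholders; every quantitative output of
  the shipped reference set is illustrative of mechanics, not a forecast.
* Disease-state mortality is age-constant (only MCI onset varies with age),
  which understates mortality at the oldest ages; the residual-clamp
  warning is the guardrail against the resulting inconsistencies.
* No informal/unpaid care costs, out-of-pocket social care, diagnostic
  capacity costs, adverse-event costs, discounting, inflation adjustment, or
  cost-effectiveness (QALY) analysis; these are out of scope by design.
* Cohort-level treatment (uptake × eligible) cannot represent individual
  treatment histories, discontinuation rules or dose effects.
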