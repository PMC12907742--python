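# admarkov

An age/sex-stratified **cohort Markov model of Alzheimer's disease (AD)
progression** for the UK, with a scenario engine for disease-modifying
therapy (DMT) efficacy, uptake and care model, and a costing layer that
projects annual and cumulative health and social care costs and their
offsets against a no-treatment baseline.

It is written for health economists and epidemiological modellers who want a
reproducible, scriptable version of the spreadsheet-style budget-impact
models used in dementia policy analysis: what happens to AD dementia
prevalence and to NHS/social-care spend between 2020 and 2040 if a DMT with
20–30% efficacy launches in 2025 and uptake ramps to 25–58% of the eligible
population?

## The model

The population is stratified by 5-year age band (0–4 … 100+) and sex, and
occupies five mutually exclusive states:

```
unimpaired → MCI due to AD → mild AD → moderate AD → severe AD
                               ↑________↓   ↑________↓
                            (backward transitions for staging
                             misclassification)
```

Each annual cycle applies, in order:

1. **transition flows** — time-homogeneous annual probabilities
   `p(MCI→mild)`, `p(mild→mod)`, `p(mod→sev)`, backward `p(mod→mild)`,
   `p(sev→mod)`, and per-state mortality, applied simultaneously to
   start-of-cycle occupancy;
2. **onset** — age-specific incidence moves unimpaired people into MCI;
3. **ageing** — one fifth of each 5-year band advances to the next band
   (the open 100+ band retains);
4. **residual** — the unimpaired count is recomputed as national projection
   minus all disease states, which is where background demography (births,
   migration, non-disease mortality) enters.

A DMT scenario multiplies the two forward edges out of the treatment-eligible
states (MCI and mild AD) by `(1 − efficacy × uptake(year))`; uptake ramps
linearly (0 in 2025 → max in 2034 in the shipped presets). Costs per
person-year: general-population healthcare (HCRU) and social care for the
non-AD states; for dementia states, the all-severity AD cost scaled by
stage-specific cost ratios, with 48% formal social-care utilisation.
DMT follow-up adds `4 × £33` (majority-primary) or `2 × £33 + 2 × £465`
(majority-specialist) per treated person-year plus a £465 initiation visit
per new starter.

**Important caveat:** the inter-state transition probabilities have no
published numeric source. The packaged values are clearly flagged
placeholders in a clinically plausible range; supply your own via the config
for quantitative work. Published values (prevalence, incidence, severity
splits, cost ratios, unit costs, in 2019 GBP) ship as the reference
parameter set, and the packaged population projection is a synthetic
stand-in for the official national projection.

## Worked example

```python
from admarkov import (core_scenarios, cost_series, offsets, project,
                      treatment_series, uk_reference_parameters)

params = uk_reference_parameters()
baseline = project(params)                      # no-DMT counterfactual
base_costs = cost_series(baseline, params.costs)

spec = core_scenarios()[1]                      # high uptake, 25% efficacy
traj = project(params, spec)
series = treatment_series(traj, spec)
off = offsets(base_costs, cost_series(traj, params.costs, spec, series), series)
print(f"{traj.at(2040).ad_dementia_total() - baseline.at(2040).ad_dementia_total():,.0f}")
print(f"£{off.cumulative_saving(2040)/1e9:.2f}bn")
```

prints

```
-52,353
£4.68bn
```

— by 2040 the scenario has 52,353 fewer people living with AD dementia than
the baseline, and has cumulatively saved £4.68bn in health and social care
costs (majority-primary follow-up; negative annual offsets are savings).
Running the same grid with majority-specialist follow-up turns the £4.68bn
saving into a £3.95bn net cost — each treated person-year costs £864 more —
which reproduces the study design's central qualitative finding: the care
delivery model matters more than the efficacy level. The `examples/`
directory has one narrative script per capability (baseline projection,
scenario grid, care-model comparison, reported-table arithmetic, synthetic
population generation).

A thin CLI wraps the same pipeline:

```bash
admarkov run --out results/ --seed 1            # baseline + 4 core scenarios
admarkov summarise results/manifest.json        # three-panel summary grid
```

writing trajectory/cost/offset CSVs, a summary grid at five-year marks
(counts, count changes, annual cost changes vs baseline) and a run manifest.
Runs are byte-reproducible given config + seed.

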