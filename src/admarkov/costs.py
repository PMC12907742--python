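"""Costing: trajectories -> annual/cumulative costs and offsets vs baseline.

Three cost streams attach to a projected trajectory:

* **health** — general-population HCRU cost per person-year for the non-AD
  states (unimpaired and MCI due to AD), and the all-severity AD HCRU cost
  scaled by the stage-specific health cost ratio for the dementia states;
* **social** — general-population formal social care (age-65 switch) for the
  non-AD states, and the all-severity AD social-care cost by sex scaled by the
  stage ratio and by the formal-care utilisation fraction (48% by default) for
  the dementia states;
* **followup / drug** — DMT delivery costs driven by the treated counts: the
  care model's visit mix per treated person-year, an initiation specialist
  visit per new starter, and optionally an annual drug price.

MCI due to AD is deliberately costed at general-population rates: the stage
cost ratios cover only the dementia severities, and no AD-specific MCI cost is
available.  Costs are undiscounted, constant per person over time, in 2019
GBP.  Offsets follow the convention scenario minus baseline, so a negative
annual offset is a saving.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .bands import STATE_INDEX, State
from .cohort import StateVector, Trajectory
from .params import CostParameters
from .scenarios import CareModel, ScenarioSpec, TreatmentSeries, treatment_series

__all__ = [
    "CostSeries",
    "OffsetSeries",
    "state_costs",
    "followup_costs",
    "drug_costs",
    "cost_series",
    "offsets",
    "change_vs_baseline",
    "percent_increase",
]

_MILD = STATE_INDEX[State.MILD]
_SEV = STATE_INDEX[State.SEVERE]


@dataclass
class CostSeries:
    """Per-year health / social / follow-up / drug costs with cumulative total."""

    years: list[int]
    health: dict[int, float]
    social: dict[int, float]
    followup: dict[int, float]
    drug: dict[int, float]
    currency: str = "GBP 2019"

    def total(self, year: int) -> float:
        return self.health[year] + self.social[year] + self.followup[year] + self.drug[year]

    def totals(self) -> dict[int, float]:
        return {y: self.total(y) for y in self.years}

    def cumulative(self) -> dict[int, float]:
        out, running = {}, 0.0
        for y in self.years:
            running += self.total(y)
            out[y] = running
        return out

    def to_frame(self, scenario: str = "") -> pd.DataFrame:
        cum = self.cumulative()
        return pd.DataFrame(
            [
                {
                    "year": y,
                    "scenario": scenario,
                    "health_gbp": self.health[y],
                    "social_gbp": self.social[y],
                    "followup_gbp": self.followup[y],
                    "drug_gbp": self.drug[y],
                    "total_gbp": self.total(y),
                    "cumulative_gbp": cum[y],
                }
                for y in self.years
            ]
        )


@dataclass
class OffsetSeries:
    """Scenario-minus-baseline cost differences (negative annual = saving)."""

    years: list[int]
    annual: dict[int, float]
    per_treated_patient: dict[int, float] = field(default_factory=dict)
    currency: str = "GBP 2019"

    def cumulative(self) -> dict[int, float]:
        out, running = {}, 0.0
        for y in self.years:
            running += self.annual[y]
            out[y] = running
        return out

    def cumulative_saving(self, year: int) -> float:
        """Headline figure: cumulative saving by ``year`` (positive = saved)."""
        return -self.cumulative()[year]

    def to_frame(self, scenario: str = "") -> pd.DataFrame:
        cum = self.cumulative()
        return pd.DataFrame(
            [
                {
                    "year": y,
                    "scenario": scenario,
                    "offset_vs_baseline_gbp": self.annual[y],
                    "cumulative_offset_gbp": cum[y],
                    "saving_per_treated_patient_gbp": self.per_treated_patient.get(y),
                }
                for y in self.years
            ]
        )


# ---------------------------------------------------------------------------


def state_costs(state: StateVector, costs: CostParameters) -> tuple[float, float]:
    """(health £, social £) for one year's state occupancy."""
    c = state.counts
    non_ad = c[STATE_INDEX[State.UNIMPAIRED]] + c[STATE_INDEX[State.MCI]]  # (bands, 2)
    dementia = c[_MILD:_SEV + 1]  # (3, bands, 2)

    health = float((non_ad * costs.england_hcru.values).sum())
    health_ratios = np.asarray(costs.ratios.health)  # (3,)
    health += float(
        (dementia.sum(axis=2) * costs.ad_hcru[None, :] * health_ratios[:, None]).sum()
    )

    social_general = costs.social_general_by_band()  # (bands,)
    social = float((non_ad * social_general[:, None]).sum())
    social_ratios = np.asarray(costs.ratios.social)
    social_ad = np.array([costs.social_ad["male"], costs.social_ad["female"]])  # (2,)
    social += float(
        (
            dementia
            * social_ad[None, None, :]
            * social_ratios[:, None, None]
            * costs.social_utilisation
        ).sum()
    )
    return health, social


def followup_costs(
    series: TreatmentSeries, care: CareModel, costs: CostParameters
) -> dict[int, float]:
    """DMT follow-up visit costs per year.

    Each treated person-year incurs the care model's visit mix; each new
    starter additionally incurs the initiation specialist visit(s).  Follow-up
    visits are charged in the initiation year as well.
    """
    p, s = costs.primary_visit_cost, costs.specialist_visit_cost
    per_treated = care.primary_visits_per_year * p + care.specialist_visits_per_year * s
    per_starter = care.initiation_specialist_visits * s
    return {
        y: series.treated[y] * per_treated + series.new_starters[y] * per_starter
        for y in series.years
    }


def drug_costs(series: TreatmentSeries, annual_price: float) -> dict[int, float]:
    """Annual drug spend: treated count x annual price."""
    if annual_price < 0:
        raise ValueError("annual_price must be >= 0")
    return {y: series.treated[y] * annual_price for y in series.years}


def cost_series(
    traj: Trajectory,
    costs: CostParameters,
    scenario: ScenarioSpec | None = None,
    series: TreatmentSeries | None = None,
    drug_price: float | None = None,
) -> CostSeries:
    """Full cost series for a trajectory.

    Follow-up and drug streams require a scenario (or a precomputed treatment
    series); the baseline has both at zero.  ``drug_price`` overrides the
    price in ``costs``; with neither set, drug costs are zero throughout.
    """
    years = traj.years
    health, social = {}, {}
    for y in years:
        h, s = state_costs(traj.at(y), costs)
        health[y], social[y] = h, s

    followup = {y: 0.0 for y in years}
    drug = {y: 0.0 for y in years}
    if scenario is not None or series is not None:
        if series is None:
            series = treatment_series(traj, scenario)
        followup = followup_costs(series, scenario.care_model, costs)
        price = drug_price if drug_price is not None else costs.drug_price_annual
        if price is not None:
            drug = drug_costs(series, price)
    return CostSeries(years=years, health=health, social=social, followup=followup, drug=drug)


def offsets(
    baseline: CostSeries, scenario: CostSeries, series: TreatmentSeries | None = None
) -> OffsetSeries:
    """Annual and cumulative scenario-minus-baseline cost differences.

    With a treatment series, also reports the per-treated-patient saving,
    -annual offset / treated(y), for years with anyone treated.
    """
    if baseline.years != scenario.years:
        raise ValueError("cost series cover different years")
    annual = {y: scenario.total(y) - baseline.total(y) for y in baseline.years}
    per_patient = {}
    if series is not None:
        for y in baseline.years:
            if series.treated.get(y, 0.0) > 0:
                per_patient[y] = -annual[y] / series.treated[y]
    return OffsetSeries(years=baseline.years, annual=annual, per_treated_patient=per_patient)


def _ad_series(obj) -> dict[int, float]:
    if isinstance(obj, Trajectory):
        return obj.ad_dementia_series()
    if isinstance(obj, Mapping):
        return {int(y): float(v) for y, v in obj.items()}
    raise TypeError("expected a Trajectory or a {year: AD count} mapping")


def change_vs_baseline(baseline, scenario) -> dict[int, float]:
    """Per-year change in total AD dementia count, scenario minus baseline.

    Accepts trajectories or plain ``{year: count}`` mappings (e.g. reported
    tables), which must cover the same years.
    """
    b, s = _ad_series(baseline), _ad_series(scenario)
    if sorted(b) != sorted(s):
        raise ValueError("baseline and scenario cover different years")
    return {y: s[y] - b[y] for y in sorted(b)}


def percent_increase(earlier: float, later: float) -> int:
    """Percentage increase from ``earlier`` to ``later``, nearest integer."""
    if earlier <= 0:
        raise ValueError("earlier count must be > 0")
    return round(100.0 * (later - earlier) / earlier)
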