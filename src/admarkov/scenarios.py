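"""Disease-modifying-therapy scenarios: efficacy, uptake ramps, care models.

A DMT is modelled as a multiplicative slowing of forward progression out of
the two treatment-eligible states (MCI due to AD and mild AD dementia): the
MCI->mild and mild->moderate annual probabilities are scaled by
(1 - efficacy x treated fraction).  This blended scaling is algebraically
identical to splitting the eligible pool into a fully-treated fraction f with
probability p(1 - e) and an untreated fraction (1 - f) with probability p.

Uptake ramps linearly from 0 at the schedule start year to its maximum at the
ramp end year, then stays flat.  Treatment is memoryless: the treated count
each year is uptake x eligible with no individual tracking, so people who
transition backward into mild AD dementia remain covered via the same
fraction.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

from .bands import State
from .cohort import StateVector, Trajectory
from .params import TransitionRateSet

__all__ = [
    "UptakeSchedule",
    "CareModel",
    "ScenarioSpec",
    "TreatmentSeries",
    "uptake_at",
    "eligible_count",
    "effective_rates",
    "treatment_series",
    "core_scenarios",
    "MAJORITY_PRIMARY",
    "MAJORITY_SPECIALIST",
    "HIGH_UPTAKE",
    "LOW_UPTAKE",
]


@dataclass(frozen=True)
class UptakeSchedule:
    """Linear ramp: 0 before start_year, max_uptake from ramp_end_year on."""

    start_year: int
    ramp_end_year: int
    max_uptake: float

    def __post_init__(self) -> None:
        if self.start_year >= self.ramp_end_year:
            raise ValueError("start_year must precede ramp_end_year")
        if not (0.0 <= self.max_uptake <= 1.0):
            raise ValueError("max_uptake must be in [0, 1]")


@dataclass(frozen=True)
class CareModel:
    """Follow-up visit mix attached to DMT delivery."""

    label: str
    primary_visits_per_year: int
    specialist_visits_per_year: int
    initiation_specialist_visits: int = 1

    def __post_init__(self) -> None:
        if min(
            self.primary_visits_per_year,
            self.specialist_visits_per_year,
            self.initiation_specialist_visits,
        ) < 0:
            raise ValueError("visit counts must be >= 0")


@dataclass(frozen=True)
class ScenarioSpec:
    """One DMT scenario: efficacy level, uptake schedule, care model, launch."""

    label: str
    efficacy: float
    uptake: UptakeSchedule
    care_model: CareModel
    launch_year: int = 2025

    def __post_init__(self) -> None:
        if not (0.0 <= self.efficacy < 1.0):
            raise ValueError("efficacy must be in [0, 1)")


@dataclass
class TreatmentSeries:
    """Per-year eligibility, uptake, treated count and new starters."""

    years: list[int]
    eligible: dict[int, float]
    uptake: dict[int, float]
    treated: dict[int, float]
    new_starters: dict[int, float]

    def treated_person_years(self) -> float:
        return sum(self.treated.values())


# ---------------------------------------------------------------------------


def uptake_at(schedule: UptakeSchedule, year: int) -> float:
    """Uptake fraction in ``year`` under the linear ramp."""
    if year <= schedule.start_year:
        return 0.0
    if year >= schedule.ramp_end_year:
        return schedule.max_uptake
    span = schedule.ramp_end_year - schedule.start_year
    return schedule.max_uptake * (year - schedule.start_year) / span


def eligible_count(state: StateVector) -> float:
    """Persons eligible for DMT: everyone in MCI due to AD or mild AD dementia."""
    return state.state_total(State.MCI) + state.state_total(State.MILD)


def effective_rates(
    rates: TransitionRateSet, efficacy: float, treated_fraction: float
) -> TransitionRateSet:
    """Treatment-adjusted transition set.

    Only the forward edges out of the eligible states change; backward
    transitions, the moderate->severe edge (moderate AD is not eligible) and
    all mortality edges are untouched.
    """
    if not (0.0 <= efficacy <= 1.0 and 0.0 <= treated_fraction <= 1.0):
        raise ValueError("efficacy and treated_fraction must be in [0, 1]")
    scale = 1.0 - efficacy * treated_fraction
    return replace(
        rates,
        mci_to_mild=rates.mci_to_mild * scale,
        mild_to_moderate=rates.mild_to_moderate * scale,
    )


def treatment_series(traj: Trajectory, scenario: ScenarioSpec) -> TreatmentSeries:
    """Treated counts along a trajectory.

    treated(y) = uptake(y) x eligible(y), zero before launch;
    new_starters(y) = max(0, treated(y) - treated(y-1)) — the simple
    incremental definition, which does not model replacement of leavers and
    therefore understates initiation visits when eligibility declines.
    """
    years = traj.years
    eligible = {y: eligible_count(traj.at(y)) for y in years}
    uptake = {
        y: (uptake_at(scenario.uptake, y) if y >= scenario.launch_year else 0.0)
        for y in years
    }
    treated = {y: uptake[y] * eligible[y] for y in years}
    new_starters = {}
    prev = 0.0
    for y in years:
        new_starters[y] = max(0.0, treated[y] - prev)
        prev = treated[y]
    return TreatmentSeries(
        years=years,
        eligible=eligible,
        uptake=uptake,
        treated=treated,
        new_starters=new_starters,
    )


# ---------------------------------------------------------------------------
# named presets: the four core scenarios of the study design

MAJORITY_PRIMARY = CareModel(
    label="majority_primary",
    primary_visits_per_year=4,
    specialist_visits_per_year=0,
    initiation_specialist_visits=1,
)
MAJORITY_SPECIALIST = CareModel(
    label="majority_specialist",
    primary_visits_per_year=2,
    specialist_visits_per_year=2,
    initiation_specialist_visits=1,
)

HIGH_UPTAKE = UptakeSchedule(start_year=2025, ramp_end_year=2034, max_uptake=0.58)
LOW_UPTAKE = UptakeSchedule(start_year=2025, ramp_end_year=2034, max_uptake=0.25)

_EFFICACY = {"high": 0.30, "medium": 0.25, "low": 0.20}


def core_scenarios(care_model: CareModel = MAJORITY_PRIMARY) -> list[ScenarioSpec]:
    """The four core scenarios: high uptake x {high, medium, low} efficacy,
    plus low uptake x medium efficacy, all launching in 2025."""
    specs = [
        ScenarioSpec(
            label=f"high_uptake_{name}_efficacy",
            efficacy=eff,
            uptake=HIGH_UPTAKE,
            care_model=care_model,
            launch_year=2025,
        )
        for name, eff in _EFFICACY.items()
    ]
    specs.append(
        ScenarioSpec(
            label="low_uptake_medium_efficacy",
            efficacy=_EFFICACY["medium"],
            uptake=LOW_UPTAKE,
            care_model=care_model,
            launch_year=2025,
        )
    )
    return specs
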