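"""Annual-cycle cohort projection of the stratified disease-state populations.

The engine advances a :class:`StateVector` (persons per disease state x 5-year
age band x sex) one calendar year at a time.  Within each cycle the order of
operations is fixed: inter-state transition flows and disease-state mortality
first, then age-specific onset (unimpaired -> MCI), then cohort ageing (one
fifth of each band moves up; the open 100+ band retains), and finally the
cognitively unimpaired population is recomputed as the residual against the
national projection, which is where background demography (births, migration,
non-disease mortality) enters the model.

Transition probabilities are time-homogeneous and, except for onset, identical
across age bands.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .bands import BAND_LABELS, N_BANDS, SEXES, STATE_INDEX, STATES, State
from .params import ModelParameters, TransitionRateSet

__all__ = [
    "StateVector",
    "Trajectory",
    "InitialisationError",
    "initialise_states",
    "step_cycle",
    "project",
]

_UN = STATE_INDEX[State.UNIMPAIRED]
_MCI = STATE_INDEX[State.MCI]
_MILD = STATE_INDEX[State.MILD]
_MOD = STATE_INDEX[State.MODERATE]
_SEV = STATE_INDEX[State.SEVERE]


class InitialisationError(ValueError):
    """Baseline disease occupancy exceeds the national projection in some cell."""


@dataclass
class StateVector:
    """Population counts per (state, age band, sex) at one calendar year.

    ``counts`` has shape (5, n_bands, 2); state order is
    (unimpaired, mci, mild, moderate, severe) and sex order (male, female).
    """

    year: int
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.shape != (len(STATES), N_BANDS, 2):
            raise ValueError(f"bad StateVector shape {self.counts.shape}")

    def state_total(self, state: State) -> float:
        return float(self.counts[STATE_INDEX[state]].sum())

    def ad_dementia_total(self) -> float:
        """People in any AD dementia stage (mild + moderate + severe)."""
        return float(self.counts[_MILD:_SEV + 1].sum())

    def population_by_cell(self) -> np.ndarray:
        """(n_bands, 2) total persons per cell, summed over states."""
        return self.counts.sum(axis=0)

    def copy(self) -> "StateVector":
        return StateVector(self.year, self.counts.copy())

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "year": self.year,
                "state": s.value,
                "age_band": lbl,
                "sex": sex,
                "persons": float(self.counts[k, i, j]),
            }
            for k, s in enumerate(STATES)
            for i, lbl in enumerate(BAND_LABELS)
            for j, sex in enumerate(SEXES)
        ]
        return pd.DataFrame(rows)


@dataclass
class Trajectory:
    """Consecutive yearly StateVectors plus per-year diagnostics."""

    states: list[StateVector]
    incident_mci: dict[int, float] = field(default_factory=dict)
    ad_deaths: dict[int, float] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)

    @property
    def years(self) -> list[int]:
        return [s.year for s in self.states]

    def at(self, year: int) -> StateVector:
        for s in self.states:
            if s.year == year:
                return s
        raise KeyError(f"trajectory does not cover year {year}")

    def ad_dementia_series(self) -> dict[int, float]:
        return {s.year: s.ad_dementia_total() for s in self.states}

    def to_frame(self) -> pd.DataFrame:
        return pd.concat([s.to_frame() for s in self.states], ignore_index=True)


# ---------------------------------------------------------------------------


def initialise_states(params: ModelParameters, year: int) -> StateVector:
    """Baseline occupancy: prevalence splits the projection into states.

    Per (band, sex) cell: AD dementia = AD prevalence x population, divided
    across mild/moderate/severe by the age-group severity split (renormalised
    to sum exactly to 1); MCI = MCI prevalence x population; unimpaired is the
    residual.  A negative residual means the prevalences are inconsistent with
    the projection and raises :class:`InitialisationError` naming the cell.
    """
    if year not in params.population:
        raise KeyError(f"population projection does not cover year {year}")
    pop = params.population[year]  # (n_bands, 2)
    counts = np.zeros((len(STATES), N_BANDS, 2))

    ad_total = params.ad_prevalence.values * pop
    mci = params.mci_prevalence.values * pop
    split = params.severity_split.as_band_matrix()  # (n_bands, 3), normalised

    counts[_MCI] = mci
    counts[_MILD] = ad_total * split[:, 0:1]
    counts[_MOD] = ad_total * split[:, 1:2]
    counts[_SEV] = ad_total * split[:, 2:3]

    residual = pop - counts[1:].sum(axis=0)
    if (residual < -1e-9).any():
        i, j = np.argwhere(residual < -1e-9)[0]
        raise InitialisationError(
            f"disease states exceed projection at band {BAND_LABELS[i]}, {SEXES[j]} "
            f"in {year} (residual {residual[i, j]:.3f})"
        )
    counts[_UN] = np.clip(residual, 0.0, None)
    return StateVector(year=year, counts=counts)


def _age_shift(arr: np.ndarray) -> np.ndarray:
    """Move 1/5 of each band to the next; the open top band retains everyone."""
    out = arr * 0.8
    out[1:] += arr[:-1] * 0.2
    out[-1] += arr[-1] * 0.2  # undo the 0.8 factor on the open band
    return out


def step_cycle(
    state: StateVector,
    rates: TransitionRateSet,
    projection_next: np.ndarray,
    ageing: bool = True,
) -> tuple[StateVector, dict]:
    """Advance one annual cycle; returns (next state, diagnostics).

    Diagnostics carry ``incident_mci``, ``ad_deaths`` and any residual-clamp
    ``warnings`` (a clamped cell signals transition rates inconsistent with the
    national projection; counts are floored at zero and flagged, not raised).
    """
    projection_next = np.asarray(projection_next, dtype=float)
    c = state.counts
    un, mci, mild, mod, sev = c[_UN], c[_MCI], c[_MILD], c[_MOD], c[_SEV]
    r = rates
    m = r.mortality

    # simultaneous probability flows from start-of-cycle occupancy
    new_mci = mci * (1.0 - r.mci_to_mild - m["mci"])
    new_mild = (
        mild * (1.0 - r.mild_to_moderate - m["mild"])
        + mci * r.mci_to_mild
        + mod * r.moderate_to_mild
    )
    new_mod = (
        mod * (1.0 - r.moderate_to_severe - r.moderate_to_mild - m["moderate"])
        + mild * r.mild_to_moderate
        + sev * r.severe_to_moderate
    )
    new_sev = sev * (1.0 - r.severe_to_moderate - m["severe"]) + mod * r.moderate_to_severe
    deaths = mci * m["mci"] + mild * m["mild"] + mod * m["moderate"] + sev * m["severe"]

    # age-specific onset out of the unimpaired pool
    incident = un * r.incidence.values
    new_mci = new_mci + incident

    if ageing:
        new_mci = _age_shift(new_mci)
        new_mild = _age_shift(new_mild)
        new_mod = _age_shift(new_mod)
        new_sev = _age_shift(new_sev)

    counts = np.zeros_like(c)
    counts[_MCI], counts[_MILD], counts[_MOD], counts[_SEV] = (
        new_mci,
        new_mild,
        new_mod,
        new_sev,
    )
    residual = projection_next - counts[1:].sum(axis=0)
    warnings = []
    if (residual < 0).any():
        for i, j in np.argwhere(residual < 0):
            warnings.append(
                f"year {state.year + 1}: disease states exceed projection at "
                f"band {BAND_LABELS[i]}, {SEXES[j]}; unimpaired clamped to 0 "
                f"(excess {-residual[i, j]:.3f} persons)"
            )
        residual = np.clip(residual, 0.0, None)
    counts[_UN] = residual

    diagnostics = {
        "incident_mci": float(incident.sum()),
        "ad_deaths": float(deaths.sum()),
        "warnings": warnings,
    }
    return StateVector(year=state.year + 1, counts=counts), diagnostics


def project(
    params: ModelParameters,
    scenario=None,
    horizon: int | None = None,
    ageing: bool = True,
) -> Trajectory:
    """Chain initialise + annual cycles from base_year to horizon.

    With a :class:`~admarkov.scenarios.ScenarioSpec`, each cycle uses
    treatment-adjusted transition probabilities: the forward progression edges
    out of the treatment-eligible states are scaled by (1 - efficacy x treated
    fraction), where the treated fraction is the scenario's uptake in the
    cycle's starting year.  Deterministic given inputs.
    """
    from .scenarios import effective_rates, uptake_at  # late import: layering

    horizon = params.horizon_year if horizon is None else horizon
    state = initialise_states(params, params.base_year)
    traj = Trajectory(states=[state])
    for year in range(params.base_year, horizon):
        if year + 1 not in params.population:
            raise KeyError(f"population projection does not cover year {year + 1}")
        rates = params.transitions
        if scenario is not None:
            treated_fraction = (
                uptake_at(scenario.uptake, year) if year >= scenario.launch_year else 0.0
            )
            rates = effective_rates(rates, scenario.efficacy, treated_fraction)
        state, diag = step_cycle(state, rates, params.population[year + 1], ageing=ageing)
        traj.states.append(state)
        traj.incident_mci[state.year] = diag["incident_mci"]
        traj.ad_deaths[state.year] = diag["ad_deaths"]
        traj.warnings.extend(diag["warnings"])
    return traj
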