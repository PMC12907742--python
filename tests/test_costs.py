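"""Costing engine: per-state arithmetic, follow-up/drug costs, offsets, reporting."""

import numpy as np
import pytest

from admarkov import (
    MAJORITY_PRIMARY,
    MAJORITY_SPECIALIST,
    REPORTED_AD_COUNTS,
    State,
    StateVector,
    change_vs_baseline,
    core_scenarios,
    cost_series,
    drug_costs,
    followup_costs,
    offsets,
    percent_increase,
    project,
    state_costs,
    treatment_series,
)
from admarkov.bands import BAND_INDEX, N_BANDS, STATE_INDEX
from admarkov.costs import CostSeries
from admarkov.scenarios import TreatmentSeries


def _one_person_state(state: State, band: str, sex: int) -> StateVector:
    counts = np.zeros((5, N_BANDS, 2))
    counts[STATE_INDEX[state], BAND_INDEX[band], sex] = 1.0
    return StateVector(2020, counts)


def _const_series(years, treated, starters=0.0) -> TreatmentSeries:
    return TreatmentSeries(
        years=list(years),
        eligible={y: treated for y in years},
        uptake={y: 1.0 for y in years},
        treated={y: treated for y in years},
        new_starters={y: starters for y in years},
    )


class TestStateCosts:
    def test_severe_male_80_84_health(self, ref_params):
        """One severe-AD male aged 80-84: all-severity AD HCRU x severe ratio."""
        health, _ = state_costs(_one_person_state(State.SEVERE, "80-84", 0), ref_params.costs)
        assert health == pytest.approx(4643.33 * 1.7597, abs=1e-9)

    def test_severe_male_social(self, ref_params):
        """AD social cost x severe ratio x 48% formal-care utilisation."""
        _, social = state_costs(_one_person_state(State.SEVERE, "80-84", 0), ref_params.costs)
        assert social == pytest.approx(12526 * 1.7622 * 0.48, abs=1e-9)

    def test_mci_costed_at_general_population_rates(self, ref_params):
        health, social = state_costs(_one_person_state(State.MCI, "80-84", 1), ref_params.costs)
        assert health == pytest.approx(3505.93)  # England HCRU, female 80-84
        assert social == pytest.approx(499.89)  # general social care, 65+

    def test_social_age_switch(self, ref_params):
        _, s_young = state_costs(_one_person_state(State.UNIMPAIRED, "40-44", 0), ref_params.costs)
        _, s_old = state_costs(_one_person_state(State.UNIMPAIRED, "70-74", 0), ref_params.costs)
        _, s_child = state_costs(_one_person_state(State.UNIMPAIRED, "10-14", 0), ref_params.costs)
        assert (s_young, s_old, s_child) == (200.26, 499.89, 0.0)

    def test_empty_state_costs_nothing(self, ref_params):
        assert state_costs(
            StateVector(2020, np.zeros((5, N_BANDS, 2))), ref_params.costs
        ) == (0.0, 0.0)


class TestFollowupAndDrugCosts:
    def test_majority_primary_visits(self, ref_params):
        series = _const_series([2030], treated=100.0)
        got = followup_costs(series, MAJORITY_PRIMARY, ref_params.costs)
        assert got[2030] == pytest.approx(100 * 4 * 33)

    def test_majority_specialist_visits(self, ref_params):
        series = _const_series([2030], treated=100.0)
        got = followup_costs(series, MAJORITY_SPECIALIST, ref_params.costs)
        assert got[2030] == pytest.approx(100 * (2 * 33 + 2 * 465))

    def test_initiation_visits_charged_per_starter(self, ref_params):
        series = _const_series([2030], treated=100.0, starters=40.0)
        got = followup_costs(series, MAJORITY_PRIMARY, ref_params.costs)
        assert got[2030] == pytest.approx(100 * 4 * 33 + 40 * 465)

    def test_no_treated_no_cost(self, ref_params):
        series = _const_series([2030], treated=0.0)
        assert followup_costs(series, MAJORITY_SPECIALIST, ref_params.costs)[2030] == 0.0

    def test_reported_2040_drug_cost_bounds(self):
        """Published treated count x published prices: £2.4bn / £42.4bn at 1 d.p."""
        series = _const_series([2040], treated=2_018_749.0)
        assert round(drug_costs(series, 1_200.0)[2040] / 1e9, 1) == 2.4
        assert round(drug_costs(series, 21_000.0)[2040] / 1e9, 1) == 42.4

    def test_zero_price(self):
        series = _const_series([2040], treated=2_018_749.0)
        assert drug_costs(series, 0.0)[2040] == 0.0

    def test_care_model_cost_identity(self, ref_params):
        """specialist - primary = 2 x (465 - 33) = £864 per treated person-year;
        initiation visits cancel. Exact over a whole projected scenario."""
        spec_p = core_scenarios(MAJORITY_PRIMARY)[1]
        spec_s = core_scenarios(MAJORITY_SPECIALIST)[1]
        traj = project(ref_params, spec_p)
        series = treatment_series(traj, spec_p)
        cs_p = cost_series(traj, ref_params.costs, spec_p, series)
        cs_s = cost_series(traj, ref_params.costs, spec_s, series)
        for y in traj.years:  # only the follow-up stream differs
            assert cs_s.followup[y] - cs_p.followup[y] == pytest.approx(
                864.0 * series.treated[y], abs=1e-6
            )
        diff = sum(cs_s.total(y) - cs_p.total(y) for y in traj.years)
        assert diff == pytest.approx(864.0 * series.treated_person_years(), rel=1e-9)


class TestCostSeries:
    def test_additivity_and_cumulative_consistency(self, ref_params):
        spec = core_scenarios()[0]
        traj = project(ref_params, spec)
        cs = cost_series(traj, ref_params.costs, spec)
        cum = cs.cumulative()
        running = 0.0
        for y in traj.years:
            assert cs.total(y) == pytest.approx(
                cs.health[y] + cs.social[y] + cs.followup[y] + cs.drug[y]
            )
            running += cs.total(y)
            assert cum[y] == pytest.approx(running, abs=1e-6)

    def test_drug_costs_zero_when_price_absent(self, ref_params):
        assert ref_params.costs.drug_price_annual is None
        spec = core_scenarios()[0]
        traj = project(ref_params, spec)
        cs = cost_series(traj, ref_params.costs, spec)
        assert all(v == 0.0 for v in cs.drug.values())

    def test_drug_price_override_populates_stream(self, ref_params):
        spec = core_scenarios()[0]
        traj = project(ref_params, spec)
        series = treatment_series(traj, spec)
        cs = cost_series(traj, ref_params.costs, spec, series, drug_price=1200.0)
        assert cs.drug[2040] == pytest.approx(series.treated[2040] * 1200.0)


class TestOffsets:
    def _toy_costs(self, totals):
        years = sorted(totals)
        return CostSeries(
            years=years,
            health={y: totals[y] for y in years},
            social={y: 0.0 for y in years},
            followup={y: 0.0 for y in years},
            drug={y: 0.0 for y in years},
        )

    def test_identical_series_offset_zero(self):
        cs = self._toy_costs({2020: 10.0, 2021: 20.0})
        off = offsets(cs, cs)
        assert all(v == 0.0 for v in off.annual.values())

    def test_running_sum_oracle(self):
        base = self._toy_costs({2020: 100.0, 2021: 100.0, 2022: 100.0})
        scen = self._toy_costs({2020: 110.0, 2021: 90.0, 2022: 70.0})
        off = offsets(base, scen)
        assert off.annual == {2020: 10.0, 2021: -10.0, 2022: -30.0}
        assert off.cumulative() == {2020: 10.0, 2021: 0.0, 2022: -30.0}
        assert off.cumulative_saving(2022) == 30.0

    def test_mismatched_years_rejected(self):
        with pytest.raises(ValueError):
            offsets(self._toy_costs({2020: 1.0}), self._toy_costs({2021: 1.0}))

    def test_per_treated_patient_sign_convention(self):
        base = self._toy_costs({2030: 1000.0})
        scen = self._toy_costs({2030: 400.0})  # £600 annual saving
        series = _const_series([2030], treated=3.0)
        off = offsets(base, scen, series)
        assert off.per_treated_patient[2030] == pytest.approx(200.0)

    def test_first_post_launch_offset_nonnegative(self, ref_params):
        """Initiation visits precede progression benefits: treatment begins as a cost."""
        base_cs = cost_series(project(ref_params), ref_params.costs)
        for spec in core_scenarios():
            traj = project(ref_params, spec)
            series = treatment_series(traj, spec)
            cs = cost_series(traj, ref_params.costs, spec, series)
            off = offsets(base_cs, cs, series)
            first_treated = min(y for y in traj.years if series.treated[y] > 0)
            assert off.annual[first_treated] >= 0.0


class TestReportingArithmetic:
    def test_change_vs_baseline_reproduces_reported_panel(self):
        """Differencing the published count panel reproduces the published
        change panel exactly, cell for cell."""
        want = {
            "high_uptake_high_efficacy": {2030: -24_186, 2035: -72_132, 2040: -97_586},
            "high_uptake_medium_efficacy": {2030: -20_135, 2035: -59_839, 2040: -80_543},
            "high_uptake_low_efficacy": {2030: -16_092, 2035: -47_656, 2040: -63_820},
            "low_uptake_medium_efficacy": {2030: -8_730, 2035: -25_688, 2040: -34_086},
        }
        base = REPORTED_AD_COUNTS["no_dmt"]
        for label, expected in want.items():
            got = change_vs_baseline(base, REPORTED_AD_COUNTS[label])
            assert got[2020] == 0 and got[2025] == 0
            for y, v in expected.items():
                assert got[y] == v

    def test_change_vs_baseline_on_trajectories(self, ref_params):
        base = project(ref_params)
        assert all(v == 0.0 for v in change_vs_baseline(base, base).values())
        scen = project(ref_params, core_scenarios()[0])
        diff = change_vs_baseline(base, scen)
        assert diff[2040] < 0

    def test_change_requires_matching_years(self):
        with pytest.raises(ValueError):
            change_vs_baseline({2020: 1.0}, {2021: 1.0})

    @pytest.mark.parametrize(
        "earlier, later, expected",
        [(570_212, 1_038_405, 82), (100, 150, 50), (7, 7, 0)],
    )
    def test_percent_increase(self, earlier, later, expected):
        assert percent_increase(earlier, later) == expected

    def test_percent_increase_undefined_for_zero_base(self):
        with pytest.raises(ValueError):
            percent_increase(0, 10)
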