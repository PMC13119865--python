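"""Resistance-cost attribution: penalty chain and trajectory-scaled savings."""

import numpy as np
import pytest

from copdcue import amr
from copdcue.amr import (
    AMRScenario,
    AMRTrajectory,
    PenaltyChain,
    annual_ddd,
    annual_savings,
    annualise_total,
    apply_penalty,
    display_two_sig,
    penalty_per_prescription,
    prescriptions_per_year,
    reduced_trajectory,
    scenario_costs,
    scenario_grid,
    scenario_savings,
    uk_net_position,
    uk_testing_cost,
)

YEARS = tuple(range(2023, 2041))


def flat_trajectory(rate=0.4, pathogen="mrsa"):
    return AMRTrajectory(pathogen=pathogen, years=YEARS, rates=(rate,) * len(YEARS))


class TestPenaltyChain:
    def test_annualised_global_loss(self):
        annual = annualise_total(1.0e14, 35)
        assert annual == pytest.approx(2.857e12, rel=1e-3)
        assert display_two_sig(annual) == pytest.approx(2.8e12)
        assert annualise_total(70.0, 35) == 2.0
        assert annualise_total(0.0, 35) == 0.0

    def test_nonpositive_horizon_rejected(self):
        with pytest.raises(ValueError):
            annualise_total(1.0, 0)

    def test_global_consumption_chain(self):
        ddds = annual_ddd(14.1, 7.8e9, 365)
        assert ddds == pytest.approx(4.014e10, rel=1e-3)
        assert prescriptions_per_year(ddds, 5) == pytest.approx(8.03e9, rel=1e-3)
        assert annual_ddd(1.0, 1000.0, 365.0) == pytest.approx(365.0)
        assert prescriptions_per_year(10.0, 5.0) == 2.0

    def test_currency_conversion_matches_published_value(self):
        assert 356.96 * 0.800769 == pytest.approx(285.84, abs=0.005)

    def test_rmf_backsolves_from_published_penalty(self):
        # the published penalty divided by the converted cost pins the RMf
        assert 105.76 / 285.84 == pytest.approx(0.37, abs=5e-4)

    def test_canonical_penalty(self, default_params):
        chain = PenaltyChain.from_config(default_params.amr)
        assert penalty_per_prescription(chain) == pytest.approx(105.76, abs=0.01)

    def test_computed_chain_and_divergence_flag(self):
        chain = PenaltyChain(use_canonical=False)
        assert chain.penalty == pytest.approx(105.44, abs=0.01)
        assert chain.derived["usd_per_prescription"] == pytest.approx(355.9, abs=0.1)
        assert chain.derived["divergence_from_canonical_gbp"] == pytest.approx(
            chain.penalty - 105.76, abs=1e-9)

    def test_displayed_intermediates_give_lower_penalty(self):
        # arithmetic on the rounded displayed values, as a cross-check
        usd = 2.8e12 / 8.02e9
        assert usd * 0.800769 * 0.37 == pytest.approx(103.4, abs=0.1)

    def test_invalid_rmf_rejected(self):
        with pytest.raises(ValueError):
            PenaltyChain(rmf=1.5)


class TestApplyPenalty:
    def test_zero_penalty_identity(self, default_params):
        updated = apply_penalty(default_params, 0.0)
        assert updated.costs["antibiotic_course"].mean == 1.84
        assert updated.to_frame().equals(default_params.to_frame())

    def test_penalty_added_to_antibiotic_costs_only(self, default_params):
        updated = apply_penalty(default_params, 105.76)
        assert updated.costs["antibiotic_course"].mean == pytest.approx(107.60)
        assert updated.costs["alternative_antibiotics"].mean == pytest.approx(106.77)
        assert updated.costs["steroid_course"].mean == 0.70
        # original untouched
        assert default_params.costs["antibiotic_course"].mean == 1.84

    @pytest.mark.parametrize("penalty", [7.45, 14.89])
    def test_sensitivity_penalties_accepted(self, default_params, penalty):
        updated = apply_penalty(default_params, penalty)
        assert updated.costs["antibiotic_course"].mean == pytest.approx(1.84 + penalty)


class TestTrajectories:
    def test_zero_reduction_identity(self):
        traj = flat_trajectory(0.4)
        assert reduced_trajectory(traj, 0.0).rates == traj.rates

    def test_quarter_reduction_of_flat_curve(self):
        reduced = reduced_trajectory(flat_trajectory(0.4), 0.25)
        assert all(r == pytest.approx(0.3) for r in reduced.rates)

    def test_rates_stay_in_unit_interval(self):
        reduced = reduced_trajectory(flat_trajectory(0.999), 0.5)
        assert all(0.0 <= r <= 1.0 for r in reduced.rates)

    def test_out_of_range_reduction_rejected(self):
        with pytest.raises(ValueError):
            reduced_trajectory(flat_trajectory(), 1.0)

    def test_missing_base_year_rejected(self):
        traj = AMRTrajectory("mrsa", (2030, 2031), (0.3, 0.3))
        scen = AMRScenario(reduction=0.1, base_annual_cost=1e12, apply_rmf=True)
        with pytest.raises(ValueError):
            scenario_costs(traj, scen)


class TestScenarioCosts:
    def test_flat_trajectory_constant_stream(self):
        scen = AMRScenario(reduction=0.1, base_annual_cost=2.2e12,
                           apply_rmf=True, rmf=0.37, copd_share=0.075)
        stream = scenario_costs(flat_trajectory(0.4), scen)
        np.testing.assert_allclose(stream, 2.2e12 * 0.37 * 0.075)

    def test_rmf_skipped_for_human_population_bases(self):
        scen = AMRScenario(reduction=0.1, base_annual_cost=5.54e11,
                           apply_rmf=False, copd_share=0.075)
        stream = scenario_costs(flat_trajectory(0.4), scen)
        np.testing.assert_allclose(stream, 5.54e11 * 0.075)

    def test_linearity_in_rates(self):
        scen = AMRScenario(reduction=0.1, base_annual_cost=1e12, apply_rmf=True)
        base = scenario_costs(flat_trajectory(0.2), scen)
        rates = tuple(0.2 * (1 + 0.05) ** k for k in range(len(YEARS)))
        doubling = AMRTrajectory("mrsa", YEARS, tuple(2 * r for r in rates))
        single = AMRTrajectory("mrsa", YEARS, rates)
        # ratio to the base year is scale-free; streams coincide
        np.testing.assert_allclose(scenario_costs(doubling, scen),
                                   scenario_costs(single, scen))
        del base

    def test_elementwise_oracle(self):
        rates = tuple(0.3 + 0.01 * k for k in range(len(YEARS)))
        traj = AMRTrajectory("prsp", YEARS, rates)
        scen = AMRScenario(reduction=0.05, base_annual_cost=1.55e11,
                           apply_rmf=False, copd_share=0.075)
        stream = scenario_costs(traj, scen)
        for i, rate in enumerate(rates):
            assert stream[i] == pytest.approx(
                1.55e11 * 0.075 * rate / rates[0], abs=1e-9 * 1.55e11)


class TestSavings:
    def test_identical_streams_zero(self):
        stream = np.full(18, 5.0)
        assert annual_savings(stream, stream) == 0.0

    def test_mismatched_ranges_rejected(self):
        with pytest.raises(ValueError):
            annual_savings(np.ones(18), np.ones(17))

    def test_flat_closed_form(self):
        scen = AMRScenario(reduction=0.1, base_annual_cost=2.2e12,
                           apply_rmf=True, rmf=0.37, copd_share=0.075)
        saving = scenario_savings(flat_trajectory(0.4), scen)
        assert saving == pytest.approx(2.2e12 * 0.37 * 0.075 * 0.1, rel=1e-12)

    def test_monotone_in_reduction(self):
        rates = tuple(0.3 * 1.01 ** k for k in range(len(YEARS)))
        traj = AMRTrajectory("prsp", YEARS, rates)
        savings = [
            scenario_savings(traj, AMRScenario(reduction=r, base_annual_cost=1e12,
                                               apply_rmf=True))
            for r in (0.01, 0.05, 0.10, 0.25)
        ]
        assert all(a < b for a, b in zip(savings, savings[1:]))

    def test_linear_in_base_cost_and_shares(self):
        traj = flat_trajectory(0.4)

        def saving(base, copd, uk):
            return scenario_savings(traj, AMRScenario(
                reduction=0.1, base_annual_cost=base, apply_rmf=False,
                copd_share=copd, uk_share=uk))

        assert saving(2e12, 0.075, 1.0) == pytest.approx(2 * saving(1e12, 0.075, 1.0))
        assert saving(1e12, 0.15, 1.0) == pytest.approx(2 * saving(1e12, 0.075, 1.0))
        assert saving(1e12, 0.075, 0.5) == pytest.approx(0.5 * saving(1e12, 0.075, 1.0))


@pytest.fixture(scope="module")
def grid():
    trajectories = {
        "mrsa": flat_trajectory(0.4, "mrsa"),
        "prsp": AMRTrajectory("prsp", YEARS,
                              tuple(0.25 * 1.015 ** k for k in range(18))),
    }
    bases = {"gdp": 2.2e12, "hospital": 5.54e11, "productivity": 1.55e11}
    return scenario_grid(trajectories, bases)


class TestScenarioGrid:
    def test_full_grid_shape(self, grid):
        # 2 pathogens x 3 UK shares x (3 bases + combined) x 4 reductions
        assert len(grid) == 2 * 3 * 4 * 4
        assert set(grid["cost_basis"]) == {
            "gdp", "hospital", "productivity", "hospital_plus_productivity"}
        assert set(grid["reduction"]) == {0.01, 0.05, 0.10, 0.25}

    def test_combined_equals_sum_of_components(self, grid):
        pivot = grid.pivot_table(index=["pathogen", "uk_share", "reduction"],
                                 columns="cost_basis",
                                 values="annual_savings_gbp")
        np.testing.assert_allclose(
            pivot["hospital_plus_productivity"],
            pivot["hospital"] + pivot["productivity"], rtol=1e-12)

    def test_uk_share_scales_savings(self, grid):
        pivot = grid.pivot_table(index=["pathogen", "cost_basis", "reduction"],
                                 columns="uk_share",
                                 values="annual_savings_gbp")
        np.testing.assert_allclose(pivot[0.5], 0.5 * pivot[1.0], rtol=1e-12)
        np.testing.assert_allclose(pivot[0.25], 0.25 * pivot[1.0], rtol=1e-12)


class TestUKComparison:
    @pytest.mark.parametrize("fraction,patients,cost", [
        (0.30, 34_500, 3_243_000), (0.50, 57_500, 5_405_000), (0.0, 0, 0),
    ])
    def test_testing_costs(self, fraction, patients, cost):
        got_patients, got_cost = uk_testing_cost(115_000, fraction, 94.0)
        assert got_patients == pytest.approx(patients)
        assert got_cost == pytest.approx(cost)

    def test_invalid_fraction_rejected(self):
        with pytest.raises(ValueError):
            uk_testing_cost(115_000, 1.2, 94.0)

    def test_net_position(self):
        assert uk_net_position(0.0, 1.0, 3.243e6) == pytest.approx(-3.243e6)
        assert uk_net_position(118e6, 1.0, 5.405e6) > 0
        # linear in both arguments
        assert uk_net_position(200.0, 0.5, 30.0) == pytest.approx(70.0)


class TestTrajectoryIO:
    def test_csv_round_trip(self, tmp_path):
        traj = flat_trajectory(0.35, "mrsa")
        path = tmp_path / "mrsa.csv"
        traj.to_frame().to_csv(path, index=False)
        back = AMRTrajectory.from_csv(path)
        assert back.pathogen == "mrsa"
        assert back.years == traj.years
        np.testing.assert_allclose(back.rates, traj.rates)
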