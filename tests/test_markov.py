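"""Cohort-model dynamics, discounting and conservation properties."""

import numpy as np
import pytest

from copdcue.markov import (
    DEAD,
    N_STATES,
    CohortTrace,
    StructuralConstants,
    TransitionModel,
    annual_to_cycle_probability,
    arm_totals,
    build_transition_model,
    discount_half_cycle,
    resolve_matrix,
    run_cohort,
    state_cost_vector,
    state_utility_vector,
)


def random_transition_model(rng: np.random.Generator,
                            max_mortality: float = 0.2) -> TransitionModel:
    alive = rng.dirichlet(np.ones(9), size=9)
    disease_death = rng.uniform(0.0, 0.05, size=9)
    mortality = np.sort(rng.uniform(0.0, max_mortality, size=101))
    return TransitionModel(alive, disease_death, mortality)


def random_entry(rng: np.random.Generator) -> np.ndarray:
    entry = rng.dirichlet(np.ones(N_STATES))
    return entry


STRUCT = StructuralConstants()


class TestConversions:
    @pytest.mark.parametrize("q,expected", [(0.0, 0.0), (1.0, 1.0),
                                            (0.04, 1 - 0.96 ** 0.25)])
    def test_annual_to_cycle(self, q, expected):
        assert annual_to_cycle_probability(q) == pytest.approx(expected, abs=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            annual_to_cycle_probability(1.5)

    def test_four_cycles_recover_annual_probability(self):
        q = 0.3
        qc = annual_to_cycle_probability(q)
        assert 1 - (1 - qc) ** 4 == pytest.approx(q, abs=1e-12)


class TestResolveMatrix:
    def test_zero_mortality_preserves_alive_block(self):
        tm = TransitionModel(np.full((9, 9), 1 / 9), np.zeros(9), np.zeros(101))
        M = resolve_matrix(tm, 60.0)
        np.testing.assert_allclose(M[:9, :9], 1 / 9, atol=1e-15)
        assert M[:9, DEAD].sum() == 0.0

    def test_certain_annual_mortality_absorbs_everything(self):
        tm = TransitionModel(np.full((9, 9), 1 / 9), np.zeros(9), np.ones(101))
        M = resolve_matrix(tm, 75.0)
        np.testing.assert_allclose(M[:9, DEAD], 1.0, atol=1e-12)

    @pytest.mark.parametrize("seed", range(20))
    def test_rows_sum_to_one(self, seed):
        tm = random_transition_model(np.random.default_rng(seed))
        for age in (60.0, 75.3, 99.9):
            M = resolve_matrix(tm, age)
            np.testing.assert_allclose(M.sum(axis=1), 1.0, atol=1e-12)
            assert (M >= 0).all() and (M <= 1).all()

    def test_competing_risks_combination(self):
        tm = TransitionModel(np.eye(9), np.full(9, 0.1),
                             np.full(101, 1 - 0.9 ** 4))  # q_cycle = 0.1
        M = resolve_matrix(tm, 60.0)
        expected_death = 1 - 0.9 * 0.9
        np.testing.assert_allclose(M[:9, DEAD], expected_death, atol=1e-12)


class TestDiscounting:
    def test_zero_rate_is_plain_sum(self):
        inc = np.array([5.0, 7.0, 11.0])
        assert discount_half_cycle(inc, 0.0) == pytest.approx(inc.sum())

    def test_single_increment_closed_form(self):
        value = discount_half_cycle([100.0], 0.035, 0.25)
        assert value == pytest.approx(100.0 * 1.035 ** (-0.125), abs=1e-9)
        assert value == pytest.approx(99.571, abs=1e-3)

    def test_later_increments_worth_less(self):
        inc = np.zeros(10)
        inc[0] = 100.0
        first = discount_half_cycle(inc, 0.035)
        inc = np.roll(inc, 5)
        assert discount_half_cycle(inc, 0.035) < first

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError):
            discount_half_cycle([1.0], -0.01)

    @pytest.mark.parametrize("seed", range(5))
    def test_totals_non_increasing_in_rate(self, seed):
        inc = np.random.default_rng(seed).uniform(0, 100, size=160)
        totals = [discount_half_cycle(inc, r) for r in (0.0, 0.015, 0.035, 0.06)]
        assert all(a >= b for a, b in zip(totals, totals[1:]))


class TestRunCohort:
    def test_full_survival_full_utility_gives_forty_qalys(self):
        tm = TransitionModel(np.eye(9), np.zeros(9), np.zeros(101))
        sc = StructuralConstants(annual_discount_rate=0.0)
        entry = np.zeros(N_STATES)
        entry[0] = 1.0
        trace = run_cohort(entry, tm, sc, np.zeros(N_STATES),
                           np.r_[np.ones(9), 0.0])
        assert trace.total_qalys == pytest.approx(40.0, abs=1e-9)

    def test_constant_hazard_geometric_decay(self):
        tm = TransitionModel(np.eye(9), np.full(9, 0.1), np.zeros(101))
        entry = np.zeros(N_STATES)
        entry[4] = 1.0
        trace = run_cohort(entry, tm, STRUCT, np.zeros(N_STATES), np.zeros(N_STATES))
        for t in (0, 1, 10, 100, 160):
            assert trace.occupancy[t, 4] == pytest.approx(0.9 ** t, rel=1e-10)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_naive_matrix_product_oracle(self, seed):
        rng = np.random.default_rng(seed)
        tm = random_transition_model(rng)
        entry = random_entry(rng)
        costs = np.r_[rng.uniform(0, 500, size=9), 0.0]
        utils = np.r_[rng.uniform(0.2, 1.0, size=9), 0.0]
        trace = run_cohort(entry, tm, STRUCT, costs, utils)

        # independent recomputation via explicit successive matrix products
        occ = entry.copy()
        total_cost = total_qaly = 0.0
        for t in range(STRUCT.n_cycles):
            d = 1.035 ** (-(t + 0.5) * 0.25)
            total_cost += d * (occ @ costs)
            total_qaly += d * (occ @ utils) * 0.25
            occ = occ @ resolve_matrix(tm, 60 + 0.25 * t)
        assert trace.total_cost == pytest.approx(total_cost, abs=1e-10)
        assert trace.total_qalys == pytest.approx(total_qaly, abs=1e-10)

    @pytest.mark.parametrize("seed", range(10))
    def test_conservation_and_absorption(self, seed):
        rng = np.random.default_rng(1000 + seed)
        tm = random_transition_model(rng)
        trace = run_cohort(random_entry(rng), tm, STRUCT,
                           np.zeros(N_STATES), np.zeros(N_STATES))
        np.testing.assert_allclose(trace.occupancy.sum(axis=1), 1.0, atol=1e-9)
        dead = trace.occupancy[:, DEAD]
        assert (np.diff(dead) >= -1e-12).all()

    def test_positive_mortality_extinguishes_cohort_eventually(self):
        tm = TransitionModel(np.full((9, 9), 1 / 9), np.zeros(9),
                             np.full(101, 0.05))
        sc = StructuralConstants(end_age=460)  # ten times the usual horizon
        entry = np.zeros(N_STATES)
        entry[0] = 1.0
        trace = run_cohort(entry, tm, sc, np.zeros(N_STATES), np.zeros(N_STATES))
        assert trace.occupancy[-1, DEAD] == pytest.approx(1.0, abs=1e-6)

    def test_invalid_entry_rejected(self):
        tm = TransitionModel(np.eye(9), np.zeros(9), np.zeros(101))
        with pytest.raises(ValueError):
            run_cohort(np.ones(N_STATES), tm, STRUCT,
                       np.zeros(N_STATES), np.zeros(N_STATES))

    def test_discounted_totals_bounded_by_undiscounted(self):
        tm = TransitionModel(np.full((9, 9), 1 / 9), np.zeros(9),
                             np.full(101, 0.05))
        entry = np.zeros(N_STATES)
        entry[0] = 1.0
        trace = run_cohort(entry, tm, STRUCT,
                           np.full(N_STATES, 10.0), np.full(N_STATES, 0.7))
        assert trace.total_cost <= trace.total_cost_undiscounted
        assert trace.total_qalys <= trace.total_qalys_undiscounted


class TestStateVectors:
    def test_cost_vector_prices_resource_use_and_admissions(self, default_params):
        costs = state_cost_vector(default_params)
        cfg = default_params.markov
        expected_stable = sum(
            default_params.costs[item].mean * q
            for item, q in cfg["resource_use"]["stable"].items()
        )
        assert costs[0] == pytest.approx(expected_stable)
        # exacerbation states carry the expected admission cost
        moderate = costs[6]
        assert moderate > costs[3] > costs[0]
        assert costs[DEAD] == 0.0

    def test_utility_vector_scales_gold_utilities(self, default_params):
        utils = state_utility_vector(default_params)
        assert utils[0] == pytest.approx(0.7820)
        assert utils[3] == pytest.approx(0.7820 * 0.85)
        assert utils[6] == pytest.approx(0.7820 * 0.70)
        assert utils[DEAD] == 0.0

    def test_build_transition_model_rows(self, default_params):
        tm = build_transition_model(default_params, np.zeros(101))
        np.testing.assert_allclose(tm.alive_block.sum(axis=1), 1.0, atol=1e-12)


class TestArmTotals:
    def _flat_trace(self, cost_level):
        tm = TransitionModel(np.eye(9), np.zeros(9), np.zeros(101))
        entry = np.zeros(N_STATES)
        entry[0] = 1.0
        return run_cohort(entry, tm, STRUCT,
                          np.r_[np.full(9, cost_level), 0.0],
                          np.r_[np.full(9, 0.8), 0.0])

    def test_identical_arms_zero_increments(self):
        trace = self._flat_trace(10.0)
        totals = arm_totals(trace, trace)
        assert totals.cost_intervention == totals.cost_control
        assert totals.qaly_intervention == totals.qaly_control

    def test_cheaper_states_lower_cost_same_qalys(self):
        totals = arm_totals(self._flat_trace(5.0), self._flat_trace(10.0))
        assert totals.cost_intervention < totals.cost_control
        assert totals.qaly_intervention == pytest.approx(totals.qaly_control)
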