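"""End-to-end two-arm model: decision tree feeding the lifetime cohort model.

`CostUtilityModel` wires the modules together: it rolls back both arm trees,
maps the resulting severity distributions onto cohort entry states, runs the
discounted lifetime simulation for each arm, and combines short-run episode
costs/utilities with lifetime totals into a cost-effectiveness result.

Because only the published table parameters (costs, utilities, pathway
probabilities) carry sampling distributions, the per-cycle transition
matrices are identical across probabilistic draws; the model therefore also
exposes a closed-form discounted occupancy operator so a probabilistic draw
costs two tree rollbacks plus O(states^2) algebra instead of a full cycle
loop.  The two routes are algebraically identical and tested against each
other.
"""

from __future__ import annotations

import numpy as np

from . import markov as mk
from . import synthetic
from .cea import CEResult, icer
from .params import ParameterSet
from .tree import ArmExpectation, build_arm_tree, rollback, severity_distribution

ARMS = ("intervention", "control")


class CostUtilityModel:
    """Deterministic evaluation of both arms under a parameter set."""

    def __init__(self, params: ParameterSet):
        self.params = params
        table = synthetic.mortality_table_from_config(params.mortality)
        self._mortality = table["qx"].to_numpy()
        self._mortality_start_age = int(table["age"].iloc[0])
        self._trees = {arm: build_arm_tree(arm, params) for arm in ARMS}
        self._operator_cache: np.ndarray | None = None

    # -- building blocks ---------------------------------------------------
    def transition_model(self, params: ParameterSet | None = None) -> mk.TransitionModel:
        return mk.build_transition_model(params or self.params, self._mortality,
                                         self._mortality_start_age)

    def arm_expectation(self, arm: str, params: ParameterSet | None = None) -> ArmExpectation:
        return rollback(self._trees[arm], params or self.params)

    def entry_distribution(self, exp: ArmExpectation,
                           params: ParameterSet | None = None) -> np.ndarray:
        params = params or self.params
        return severity_distribution(exp, params.markov["stage_mix"],
                                     params.markov.get("entry_states"))

    def run_arm(self, arm: str, params: ParameterSet | None = None) -> mk.CohortTrace:
        params = params or self.params
        exp = self.arm_expectation(arm, params)
        return mk.run_cohort(
            self.entry_distribution(exp, params),
            self.transition_model(params),
            params.structural,
            mk.state_cost_vector(params),
            mk.state_utility_vector(params),
        )

    def _arm_totals(self, arm: str, params: ParameterSet,
                    markov_cost_qalys) -> tuple[float, float]:
        """Episode (tree) + lifetime (cohort) cost and QALYs for one arm."""
        exp = self.arm_expectation(arm, params)
        episode_years = float(params.tree.get("episode_duration_years", 0.25))
        m_cost, m_qalys = markov_cost_qalys(arm, exp)
        return (exp.expected_cost + m_cost,
                exp.expected_payoff * episode_years + m_qalys)

    # -- full evaluations --------------------------------------------------
    def evaluate(self, params: ParameterSet | None = None) -> CEResult:
        """Tree rollback + explicit cycle-loop cohort run for both arms."""
        params = params or self.params

        def markov_part(arm, exp):
            trace = mk.run_cohort(
                self.entry_distribution(exp, params),
                self.transition_model(params),
                params.structural,
                mk.state_cost_vector(params),
                mk.state_utility_vector(params),
            )
            return trace.total_cost, trace.total_qalys

        ci, qi = self._arm_totals("intervention", params, markov_part)
        cc, qc = self._arm_totals("control", params, markov_part)
        return icer(ci, cc, qi, qc)

    def traces(self, params: ParameterSet | None = None) -> dict[str, mk.CohortTrace]:
        return {arm: self.run_arm(arm, params) for arm in ARMS}

    # -- fast route (fixed transition dynamics) ----------------------------
    def discounted_operator(self) -> np.ndarray:
        """A = sum_t d_t * C_t with C_t the t-step transition product and
        d_t the half-cycle discount factor, so that the discounted lifetime
        total of any per-state increment vector v is entry @ A @ v."""
        if self._operator_cache is None:
            sc = self.params.structural
            tm = self.transition_model()
            disc = mk.discount_factors(sc.n_cycles, sc.annual_discount_rate,
                                       sc.cycle_length_years)
            A = np.zeros((mk.N_STATES, mk.N_STATES))
            C = np.eye(mk.N_STATES)
            for t in range(sc.n_cycles):
                A += disc[t] * C
                age = sc.start_age + t * sc.cycle_length_years
                C = C @ mk.resolve_matrix(tm, age, sc.cycle_length_years)
            self._operator_cache = A
        return self._operator_cache

    def evaluate_fast(self, params: ParameterSet | None = None) -> CEResult:
        """Same result as :meth:`evaluate`, assuming ``params`` differs from
        the construction-time set only in tree/cost/utility values (the
        transition dynamics and horizon are taken from the cached operator)."""
        params = params or self.params
        A = self.discounted_operator()
        c = mk.state_cost_vector(params)
        u = mk.state_utility_vector(params) * params.structural.cycle_length_years

        def markov_part(arm, exp):
            entry = self.entry_distribution(exp, params)
            propagated = entry @ A
            return float(propagated @ c), float(propagated @ u)

        ci, qi = self._arm_totals("intervention", params, markov_part)
        cc, qc = self._arm_totals("control", params, markov_part)
        return icer(ci, cc, qi, qc)
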