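"""Lifetime cohort model: 10 states over three-month cycles from age 60 to 100.

States are the cross of exacerbation severity {stable, mild, moderate} and
GOLD stage {II, III, IV}, plus an absorbing dead state.  Each cycle the
cohort moves by a row-stochastic matrix assembled from (i) severity
transitions, (ii) one-way GOLD progression, (iii) disease-specific excess
mortality and (iv) age-dependent all-cause mortality overlaid by rescaling
the alive rows.  Costs and QALYs accrue per cycle from state-occupancy and
are discounted with a half-cycle (mid-cycle) correction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .params import ParameterSet, StructuralConstants

SEVERITIES = ("stable", "mild", "moderate")
STAGES = ("stage_2", "stage_3", "stage_4")
STATES = tuple(f"{sev}_{stage}" for sev in SEVERITIES for stage in STAGES) + ("dead",)
N_STATES = len(STATES)
DEAD = N_STATES - 1


def state_index(severity: str, stage: str) -> int:
    return SEVERITIES.index(severity) * len(STAGES) + STAGES.index(stage)


def annual_to_cycle_probability(q_annual: float, cycle_length_years: float = 0.25) -> float:
    """Convert an annual event probability to a per-cycle probability.

    Uses the constant-rate identity 1 - (1 - q)^(cycle/year).
    """
    if not (0.0 <= q_annual <= 1.0):
        raise ValueError(f"annual probability {q_annual} outside [0, 1]")
    return 1.0 - (1.0 - q_annual) ** cycle_length_years


@dataclass
class TransitionModel:
    """Alive-state dynamics plus mortality inputs.

    ``alive_block`` is the 9x9 row-stochastic matrix of movements among the
    alive states conditional on survival; ``disease_death`` is the per-cycle
    excess death probability by alive state; ``mortality_annual`` is the
    annual all-cause death probability indexed by single year of age
    starting at ``mortality_start_age``.
    """

    alive_block: np.ndarray
    disease_death: np.ndarray
    mortality_annual: np.ndarray
    mortality_start_age: int = 0

    def __post_init__(self) -> None:
        self.alive_block = np.asarray(self.alive_block, dtype=float)
        self.disease_death = np.asarray(self.disease_death, dtype=float)
        self.mortality_annual = np.asarray(self.mortality_annual, dtype=float)
        if self.alive_block.shape != (N_STATES - 1, N_STATES - 1):
            raise ValueError("alive_block must be 9x9")
        if not np.allclose(self.alive_block.sum(axis=1), 1.0, atol=1e-12):
            raise ValueError("alive_block rows must sum to 1")
        if (self.alive_block < 0).any() or (self.alive_block > 1).any():
            raise ValueError("alive_block entries must lie in [0, 1]")
        if ((self.disease_death < 0) | (self.disease_death > 1)).any():
            raise ValueError("disease_death entries must lie in [0, 1]")
        if ((self.mortality_annual < 0) | (self.mortality_annual > 1)).any():
            raise ValueError("mortality probabilities must lie in [0, 1]")

    def annual_mortality_at(self, age: float) -> float:
        idx = int(np.floor(age)) - self.mortality_start_age
        if idx < 0:
            raise ValueError(f"age {age} below mortality table range")
        idx = min(idx, len(self.mortality_annual) - 1)
        return float(self.mortality_annual[idx])


def build_transition_model(params: ParameterSet, mortality_annual,
                           mortality_start_age: int = 0) -> TransitionModel:
    """Assemble the transition model from the ``markov`` config block."""
    cfg = params.markov
    sev_cfg = cfg["severity_transitions"]
    sev = np.array([[float(sev_cfg[a][b]) for b in SEVERITIES] for a in SEVERITIES])
    if not np.allclose(sev.sum(axis=1), 1.0, atol=1e-9):
        raise ValueError("markov.severity_transitions rows must sum to 1")
    prog = cfg.get("stage_progression", {})
    p23 = float(prog.get("stage_2_to_3", 0.0))
    p34 = float(prog.get("stage_3_to_4", 0.0))
    stage = np.array([
        [1.0 - p23, p23, 0.0],
        [0.0, 1.0 - p34, p34],
        [0.0, 0.0, 1.0],
    ])
    # joint move: severity and stage transitions are independent within a cycle
    alive = np.einsum("ac,bd->abcd", sev, stage).reshape(9, 9)
    dd_cfg = cfg.get("disease_death", {})
    disease_death = np.repeat(
        [float(dd_cfg.get(s, 0.0)) for s in SEVERITIES], len(STAGES)
    )
    return TransitionModel(alive, disease_death, mortality_annual,
                           mortality_start_age=mortality_start_age)


def resolve_matrix(tm: TransitionModel, age: float,
                   cycle_length_years: float = 0.25) -> np.ndarray:
    """Row-stochastic 10x10 matrix for one cycle starting at ``age``.

    All-cause and disease-specific death compete independently:
    q = 1 - (1 - q_ac)(1 - q_ds); surviving mass follows the alive block.
    """
    q_ac = annual_to_cycle_probability(tm.annual_mortality_at(age), cycle_length_years)
    q = 1.0 - (1.0 - q_ac) * (1.0 - tm.disease_death)
    M = np.zeros((N_STATES, N_STATES))
    M[:DEAD, :DEAD] = tm.alive_block * (1.0 - q)[:, None]
    M[:DEAD, DEAD] = q
    M[DEAD, DEAD] = 1.0
    if not np.allclose(M.sum(axis=1), 1.0, atol=1e-12):
        raise RuntimeError("resolved transition matrix rows do not sum to 1")
    return M


def discount_half_cycle(increments, annual_rate: float,
                        cycle_length_years: float = 0.25) -> float:
    """Total of per-cycle increments discounted to mid-cycle.

    The increment of cycle t (t = 0, 1, ...) is weighted by
    (1 + r)^(-(t + 0.5) * cycle_length), the half-cycle reading of
    discrete-time discounting.
    """
    if annual_rate < 0:
        raise ValueError("discount rate must be >= 0")
    inc = np.asarray(increments, dtype=float)
    t = np.arange(len(inc))
    return float(np.sum(inc * (1.0 + annual_rate) ** (-(t + 0.5) * cycle_length_years)))


def discount_factors(n_cycles: int, annual_rate: float,
                     cycle_length_years: float = 0.25) -> np.ndarray:
    t = np.arange(n_cycles)
    return (1.0 + annual_rate) ** (-(t + 0.5) * cycle_length_years)


@dataclass
class CohortTrace:
    """Per-cycle occupancy and accumulated (discounted) costs and QALYs."""

    occupancy: np.ndarray          # (n_cycles + 1, 10); row t = start of cycle t
    cost_increments: np.ndarray    # undiscounted, per cycle
    qaly_increments: np.ndarray    # undiscounted, per cycle
    annual_discount_rate: float
    cycle_length_years: float
    start_age: float

    @property
    def n_cycles(self) -> int:
        return len(self.cost_increments)

    @property
    def total_cost_undiscounted(self) -> float:
        return float(self.cost_increments.sum())

    @property
    def total_qalys_undiscounted(self) -> float:
        return float(self.qaly_increments.sum())

    @property
    def total_cost(self) -> float:
        return discount_half_cycle(self.cost_increments, self.annual_discount_rate,
                                   self.cycle_length_years)

    @property
    def total_qalys(self) -> float:
        return discount_half_cycle(self.qaly_increments, self.annual_discount_rate,
                                   self.cycle_length_years)

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(self.occupancy[:-1], columns=list(STATES))
        frame.insert(0, "cycle", np.arange(self.n_cycles))
        frame.insert(1, "age", self.start_age
                     + np.arange(self.n_cycles) * self.cycle_length_years)
        frame["cost_increment"] = self.cost_increments
        frame["qaly_increment"] = self.qaly_increments
        disc = discount_factors(self.n_cycles, self.annual_discount_rate,
                                self.cycle_length_years)
        frame["cost_increment_discounted"] = self.cost_increments * disc
        frame["qaly_increment_discounted"] = self.qaly_increments * disc
        return frame


def state_cost_vector(params: ParameterSet) -> np.ndarray:
    """Per-cycle cost by state: resource-use quantities priced at unit costs,
    plus the expected cost of admission events in exacerbation states."""
    cfg = params.markov
    admission = cfg.get("admission_probability", {})
    costs = np.zeros(N_STATES)
    for s_idx, severity in enumerate(SEVERITIES):
        per_cycle = 0.0
        for item, quantity in cfg.get("resource_use", {}).get(severity, {}).items():
            if item not in params.costs:
                raise ValueError(f"markov.resource_use.{severity}: unknown cost item {item!r}")
            per_cycle += params.costs[item].mean * float(quantity)
        per_cycle += float(admission.get(severity, 0.0)) * params.costs["copd_hospital_stay"].mean
        for g_idx in range(len(STAGES)):
            costs[s_idx * len(STAGES) + g_idx] = per_cycle
    return costs


def state_utility_vector(params: ParameterSet) -> np.ndarray:
    """Utility weight by state: GOLD-stage utility scaled by the exacerbation
    multiplier of the severity level; dead = 0."""
    cfg = params.markov
    multipliers = cfg.get("exacerbation_utility_multiplier",
                          {"stable": 1.0, "mild": 1.0, "moderate": 1.0})
    utilities = np.zeros(N_STATES)
    for s_idx, severity in enumerate(SEVERITIES):
        m = float(multipliers.get(severity, 1.0))
        for g_idx, stage in enumerate(STAGES):
            utilities[s_idx * len(STAGES) + g_idx] = params.utilities[stage].value * m
    return utilities


def run_cohort(entry, tm: TransitionModel, sc: StructuralConstants,
               state_costs, state_utilities) -> CohortTrace:
    """Propagate the cohort over the full horizon and accrue increments.

    Increment of cycle t uses start-of-cycle occupancy: QALYs as
    occupancy . utility x cycle length, costs as occupancy . state cost.
    Discounting is applied on readout via :func:`discount_half_cycle`.
    """
    entry = np.asarray(entry, dtype=float)
    if entry.shape != (N_STATES,):
        raise ValueError(f"entry distribution must have {N_STATES} states")
    if abs(entry.sum() - 1.0) > 1e-9 or (entry < -1e-12).any():
        raise ValueError("entry distribution must be a probability vector")
    c = np.asarray(state_costs, dtype=float)
    u = np.asarray(state_utilities, dtype=float)
    n = sc.n_cycles

    occupancy = np.empty((n + 1, N_STATES))
    cost_inc = np.empty(n)
    qaly_inc = np.empty(n)
    occ = entry.copy()
    for t in range(n):
        occupancy[t] = occ
        cost_inc[t] = occ @ c
        qaly_inc[t] = (occ @ u) * sc.cycle_length_years
        age = sc.start_age + t * sc.cycle_length_years
        occ = occ @ resolve_matrix(tm, age, sc.cycle_length_years)
    occupancy[n] = occ
    return CohortTrace(occupancy, cost_inc, qaly_inc,
                       sc.annual_discount_rate, sc.cycle_length_years, sc.start_age)


@dataclass
class ArmTotals:
    cost_intervention: float
    qaly_intervention: float
    cost_control: float
    qaly_control: float


def arm_totals(intervention_trace: CohortTrace, control_trace: CohortTrace) -> ArmTotals:
    """Discounted lifetime cost and QALY totals feeding the CEA module."""
    return ArmTotals(
        cost_intervention=intervention_trace.total_cost,
        qaly_intervention=intervention_trace.total_qalys,
        cost_control=control_trace.total_cost,
        qaly_control=control_trace.total_qalys,
    )
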