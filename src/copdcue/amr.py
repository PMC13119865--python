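"""Attaching antimicrobial-resistance costs to antibiotic prescribing.

Two complementary procedures:

* **Per-prescription penalty** — divides a projected global GDP loss from
  resistance across the global volume of antibiotic prescriptions, converts
  to GBP and scales by a resistance-modulating factor (RMf, the fraction of
  the resistance burden attributable to human consumption).  The resulting
  penalty is added to every antibiotic-course cost in the decision model.
* **Trajectory-scaled savings** — anchors an annual global AMR cost to the
  2023 resistance rate of a proxy pathogen (MRSA or PRSP), scales it along
  the projected rate trajectory to 2040, and values a testing-induced
  constant relative reduction in resistance as a yearly savings stream,
  with a COPD prescribing share, optional RMf, UK cost shares and a
  comparison against national testing costs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .params import ParameterSet

logger = logging.getLogger(__name__)

# Cost items that represent a dispensed antibiotic course.
ANTIBIOTIC_COST_KEYS = ("antibiotic_course", "alternative_antibiotics")


@dataclass(frozen=True)
class AMRTrajectory:
    """Yearly resistance proportions for one proxy pathogen."""

    pathogen: str
    years: tuple
    rates: tuple

    def __post_init__(self) -> None:
        if len(self.years) != len(self.rates):
            raise ValueError("years and rates must have equal length")
        if any(not (0.0 <= r <= 1.0) for r in self.rates):
            raise ValueError("resistance rates must lie in [0, 1]")

    def rate_at(self, year: int) -> float:
        try:
            return self.rates[self.years.index(year)]
        except ValueError:
            raise ValueError(f"{self.pathogen}: year {year} not in trajectory") from None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"year": self.years, "rate": self.rates,
                             "pathogen": self.pathogen})

    @classmethod
    def from_csv(cls, path, pathogen: str | None = None) -> "AMRTrajectory":
        frame = pd.read_csv(path, comment="#")
        name = pathogen or (frame["pathogen"].iloc[0] if "pathogen" in frame else "unknown")
        return cls(pathogen=str(name),
                   years=tuple(int(y) for y in frame["year"]),
                   rates=tuple(float(r) for r in frame["rate"]))


def reduced_trajectory(base: AMRTrajectory, reduction: float) -> AMRTrajectory:
    """Apply a constant relative reduction to every yearly rate."""
    if not (0.0 <= reduction < 1.0):
        raise ValueError(f"reduction {reduction} outside [0, 1)")
    return AMRTrajectory(pathogen=base.pathogen, years=base.years,
                         rates=tuple(r * (1.0 - reduction) for r in base.rates))


# ---------------------------------------------------------------------------
# Per-prescription penalty chain
# ---------------------------------------------------------------------------

def annualise_total(total: float, horizon_years: float) -> float:
    """Average annual burden of a multi-year total loss."""
    if horizon_years <= 0:
        raise ValueError("horizon must be strictly positive")
    return total / horizon_years


def display_two_sig(value: float) -> float:
    """Truncate to two significant figures (display convention of the chain)."""
    if value == 0:
        return 0.0
    import math
    exp = math.floor(math.log10(abs(value)))
    factor = 10.0 ** (exp - 1)
    return math.trunc(value / factor) * factor


def annual_ddd(rate_per_1000_per_day: float, population: float,
               days_per_year: float = 365.0) -> float:
    """Defined daily doses consumed per year at a given consumption rate."""
    if rate_per_1000_per_day < 0 or population <= 0 or days_per_year <= 0:
        raise ValueError("consumption inputs must be positive")
    return rate_per_1000_per_day / 1000.0 * population * days_per_year


def prescriptions_per_year(annual_ddd_count: float, course_days: float) -> float:
    """Prescription courses per year given a standard course length."""
    if course_days <= 0:
        raise ValueError("course length must be strictly positive")
    return annual_ddd_count / course_days


@dataclass
class PenaltyChain:
    """Full derivation of the per-prescription resistance penalty.

    Carries both the computed chain and the canonical published intermediate
    values; ``penalty`` follows the canonical values when ``use_canonical``
    (the default), and any divergence between the two chains is flagged.
    """

    total_gdp_loss_usd: float = 1.0e14
    horizon_years: float = 35.0
    ddd_per_1000_per_day: float = 14.1
    population: float = 7.8e9
    course_days: float = 5.0
    exchange_rate_gbp_per_usd: float = 0.800769
    rmf: float = 0.37
    use_canonical: bool = True
    canonical_usd_per_prescription: float = 356.96
    canonical_gbp_per_prescription: float = 285.84
    canonical_penalty_gbp: float = 105.76
    derived: dict = field(default_factory=dict, init=False)

    def __post_init__(self) -> None:
        if not (0.0 < self.rmf <= 1.0):
            raise ValueError(f"RMf {self.rmf} outside (0, 1]")
        annual_cost = annualise_total(self.total_gdp_loss_usd, self.horizon_years)
        ddds = annual_ddd(self.ddd_per_1000_per_day, self.population)
        prescriptions = prescriptions_per_year(ddds, self.course_days)
        usd = annual_cost / prescriptions
        gbp = usd * self.exchange_rate_gbp_per_usd
        self.derived = {
            "annual_cost_usd": annual_cost,
            "annual_cost_usd_display": display_two_sig(annual_cost),
            "annual_ddd": ddds,
            "prescriptions_per_year": prescriptions,
            "usd_per_prescription": usd,
            "gbp_per_prescription": gbp,
            "penalty_gbp": gbp * self.rmf,
        }
        self.derived["divergence_from_canonical_gbp"] = (
            self.derived["penalty_gbp"] - self.canonical_penalty_gbp
        )
        if abs(self.derived["divergence_from_canonical_gbp"]) > 0.005:
            logger.warning(
                "computed penalty £%.2f diverges from canonical £%.2f "
                "(published intermediates are not mutually consistent)",
                self.derived["penalty_gbp"], self.canonical_penalty_gbp,
            )

    @property
    def penalty(self) -> float:
        if self.use_canonical:
            return self.canonical_gbp_per_prescription * self.rmf
        return self.derived["penalty_gbp"]

    @classmethod
    def from_config(cls, amr_cfg: dict) -> "PenaltyChain":
        canonical = amr_cfg.get("canonical", {})
        return cls(
            total_gdp_loss_usd=float(amr_cfg.get("gdp_loss_total_usd", 1.0e14)),
            horizon_years=float(amr_cfg.get("horizon_years", 35)),
            ddd_per_1000_per_day=float(amr_cfg.get("ddd_per_1000_per_day", 14.1)),
            population=float(amr_cfg.get("population", 7.8e9)),
            course_days=float(amr_cfg.get("course_days", 5)),
            exchange_rate_gbp_per_usd=float(amr_cfg.get("exchange_rate_gbp_per_usd", 0.800769)),
            rmf=float(amr_cfg.get("rmf", 0.37)),
            use_canonical=bool(amr_cfg.get("use_canonical", True)),
            canonical_usd_per_prescription=float(canonical.get("usd_per_prescription", 356.96)),
            canonical_gbp_per_prescription=float(canonical.get("gbp_per_prescription", 285.84)),
            canonical_penalty_gbp=float(canonical.get("penalty_gbp", 105.76)),
        )


def penalty_per_prescription(chain: PenaltyChain) -> float:
    """The per-prescription resistance penalty in GBP (see :class:`PenaltyChain`)."""
    return chain.penalty


def apply_penalty(params: ParameterSet, penalty: float) -> ParameterSet:
    """Return a copy with the penalty added to every antibiotic-course cost."""
    if penalty < 0:
        raise ValueError("penalty must be >= 0")
    updated = params.copy()
    for key in ANTIBIOTIC_COST_KEYS:
        updated.costs[key].mean += penalty
    return updated


# ---------------------------------------------------------------------------
# Trajectory-scaled annual savings
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AMRScenario:
    """One cell of the savings analysis grid."""

    reduction: float
    base_annual_cost: float
    apply_rmf: bool
    rmf: float = 0.37
    copd_share: float = 0.075
    uk_share: float = 1.0
    base_year: int = 2023

    def __post_init__(self) -> None:
        if not (0.0 < self.reduction < 1.0):
            raise ValueError("reduction must lie in (0, 1)")
        if not (0.0 < self.copd_share < 1.0):
            raise ValueError("copd_share must lie in (0, 1)")
        if not (0.0 < self.uk_share <= 1.0):
            raise ValueError("uk_share must lie in (0, 1]")


def scenario_costs(traj: AMRTrajectory, scen: AMRScenario,
                   anchor_rate: float | None = None) -> np.ndarray:
    """Yearly COPD-attributable AMR cost stream under a trajectory.

    cost_t = base_annual_cost x (rate_t / rate_base_year) x RMf-if-applied
    x copd_share.  The RMf applies only to the GDP-derived cost basis; the
    hospital and productivity bases already concern the human population.
    ``anchor_rate`` overrides the base-year rate used as the denominator:
    a testing-reduced trajectory stays anchored to the usual-care base-year
    rate, so its lower rates translate into lower costs.
    """
    base_rate = anchor_rate if anchor_rate is not None else traj.rate_at(scen.base_year)
    if base_rate == 0:
        raise ValueError(f"{traj.pathogen}: zero resistance rate in base year")
    factor = scen.base_annual_cost * (scen.rmf if scen.apply_rmf else 1.0) * scen.copd_share
    return factor * np.asarray(traj.rates) / base_rate


def annual_savings(usual: np.ndarray, tested: np.ndarray) -> float:
    """Mean yearly difference between the usual-care and tested cost streams."""
    usual = np.asarray(usual, dtype=float)
    tested = np.asarray(tested, dtype=float)
    if usual.shape != tested.shape:
        raise ValueError("cost streams must cover the same years")
    return float(np.mean(usual - tested))


def scenario_savings(traj: AMRTrajectory, scen: AMRScenario) -> float:
    """Annual savings from a constant relative resistance reduction."""
    anchor = traj.rate_at(scen.base_year)
    usual = scenario_costs(traj, scen, anchor_rate=anchor)
    tested = scenario_costs(reduced_trajectory(traj, scen.reduction), scen,
                            anchor_rate=anchor)
    return annual_savings(usual, tested) * scen.uk_share


def scenario_grid(
    trajectories: dict[str, AMRTrajectory],
    bases: dict[str, float],
    reductions=(0.01, 0.05, 0.10, 0.25),
    uk_shares=(1.0, 0.5, 0.25),
    rmf: float = 0.37,
    copd_share: float = 0.075,
    rmf_bases: tuple = ("gdp",),
) -> pd.DataFrame:
    """Annual savings for the full pathogen x reduction x cost-basis x
    UK-share grid, plus the additive hospital+productivity combination."""
    rows = []
    for pathogen, traj in trajectories.items():
        for uk_share in uk_shares:
            for basis, base_cost in bases.items():
                for reduction in reductions:
                    scen = AMRScenario(
                        reduction=reduction, base_annual_cost=base_cost,
                        apply_rmf=basis in rmf_bases, rmf=rmf,
                        copd_share=copd_share, uk_share=uk_share,
                    )
                    rows.append({
                        "pathogen": pathogen, "uk_share": uk_share,
                        "cost_basis": basis, "reduction": reduction,
                        "annual_savings_gbp": scenario_savings(traj, scen),
                    })
    frame = pd.DataFrame(rows)
    if {"hospital", "productivity"} <= set(bases):
        combined = (
            frame[frame["cost_basis"].isin(["hospital", "productivity"])]
            .groupby(["pathogen", "uk_share", "reduction"], as_index=False)
            ["annual_savings_gbp"].sum()
        )
        combined["cost_basis"] = "hospital_plus_productivity"
        frame = pd.concat([frame, combined], ignore_index=True)
    return frame


# ---------------------------------------------------------------------------
# UK testing-cost comparison
# ---------------------------------------------------------------------------

def uk_testing_cost(annual_diagnoses: float, exacerbation_fraction: float,
                    unit_cost: float) -> tuple[float, float]:
    """(patients tested per year, annual testing cost in GBP)."""
    if annual_diagnoses < 0 or unit_cost < 0:
        raise ValueError("inputs must be nonnegative")
    if not (0.0 <= exacerbation_fraction <= 1.0):
        raise ValueError("exacerbation fraction must lie in [0, 1]")
    patients = annual_diagnoses * exacerbation_fraction
    return patients, patients * unit_cost


def uk_net_position(savings: float, uk_share: float, testing_cost: float) -> float:
    """Annual UK-attributable savings net of the testing programme cost."""
    if not (0.0 < uk_share <= 1.0):
        raise ValueError("uk_share must lie in (0, 1]")
    return savings * uk_share - testing_cost
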