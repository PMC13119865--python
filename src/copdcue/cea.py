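"""Cost-effectiveness calculus and sensitivity analyses.

Incremental cost-effectiveness ratios with dominance classification, net
monetary benefit, one-way deterministic sensitivity analysis with the
±39.2% bound rule, break-even (threshold) price search, and Monte-Carlo
probabilistic sensitivity analysis with cost-effectiveness plane and
acceptability-curve outputs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .params import ParameterSet

_EPS = 1e-9


@dataclass(frozen=True)
class CEResult:
    """Per-arm totals, incrementals and ICER/dominance classification."""

    cost_intervention: float
    cost_control: float
    qaly_intervention: float
    qaly_control: float

    @property
    def incremental_cost(self) -> float:
        return self.cost_intervention - self.cost_control

    @property
    def incremental_qaly(self) -> float:
        return self.qaly_intervention - self.qaly_control

    @property
    def classification(self) -> str:
        dc, dq = self.incremental_cost, self.incremental_qaly
        if abs(dc) < _EPS and abs(dq) < _EPS:
            return "equivalent"
        if dc < 0 and dq > 0:
            return "dominant"
        if dc > 0 and dq < 0:
            return "dominated"
        if abs(dq) < _EPS:  # equal effectiveness, unequal cost
            return "weakly_dominant" if dc < 0 else "weakly_dominated"
        return "icer"

    @property
    def icer(self) -> float | None:
        """Ratio reported only when the trade-off is real (both increments
        nonzero with agreeing signs); dominance cases carry no number."""
        if self.classification == "icer":
            return self.incremental_cost / self.incremental_qaly
        return None

    def nmb(self, wtp: float) -> float:
        return nmb(self.incremental_cost, self.incremental_qaly, wtp)

    def summary(self) -> dict:
        return {
            "cost_intervention": self.cost_intervention,
            "cost_control": self.cost_control,
            "qaly_intervention": self.qaly_intervention,
            "qaly_control": self.qaly_control,
            "incremental_cost": self.incremental_cost,
            "incremental_qaly": self.incremental_qaly,
            "icer": self.icer,
            "classification": self.classification,
        }


def icer(cost_intervention: float, cost_control: float,
         qaly_intervention: float, qaly_control: float) -> CEResult:
    """Build a :class:`CEResult`; dominance is classified before any ratio."""
    values = (cost_intervention, cost_control, qaly_intervention, qaly_control)
    if not all(np.isfinite(values)):
        raise ValueError("ICER inputs must be finite")
    return CEResult(cost_intervention, cost_control, qaly_intervention, qaly_control)


def nmb(incremental_cost: float, incremental_qaly: float, wtp: float) -> float:
    """Net monetary benefit lambda * dQALY - dCost at willingness-to-pay lambda."""
    if wtp < 0:
        raise ValueError("willingness-to-pay threshold must be >= 0")
    return wtp * incremental_qaly - incremental_cost


# ---------------------------------------------------------------------------
# One-way deterministic sensitivity analysis
# ---------------------------------------------------------------------------

# Default relative half-width: a 95% interval for a parameter whose SE is
# 20% of its mean (1.96 * 0.2 = 0.392).
DSA_RELATIVE_RANGE = 0.392

# The twelve parameters of the published one-way analysis.
DEFAULT_DSA_ITEMS = (
    "costs.rp21_test",
    "costs.ae_without_admission",
    "costs.copd_hospital_stay",
    "costs.antibiotic_course",
    "utilities.partially_recovered",
    "utilities.fully_recovered",
    "probabilities.control.antibiotics_initial",
    "probabilities.hospitalisation.control_bacterial",
    "probabilities.hospitalisation.control_viral",
    "probabilities.intervention.antibiotics_initial",
    "probabilities.hospitalisation.intervention_ab",
    "probabilities.hospitalisation.intervention_st_ab",
)


def dsa_bounds(path: str, base: float,
               relative_range: float = DSA_RELATIVE_RANGE) -> tuple[float, float]:
    """Default one-way bounds base*(1 -/+ range), capped at 1 for items that
    are probabilities or utilities."""
    lo = base * (1.0 - relative_range)
    hi = base * (1.0 + relative_range)
    if path.startswith(("probabilities.", "utilities.")):
        hi = min(hi, 1.0)
        lo = max(lo, 0.0)
    return lo, hi


@dataclass(frozen=True)
class DSAResult:
    item: str
    base: float
    lo: float
    hi: float
    result_at_lo: CEResult
    result_at_hi: CEResult


def one_way_dsa(model, item: str, lo: float | None = None,
                hi: float | None = None) -> DSAResult:
    """Re-run the full pipeline at each extreme of one parameter."""
    base = model.params.get_value(item)
    if lo is None or hi is None:
        d_lo, d_hi = dsa_bounds(item, base)
        lo = d_lo if lo is None else lo
        hi = d_hi if hi is None else hi
    if not (lo <= base <= hi):
        raise ValueError(f"{item}: bounds ({lo}, {hi}) do not bracket base {base}")
    if item.startswith(("probabilities.", "utilities.")) and hi > 1.0:
        raise ValueError(f"{item}: upper bound {hi} outside admissible range")

    def run_at(value: float) -> CEResult:
        params = model.params.copy()
        params.set_value(item, value)
        return model.evaluate(params)

    return DSAResult(item, base, lo, hi, run_at(lo), run_at(hi))


def dsa_table(model, items=DEFAULT_DSA_ITEMS) -> pd.DataFrame:
    """One-way analysis over ``items``; layout mirrors the published table."""
    rows = []
    for item in items:
        res = one_way_dsa(model, item)
        rows.append({
            "parameter": item,
            "base": res.base,
            "minimum": res.lo,
            "icer_at_minimum": _classification_text(res.result_at_lo),
            "maximum": res.hi,
            "icer_at_maximum": _classification_text(res.result_at_hi),
        })
    return pd.DataFrame(rows)


def _classification_text(result: CEResult) -> str:
    if result.icer is not None:
        return f"{result.icer:.0f}"
    return result.classification


# ---------------------------------------------------------------------------
# Threshold (break-even price) analysis
# ---------------------------------------------------------------------------

def threshold_price(model, price_item: str = "costs.rp21_test",
                    wtp: float = 20_000.0, tol: float = 0.01,
                    bracket_hi: float = 1.0e5) -> float:
    """Price at which the intervention's net monetary benefit crosses zero.

    The price enters the intervention arm's cost exactly once, so NMB is
    strictly decreasing and linear in it; a sign-change bracket is located
    and bisected to ``tol`` (£).
    """
    def nmb_at(price: float) -> float:
        params = model.params.copy()
        params.set_value(price_item, price)
        return model.evaluate_fast(params).nmb(wtp)

    lo, hi = 0.0, float(bracket_hi)
    nmb_lo, nmb_hi = nmb_at(lo), nmb_at(hi)
    if nmb_lo < 0 or nmb_hi > 0:
        raise ValueError(
            f"no break-even price in [{lo}, {hi}]: NMB({lo}) = {nmb_lo:.2f}, "
            f"NMB({hi}) = {nmb_hi:.2f}"
        )
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if nmb_at(mid) > 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


# ---------------------------------------------------------------------------
# Probabilistic sensitivity analysis
# ---------------------------------------------------------------------------

@dataclass
class PSASampleSet:
    """Monte-Carlo draws of (incremental cost, incremental QALY)."""

    seed: int
    draws: np.ndarray  # shape (n, 2): columns dCost, dQALY

    @property
    def n(self) -> int:
        return len(self.draws)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.draws,
                            columns=["incremental_cost", "incremental_qaly"])


def sample_parameter_draws(params: ParameterSet, n: int,
                           rng: np.random.Generator) -> dict[str, np.ndarray]:
    """Vectorised draws for every distribution-carrying item.

    Items are visited in a fixed deterministic order so a given seed always
    yields the same draw set; items without a valid distribution (fixed
    utilities, zero SEs) stay at their point value.
    """
    draws: dict[str, np.ndarray] = {}
    for path, item in params.iter_items():
        spec = item.spec
        if spec is None:
            continue
        try:
            draws[path] = spec.sample(rng, size=n)
        except Exception as exc:  # pragma: no cover - defensive
            raise RuntimeError(f"sampling failed for {path}: {exc}") from exc
    return draws


def run_psa(model, n: int | None = None, seed: int = 0) -> PSASampleSet:
    """Monte-Carlo PSA: every draw re-samples all distribution-carrying
    parameters (shared draws across arms) and re-runs tree + cohort model
    for both arms."""
    params = model.params
    if n is None:
        n = params.structural.psa_draws
    if n < 0:
        raise ValueError("number of draws must be >= 0")
    rng = np.random.default_rng(seed)
    draws = sample_parameter_draws(params, n, rng)

    working = params.copy()
    out = np.empty((n, 2))
    for i in range(n):
        for path, values in draws.items():
            working.set_value(path, float(values[i]))
        result = model.evaluate_fast(working)
        out[i, 0] = result.incremental_cost
        out[i, 1] = result.incremental_qaly
    if not np.all(np.isfinite(out)):
        raise RuntimeError("PSA produced non-finite incremental values")
    return PSASampleSet(seed=seed, draws=out)


DEFAULT_WTP_GRID = np.arange(0.0, 50_001.0, 1_000.0)


@dataclass
class CEAC:
    """Probability the intervention is cost-effective across thresholds."""

    thresholds: np.ndarray
    probabilities: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"wtp_threshold": self.thresholds,
                             "p_cost_effective": self.probabilities})

    def at(self, wtp: float) -> float:
        idx = int(np.argmin(np.abs(self.thresholds - wtp)))
        if abs(self.thresholds[idx] - wtp) > 1e-9:
            raise ValueError(f"threshold {wtp} not on the CEAC grid")
        return float(self.probabilities[idx])


def ceac(samples: PSASampleSet, thresholds=DEFAULT_WTP_GRID) -> CEAC:
    """Fraction of draws with positive net monetary benefit at each
    threshold; draws exactly at NMB = 0 count half."""
    if samples.n == 0:
        raise ValueError("cannot build a CEAC from an empty sample set")
    thresholds = np.asarray(thresholds, dtype=float)
    dc = samples.draws[:, 0]
    dq = samples.draws[:, 1]
    nmb_matrix = thresholds[:, None] * dq[None, :] - dc[None, :]
    probs = (nmb_matrix > 0).mean(axis=1) + 0.5 * (nmb_matrix == 0).mean(axis=1)
    return CEAC(thresholds=thresholds, probabilities=probs)
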