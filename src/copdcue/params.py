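"""Model inputs: unit costs, utilities, pathway probabilities and structural constants.

Every input carries the distribution used for probabilistic sensitivity
analysis: Gamma for costs, Beta for probabilities and utilities, parameterised
from the published mean and standard error by the method of moments (the
standard convention in health-economic models, where sources report only
moments and a distribution family).
"""

from __future__ import annotations

import copy
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Iterator

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

DEFAULT_CONFIG_PATH = Path(__file__).parent / "data" / "default_config.yaml"


class ConfigError(ValueError):
    """A configuration file failed schema or range validation."""


@dataclass(frozen=True)
class GammaSpec:
    """Shape/scale Gamma parameterisation matching a (mean, se) pair."""

    shape: float
    scale: float

    @property
    def mean(self) -> float:
        return self.shape * self.scale

    @property
    def sd(self) -> float:
        return math.sqrt(self.shape) * self.scale

    def sample(self, rng: np.random.Generator, size=None):
        return rng.gamma(self.shape, self.scale, size=size)


@dataclass(frozen=True)
class BetaSpec:
    """Alpha/beta Beta parameterisation matching a (mean, se) pair."""

    alpha: float
    beta: float

    @property
    def mean(self) -> float:
        return self.alpha / (self.alpha + self.beta)

    @property
    def sd(self) -> float:
        n = self.alpha + self.beta
        return math.sqrt(self.alpha * self.beta / (n * n * (n + 1.0)))

    def sample(self, rng: np.random.Generator, size=None):
        return rng.beta(self.alpha, self.beta, size=size)


def gamma_from_moments(mean: float, se: float, *, name: str = "item") -> GammaSpec:
    """Method-of-moments Gamma: shape = (mean/se)^2, scale = se^2/mean.

    Raises :class:`ConfigError` for non-positive mean or SE (a degenerate SE
    has no Gamma representation; such items are held fixed instead).
    """
    if not (mean > 0.0):
        raise ConfigError(f"{name}: Gamma requires mean > 0, got {mean}")
    if not (se > 0.0):
        raise ConfigError(f"{name}: Gamma requires se > 0, got {se}")
    return GammaSpec(shape=(mean / se) ** 2, scale=se * se / mean)


def beta_from_moments(
    mean: float,
    se: float,
    *,
    name: str = "item",
    invalid_policy: str = "raise",
) -> BetaSpec:
    """Method-of-moments Beta for a probability or utility with given SE.

    With nu = mean(1-mean)/se^2 - 1, alpha = mean*nu and beta = (1-mean)*nu.
    A Beta with the requested moments exists only when se^2 < mean(1-mean).
    ``invalid_policy`` controls the impossible case: ``"raise"`` rejects it,
    ``"clamp"`` shrinks the SE to 0.95*sqrt(mean(1-mean)) with a warning so a
    typo'd source SE still yields a usable (very diffuse) distribution.
    """
    if not (0.0 < mean < 1.0):
        raise ConfigError(f"{name}: Beta requires 0 < mean < 1, got {mean}")
    if not (se > 0.0):
        raise ConfigError(f"{name}: Beta requires se > 0, got {se}")
    variance_cap = mean * (1.0 - mean)
    if se * se >= variance_cap:
        if invalid_policy == "clamp":
            clamped = 0.95 * math.sqrt(variance_cap)
            logger.warning(
                "%s: se %.4g is incompatible with mean %.4g "
                "(se^2 >= mean(1-mean)); clamped to %.4g",
                name, se, mean, clamped,
            )
            se = clamped
        else:
            raise ConfigError(
                f"{name}: se {se} incompatible with mean {mean} "
                f"(requires se^2 < mean(1-mean) = {variance_cap:.4g})"
            )
    nu = variance_cap / (se * se) - 1.0
    return BetaSpec(alpha=mean * nu, beta=(1.0 - mean) * nu)


@dataclass
class CostItem:
    """A unit cost in 2022 GBP with its Gamma sampling distribution."""

    name: str
    mean: float
    se: float

    def __post_init__(self) -> None:
        if self.mean < 0 or self.se < 0:
            raise ConfigError(f"{self.name}: cost mean/se must be >= 0")

    @property
    def spec(self) -> GammaSpec | None:
        if self.se == 0:
            return None
        return gamma_from_moments(self.mean, self.se, name=self.name)


@dataclass
class ProbabilityItem:
    """A pathway probability with its Beta sampling distribution."""

    name: str
    mean: float
    se: float
    invalid_policy: str = "raise"

    def __post_init__(self) -> None:
        if not (0.0 <= self.mean <= 1.0):
            raise ConfigError(f"{self.name}: probability {self.mean} outside [0, 1]")
        if self.se < 0:
            raise ConfigError(f"{self.name}: se must be >= 0")

    @property
    def spec(self) -> BetaSpec | None:
        if self.se == 0 or self.mean in (0.0, 1.0):
            return None
        return beta_from_moments(
            self.mean, self.se, name=self.name, invalid_policy=self.invalid_policy
        )


@dataclass
class UtilityItem:
    """A health-state utility weight; ``fixed`` items (dead = 0) are never sampled."""

    name: str
    value: float
    se: float = 0.0
    fixed: bool = False

    def __post_init__(self) -> None:
        if self.fixed:
            return
        if not (0.0 < self.value <= 1.0):
            raise ConfigError(f"{self.name}: utility {self.value} outside (0, 1]")
        if self.se < 0:
            raise ConfigError(f"{self.name}: se must be >= 0")

    @property
    def spec(self) -> BetaSpec | None:
        if self.fixed or self.se == 0:
            return None
        return beta_from_moments(self.value, self.se, name=self.name)


@dataclass
class StructuralConstants:
    annual_discount_rate: float = 0.035
    cycle_length_years: float = 0.25
    start_age: float = 60.0
    end_age: float = 100.0
    cohort_size: int = 10_000
    wtp_threshold: float = 20_000.0
    psa_draws: int = 10_000
    test_sensitivity: float = 0.97

    def __post_init__(self) -> None:
        for attr in ("cycle_length_years", "cohort_size", "wtp_threshold", "psa_draws"):
            if getattr(self, attr) <= 0:
                raise ConfigError(f"structural.{attr} must be strictly positive")
        if self.annual_discount_rate < 0:
            raise ConfigError("structural.annual_discount_rate must be >= 0")
        if self.end_age <= self.start_age:
            raise ConfigError("structural.end_age must exceed start_age")
        if not (0.0 < self.test_sensitivity <= 1.0):
            raise ConfigError("structural.test_sensitivity must be in (0, 1]")

    @property
    def n_cycles(self) -> int:
        n = (self.end_age - self.start_age) / self.cycle_length_years
        if abs(n - round(n)) > 1e-9:
            raise ConfigError("model horizon must be an integer number of cycles")
        return int(round(n))


# Items expected in a complete configuration; the shipped defaults echo the
# published unit-cost, utility and probability tables verbatim.
COST_KEYS = (
    "prescription", "phone_call", "patient_contact", "home_visit",
    "gp_consultation", "ae_without_admission", "copd_hospital_stay",
    "community_nurse_follow_up", "outpatient_follow_up", "rp21_test",
    "antibiotic_course", "steroid_course", "alternative_antibiotics",
    "secondary_care_follow_up", "primary_care_follow_up",
    "secondary_care_spirometry", "primary_care_spirometry",
    "influenza_vaccination", "oxygen_therapy",
)
RECOVERY_UTILITY_KEYS = ("dead", "partially_recovered", "fully_recovered")
GOLD_UTILITY_KEYS = ("stage_2", "stage_3", "stage_4")
PROBABILITY_KEYS = (
    "intervention.antibiotics_initial",
    "intervention.improve_initial_antibiotics",
    "intervention.improve_second_ab_ae",
    "intervention.improve_second_st_ab",
    "intervention.improve_initial_st_ab",
    "intervention.improve_second_ab",
    "control.antibiotics_initial",
    "control.improve_initial_antibiotics",
    "control.improve_initial_st_ab",
    "control.improve_second_st_ab",
    "control.improve_second_ab",
    "control.improve_second_ab_ae",
    "shared.mortality_after_admission",
    "shared.improve_third_treatment",
)
HOSPITALISATION_KEYS = (
    "hospitalisation.control_bacterial",
    "hospitalisation.control_viral",
    "hospitalisation.intervention_ab",
    "hospitalisation.intervention_st_ab",
)


@dataclass
class ParameterSet:
    """Fully validated model inputs plus structural configuration blocks.

    ``costs`` / ``probabilities`` / ``utilities`` hold the sampled items;
    ``tree``, ``markov``, ``mortality`` and ``amr`` are plain config mappings
    consumed by the downstream modules (their synthetic/assumption entries are
    flagged in the shipped file).
    """

    costs: dict[str, CostItem]
    probabilities: dict[str, ProbabilityItem]
    utilities: dict[str, UtilityItem]
    structural: StructuralConstants
    tree: dict[str, Any] = field(default_factory=dict)
    markov: dict[str, Any] = field(default_factory=dict)
    mortality: dict[str, Any] = field(default_factory=dict)
    amr: dict[str, Any] = field(default_factory=dict)
    invalid_beta_policy: str = "clamp"

    def copy(self) -> "ParameterSet":
        return copy.deepcopy(self)

    # -- dotted-path access (used by the DSA and the PSA) ------------------
    def _locate(self, path: str):
        group, _, key = path.partition(".")
        if group == "costs":
            return self.costs, key, "mean"
        if group == "probabilities":
            return self.probabilities, key, "mean"
        if group == "utilities":
            return self.utilities, key, "value"
        raise KeyError(f"unknown parameter path {path!r}")

    def get_value(self, path: str) -> float:
        table, key, attr = self._locate(path)
        if key not in table:
            raise KeyError(f"unknown parameter path {path!r}")
        return getattr(table[key], attr)

    def set_value(self, path: str, value: float) -> None:
        table, key, attr = self._locate(path)
        if key not in table:
            raise KeyError(f"unknown parameter path {path!r}")
        setattr(table[key], attr, value)

    def iter_items(self) -> Iterator[tuple[str, Any]]:
        """All (path, item) pairs in deterministic order."""
        for key in sorted(self.costs):
            yield f"costs.{key}", self.costs[key]
        for key in sorted(self.probabilities):
            yield f"probabilities.{key}", self.probabilities[key]
        for key in sorted(self.utilities):
            yield f"utilities.{key}", self.utilities[key]

    def to_frame(self) -> pd.DataFrame:
        """Resolved parameter table (one row per item) for audit export."""
        rows = []
        for path, item in self.iter_items():
            if isinstance(item, CostItem):
                dist, mean = "Gamma", item.mean
            elif isinstance(item, ProbabilityItem):
                dist, mean = "Beta", item.mean
            else:
                dist, mean = ("Fixed" if item.fixed else "Beta"), item.value
            rows.append({"parameter": path, "mean": mean, "se": item.se,
                         "distribution": dist})
        return pd.DataFrame(rows)


def _require_mapping(node: Any, path: str) -> dict:
    if not isinstance(node, dict):
        raise ConfigError(f"{path}: expected a mapping, got {type(node).__name__}")
    return node


def _pop_number(node: dict, key: str, path: str) -> float:
    if key not in node:
        raise ConfigError(f"{path}.{key}: missing required value")
    value = node.pop(key)
    if not isinstance(value, (int, float)) or isinstance(value, bool):
        raise ConfigError(f"{path}.{key}: expected a number, got {value!r}")
    return float(value)


def _reject_unknown(node: dict, path: str) -> None:
    if node:
        raise ConfigError(f"{path}: unknown keys {sorted(node)}")


def load_config(path: str | Path | None = None) -> ParameterSet:
    """Load and validate a YAML configuration into a :class:`ParameterSet`.

    With no argument the packaged defaults are loaded.  Validation is strict:
    every expected item must be present, ranges are enforced, unknown keys in
    the item tables are rejected, and the identity
    ``P(antibiotics | intervention) = 1 - test sensitivity`` is enforced.
    """
    path = Path(path) if path is not None else DEFAULT_CONFIG_PATH
    if not path.exists():
        raise ConfigError(f"configuration file not found: {path}")
    with open(path) as fh:
        try:
            raw = yaml.safe_load(fh)
        except yaml.YAMLError as exc:
            raise ConfigError(f"{path}: malformed YAML ({exc})") from exc
    raw = _require_mapping(raw, str(path))

    policies = _require_mapping(raw.pop("policies", {}), "policies")
    invalid_policy = policies.pop("invalid_beta", "clamp")
    if invalid_policy not in ("raise", "clamp"):
        raise ConfigError(f"policies.invalid_beta must be raise|clamp, got {invalid_policy!r}")
    _reject_unknown(policies, "policies")

    structural_node = _require_mapping(raw.pop("structural", None), "structural")
    structural = StructuralConstants(**{
        key: _pop_number(structural_node, key, "structural")
        for key in (
            "annual_discount_rate", "cycle_length_years", "start_age", "end_age",
            "cohort_size", "wtp_threshold", "psa_draws", "test_sensitivity",
        )
    })
    structural.cohort_size = int(structural.cohort_size)
    structural.psa_draws = int(structural.psa_draws)
    _reject_unknown(structural_node, "structural")

    cost_node = _require_mapping(raw.pop("costs", None), "costs")
    costs = {}
    for key in COST_KEYS:
        if key not in cost_node:
            raise ConfigError(f"costs.{key}: missing required item")
        item = _require_mapping(cost_node.pop(key), f"costs.{key}")
        costs[key] = CostItem(
            name=f"costs.{key}",
            mean=_pop_number(item, "mean", f"costs.{key}"),
            se=_pop_number(item, "se", f"costs.{key}"),
        )
        _reject_unknown(item, f"costs.{key}")
    _reject_unknown(cost_node, "costs")

    prob_node = _require_mapping(raw.pop("probabilities", None), "probabilities")
    probabilities: dict[str, ProbabilityItem] = {}
    for dotted in PROBABILITY_KEYS + HOSPITALISATION_KEYS:
        group, _, key = dotted.partition(".")
        group_node = prob_node.get(group)
        if not isinstance(group_node, dict) or key not in group_node:
            raise ConfigError(f"probabilities.{dotted}: missing required item")
        item = _require_mapping(group_node.pop(key), f"probabilities.{dotted}")
        probabilities[dotted] = ProbabilityItem(
            name=f"probabilities.{dotted}",
            mean=_pop_number(item, "mean", f"probabilities.{dotted}"),
            se=_pop_number(item, "se", f"probabilities.{dotted}"),
            invalid_policy=invalid_policy,
        )
        _reject_unknown(item, f"probabilities.{dotted}")
    for group, group_node in prob_node.items():
        _reject_unknown(_require_mapping(group_node, f"probabilities.{group}"),
                        f"probabilities.{group}")

    util_node = _require_mapping(raw.pop("utilities", None), "utilities")
    utilities: dict[str, UtilityItem] = {}
    recovery = _require_mapping(util_node.pop("recovery", None), "utilities.recovery")
    for key in RECOVERY_UTILITY_KEYS:
        if key not in recovery:
            raise ConfigError(f"utilities.recovery.{key}: missing required item")
        item = _require_mapping(recovery.pop(key), f"utilities.recovery.{key}")
        fixed = bool(item.pop("fixed", False))
        utilities[key] = UtilityItem(
            name=f"utilities.{key}",
            value=_pop_number(item, "value", f"utilities.recovery.{key}"),
            se=_pop_number(item, "se", f"utilities.recovery.{key}") if "se" in item else 0.0,
            fixed=fixed,
        )
        _reject_unknown(item, f"utilities.recovery.{key}")
    _reject_unknown(recovery, "utilities.recovery")
    gold = _require_mapping(util_node.pop("gold", None), "utilities.gold")
    for key in GOLD_UTILITY_KEYS:
        if key not in gold:
            raise ConfigError(f"utilities.gold.{key}: missing required item")
        item = _require_mapping(gold.pop(key), f"utilities.gold.{key}")
        utilities[key] = UtilityItem(
            name=f"utilities.{key}",
            value=_pop_number(item, "value", f"utilities.gold.{key}"),
            se=_pop_number(item, "se", f"utilities.gold.{key}"),
        )
        _reject_unknown(item, f"utilities.gold.{key}")
    _reject_unknown(gold, "utilities.gold")
    _reject_unknown(util_node, "utilities")

    if utilities["dead"].value != 0.0 or not utilities["dead"].fixed:
        raise ConfigError("utilities.recovery.dead must be fixed at exactly 0")

    tree = _require_mapping(raw.pop("tree", {}), "tree")
    markov = _require_mapping(raw.pop("markov", {}), "markov")
    mortality = _require_mapping(raw.pop("mortality", {}), "mortality")
    amr = _require_mapping(raw.pop("amr", {}), "amr")
    _reject_unknown(raw, str(path))

    # Enforced modelling identity rather than two free numbers.
    derived = 1.0 - structural.test_sensitivity
    stated = probabilities["intervention.antibiotics_initial"].mean
    if abs(stated - derived) > 1e-9:
        raise ConfigError(
            "probabilities.intervention.antibiotics_initial must equal "
            f"1 - test_sensitivity ({derived:.6g}), got {stated}"
        )

    params = ParameterSet(
        costs=costs, probabilities=probabilities, utilities=utilities,
        structural=structural, tree=tree, markov=markov, mortality=mortality,
        amr=amr, invalid_beta_policy=invalid_policy,
    )
    _validate_blocks(params)
    return params


def _validate_blocks(params: ParameterSet) -> None:
    mix = params.markov.get("stage_mix")
    if mix is not None:
        if len(mix) != 3 or any(m < 0 for m in mix) or abs(sum(mix) - 1.0) > 1e-9:
            raise ConfigError("markov.stage_mix must be 3 nonnegative values summing to 1")
    split = params.tree.get("second_line_ae_split")
    if split is not None and not (0.0 <= split <= 1.0):
        raise ConfigError("tree.second_line_ae_split must lie in [0, 1]")
    for key in ("p_bacterial_control", "full_recovery_after_admission"):
        value = params.tree.get(key)
        if value is not None and not (0.0 <= value <= 1.0):
            raise ConfigError(f"tree.{key} must lie in [0, 1]")
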