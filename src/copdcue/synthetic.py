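"""Seeded generators for model inputs that the evidence base does not print.

Three inputs of the pipeline come from external sources that are not part of
the published parameter tables: yearly antimicrobial-resistance rate
trajectories (2023-2040), an all-cause mortality life table, and the
inter-state transition intensities of the cohort model.  Each generator here
is a pure function of its spec (seed included) and emits data that passes
the consuming modules' validators; every CSV written carries a provenance
header marking it as synthetic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .amr import AMRTrajectory

TRAJECTORY_YEARS = tuple(range(2023, 2041))


@dataclass(frozen=True)
class TrajectoryGeneratorSpec:
    """Drifting resistance-rate curve with optional seeded perturbations.

    ``annual_trend`` is a per-year drift: relative (multiplicative, e.g.
    -0.02 for a 2%/year decline) or additive in rate units, chosen by
    ``trend_kind``.  Rates are clipped to [0.001, 0.999].
    """

    pathogen: str
    start_rate: float
    annual_trend: float = 0.0
    trend_kind: str = "relative"
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.start_rate < 1.0):
            raise ValueError("start_rate must lie in (0, 1)")
        if self.trend_kind not in ("relative", "additive"):
            raise ValueError("trend_kind must be 'relative' or 'additive'")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def generate_amr_trajectory(spec: TrajectoryGeneratorSpec) -> AMRTrajectory:
    """Yearly resistance proportions 2023-2040, deterministic per seed."""
    k = np.arange(len(TRAJECTORY_YEARS), dtype=float)
    if spec.trend_kind == "relative":
        rates = spec.start_rate * (1.0 + spec.annual_trend) ** k
    else:
        rates = spec.start_rate + spec.annual_trend * k
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        noise = rng.normal(0.0, spec.noise_sd, size=len(k))
        noise[0] = 0.0  # anchor the 2023 base year exactly at start_rate
        rates = rates + noise
    rates = np.clip(rates, 0.001, 0.999)
    return AMRTrajectory(pathogen=spec.pathogen,
                         years=TRAJECTORY_YEARS,
                         rates=tuple(float(r) for r in rates))


@dataclass(frozen=True)
class MortalityGeneratorSpec:
    """Gompertz-style annual all-cause mortality over ages 0-100.

    q(age) = clip(baseline * exp(slope * age), 0, 1), optionally perturbed
    by seeded multiplicative log-normal noise.
    """

    baseline: float = 2.0e-5
    slope: float = 0.097
    age_min: int = 0
    age_max: int = 100
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.baseline <= 0 or self.slope < 0:
            raise ValueError("baseline must be > 0 and slope >= 0")
        if self.age_max <= self.age_min:
            raise ValueError("age_max must exceed age_min")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def generate_mortality_table(spec: MortalityGeneratorSpec) -> pd.DataFrame:
    """Age-indexed annual death probabilities (columns: age, qx)."""
    ages = np.arange(spec.age_min, spec.age_max + 1)
    qx = spec.baseline * np.exp(spec.slope * ages.astype(float))
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        qx = qx * np.exp(rng.normal(0.0, spec.noise_sd, size=len(ages)))
    qx = np.clip(qx, 0.0, 1.0)
    return pd.DataFrame({"age": ages, "qx": qx})


def mortality_table_from_config(cfg: dict) -> pd.DataFrame:
    """Materialise the mortality table named by a ``mortality`` config block.

    ``kind: synthetic_gompertz`` generates the table; ``kind: csv`` reads an
    (age, qx) file (comment lines allowed).
    """
    kind = cfg.get("kind", "synthetic_gompertz")
    if kind == "synthetic_gompertz":
        spec = MortalityGeneratorSpec(
            baseline=float(cfg.get("baseline", 2.0e-5)),
            slope=float(cfg.get("slope", 0.097)),
            noise_sd=float(cfg.get("noise_sd", 0.0)),
            seed=int(cfg.get("seed", 0)),
        )
        return generate_mortality_table(spec)
    if kind == "csv":
        table = pd.read_csv(cfg["path"], comment="#")
        if not {"age", "qx"} <= set(table.columns):
            raise ValueError("mortality CSV must have 'age' and 'qx' columns")
        return table[["age", "qx"]]
    raise ValueError(f"unknown mortality table kind {kind!r}")


def generate_transition_defaults(seed: int, stage_mix,
                                 exacerbation_intensity: float = 1.0,
                                 progression_intensity: float = 1.0,
                                 jitter: float = 0.0) -> dict:
    """Synthesise a cohort-model transition config block.

    Baseline intensities reproduce the shipped defaults; the two intensity
    knobs scale the tendency to exacerbate and to progress through GOLD
    stages, and ``jitter`` adds seeded relative perturbations before rows
    are renormalised (rows always sum to 1).  The block is flagged as an
    assumption in its provenance metadata.
    """
    mix = np.asarray(stage_mix, dtype=float)
    if mix.shape != (3,) or abs(mix.sum() - 1.0) > 1e-9 or (mix < 0).any():
        raise ValueError("stage mix must be 3 nonnegative values summing to 1")
    rng = np.random.default_rng(seed)

    base = {
        "stable": {"stable": 0.85, "mild": 0.12, "moderate": 0.03},
        "mild": {"stable": 0.30, "mild": 0.50, "moderate": 0.20},
        "moderate": {"stable": 0.05, "mild": 0.25, "moderate": 0.70},
    }
    worse = {"stable": ("mild", "moderate"), "mild": ("moderate",),
             "moderate": ("moderate",)}
    transitions = {}
    for row, probs in base.items():
        scaled = dict(probs)
        for target in worse[row]:
            scaled[target] = min(1.0, scaled[target] * exacerbation_intensity)
        if jitter > 0:
            for target in scaled:
                scaled[target] *= float(np.exp(rng.normal(0.0, jitter)))
        total = sum(scaled.values())
        transitions[row] = {k: v / total for k, v in scaled.items()}

    progression = {
        "stage_2_to_3": min(1.0, 0.010 * progression_intensity),
        "stage_3_to_4": min(1.0, 0.010 * progression_intensity),
    }
    return {
        "assumption": True,
        "provenance": {"generator": "generate_transition_defaults", "seed": int(seed),
                       "exacerbation_intensity": exacerbation_intensity,
                       "progression_intensity": progression_intensity,
                       "jitter": jitter},
        "stage_mix": [float(m) for m in mix],
        "severity_transitions": transitions,
        "stage_progression": progression,
    }


def write_csv_with_provenance(frame: pd.DataFrame, path, spec) -> None:
    """Write a CSV with a comment header recording the synthetic provenance."""
    with open(path, "w") as fh:
        fh.write(f"# synthetic: generated by copdcue from {spec!r}\n")
        frame.to_csv(fh, index=False)


def trajectory_from_config(pathogen: str, cfg: dict) -> AMRTrajectory:
    """Build a pathogen trajectory from an ``amr.trajectories`` config entry."""
    spec = TrajectoryGeneratorSpec(
        pathogen=pathogen,
        start_rate=float(cfg["start_rate"]),
        annual_trend=float(cfg.get("annual_trend", 0.0)),
        trend_kind=str(cfg.get("trend_kind", "relative")),
        noise_sd=float(cfg.get("noise_sd", 0.0)),
        seed=int(cfg.get("seed", 0)),
    )
    return generate_amr_trajectory(spec)
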