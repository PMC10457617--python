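"""Natural-history parameterization: disease-process rates and the life table.

The microsimulator is configured entirely through :class:`NaturalHistoryParams`.
The packaged default parameter file (``data/default_params.yaml``) is a
documented stand-in calibration chosen to produce plausible US-like benchmarks
(lifetime adenoma prevalence roughly 30-40%, unscreened lifetime colorectal
cancer risk roughly 4-5%); it is not a transcription of any published
calibrated model and users with access to a calibrated parameter set should
supply their own file in the same schema.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml

__all__ = [
    "ConfigurationError",
    "LifeTable",
    "TransitionCoeffs",
    "SurvivalParams",
    "NaturalHistoryParams",
    "load_params",
    "default_params",
]

STAGES = (1, 2, 3, 4)


class ConfigurationError(ValueError):
    """A parameter or configuration value violates its documented constraint."""


def _require(condition: bool, fieldname: str, message: str) -> None:
    if not condition:
        raise ConfigurationError(f"{fieldname}: {message}")


class LifeTable:
    """Sex-specific annual all-cause death probabilities, ages 0-100.

    Death-age draws are by inverse CDF on the discrete annual grid with a
    uniform within-year jitter, conditional on survival to a given entry age.
    """

    def __init__(self, ages: Sequence[int], qx: Mapping[str, Sequence[float]]):
        self.ages = np.asarray(ages, dtype=int)
        self.qx = {sex: np.asarray(v, dtype=float) for sex, v in qx.items()}
        _require(set(self.qx) == {"female", "male"}, "life_table", "needs qx_female and qx_male columns")
        for sex, q in self.qx.items():
            _require(len(q) == len(self.ages), "life_table", "age/qx length mismatch")
            _require(bool(np.all((q >= 0) & (q <= 1))), "life_table", f"qx_{sex} outside [0,1]")
            _require(q[-1] == 1.0, "life_table", f"qx_{sex} must reach 1 at the final age")
        _require(bool(np.all(np.diff(self.ages) == 1)), "life_table", "ages must be consecutive integers")
        self._cdf_cache: dict[tuple[str, int], tuple[np.ndarray, np.ndarray]] = {}

    @classmethod
    def from_csv(cls, path: str | Path) -> "LifeTable":
        import pandas as pd

        t = pd.read_csv(path)
        return cls(t["age"].to_numpy(), {"female": t["qx_female"].to_numpy(), "male": t["qx_male"].to_numpy()})

    def _conditional(self, sex: str, from_age: int) -> tuple[np.ndarray, np.ndarray]:
        """Ages and CDF of the integer death year, conditional on reaching from_age."""
        key = (sex, from_age)
        if key not in self._cdf_cache:
            q = self.qx[sex][from_age:]
            surv = np.concatenate([[1.0], np.cumprod(1.0 - q)[:-1]])
            pmf = surv * q
            pmf = pmf / pmf.sum()
            self._cdf_cache[key] = (self.ages[from_age:].astype(float), np.cumsum(pmf))
        return self._cdf_cache[key]

    def draw_death_age(self, sex: str, rng: np.random.Generator, from_age: int = 40) -> float:
        ages, cdf = self._conditional(sex, from_age)
        i = int(np.searchsorted(cdf, rng.random(), side="right"))
        i = min(i, len(ages) - 1)
        return float(ages[i]) + float(rng.random())

    def expected_death_age(self, sex: str, from_age: int = 40) -> float:
        """Closed-form mean of the jittered conditional death age."""
        ages, cdf = self._conditional(sex, from_age)
        pmf = np.diff(np.concatenate([[0.0], cdf]))
        return float(np.sum(pmf * (ages + 0.5)))


@dataclass(frozen=True)
class TransitionCoeffs:
    """Adenoma -> preclinical cancer hazard: h(t) = exp(log_hazard_at_10mm
    + male_log_effect*[male] + age_log_slope*(age-50)) * (d(t)/10)^size_power.

    ``log_hazard_at_10mm`` may be -inf (zero hazard, nothing ever transforms).
    """

    log_hazard_at_10mm: float
    size_power: float = 0.0
    male_log_effect: float = 0.0
    age_log_slope: float = 0.0

    def validate(self) -> None:
        _require(not math.isnan(self.log_hazard_at_10mm), "transition_coeffs.log_hazard_at_10mm", "must not be NaN")
        _require(self.size_power >= 0, "transition_coeffs.size_power", "must be >= 0")


@dataclass(frozen=True)
class SurvivalParams:
    """Stage- and age-banded cancer survival: a stage-specific probability of
    cure, otherwise an exponential excess death hazard scaled by an age-band
    multiplier at diagnosis."""

    cure_prob: Mapping[int, float]
    excess_hazard: Mapping[int, float]
    age_band_edges: tuple[float, ...] = (65.0, 75.0)
    age_band_multipliers: tuple[float, ...] = (1.0, 1.15, 1.4)

    def validate(self) -> None:
        for stage in STAGES:
            _require(stage in self.cure_prob, "survival_params.cure_prob", f"missing stage {stage}")
            _require(stage in self.excess_hazard, "survival_params.excess_hazard", f"missing stage {stage}")
            _require(0 <= self.cure_prob[stage] <= 1, "survival_params.cure_prob", f"stage {stage} outside [0,1]")
            _require(self.excess_hazard[stage] >= 0, "survival_params.excess_hazard", f"stage {stage} negative")
        _require(
            len(self.age_band_multipliers) == len(self.age_band_edges) + 1,
            "survival_params.age_band_multipliers",
            "need one more multiplier than band edges",
        )
        _require(all(m > 0 for m in self.age_band_multipliers), "survival_params.age_band_multipliers", "must be > 0")

    def hazard(self, stage: int, diagnosis_age: float) -> float:
        if stage not in self.excess_hazard:
            raise ConfigurationError(f"survival_params: unknown stage {stage!r}")
        band = int(np.searchsorted(np.asarray(self.age_band_edges), diagnosis_age, side="right"))
        return float(self.excess_hazard[stage]) * float(self.age_band_multipliers[band])


@dataclass(frozen=True)
class NaturalHistoryParams:
    """All disease-process rates and distribution parameters.

    Adenoma onsets follow a non-homogeneous Poisson process with per-person
    intensity ``exp(adenoma_baseline_log_rate + frailty + sex_log_effect*[male])
    * age_effect(age)`` where the age effect is piecewise constant on the
    bands given by ``age_effect_knots``.
    """

    adenoma_baseline_log_rate: float
    frailty_sd: float
    sex_log_effect: float
    age_effect_knots: tuple[tuple[float, float], ...]
    segment_probs: Mapping[str, float]
    growth_time_to_10mm: Mapping[str, Mapping[str, float]]  # lognormal meanlog/sdlog per segment
    transition_coeffs: TransitionCoeffs
    sojourn_params: Mapping[str, float]  # lognormal meanlog/sdlog
    stage_dwell_means: tuple[float, float, float]  # mean years in preclinical stages I, II, III
    survival_params: SurvivalParams
    life_table: LifeTable
    initial_diameter_mm: float = 1.0
    max_diameter_mm: float = 50.0
    max_age: float = 100.0
    entry_age: float = 40.0

    def validate(self) -> None:
        _require(self.frailty_sd >= 0, "frailty_sd", "must be >= 0")
        _require(len(self.age_effect_knots) >= 1, "age_effect_knots", "need at least one (age, multiplier) pair")
        prev = -math.inf
        for age, mult in self.age_effect_knots:
            _require(age > prev, "age_effect_knots", "knot ages must be strictly increasing")
            _require(mult >= 0, "age_effect_knots", "multipliers must be >= 0")
            prev = age
        _require(abs(sum(self.segment_probs.values()) - 1.0) < 1e-9, "segment_probs", "must sum to 1")
        _require(all(p >= 0 for p in self.segment_probs.values()), "segment_probs", "must be >= 0")
        for seg in self.segment_probs:
            _require(seg in self.growth_time_to_10mm, "growth_time_to_10mm", f"missing segment {seg!r}")
            _require(self.growth_time_to_10mm[seg]["sdlog"] >= 0, "growth_time_to_10mm", "sdlog must be >= 0")
        self.transition_coeffs.validate()
        _require(self.sojourn_params["sdlog"] >= 0, "sojourn_params", "sdlog must be >= 0")
        _require(len(self.stage_dwell_means) == 3, "stage_dwell_means", "need dwell means for stages I, II, III")
        _require(all(m > 0 for m in self.stage_dwell_means), "stage_dwell_means", "must be > 0")
        self.survival_params.validate()
        _require(0 < self.initial_diameter_mm < 10.0, "initial_diameter_mm", "must lie in (0, 10) mm")
        _require(self.max_diameter_mm > 10.0, "max_diameter_mm", "must exceed the 10 mm threshold")
        _require(self.entry_age < self.max_age, "entry_age", "must be below max_age")

    def age_effect(self, age: float) -> float:
        """Piecewise-constant age multiplier; 0 before the first knot."""
        mult = 0.0
        for knot_age, m in self.age_effect_knots:
            if age >= knot_age:
                mult = m
            else:
                break
        return mult

    # -- age-band decomposition used by the Poisson onset sampler ----------
    def age_bands(self) -> list[tuple[float, float, float]]:
        """(start, end, multiplier) bands covering [first knot, max_age]."""
        knots = list(self.age_effect_knots) + [(self.max_age, 0.0)]
        out = []
        for (a0, m), (a1, _) in zip(knots[:-1], knots[1:]):
            if a1 > a0 and m > 0:
                out.append((a0, min(a1, self.max_age), m))
        return out


_ALLOWED_KEYS = {
    "adenoma_baseline_log_rate",
    "frailty_sd",
    "sex_log_effect",
    "age_effect_knots",
    "segment_probs",
    "growth_time_to_10mm",
    "transition_coeffs",
    "sojourn_params",
    "stage_dwell_means",
    "survival_params",
    "initial_diameter_mm",
    "max_diameter_mm",
    "max_age",
    "entry_age",
    "life_table_csv",
}


def params_from_dict(d: Mapping, life_table: LifeTable | None = None, base_dir: Path | None = None) -> NaturalHistoryParams:
    """Build and validate :class:`NaturalHistoryParams` from a plain mapping
    (the YAML schema). Unknown keys are rejected."""
    unknown = set(d) - _ALLOWED_KEYS
    if unknown:
        raise ConfigurationError(f"unknown parameter keys: {sorted(unknown)}")
    if life_table is None:
        csv_name = d.get("life_table_csv")
        if csv_name is None:
            life_table = default_life_table()
        else:
            path = Path(csv_name)
            if base_dir is not None and not path.is_absolute():
                path = base_dir / path
            life_table = LifeTable.from_csv(path)
    tc = d["transition_coeffs"]
    log_h = tc["log_hazard_at_10mm"]
    if isinstance(log_h, str):  # YAML has no literal -inf
        log_h = float(log_h)
    sp = d["survival_params"]
    params = NaturalHistoryParams(
        adenoma_baseline_log_rate=float(d["adenoma_baseline_log_rate"]),
        frailty_sd=float(d["frailty_sd"]),
        sex_log_effect=float(d["sex_log_effect"]),
        age_effect_knots=tuple((float(a), float(m)) for a, m in d["age_effect_knots"]),
        segment_probs=dict(d["segment_probs"]),
        growth_time_to_10mm={k: dict(v) for k, v in d["growth_time_to_10mm"].items()},
        transition_coeffs=TransitionCoeffs(
            log_hazard_at_10mm=float(log_h),
            size_power=float(tc.get("size_power", 0.0)),
            male_log_effect=float(tc.get("male_log_effect", 0.0)),
            age_log_slope=float(tc.get("age_log_slope", 0.0)),
        ),
        sojourn_params=dict(d["sojourn_params"]),
        stage_dwell_means=tuple(float(x) for x in d["stage_dwell_means"]),
        survival_params=SurvivalParams(
            cure_prob={int(k): float(v) for k, v in sp["cure_prob"].items()},
            excess_hazard={int(k): float(v) for k, v in sp["excess_hazard"].items()},
            age_band_edges=tuple(float(x) for x in sp.get("age_band_edges", (65.0, 75.0))),
            age_band_multipliers=tuple(float(x) for x in sp.get("age_band_multipliers", (1.0, 1.15, 1.4))),
        ),
        life_table=life_table,
        initial_diameter_mm=float(d.get("initial_diameter_mm", 1.0)),
        max_diameter_mm=float(d.get("max_diameter_mm", 50.0)),
        max_age=float(d.get("max_age", 100.0)),
        entry_age=float(d.get("entry_age", 40.0)),
    )
    params.validate()
    return params


def load_params(path: str | Path) -> NaturalHistoryParams:
    """Load a YAML/JSON natural-history parameter file."""
    path = Path(path)
    with open(path) as fh:
        d = yaml.safe_load(fh)
    return params_from_dict(d, base_dir=path.parent)


def _data_path(name: str) -> Path:
    return Path(str(resources.files("crcscreen").joinpath("data", name)))


def default_life_table() -> LifeTable:
    return LifeTable.from_csv(_data_path("life_table_synthetic_us.csv"))


def default_params() -> NaturalHistoryParams:
    """The packaged stand-in calibration (see module docstring)."""
    return load_params(_data_path("default_params.yaml"))
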