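"""Screening-strategy overlay on a fixed natural history.

A strategy offers a noninvasive test on a fixed age grid (start, start +
interval, ...).  Each offer is completed with the per-round adherence
probability; a positive result triggers a same-day follow-up colonoscopy
(completed with probability 1), which removes detected adenomas per-lesion
and diagnoses preclinical cancer if seen.  Findings feed a surveillance
policy; a clean follow-up colonoscopy (a false positive) defers the return
to screening by the post-negative rescreen interval.

Test positivity uses the per-person most-advanced-lesion convention under
which trial sensitivities are measured; colonoscopy detection is per lesion.

The overlay never mutates the individual: removals and diagnoses are tracked
in local state, and the downstream consequences (prevented cancers, earlier
stage, new survival draw from the cancer's pre-drawn uniforms) are recomputed
so that an inert strategy reproduces the unscreened arm exactly.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import ClassVar, Optional

import numpy as np

from .natural_history import (
    Adenoma,
    Individual,
    LifeHistory,
    _finish_naturally,
    adenoma_diameter,
    crc_death_age,
)
from .params import ConfigurationError, NaturalHistoryParams

__all__ = [
    "TestSpec",
    "AdherenceModel",
    "Strategy",
    "ColonoscopySpec",
    "SurveillancePolicy",
    "derive_nonadvanced_sensitivity",
    "most_advanced_category",
    "positivity_probability",
    "schedule_and_run",
    "count_resources",
]

CATEGORIES = ("none", "nonadvanced_adenoma", "advanced_adenoma", "preclinical_crc")
ADVANCED_MM = 10.0  # >= is inclusive: a 10.0 mm adenoma is advanced


def derive_nonadvanced_sensitivity(sens_advanced: float, specificity: float) -> float:
    """Nonadvanced-adenoma sensitivity from the half-rule: half the advanced
    sensitivity in excess of the accidental-finding floor (1 - specificity),
    added back onto that floor."""
    if not (0.0 <= sens_advanced <= 1.0 and 0.0 <= specificity <= 1.0):
        raise ConfigurationError("sensitivity and specificity must lie in [0,1]")
    floor = 1.0 - specificity
    if sens_advanced < floor:
        raise ConfigurationError(
            f"sens_advanced {sens_advanced} below the accidental-finding floor {floor}")
    return floor + (sens_advanced - floor) / 2.0


@dataclass(frozen=True)
class TestSpec:
    """One noninvasive test: per-person sensitivities by most advanced lesion
    category, specificity, and the recommended repeat interval."""

    __test__: ClassVar[bool] = False  # "Test" prefix is domain vocabulary, not pytest's

    name: str
    sens_nonadvanced: float
    sens_advanced: float
    sens_crc: float
    specificity: float
    interval_years: int

    def validate(self) -> None:
        for f in ("sens_nonadvanced", "sens_advanced", "sens_crc", "specificity"):
            v = getattr(self, f)
            if not (0.0 <= v <= 1.0):
                raise ConfigurationError(f"{self.name}.{f}: {v} outside [0,1]")
        if self.interval_years < 1:
            raise ConfigurationError(f"{self.name}.interval_years: must be >= 1")
        if not (self.sens_crc >= self.sens_advanced >= self.sens_nonadvanced):
            warnings.warn(
                f"{self.name}: sensitivities not ordered crc >= advanced >= nonadvanced",
                stacklevel=2)


@dataclass(frozen=True)
class AdherenceModel:
    """Per-round completion model: each offered test is completed
    independently with probability ``rate``."""

    kind: str = "perfect"  # "perfect" | "per_round"
    rate: float = 1.0

    def validate(self) -> None:
        if self.kind not in ("perfect", "per_round"):
            raise ConfigurationError(f"adherence.kind: unknown kind {self.kind!r}")
        if not (0.0 <= self.rate <= 1.0):
            raise ConfigurationError(f"adherence.rate: {self.rate} outside [0,1]")
        if self.kind == "perfect" and self.rate != 1.0:
            raise ConfigurationError("adherence.rate: perfect adherence requires rate = 1")

    @staticmethod
    def per_round(rate: float) -> "AdherenceModel":
        return AdherenceModel("perfect", 1.0) if rate == 1.0 else AdherenceModel("per_round", rate)


@dataclass(frozen=True)
class Strategy:
    test: TestSpec
    adherence: AdherenceModel = AdherenceModel()
    start_age: float = 45.0
    stop_age: float = 75.0
    followup_adherence: float = 1.0  # positive tests are always followed up

    def validate(self) -> None:
        self.test.validate()
        self.adherence.validate()
        if not self.start_age < self.stop_age:
            raise ConfigurationError("strategy.start_age: must be below stop_age")
        if self.followup_adherence != 1.0:
            raise ConfigurationError("strategy.followup_adherence: fixed at 1.0 in this analysis")

    def offer_ages(self) -> list[float]:
        ages, a = [], self.start_age
        while a <= self.stop_age + 1e-9:
            ages.append(a)
            a += self.test.interval_years
        return ages


@dataclass(frozen=True)
class ColonoscopySpec:
    """Follow-up/surveillance colonoscopy: per-lesion detection by size class
    (cancer uses the large-lesion sensitivity) and the rescreen deferral after
    a negative examination."""

    sens_small: float = 0.75   # adenoma <= 5 mm
    sens_medium: float = 0.85  # 6-9 mm
    sens_large: float = 0.95   # >= 10 mm, and preclinical cancer
    post_negative_rescreen_years: float = 10.0

    def validate(self) -> None:
        if not (0.0 <= self.sens_small <= self.sens_medium <= self.sens_large <= 1.0):
            raise ConfigurationError(
                "colonoscopy sensitivities must satisfy 0 <= small <= medium <= large <= 1")
        if self.post_negative_rescreen_years <= 0:
            raise ConfigurationError("post_negative_rescreen_years must be > 0")

    def sens_for_diameter(self, mm: float) -> float:
        if mm >= ADVANCED_MM:
            return self.sens_large
        if mm > 5.0:
            return self.sens_medium
        return self.sens_small


@dataclass(frozen=True)
class SurveillancePolicy:
    """Post-polypectomy surveillance: a shorter interval after high-risk
    findings (any adenoma >= 10 mm, or >= 3 adenomas removed), a longer one
    after low-risk findings, stopping at ``stop_age``."""

    high_risk_interval_years: float = 3.0
    low_risk_interval_years: float = 5.0
    stop_age: float = 85.0

    def validate(self) -> None:
        if self.high_risk_interval_years <= 0 or self.low_risk_interval_years <= 0:
            raise ConfigurationError("surveillance intervals must be > 0")


def _category_from_lesions(diameters: list[float], cancer_present: bool) -> str:
    if cancer_present:
        return "preclinical_crc"
    if any(d >= ADVANCED_MM for d in diameters):
        return "advanced_adenoma"
    if diameters:
        return "nonadvanced_adenoma"
    return "none"


def most_advanced_category(individual: Individual, age: float, params: NaturalHistoryParams,
                           removed: set[int] | frozenset[int] = frozenset()) -> str:
    """Per-person lesion category at ``age``: preclinical cancer dominates,
    then any adenoma >= 10 mm, then any adenoma, else none.  ``removed``
    holds indices of adenomas already resected."""
    adenomas, cancers = _lesion_state(individual, age, set(removed), params)
    return _category_from_lesions([d for _, _, d in adenomas], bool(cancers))


def positivity_probability(test: TestSpec, category: str) -> float:
    if category == "none":
        return 1.0 - test.specificity
    if category == "nonadvanced_adenoma":
        return test.sens_nonadvanced
    if category == "advanced_adenoma":
        return test.sens_advanced
    if category == "preclinical_crc":
        return test.sens_crc
    raise ConfigurationError(f"unknown lesion category {category!r}")


# ---------------------------------------------------------------------------
# the overlay


def _lesion_state(individual: Individual, age: float, removed: set[int],
                  params: NaturalHistoryParams):
    """Live lesions at ``age``: (untransformed adenomas with diameters,
    preclinical cancers) excluding removed adenomas and not-yet-onset lesions."""
    adenomas: list[tuple[int, Adenoma, float]] = []
    cancers: list[tuple[int, "object"]] = []
    for i, a in enumerate(individual.adenomas):
        if i in removed or a.onset_age > age:
            continue
        if a.transformation_age is not None and age >= a.transformation_age:
            cancers.append((i, a.cancer))
        else:
            adenomas.append((i, a, adenoma_diameter(a, age, params)))
    return adenomas, cancers


def schedule_and_run(individual: Individual, strategy: Strategy, params: NaturalHistoryParams,
                     colono: ColonoscopySpec | None = None,
                     policy: SurveillancePolicy | None = None,
                     rng: np.random.Generator | None = None) -> LifeHistory:
    """Run one person through one screening strategy.

    The screening stream is re-opened from the person's seed bundle unless an
    explicit ``rng`` is supplied, so every strategy arm sees the same draws.
    At every offered round one adherence uniform and one positivity uniform
    are consumed regardless of the outcome, keeping the stream aligned across
    strategies that differ only in adherence or sensitivity.
    """
    colono = colono or ColonoscopySpec()
    policy = policy or SurveillancePolicy()
    strategy.validate()
    colono.validate()
    policy.validate()
    rng = rng if rng is not None else individual.screening_rng()

    test = strategy.test
    adh_rate = 1.0 if strategy.adherence.kind == "perfect" else strategy.adherence.rate
    history = LifeHistory(individual.id)
    removed: set[int] = set()
    removed_pre_transform: set[int] = set()
    other_death = individual.other_cause_death_age

    offer_iter = iter(strategy.offer_ages())
    next_offer = next(offer_iter, None)
    resume_age = strategy.start_age  # earliest age screening may resume
    surveillance_age: Optional[float] = None

    def earliest_clinical() -> tuple[float, Optional[object]]:
        best_age, best = math.inf, None
        for i, a in enumerate(individual.adenomas):
            c = a.cancer
            if c is None or i in removed_pre_transform or i in removed:
                continue
            if c.clinical_detection_age < best_age:
                best_age, best = c.clinical_detection_age, c
        return best_age, best

    def do_colonoscopy(age: float, reason: str) -> str:
        """Returns 'diagnosed', 'findings' or 'clean'."""
        adenomas, cancers = _lesion_state(individual, age, removed, params)
        detected_cancers = [c for _, c in cancers if rng.random() < colono.sens_large]
        if detected_cancers:
            history.add(age, "colonoscopy", reason)
            cancer = max(detected_cancers, key=lambda c: (c.stage_at(age), -c.onset_age))
            stage = cancer.stage_at(age)
            history.add(age, "crc_diagnosis", stage, "screen_detected")
            death = crc_death_age(stage, age, individual.sex, params,
                                  uniforms=(cancer.u_cure, cancer.u_time))
            if death is not None and death < other_death:
                history.add(death, "death", "crc")
            else:
                history.add(other_death, "death", "other")
            return "diagnosed"
        history.add(age, "colonoscopy", reason)
        n_removed, any_large = 0, False
        for i, a, diam in adenomas:
            if rng.random() < colono.sens_for_diameter(diam):
                removed.add(i)
                removed_pre_transform.add(i)  # lesions past transformation sit in the cancer list
                history.add(age, "adenoma_removed", round(diam, 3))
                n_removed += 1
                any_large = any_large or diam >= ADVANCED_MM
        if n_removed == 0:
            return "clean"
        return "high" if (any_large or n_removed >= 3) else "low"

    while True:
        # next management contact: surveillance takes precedence over screening
        while next_offer is not None and (next_offer < resume_age - 1e-9):
            rng.random()  # consume the tick's (adherence, positivity) pair so the
            rng.random()  # stream stays aligned across strategies that skip differently
            next_offer = next(offer_iter, None)
        if surveillance_age is not None:
            contact, contact_kind = surveillance_age, "surveillance"
        elif next_offer is not None:
            contact, contact_kind = next_offer, "screen"
        else:
            contact, contact_kind = math.inf, "done"

        clin_age, clin_cancer = earliest_clinical()
        horizon = min(other_death, clin_age)
        if contact >= horizon:
            _finish_naturally(history, individual, params, from_age=0.0,
                              excluded=frozenset(removed_pre_transform))
            break

        if contact_kind == "surveillance":
            surveillance_age = None
            outcome = do_colonoscopy(contact, "surveillance")
            if outcome == "diagnosed":
                break
            if outcome == "clean":
                resume_age = contact + colono.post_negative_rescreen_years
            else:
                interval = (policy.high_risk_interval_years if outcome == "high"
                            else policy.low_risk_interval_years)
                nxt = contact + interval
                if nxt <= policy.stop_age:
                    surveillance_age = nxt
                else:
                    resume_age = nxt
            continue

        # screening offer
        u_adh = rng.random()
        u_pos = rng.random()
        next_offer = next(offer_iter, None)
        if u_adh >= adh_rate:
            continue
        adenomas, cancers = _lesion_state(individual, contact, removed, params)
        category = _category_from_lesions([d for _, _, d in adenomas], bool(cancers))
        p = positivity_probability(test, category)
        positive = u_pos < p
        history.add(contact, "test", test.name, "positive" if positive else "negative")
        if not positive:
            continue
        outcome = do_colonoscopy(contact, "followup")
        if outcome == "diagnosed":
            break
        if outcome == "clean":  # false positive
            resume_age = contact + colono.post_negative_rescreen_years
        else:
            interval = (policy.high_risk_interval_years if outcome == "high"
                        else policy.low_risk_interval_years)
            nxt = contact + interval
            if nxt <= policy.stop_age:
                surveillance_age = nxt
            else:
                resume_age = nxt

    history.validate()
    return history


def count_resources(history: LifeHistory) -> tuple[int, dict[str, int]]:
    """(noninvasive tests performed, colonoscopies by reason)."""
    tests = 0
    colos = {"followup": 0, "surveillance": 0, "diagnostic": 0}
    for ev in history.events:
        if ev.kind == "test":
            tests += 1
        elif ev.kind == "colonoscopy":
            colos[ev.detail[0]] += 1
    return tests, colos
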