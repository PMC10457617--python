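"""Unscreened colorectal-cancer natural histories for an average-risk cohort.

Each simulated person enters the cohort alive and free of diagnosed cancer at
age 40.  Adenomas arise from a non-homogeneous Poisson process with individual
frailty, grow along a bounded deterministic curve, and may transform into
preclinical cancer whose stage advances through dwell times until clinical
presentation; death is the earlier of other-cause death (life table) and
cancer death (stage- and age-dependent survival).

Randomness is organized as counter-based (Philox) streams keyed by
``(master_seed, person id, redraw attempt, stream tag)`` so that cohorts are
reproducible independently of execution order, and so that the screening
overlay can re-open a person's dedicated screening stream without touching the
disease trajectory — the common-random-numbers design that makes paired
between-strategy comparisons noise-free at the individual level.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np

from .params import ConfigurationError, NaturalHistoryParams, STAGES

__all__ = [
    "Adenoma",
    "PreclinicalCancer",
    "Individual",
    "Event",
    "LifeHistory",
    "draw_individual",
    "generate_adenomas",
    "adenoma_diameter",
    "assign_transformation",
    "build_cancer",
    "crc_death_age",
    "simulate_unscreened",
    "generate_individual",
    "build_cohort",
    "person_rng",
]

_NH_STREAM = 0
_SCREEN_STREAM = 1


def person_rng(master_seed: int, person_id: int, attempt: int, stream: int) -> np.random.Generator:
    """Counter-based random stream for one person.

    The Philox key packs (person id, attempt, stream tag) into the second key
    word, with the master seed as the first, so streams never collide across
    persons, redraw attempts, or purposes.
    """
    word = (np.uint64(person_id) << np.uint64(16)) | (np.uint64(attempt) << np.uint64(8)) | np.uint64(stream)
    key = np.array([np.uint64(master_seed), word], dtype=np.uint64)
    return np.random.Generator(np.random.Philox(key=key))


# ---------------------------------------------------------------------------
# lesion and person containers


@dataclass
class PreclinicalCancer:
    """An invasive cancer from its preclinical onset to clinical presentation.

    ``stage_entry_ages`` holds the four ages at which the (undetected) tumor
    enters AJCC stages I-IV; entries beyond the clinical detection age are the
    counterfactual schedule the tumor would have followed.  ``u_cure`` and
    ``u_time`` are pre-drawn survival uniforms so that the post-diagnosis
    survival draw is coupled across screening strategies: detecting the same
    tumor earlier maps the same underlying draw through a better stage.
    """

    onset_age: float
    sojourn_years: float
    stage_entry_ages: tuple[float, float, float, float]
    u_cure: float
    u_time: float

    @property
    def clinical_detection_age(self) -> float:
        return self.onset_age + self.sojourn_years

    def stage_at(self, age: float) -> int:
        if age < self.onset_age:
            raise ValueError("cancer has no stage before its preclinical onset")
        stage = 1
        for s, entry in zip(STAGES, self.stage_entry_ages):
            if age >= entry:
                stage = s
        return stage


@dataclass
class Adenoma:
    """One adenomatous polyp: onset, location, growth anchor and (optional)
    malignant transformation pinned to this lesion."""

    onset_age: float
    segment: str
    growth_years_to_10mm: float
    transformation_age: Optional[float] = None
    cancer: Optional[PreclinicalCancer] = None


@dataclass
class Individual:
    id: int
    sex: str  # "female" | "male"
    frailty: float
    other_cause_death_age: float
    adenomas: list[Adenoma] = field(default_factory=list)
    master_seed: int = 0
    attempt: int = 0

    def screening_rng(self) -> np.random.Generator:
        """Fresh screening stream; identical draws every time it is opened."""
        return person_rng(self.master_seed, self.id, self.attempt, _SCREEN_STREAM)


@dataclass(frozen=True)
class Event:
    age: float
    kind: str  # test | colonoscopy | adenoma_removed | crc_diagnosis | death
    detail: tuple = ()


@dataclass
class LifeHistory:
    """Time-ordered event list for one person under one (non-)screening arm."""

    individual_id: int
    events: list[Event] = field(default_factory=list)

    def add(self, age: float, kind: str, *detail) -> None:
        self.events.append(Event(age, kind, tuple(detail)))

    @property
    def death_age(self) -> float:
        last = self.events[-1]
        if last.kind != "death":
            raise ValueError("life history has no death event")
        return last.age

    @property
    def death_cause(self) -> str:
        last = self.events[-1]
        if last.kind != "death":
            raise ValueError("life history has no death event")
        return last.detail[0]

    @property
    def crc_diagnosis(self) -> Optional[Event]:
        for ev in self.events:
            if ev.kind == "crc_diagnosis":
                return ev
        return None

    def clinical_events(self) -> list[Event]:
        """Events with clinical consequence (test administrations excluded)."""
        return [ev for ev in self.events if ev.kind != "test"]

    def validate(self) -> None:
        ages = [ev.age for ev in self.events]
        if ages != sorted(ages):
            raise ValueError("event ages must be non-decreasing")
        kinds = [ev.kind for ev in self.events]
        if kinds.count("death") != 1 or kinds[-1] != "death":
            raise ValueError("exactly one death event, last in the list")
        if kinds.count("crc_diagnosis") > 1:
            raise ValueError("at most one cancer diagnosis per person")


# ---------------------------------------------------------------------------
# operations


def draw_individual(params: NaturalHistoryParams, person_id: int, rng: np.random.Generator,
                    master_seed: int = 0, attempt: int = 0) -> Individual:
    """Draw sex (50/50), frailty ~ Normal(0, frailty_sd^2) and an other-cause
    death age from the life table conditional on survival to cohort entry."""
    params.validate()
    sex = "male" if rng.random() < 0.5 else "female"
    frailty = float(rng.normal(0.0, params.frailty_sd)) if params.frailty_sd > 0 else 0.0
    death_age = params.life_table.draw_death_age(sex, rng, from_age=int(params.entry_age))
    return Individual(id=person_id, sex=sex, frailty=frailty, other_cause_death_age=death_age,
                      master_seed=master_seed, attempt=attempt)


def generate_adenomas(individual: Individual, params: NaturalHistoryParams,
                      rng: np.random.Generator) -> list[Adenoma]:
    """Sample adenoma onsets from the person's non-homogeneous Poisson process
    up to ``max_age`` and attach location and growth draws to each lesion.

    With a piecewise-constant age effect the process restricted to an age band
    is homogeneous, so onsets are drawn band by band: a Poisson count, then
    uniform onset ages within the band.
    """
    log_rate = params.adenoma_baseline_log_rate + individual.frailty
    if individual.sex == "male":
        log_rate += params.sex_log_effect
    base = math.exp(log_rate) if log_rate > -math.inf else 0.0
    segments = list(params.segment_probs)
    seg_probs = [params.segment_probs[s] for s in segments]
    adenomas: list[Adenoma] = []
    for a0, a1, mult in params.age_bands():
        lam = base * mult * (a1 - a0)
        if lam <= 0.0:
            continue
        count = int(rng.poisson(lam))
        for _ in range(count):
            onset = a0 + (a1 - a0) * rng.random()
            seg = segments[0] if len(segments) == 1 else segments[_categorical(rng, seg_probs)]
            g = params.growth_time_to_10mm[seg]
            growth = float(np.exp(rng.normal(g["meanlog"], g["sdlog"])))
            adenomas.append(Adenoma(onset_age=onset, segment=seg, growth_years_to_10mm=growth))
    adenomas.sort(key=lambda a: a.onset_age)
    return adenomas


def _categorical(rng: np.random.Generator, probs: list[float]) -> int:
    u = rng.random()
    acc = 0.0
    for i, p in enumerate(probs):
        acc += p
        if u < acc:
            return i
    return len(probs) - 1


def _growth_lambda(adenoma: Adenoma, params: NaturalHistoryParams) -> float:
    d0, dmax = params.initial_diameter_mm, params.max_diameter_mm
    # solve d_max - (d_max - d0) * exp(-lam * t10) = 10
    return -math.log((dmax - 10.0) / (dmax - d0)) / adenoma.growth_years_to_10mm


def adenoma_diameter(adenoma: Adenoma, age: float, params: NaturalHistoryParams) -> float:
    """Deterministic diameter (mm) at ``age``: an exponential approach to the
    asymptote, anchored to pass through 10 mm at onset + growth_years_to_10mm."""
    if age < adenoma.onset_age:
        raise ValueError("diameter undefined before adenoma onset")
    t = age - adenoma.onset_age
    d0, dmax = params.initial_diameter_mm, params.max_diameter_mm
    return dmax - (dmax - d0) * math.exp(-_growth_lambda(adenoma, params) * t)


_HAZARD_GRID_STEP = 0.5  # years; trapezoid integration grid for transformation


def assign_transformation(adenoma: Adenoma, individual_sex: str, params: NaturalHistoryParams,
                          rng: np.random.Generator) -> Adenoma:
    """Draw the adenoma's malignant-transformation age (or none).

    The hazard is size-dependent (and optionally age/sex-dependent) along the
    deterministic growth curve; the draw inverts the cumulative hazard on a
    half-year grid against a unit exponential.  The exponential deviate is
    consumed from the stream whether or not the lesion ever transforms, so the
    stream layout does not depend on the outcome.
    """
    e = float(rng.exponential())
    tc = params.transition_coeffs
    if tc.log_hazard_at_10mm == -math.inf:
        adenoma.transformation_age = None
        return adenoma
    horizon = params.max_age - adenoma.onset_age
    if horizon <= 0:
        adenoma.transformation_age = None
        return adenoma
    n = max(2, int(horizon / _HAZARD_GRID_STEP) + 1)
    t = np.linspace(0.0, horizon, n)
    d0, dmax = params.initial_diameter_mm, params.max_diameter_mm
    diam = dmax - (dmax - d0) * np.exp(-_growth_lambda(adenoma, params) * t)
    log_h = tc.log_hazard_at_10mm + tc.size_power * (np.log(diam) - math.log(10.0))
    if individual_sex == "male":
        log_h = log_h + tc.male_log_effect
    if tc.age_log_slope != 0.0:
        log_h = log_h + tc.age_log_slope * (adenoma.onset_age + t - 50.0)
    h = np.exp(log_h)
    cum = np.concatenate([[0.0], np.cumsum(0.5 * (h[1:] + h[:-1]) * np.diff(t))])
    if e >= cum[-1]:
        adenoma.transformation_age = None
    else:
        adenoma.transformation_age = adenoma.onset_age + float(np.interp(e, cum, t))
    return adenoma


def build_cancer(adenoma: Adenoma, params: NaturalHistoryParams, rng: np.random.Generator) -> PreclinicalCancer:
    """Attach the preclinical cancer that grows out of a transformed adenoma:
    a lognormal sojourn to clinical presentation and exponential stage dwell
    times fixing the ages of entry into AJCC stages I-IV."""
    if adenoma.transformation_age is None:
        raise ValueError("adenoma has no transformation age")
    onset = adenoma.transformation_age
    sp = params.sojourn_params
    sojourn = float(np.exp(rng.normal(sp["meanlog"], sp["sdlog"])))
    dwells = [float(rng.exponential(m)) for m in params.stage_dwell_means]
    entries = (onset,
               onset + dwells[0],
               onset + dwells[0] + dwells[1],
               onset + dwells[0] + dwells[1] + dwells[2])
    cancer = PreclinicalCancer(onset_age=onset, sojourn_years=sojourn, stage_entry_ages=entries,
                               u_cure=float(rng.random()), u_time=float(rng.random()))
    adenoma.cancer = cancer
    return cancer


def crc_death_age(stage: int, diagnosis_age: float, sex: str, params: NaturalHistoryParams,
                  rng: np.random.Generator | None = None,
                  uniforms: tuple[float, float] | None = None) -> Optional[float]:
    """Cancer-specific death age after diagnosis, or None if cured.

    A stage-specific cure draw, otherwise an exponential excess-hazard
    survival time with an age-band multiplier at diagnosis.  ``uniforms``
    allows the caller to supply pre-drawn (cure, time) deviates — the
    common-random-number coupling used by the screening overlay.
    """
    if stage not in STAGES:
        raise ConfigurationError(f"unknown AJCC stage {stage!r}")
    if uniforms is None:
        if rng is None:
            raise ValueError("either rng or uniforms must be given")
        uniforms = (float(rng.random()), float(rng.random()))
    u_cure, u_time = uniforms
    sv = params.survival_params
    if u_cure < sv.cure_prob[stage]:
        return None
    h = sv.hazard(stage, diagnosis_age)
    if h <= 0.0:
        return None
    return diagnosis_age - math.log(max(u_time, 1e-300)) / h


def live_cancers(individual: Individual) -> list[PreclinicalCancer]:
    return [a.cancer for a in individual.adenomas if a.cancer is not None]


def simulate_unscreened(individual: Individual, params: NaturalHistoryParams) -> LifeHistory:
    """The no-screening arm: the earliest clinical presentation (if it beats
    other-cause death) yields a diagnostic colonoscopy, a diagnosis and a
    survival draw; otherwise the person dies of other causes undiagnosed."""
    history = LifeHistory(individual.id)
    _finish_naturally(history, individual, params, from_age=params.entry_age,
                      excluded=frozenset())
    history.validate()
    return history


def _finish_naturally(history: LifeHistory, individual: Individual, params: NaturalHistoryParams,
                      from_age: float, excluded: frozenset[int]) -> None:
    """Append the post-screening (or entirely unscreened) natural course:
    clinical presentation of any surviving cancer, then death.

    ``excluded`` holds ids of adenomas removed before transformation, whose
    cancers therefore never occur.
    """
    other = individual.other_cause_death_age
    candidates = [a.cancer for i, a in enumerate(individual.adenomas)
                  if a.cancer is not None and i not in excluded
                  and a.cancer.clinical_detection_age >= from_age]
    candidates.sort(key=lambda c: c.clinical_detection_age)
    if candidates and candidates[0].clinical_detection_age < other:
        cancer = candidates[0]
        det = cancer.clinical_detection_age
        stage = cancer.stage_at(det)
        history.add(det, "colonoscopy", "diagnostic")
        history.add(det, "crc_diagnosis", stage, "clinical")
        death = crc_death_age(stage, det, individual.sex, params,
                              uniforms=(cancer.u_cure, cancer.u_time))
        if death is not None and death < other:
            history.add(death, "death", "crc")
        else:
            history.add(other, "death", "other")
    else:
        history.add(other, "death", "other")


# ---------------------------------------------------------------------------
# cohort generation


def generate_individual(params: NaturalHistoryParams, person_id: int, master_seed: int) -> Individual:
    """Generate one person's complete latent disease trajectory.

    Trajectories implying clinical cancer before cohort entry at 40 are
    rejected and redrawn from a fresh stream, keeping the 'free of diagnosed
    cancer at 40' cohort definition exact.
    """
    for attempt in range(64):
        rng = person_rng(master_seed, person_id, attempt, _NH_STREAM)
        ind = draw_individual(params, person_id, rng, master_seed=master_seed, attempt=attempt)
        ind.adenomas = generate_adenomas(ind, params, rng)
        ok = True
        for adenoma in ind.adenomas:
            assign_transformation(adenoma, ind.sex, params, rng)
            if adenoma.transformation_age is not None:
                cancer = build_cancer(adenoma, params, rng)
                if cancer.clinical_detection_age < params.entry_age:
                    ok = False
        if ok:
            return ind
    raise RuntimeError(f"person {person_id}: rejection sampling failed after 64 attempts")


def build_cohort(params: NaturalHistoryParams, n: int, master_seed: int) -> list[Individual]:
    """n independent average-risk persons, reproducible from the master seed."""
    params.validate()
    return [generate_individual(params, i, master_seed) for i in range(n)]
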