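"""Scenario grids, incremental life-year tradeoff matrices, and the
threshold search for blood-test adenoma sensitivity.

All cells of a grid share one natural-history cohort (cached per master
seed), so between-cell differences are paired and the bisection search sees a
deterministic, monotone empirical response."""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Callable, Mapping, Optional, Sequence

import pandas as pd
import yaml

from .natural_history import Individual, build_cohort, simulate_unscreened
from .outcomes import OutcomeSummary, summarize
from .params import ConfigurationError, NaturalHistoryParams
from .screening import (
    AdherenceModel,
    ColonoscopySpec,
    Strategy,
    SurveillancePolicy,
    TestSpec,
    derive_nonadvanced_sensitivity,
    schedule_and_run,
)

__all__ = [
    "load_test_specs",
    "real_world_adherence",
    "ScenarioGrid",
    "ThresholdQuery",
    "CohortCache",
    "run_strategy",
    "run_grid",
    "incremental_matrix",
    "threshold_search",
    "BracketError",
]

GRID_ADHERENCE_LEVELS = (0.3, 0.4, 0.5, 0.6, 0.7, 1.0)


def _tests_file() -> Path:
    return Path(str(resources.files("crcscreen").joinpath("data", "screening_tests.yaml")))


def load_test_specs(path: str | Path | None = None) -> dict[str, TestSpec]:
    """The packaged noninvasive-test assumption set (or a user file in the
    same schema)."""
    with open(path or _tests_file()) as fh:
        d = yaml.safe_load(fh)
    specs = {}
    for name, row in d["tests"].items():
        spec = TestSpec(name=name, **row)
        spec.validate()
        specs[name] = spec
    return specs


def real_world_adherence(path: str | Path | None = None) -> dict[str, float]:
    with open(path or _tests_file()) as fh:
        return dict(yaml.safe_load(fh)["real_world_adherence"])


@dataclass(frozen=True)
class ScenarioGrid:
    """The cross of strategies x adherence levels, plus real-world adherence
    for tests that have an observed rate."""

    tests: Mapping[str, TestSpec]
    adherence_levels: Sequence[float] = GRID_ADHERENCE_LEVELS
    real_world_rates: Mapping[str, float] = field(default_factory=dict)

    @classmethod
    def default(cls) -> "ScenarioGrid":
        return cls(tests=load_test_specs(), real_world_rates=real_world_adherence())

    def cells(self) -> list[tuple[str, str, float]]:
        """(test name, adherence label, rate) for every grid cell."""
        out = []
        for name in self.tests:
            for rate in self.adherence_levels:
                out.append((name, f"{rate:g}", float(rate)))
            if name in self.real_world_rates:
                out.append((name, "real_world", float(self.real_world_rates[name])))
        return out


class CohortCache:
    """Natural-history cohorts and unscreened arms, keyed by (n, master_seed).

    Grid evaluations and threshold searches re-use one cohort so that every
    cell sees identical disease realizations (common random numbers)."""

    def __init__(self, params: NaturalHistoryParams, max_entries: int = 4):
        self.params = params
        self.max_entries = max_entries
        self._store: dict[tuple[int, int], tuple[list[Individual], list]] = {}

    def get(self, n: int, master_seed: int):
        key = (n, master_seed)
        if key not in self._store:
            if len(self._store) >= self.max_entries:
                self._store.pop(next(iter(self._store)))
            cohort = build_cohort(self.params, n, master_seed)
            unscreened = [simulate_unscreened(ind, self.params) for ind in cohort]
            self._store[key] = (cohort, unscreened)
        return self._store[key]


def run_strategy(strategy: Strategy, params: NaturalHistoryParams, n: int, master_seed: int,
                 colono: ColonoscopySpec | None = None,
                 policy: SurveillancePolicy | None = None,
                 cache: CohortCache | None = None) -> OutcomeSummary:
    """Simulate one strategy arm against its paired no-screening arm."""
    cache = cache or CohortCache(params)
    cohort, unscreened = cache.get(n, master_seed)
    screened = [schedule_and_run(ind, strategy, params, colono, policy) for ind in cohort]
    return summarize(screened, unscreened, entry_age=params.entry_age)


def run_grid(grid: ScenarioGrid, params: NaturalHistoryParams, n: int, master_seed: int,
             colono: ColonoscopySpec | None = None,
             policy: SurveillancePolicy | None = None,
             cache: CohortCache | None = None) -> pd.DataFrame:
    """One OutcomeSummary row per (test, adherence) cell, all cells sharing
    the same cohort realization; deterministic given the master seed."""
    cache = cache or CohortCache(params)
    rows = []
    for test_name, label, rate in grid.cells():
        strategy = Strategy(test=grid.tests[test_name], adherence=AdherenceModel.per_round(rate))
        s = run_strategy(strategy, params, n, master_seed, colono, policy, cache)
        row = {
            "test": test_name,
            "adherence": label,
            "adherence_rate": rate,
            "n": s.n,
            "lyg_per_1000": s.lyg_per_1000,
            "se_lyg": s.se_lyg,
            "crc_cases_per_1000": s.crc_cases_per_1000,
            "crc_deaths_per_1000": s.crc_deaths_per_1000,
            "incidence_reduction_pct": s.incidence_reduction_pct,
            "mortality_reduction_pct": s.mortality_reduction_pct,
            "cases_averted_per_1000": s.cases_averted_per_1000,
            "deaths_averted_per_1000": s.deaths_averted_per_1000,
            "noninvasive_tests_per_1000": s.noninvasive_tests_per_1000,
            "colonoscopies_per_1000": s.colonoscopies_per_1000,
            "colonoscopies_followup_per_1000": s.colonoscopies_by_reason_per_1000["followup"],
            "colonoscopies_surveillance_per_1000": s.colonoscopies_by_reason_per_1000["surveillance"],
            "colonoscopies_diagnostic_per_1000": s.colonoscopies_by_reason_per_1000["diagnostic"],
            "master_seed": master_seed,
        }
        rows.append(row)
    return pd.DataFrame(rows)


def incremental_matrix(grid_results: pd.DataFrame, reference: str) -> pd.DataFrame:
    """Life-years-gained differences versus a reference test.

    Rows are (other test, its adherence label); columns are the reference
    test's adherence labels; entries are LYG_other - LYG_reference, so a
    negative entry means the reference test gains more.  All cells must come
    from the same master seed (paired cohorts)."""
    if grid_results["master_seed"].nunique() != 1:
        raise PairingMismatch("grid results mix master seeds; differences would be unpaired")
    ref = grid_results[grid_results["test"] == reference]
    if ref.empty:
        raise ConfigurationError(f"reference test {reference!r} not in grid results")
    others = grid_results[grid_results["test"] != reference]
    mat = pd.DataFrame(
        {f"{reference}@{r.adherence}": others["lyg_per_1000"].to_numpy() - r.lyg_per_1000
         for r in ref.itertuples()},
        index=pd.MultiIndex.from_frame(others[["test", "adherence"]]),
    )
    return mat


class PairingMismatch(ValueError):
    pass


class BracketError(ValueError):
    """The bracket endpoints do not straddle the comparator response."""


@dataclass(frozen=True)
class ThresholdQuery:
    """Find the blood-test adenoma sensitivity whose LYG matches a comparator.

    The free dimension is the advanced-adenoma sensitivity; the nonadvanced
    value is tied to it either by the half-rule (``advanced_with_half_rule``)
    or set equal (``both_equal``).  CRC sensitivity and specificity stay at
    the minimum-threshold values of the blood-test template."""

    comparator_lyg: float
    tolerance: float = 2.0  # years per 1000
    bracket: tuple[float, float] = (0.10, 0.60)
    free_dimension: str = "advanced_with_half_rule"  # | "both_equal"
    sens_crc: float = 0.74
    specificity: float = 0.90
    interval_years: int = 3
    adherence_rate: float = 1.0
    min_bracket_width: float = 0.005  # stop below half a percentage point

    def validate(self) -> None:
        lo, hi = self.bracket
        floor = 1.0 - self.specificity
        if not (floor <= lo < hi <= 1.0):
            raise ConfigurationError("bracket must lie within [1 - specificity, 1]")
        if self.tolerance <= 0:
            raise ConfigurationError("tolerance must be > 0")
        if self.free_dimension not in ("advanced_with_half_rule", "both_equal"):
            raise ConfigurationError(f"unknown free_dimension {self.free_dimension!r}")

    def test_spec(self, sens_advanced: float) -> TestSpec:
        if self.free_dimension == "advanced_with_half_rule":
            nonadv = derive_nonadvanced_sensitivity(sens_advanced, self.specificity)
        else:
            nonadv = sens_advanced
        return TestSpec(name=f"blood_adv{sens_advanced:.4f}",
                        sens_nonadvanced=nonadv, sens_advanced=sens_advanced,
                        sens_crc=self.sens_crc, specificity=self.specificity,
                        interval_years=self.interval_years)


def threshold_search(query: ThresholdQuery,
                     params: NaturalHistoryParams | None = None,
                     n: int | None = None,
                     master_seed: int | None = None,
                     evaluator: Callable[[float], float] | None = None,
                     cache: CohortCache | None = None) -> float:
    """Bisection on advanced-adenoma sensitivity until the simulated LYG
    matches the comparator within tolerance (or the bracket closes).

    ``evaluator`` maps a sensitivity to LYG per 1000; when omitted, the
    simulated blood-test response at fixed seeds is used, which is monotone
    and — thanks to the shared cohort — free of between-evaluation noise."""
    query.validate()
    if evaluator is None:
        if params is None or n is None or master_seed is None:
            raise ConfigurationError("simulation evaluator needs params, n and master_seed")
        cache = cache or CohortCache(params)

        def evaluator(s: float) -> float:
            strategy = Strategy(test=query.test_spec(s),
                                adherence=AdherenceModel.per_round(query.adherence_rate))
            return run_strategy(strategy, params, n, master_seed, cache=cache).lyg_per_1000

    lo, hi = query.bracket
    f_lo, f_hi = evaluator(lo), evaluator(hi)
    if abs(f_lo - query.comparator_lyg) <= query.tolerance:
        return lo
    if abs(f_hi - query.comparator_lyg) <= query.tolerance:
        return hi
    if not (min(f_lo, f_hi) < query.comparator_lyg < max(f_lo, f_hi)):
        raise BracketError(
            f"comparator LYG {query.comparator_lyg} not straddled by bracket: "
            f"LYG({lo}) = {f_lo:.2f}, LYG({hi}) = {f_hi:.2f}")
    increasing = f_hi > f_lo
    while hi - lo > query.min_bracket_width:
        mid = 0.5 * (lo + hi)
        f_mid = evaluator(mid)
        if abs(f_mid - query.comparator_lyg) <= query.tolerance:
            return mid
        if (f_mid < query.comparator_lyg) == increasing:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)
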