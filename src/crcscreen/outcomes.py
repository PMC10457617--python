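"""Paired per-1000 comparative outcomes between a screening arm and the
common-random-number no-screening arm.

Because both arms share each person's disease trajectory, per-person paired
differences carry no between-person noise and the Monte-Carlo standard error
of life-years gained comes straight from the paired-difference distribution.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .natural_history import LifeHistory
from .screening import count_resources

__all__ = ["OutcomeSummary", "life_years", "summarize"]


class PairingError(ValueError):
    """The two cohorts are not the same persons in the same order."""


def life_years(history: LifeHistory, entry_age: float = 40.0) -> float:
    """Undiscounted person-years lived from cohort entry to death."""
    return history.death_age - entry_age


@dataclass(frozen=True)
class OutcomeSummary:
    """Per-1000 comparative outcomes for one (strategy, adherence) cell."""

    n: int
    lyg_per_1000: float
    se_lyg: float
    crc_cases_per_1000: float
    crc_deaths_per_1000: float
    unscreened_cases_per_1000: float
    unscreened_deaths_per_1000: float
    incidence_reduction_pct: float
    mortality_reduction_pct: float
    cases_averted_per_1000: float
    deaths_averted_per_1000: float
    noninvasive_tests_per_1000: float
    colonoscopies_per_1000: float
    colonoscopies_by_reason_per_1000: dict[str, float] = field(default_factory=dict)

    def validate(self) -> None:
        if not np.isfinite(self.lyg_per_1000):
            raise ValueError("lyg_per_1000 must be finite")
        if self.crc_deaths_per_1000 > self.crc_cases_per_1000 + 1e-9:
            raise ValueError("deaths cannot exceed cases")
        for r in (self.incidence_reduction_pct, self.mortality_reduction_pct):
            if not (-100.0 - 1e-9 <= r <= 100.0 + 1e-9):
                raise ValueError("reductions must lie in [-100, 100]")


def _pct_reduction(screened: float, unscreened: float) -> float:
    if unscreened == 0.0:
        return 0.0
    return 100.0 * (1.0 - screened / unscreened)


def summarize(screened: list[LifeHistory], unscreened: list[LifeHistory],
              entry_age: float = 40.0) -> OutcomeSummary:
    """Collapse a paired pair of cohorts into per-1000 comparative outcomes."""
    if len(screened) != len(unscreened):
        raise PairingError("cohorts differ in size")
    n = len(screened)
    if n == 0:
        raise PairingError("empty cohorts")
    diffs = np.empty(n)
    s_cases = s_deaths = u_cases = u_deaths = 0
    tests = 0
    colos_by_reason = {"followup": 0, "surveillance": 0, "diagnostic": 0}
    for k, (s, u) in enumerate(zip(screened, unscreened)):
        if s.individual_id != u.individual_id:
            raise PairingError(
                f"position {k}: screened person {s.individual_id} vs unscreened {u.individual_id}")
        diffs[k] = life_years(s, entry_age) - life_years(u, entry_age)
        s_cases += s.crc_diagnosis is not None
        u_cases += u.crc_diagnosis is not None
        s_deaths += s.death_cause == "crc"
        u_deaths += u.death_cause == "crc"
        t, c = count_resources(s)
        tests += t
        for reason, cnt in c.items():
            colos_by_reason[reason] += cnt
    per1000 = 1000.0 / n
    se = float(diffs.std(ddof=1) / np.sqrt(n) * 1000.0) if n > 1 else float("nan")
    summary = OutcomeSummary(
        n=n,
        lyg_per_1000=float(diffs.mean() * 1000.0),
        se_lyg=se,
        crc_cases_per_1000=s_cases * per1000,
        crc_deaths_per_1000=s_deaths * per1000,
        unscreened_cases_per_1000=u_cases * per1000,
        unscreened_deaths_per_1000=u_deaths * per1000,
        incidence_reduction_pct=_pct_reduction(s_cases, u_cases),
        mortality_reduction_pct=_pct_reduction(s_deaths, u_deaths),
        cases_averted_per_1000=(u_cases - s_cases) * per1000,
        deaths_averted_per_1000=(u_deaths - s_deaths) * per1000,
        noninvasive_tests_per_1000=tests * per1000,
        colonoscopies_per_1000=sum(colos_by_reason.values()) * per1000,
        colonoscopies_by_reason_per_1000={k: v * per1000 for k, v in colos_by_reason.items()},
    )
    summary.validate()
    return summary
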