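"""Aggregate paired person histories into screening-effectiveness measures.

Conventions:

* *Cancer cases* are clinical diagnoses plus screen-detected invasive
  cancers (stages I-III/IV); resected preinvasive lesions are not cases.
* *PC deaths* include deaths from resection surgery (screening-induced, so
  they must count against screening in mortality outcomes); incidence is
  unaffected.
* Person-years run from birth to death in each arm, so rates differ between
  arms both through counts and through screening-extended lives.
* NNS / NNSurv / NNT divide screening tests / surveillance tests / total
  resections by the between-arm difference in PC deaths of the paired,
  equally-sized cohorts.  Internal arithmetic is unrounded; display
  rounding follows the conventional precision (NNS integer, NNSurv and NNT
  one decimal).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

RESECTION_LABELS = ("false_positive", "LGD", "IGD", "HGD",
                    "SD_cancer_I", "SD_cancer_II", "SD_cancer_III_IV")


class OutcomeError(ValueError):
    pass


def rate_per_100k(count: float, person_years: float) -> float:
    """Events per 100,000 person-years."""
    if person_years <= 0:
        raise OutcomeError("person_years must be positive")
    return count / person_years * 1e5


@dataclass
class ScenarioCounters:
    """Raw event counts for one simulated arm."""

    n_persons: int
    person_years: float
    cancer_cases: int
    pc_deaths: int                 # incl. surgical deaths
    other_deaths: int
    screen_tests: int = 0
    surveillance_tests: int = 0
    resections_by_stage: dict = field(default_factory=dict)
    interval_cancers_5y: int = 0
    interval_cancers_total: int = 0
    person_years_post_negative: float = 0.0

    def __post_init__(self):
        if self.n_persons != self.pc_deaths + self.other_deaths:
            raise OutcomeError("every person must die of exactly one cause")

    @property
    def total_resections(self) -> int:
        return int(sum(self.resections_by_stage.values()))

    @property
    def incidence_rate(self) -> float:
        return rate_per_100k(self.cancer_cases, self.person_years)

    @property
    def mortality_rate(self) -> float:
        return rate_per_100k(self.pc_deaths, self.person_years)


def counters_from_unscreened(cohort) -> ScenarioCounters:
    cases = int(cohort.case_mask.sum())
    deaths = int(cohort.pc_death_mask.sum())
    return ScenarioCounters(
        n_persons=cohort.n,
        person_years=float(cohort.final_death.sum()),
        cancer_cases=cases, pc_deaths=deaths,
        other_deaths=cohort.n - deaths)


def counters_from_screened(n: int, arrs: dict) -> ScenarioCounters:
    """Build counters from the per-person arrays of the screening engine."""
    cases = int((arrs["clinical_dx_stage"] > 0).sum() + (arrs["sd_stage"] > 0).sum())
    pc_deaths = int((arrs["cause"] > 0).sum())  # cancer + surgical
    res = arrs["resections"]
    by_stage = {RESECTION_LABELS[k]: int(res[:, k].sum()) for k in range(6)}
    by_stage[RESECTION_LABELS[6]] = int((arrs["sd_stage"] == 6).sum())
    post_neg = arrs["final_death_age"] - arrs["first_negative_screen_age"]
    return ScenarioCounters(
        n_persons=n,
        person_years=float(arrs["final_death_age"].sum()),
        cancer_cases=cases, pc_deaths=pc_deaths,
        other_deaths=n - pc_deaths,
        screen_tests=int(arrs["n_screen_tests"].sum()),
        surveillance_tests=int(arrs["n_surveillance_tests"].sum()),
        resections_by_stage=by_stage,
        interval_cancers_5y=int(arrs["interval_cancer_5y"].sum()),
        interval_cancers_total=int(arrs["interval_cancer"].sum()),
        person_years_post_negative=float(np.nansum(post_neg)))


@dataclass
class Effectiveness:
    deaths_prevented: float
    nns: float
    nnsurv: float
    nnt: float
    undefined: bool = False


def effectiveness_ratios(screened: ScenarioCounters,
                         unscreened: ScenarioCounters) -> Effectiveness:
    """NNS, NNSurv and NNT per cancer death prevented (paired cohorts)."""
    if screened.n_persons != unscreened.n_persons:
        raise OutcomeError("arms must simulate the same persons")
    prevented = unscreened.pc_deaths - screened.pc_deaths
    if prevented <= 0:
        return Effectiveness(prevented, math.nan, math.nan, math.nan,
                             undefined=True)
    return Effectiveness(
        deaths_prevented=prevented,
        nns=screened.screen_tests / prevented,
        nnsurv=screened.surveillance_tests / prevented,
        nnt=screened.total_resections / prevented)


def life_years_gained(final_death_screened: np.ndarray,
                      final_death_unscreened: np.ndarray) -> float:
    """Sum of per-person death-age differences (negative for harmed persons)."""
    if final_death_screened.shape != final_death_unscreened.shape:
        raise OutcomeError("paired arms must be person-aligned")
    return float(np.sum(final_death_screened - final_death_unscreened))


def interval_cancer_rate(counters: ScenarioCounters, window: str = "total") -> float:
    """Interval cancers per 100,000 person-years lived after a first negative screen.

    An interval cancer is a clinical diagnosis whose most recent screening
    test was negative ('total': any time after, including past the stop age;
    '5y': within five years of that negative screen).
    """
    count = (counters.interval_cancers_total if window == "total"
             else counters.interval_cancers_5y)
    if counters.person_years_post_negative <= 0:
        return 0.0
    return rate_per_100k(count, counters.person_years_post_negative)


@dataclass
class OutcomeTable:
    """One screened-vs-unscreened comparison in the standard layout."""

    scenario: str
    unscreened: ScenarioCounters
    screened: ScenarioCounters
    lyg: float

    @property
    def effectiveness(self) -> Effectiveness:
        return effectiveness_ratios(self.screened, self.unscreened)

    @property
    def case_reduction_pct(self) -> float:
        u = self.unscreened.cancer_cases
        return 100.0 * (u - self.screened.cancer_cases) / u

    @property
    def death_reduction_pct(self) -> float:
        u = self.unscreened.pc_deaths
        return 100.0 * (u - self.screened.pc_deaths) / u

    @property
    def incidence_reduction_pct(self) -> float:
        u = self.unscreened.incidence_rate
        return 100.0 * (u - self.screened.incidence_rate) / u

    @property
    def mortality_reduction_pct(self) -> float:
        u = self.unscreened.mortality_rate
        return 100.0 * (u - self.screened.mortality_rate) / u

    def to_dict(self) -> dict:
        eff = self.effectiveness
        per10k = 10_000 / self.unscreened.n_persons
        s, u = self.screened, self.unscreened
        return {
            "scenario": self.scenario,
            "n_persons": u.n_persons,
            "cases_per_10k_unscreened": u.cancer_cases * per10k,
            "cases_per_10k_screened": s.cancer_cases * per10k,
            "case_reduction_pct": self.case_reduction_pct,
            "deaths_per_10k_unscreened": u.pc_deaths * per10k,
            "deaths_per_10k_screened": s.pc_deaths * per10k,
            "death_reduction_pct": self.death_reduction_pct,
            "incidence_rate_unscreened": u.incidence_rate,
            "incidence_rate_screened": s.incidence_rate,
            "incidence_reduction_pct": self.incidence_reduction_pct,
            "mortality_rate_unscreened": u.mortality_rate,
            "mortality_rate_screened": s.mortality_rate,
            "mortality_reduction_pct": self.mortality_reduction_pct,
            "screen_tests_per_10k": s.screen_tests * per10k,
            "surveillance_tests_per_10k": s.surveillance_tests * per10k,
            "resections_per_10k": s.total_resections * per10k,
            "resections_by_stage_per_10k": {
                k: v * per10k for k, v in s.resections_by_stage.items()},
            "lyg_per_10k": self.lyg * per10k,
            "interval_cancer_rate_total": interval_cancer_rate(s, "total"),
            "interval_cancer_rate_5y": interval_cancer_rate(s, "5y"),
            "deaths_prevented_per_10k": eff.deaths_prevented * per10k,
            "nns": eff.nns,
            "nnsurv": eff.nnsurv,
            "nnt": eff.nnt,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def outcome_frame(tables: list) -> pd.DataFrame:
    """Long-format DataFrame over scenarios (sensitivity-grid output)."""
    rows = []
    for t in tables:
        d = t.to_dict()
        d.pop("resections_by_stage_per_10k")
        rows.append(d)
    return pd.DataFrame(rows)


def display_round(value: float, kind: str):
    """Display precision: NNS integer, NNSurv/NNT one decimal, rates integer."""
    if math.isnan(value):
        return value
    if kind == "nns":
        return round(value)
    if kind in ("nnsurv", "nnt"):
        return round(value, 1)
    if kind == "rate":
        return round(value)
    return value
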