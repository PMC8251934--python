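"""Screening, surveillance and surgical management overlaid on a disease course.

State machine
-------------
From ``start_age`` to ``stop_age`` every living, not-yet-diagnosed person is
offered a combined EUS/MRI screen at the policy interval (adherence 100%).
A test is positive with the stage-specific sensitivity when a lesion is
present, and with 1 - specificity when the pancreas is healthy (false
positive).  A positive test (screen or surveillance) leads to

* palliative care if the true stage is preclinical cancer III/IV (screen-
  detected late cancer: the stage III/IV survival law applies, no resection);
* resection with the stage-specific probability ``resect_prob_given_positive``
  (surgical mortality applies; resected preinvasive lesions are cured and the
  person re-enters the at-risk state, possibly growing a new lesion; resected
  preclinical stage I/II cancers are screen-detected cases that keep the
  observed clinical stage-specific survival);
* otherwise 6-monthly surveillance with the same test, during which the
  disease keeps progressing, until resection, clinical diagnosis, death, or
  -- for false positives -- a run of consecutive negative surveillance tests
  that sends the person back to routine screening.

Routine screens are suppressed while a person is under surveillance; persons
exit the program at (screen- or clinically-) diagnosed cancer or death.

Draw protocol
-------------
Screening consumes one uniform per stochastic decision, in strict event
order, from the person's counter-based stream (:mod:`pancsim.rng`):
test outcome; then for a positive: management (resect vs surveil; skipped
for stage III/IV); then surgical death for a resection; then, after a
curative preinvasive resection, one uniform for the re-onset age and -- if
the new onset falls before other-cause death -- a fixed block of ten
uniforms (fate, shared stage quantile, three (detection, timing) pairs,
survival Bernoulli, survival timing) describing the new lesion.  The
compiled cohort engine (:mod:`pancsim._engine`) and the pure-Python
reference walk below implement this protocol identically; their exact
agreement is enforced by tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .natural_history import (INF, PathwayConfig, Stage, _lesion_timeline,
                              sample_onset_age_conditional)
from .rng import CounterStream

CAUSE_OTHER, CAUSE_PC, CAUSE_SURGICAL = 0, 1, 2


class PolicyError(ValueError):
    pass


@dataclass(frozen=True)
class ScreeningPolicy:
    start_age: float = 50.0
    stop_age: float = 75.0
    interval: float = 1.0
    surveillance_interval: float = 0.5
    adherence: float = 1.0

    def __post_init__(self):
        if self.start_age >= self.stop_age:
            raise PolicyError("start_age must be below stop_age")
        if self.interval <= 0 or self.surveillance_interval <= 0:
            raise PolicyError("intervals must be positive")
        if self.adherence != 1.0:
            raise PolicyError("only full adherence is modeled")


@dataclass(frozen=True)
class TestCharacteristics:
    """Stage-specific sensitivity (LGD..preclinical III/IV) and specificity."""

    __test__ = False  # not a pytest collectable despite the name

    sensitivity: tuple = (0.60, 0.60, 0.75, 0.90, 0.93, 0.99)
    specificity: float = 0.90

    def __post_init__(self):
        if len(self.sensitivity) != 6:
            raise PolicyError("sensitivity needs 6 entries (LGD..preclinical III/IV)")
        vals = (*self.sensitivity, self.specificity)
        if any(not (0.0 <= p <= 1.0) for p in vals):
            raise PolicyError("probabilities must lie in [0, 1]")
        s = self.sensitivity[3:]
        if any(s[i] > s[i + 1] for i in range(2)):
            raise PolicyError("sensitivity must be non-decreasing over preclinical stages")

    def scaled(self, multiplier: float) -> "TestCharacteristics":
        """Sensitivity multiplied per stage and capped at 1 (sensitivity analyses)."""
        sens = tuple(min(1.0, p * multiplier) for p in self.sensitivity)
        return TestCharacteristics(sensitivity=sens, specificity=self.specificity)

    def with_specificity(self, spec: float) -> "TestCharacteristics":
        return TestCharacteristics(sensitivity=self.sensitivity, specificity=spec)


@dataclass(frozen=True)
class ManagementPolicy:
    """What happens after a positive test.

    ``resect_prob_given_positive`` covers the five resectable stages
    (LGD, IGD, HGD, preclinical I, preclinical II), applied at any positive
    test; stage III/IV is never resected.  ``resect_prob_false_positive``
    is the wrongful-resection probability for a healthy pancreas (0 by
    default: false positives go to surveillance and return to routine
    screening after ``false_positive_surveillance_rounds`` consecutive
    negative tests).  The 0.9 defaults reproduce the anchor that 81% of
    persons in preclinical stage I are resected per round (0.9 sensitivity
    x 0.9 resection); they are fully configurable.
    """

    resect_prob_given_positive: tuple = (0.9, 0.9, 0.9, 0.9, 0.9)
    resect_prob_false_positive: float = 0.0
    surgical_mortality: float = 0.03
    false_positive_surveillance_rounds: int = 1

    def __post_init__(self):
        if len(self.resect_prob_given_positive) != 5:
            raise PolicyError("resect_prob_given_positive needs 5 entries (LGD..preclinical II)")
        probs = (*self.resect_prob_given_positive, self.resect_prob_false_positive)
        if any(not (0.0 <= p <= 1.0) for p in probs):
            raise PolicyError("probabilities must lie in [0, 1]")
        if not (0.0 <= self.surgical_mortality < 1.0):
            raise PolicyError("surgical_mortality must lie in [0, 1)")
        if self.false_positive_surveillance_rounds < 1:
            raise PolicyError("false_positive_surveillance_rounds must be >= 1")

    def resect_prob_vector(self) -> np.ndarray:
        """Index by true stage 0..5 (0 = healthy pancreas, 1..5 = LGD..preclinical II)."""
        return np.array([self.resect_prob_false_positive,
                         *self.resect_prob_given_positive])

    def with_surgical_mortality(self, p: float) -> "ManagementPolicy":
        return ManagementPolicy(self.resect_prob_given_positive,
                                self.resect_prob_false_positive, p,
                                self.false_positive_surveillance_rounds)


def screen_schedule(policy: ScreeningPolicy) -> np.ndarray:
    """Offered screening ages: start, start+interval, ... <= stop."""
    n = int(math.floor((policy.stop_age - policy.start_age) / policy.interval + 1e-9)) + 1
    return policy.start_age + policy.interval * np.arange(n)


def apply_test(true_stage: int, chars: TestCharacteristics, u: float) -> bool:
    """Positive/negative test outcome for the given true stage.

    Healthy pancreas (stage NONE) is positive with 1 - specificity; a
    preinvasive/preclinical lesion with its stage sensitivity.  Clinically
    diagnosed persons have left screening, so clinical stages are rejected.
    """
    stage = int(true_stage)
    if stage == Stage.NONE:
        return u < 1.0 - chars.specificity
    if Stage.LGD <= stage <= Stage.PRECLIN_III_IV:
        return u < chars.sensitivity[stage - 1]
    raise PolicyError(f"stage {Stage(stage)!r} is not screen-testable")


def manage_positive(detected_stage: int, mgmt: ManagementPolicy, u: float) -> str:
    """Disposition after a positive test: 'palliate' | 'resect' | 'surveil'."""
    stage = int(detected_stage)
    if stage == Stage.PRECLIN_III_IV:
        return "palliate"
    if stage == Stage.NONE:
        p = mgmt.resect_prob_false_positive
    elif Stage.LGD <= stage <= Stage.PRECLIN_II:
        p = mgmt.resect_prob_given_positive[stage - 1]
    else:
        raise PolicyError(f"stage {Stage(stage)!r} cannot be managed as screen-positive")
    return "resect" if u < p else "surveil"


# ---------------------------------------------------------------------------
# Reference per-person walk (the event-by-event oracle)
# ---------------------------------------------------------------------------

@dataclass
class PersonCourse:
    """One person's latent unscreened timeline, as consumed by the walk."""

    other_death: float
    onset: float          # inf = never develops a lesion (before death)
    indolent: bool
    entry: np.ndarray     # latent entry ages LGD..preclinical III/IV (inf pad)
    dx_age: float         # latent clinical-diagnosis age (inf = never)
    dx_stage: int         # 0 or 4/5/6 (preclinical stage at diagnosis)
    pc_death: float       # latent cancer death age (inf = cured/undiagnosed)
    surv_u: float
    surv_t: float


def person_course(cohort, i: int) -> PersonCourse:
    return PersonCourse(
        other_death=float(cohort.other_death[i]), onset=float(cohort.onset[i]),
        indolent=bool(cohort.indolent[i]), entry=cohort.entry[i].copy(),
        dx_age=float(cohort.dx_age[i]), dx_stage=int(cohort.dx_stage[i]),
        pc_death=float(cohort.pc_death[i]), surv_u=float(cohort.surv_u[i]),
        surv_t=float(cohort.surv_t[i]))


@dataclass
class ScreenedHistory:
    """The person's history after screening is applied."""

    n_screen_tests: int = 0
    n_surveillance_tests: int = 0
    resections: np.ndarray = field(default_factory=lambda: np.zeros(6, dtype=np.int64))
    screen_dx: Optional[tuple] = None        # (age, preclinical stage 4/5/6)
    clinical_dx: Optional[tuple] = None      # (age, preclinical stage 4/5/6)
    final_death_age: float = INF
    death_cause: int = CAUSE_OTHER
    interval_cancer: bool = False
    interval_cancer_5y: bool = False
    first_negative_screen_age: float = math.nan
    events: list = field(default_factory=list)


def _stage_at(onset: float, entry: np.ndarray, age: float) -> int:
    if not (age >= onset):
        return 0
    stage = 0
    for k in range(6):
        if age >= entry[k]:
            stage = k + 1
    return stage


def simulate_screened_history(person: PersonCourse, policy: ScreeningPolicy,
                              chars: TestCharacteristics, mgmt: ManagementPolicy,
                              config: PathwayConfig,
                              stream: CounterStream) -> ScreenedHistory:
    """Walk one person through the screening state machine (reference engine).

    Deliberately written as a plain interpreted event loop; the compiled
    cohort engine must agree with it event by event given the same draws.
    """
    h = ScreenedHistory()
    od = person.other_death
    onset, indolent = person.onset, person.indolent
    entry = person.entry.copy()
    dx_age, dx_stage, pc_death = person.dx_age, person.dx_stage, person.pc_death
    surv_u, surv_t = person.surv_u, person.surv_t

    sched = screen_schedule(policy)
    i = 0
    in_surveillance = False
    surv_next = 0.0
    fp_streak = 0
    last_screen_negative = False
    last_neg_age = math.nan
    h.final_death_age = od
    exited = False
    resect_prob = mgmt.resect_prob_vector()
    sens = chars.sensitivity
    one_minus_spec = 1.0 - chars.specificity

    def record_clinical_dx():
        h.clinical_dx = (dx_age, dx_stage)
        if pc_death < od:
            h.final_death_age = pc_death
            h.death_cause = CAUSE_PC
        if h.n_screen_tests > 0 and last_screen_negative:
            h.interval_cancer = True
            if dx_age - last_neg_age <= 5.0:
                h.interval_cancer_5y = True
        h.events.append(("clinical_dx", dx_age, dx_stage))

    while True:
        if in_surveillance:
            a = surv_next
        else:
            if i >= len(sched):
                break
            a = sched[i]
        if dx_age < a and dx_age < od:
            record_clinical_dx()
            exited = True
            break
        if od <= a:
            break
        if not in_surveillance:
            i += 1
        stage = _stage_at(onset, entry, a)
        u = stream.next()
        positive = (u < one_minus_spec) if stage == 0 else (u < sens[stage - 1])
        if in_surveillance:
            h.n_surveillance_tests += 1
            h.events.append(("surveillance_test", a, stage))
        else:
            h.n_screen_tests += 1
            h.events.append(("screen_test", a, stage))
            last_screen_negative = not positive
            if not positive:
                last_neg_age = a
                if math.isnan(h.first_negative_screen_age):
                    h.first_negative_screen_age = a

        if not positive:
            if in_surveillance:
                if stage == 0:
                    fp_streak += 1
                    if fp_streak >= mgmt.false_positive_surveillance_rounds:
                        in_surveillance = False
                        while i < len(sched) and sched[i] <= a:
                            i += 1
                    else:
                        surv_next = a + policy.surveillance_interval
                else:
                    surv_next = a + policy.surveillance_interval
            continue

        # --- positive test ---
        if stage == Stage.PRECLIN_III_IV:
            h.screen_dx = (a, 6)
            h.events.append(("palliate", a, 6))
            pc = a + 5.0 * (1.0 - surv_t)
            if pc < od:
                h.final_death_age = pc
                h.death_cause = CAUSE_PC
            exited = True
            break
        u2 = stream.next()
        if u2 < resect_prob[stage]:
            h.resections[stage] += 1
            h.events.append(("resection", a, stage))
            u3 = stream.next()
            if u3 < mgmt.surgical_mortality:
                h.final_death_age = a
                h.death_cause = CAUSE_SURGICAL
                h.events.append(("surgical_death", a, stage))
                exited = True
                break
            if stage in (4, 5):  # screen-detected cancer stage I/II
                h.screen_dx = (a, stage)
                s5 = config.five_year_survival[stage - 4]
                if not (surv_u < s5):
                    pc = a + 5.0 * (1.0 - surv_t)
                    if pc < od:
                        h.final_death_age = pc
                        h.death_cause = CAUSE_PC
                exited = True
                break
            # preinvasive lesion removed (or wrongful resection of a healthy
            # pancreas): back to routine screening, at risk of a new lesion
            if stage != 0:
                onset, dx_age, dx_stage, pc_death = INF, INF, 0, INF
                entry = np.full(6, INF)
                u4 = stream.next()
                new_onset = sample_onset_age_conditional(config, a, u4)
                if new_onset < od:
                    onset = new_onset
                    uf = stream.next()
                    indolent = uf < config.indolent_fraction
                    v = stream.next()
                    det_u = np.empty(3)
                    det_w = np.empty(3)
                    for j in range(3):
                        det_u[j] = stream.next()
                        det_w[j] = stream.next()
                    us = stream.next()
                    ts = stream.next()
                    entry, dx_age, dx_stage, pc_death = _lesion_timeline(
                        config, new_onset, indolent, v, det_u, det_w, us, ts)
                    surv_u, surv_t = us, ts
                    h.events.append(("re_onset", new_onset, 1))
            in_surveillance = False
            fp_streak = 0
            while i < len(sched) and sched[i] <= a:
                i += 1
        else:
            in_surveillance = True
            fp_streak = 0
            surv_next = a + policy.surveillance_interval
            h.events.append(("to_surveillance", a, stage))

    if not exited and dx_age < od:
        record_clinical_dx()
    return h


def load_screening_config(source):
    """Read (ScreeningPolicy, TestCharacteristics, ManagementPolicy) from YAML.

    Recognized top-level keys: ``policy``, ``test``, ``management``; each is
    optional and maps onto the corresponding dataclass fields.
    """
    import yaml

    if hasattr(source, "read"):
        raw = yaml.safe_load(source) or {}
    else:
        with open(source) as fh:
            raw = yaml.safe_load(fh) or {}
    pol = ScreeningPolicy(**raw.get("policy", {}))
    test = raw.get("test", {})
    if "sensitivity" in test:
        test["sensitivity"] = tuple(test["sensitivity"])
    chars = TestCharacteristics(**test)
    m = raw.get("management", {})
    if "resect_prob_given_positive" in m:
        m["resect_prob_given_positive"] = tuple(m["resect_prob_given_positive"])
    return pol, chars, ManagementPolicy(**m)


def event_log_frame(cohort, policy: ScreeningPolicy, chars: TestCharacteristics,
                    mgmt: ManagementPolicy, config: PathwayConfig, seed: int,
                    persons=None):
    """Per-person screening event log as a DataFrame.

    Replays the reference walk for the requested persons (default: all) with
    the same counter streams as the production engine, so the log describes
    exactly what the engine simulated.  Columns: person_id, event_type, age,
    stage.
    """
    import pandas as pd

    rows = []
    idx = range(cohort.n) if persons is None else persons
    for i in idx:
        h = simulate_screened_history(person_course(cohort, i), policy, chars,
                                      mgmt, config, CounterStream(seed, i))
        rows.extend((i, ev, age, stage) for ev, age, stage in h.events)
    return pd.DataFrame(rows, columns=["person_id", "event_type", "age", "stage"])
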